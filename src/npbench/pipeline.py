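"""End-to-end run orchestration: config validation, stage execution,
and reproducibility manifests.

A run is driven by one YAML config and one root seed.  The root seed fans
out into named per-stage substreams (see :mod:`npbench.synthetic`), so
inserting a stage never shifts another stage's randomness.  Every output
file is hashed into the run manifest, making a run reproducible and
diffable bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .benchmarking import benchmark_matrix, prioritize, reports_to_frame
from .consistency import all_pairs_consistency
from .efficacy import score_all_pairs
from .io import (
    write_known_associations,
    write_ppi,
    write_tripartite,
)
from .model import KnownAssociations
from .synthetic import ConfigError, SyntheticConfig, generate_all
from .target_scoring import DampingParams, grid_search_damping, score_table

logger = logging.getLogger("npbench")

ALL_STAGES = ("generate", "consistency", "targets", "grid", "predict", "evaluate")


@dataclass
class MethodConfig:
    w_hc: float = 1.0
    w_ct: float = 0.4
    grid_w_hc: list = field(default_factory=lambda: [0.0, 0.5, 1.0])
    grid_w_ct: list = field(default_factory=lambda: [0.0, 0.2, 0.4, 0.8])
    threshold: float = 0.4
    alpha: float = 0.85
    epsilon: float = 1e-6
    n_perm: int = 1000
    efficacy_method: str = "msi"
    consistency_level: str = "herb"


@dataclass
class RunConfig:
    out_dir: str = "npbench_run"
    seed: int = 0
    verbosity: str = "info"
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    methods: MethodConfig = field(default_factory=MethodConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _check_keys(given: dict, allowed: list[str], where: str, errors: list[str]):
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            msg = f"unknown key {where}{key!r}"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            errors.append(msg)


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config.

    Unknown keys are rejected with a nearest-key suggestion; all schema
    violations are aggregated into one error message.  Defaults are
    logged.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    top_allowed = [f.name for f in dataclasses.fields(RunConfig)]
    _check_keys(raw, top_allowed, "", errors)

    syn_raw = raw.get("synthetic", {}) or {}
    syn_allowed = [f.name for f in dataclasses.fields(SyntheticConfig)]
    if isinstance(syn_raw, dict):
        _check_keys(syn_raw, syn_allowed, "synthetic.", errors)
    else:
        errors.append("synthetic: must be a mapping")

    m_raw = raw.get("methods", {}) or {}
    m_allowed = [f.name for f in dataclasses.fields(MethodConfig)]
    if isinstance(m_raw, dict):
        _check_keys(m_raw, m_allowed, "methods.", errors)
    else:
        errors.append("methods: must be a mapping")

    stages = raw.get("stages", list(ALL_STAGES))
    for s in stages if isinstance(stages, list) else [stages]:
        if s not in ALL_STAGES:
            hint = difflib.get_close_matches(str(s), ALL_STAGES, n=1)
            msg = f"unknown stage {s!r}"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            errors.append(msg)

    cfg = None
    if not errors:
        try:
            syn_kwargs = dict(syn_raw)
            if "seed" not in syn_kwargs:
                syn_kwargs["seed"] = int(raw.get("seed", 0))
            cfg = RunConfig(
                out_dir=str(raw.get("out_dir", "npbench_run")),
                seed=int(raw.get("seed", 0)),
                verbosity=str(raw.get("verbosity", "info")),
                stages=list(stages) if isinstance(stages, list) else [stages],
                synthetic=SyntheticConfig(**syn_kwargs),
                methods=MethodConfig(**m_raw),
            )
        except (ConfigError, TypeError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigError(f"invalid config {path}:\n  " + "\n  ".join(errors))
    defaults = RunConfig()
    for f in dataclasses.fields(RunConfig):
        if getattr(cfg, f.name) == getattr(defaults, f.name) and f.name not in raw:
            logger.debug("config default: %s = %r", f.name, getattr(cfg, f.name))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages_run: list = field(default_factory=list)
    file_hashes: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    wall_time_s: float = 0.0
    failed_stage: Optional[str] = None

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                  sort_keys=True, default=str),
                       encoding="utf-8")
        tmp.replace(path)  # atomic on POSIX


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def write_fixture_set(dataset, out: Path) -> list[Path]:
    """Write a generated dataset in the standard TSV dialects plus
    ground_truth.json."""
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for db in dataset.databases:
        d = out / db.db_label
        d.mkdir(exist_ok=True)
        write_tripartite(db, d / "herb_compound.tsv", d / "compound_target.tsv")
        written += [d / "herb_compound.tsv", d / "compound_target.tsv"]
    write_tripartite(dataset.truth.latent, out / "latent_herb_compound.tsv",
                     out / "latent_compound_target.tsv")
    written += [out / "latent_herb_compound.tsv", out / "latent_compound_target.tsv"]
    write_ppi(dataset.ppi, out / "ppi.tsv")
    written.append(out / "ppi.tsv")
    write_known_associations(dataset.truth.known,
                             ht_path=out / "known_herb_target.tsv",
                             ct_path=out / "known_compound_target.tsv",
                             dp_path=out / "known_disease_protein.tsv")
    written += [out / "known_herb_target.tsv", out / "known_compound_target.tsv",
                out / "known_disease_protein.tsv"]

    nodes_path, edges_path = out / "msi_nodes.tsv", out / "msi_edges.tsv"
    with nodes_path.open("w", encoding="utf-8") as fh:
        fh.write("node_id\tnode_type\n")
        for node in dataset.msi.nodes:
            fh.write(f"{node.value}\t{dataset.msi.node_type[node]}\n")
    with edges_path.open("w", encoding="utf-8") as fh:
        fh.write("src\tdst\tedge_type\tweight\n")
        for src, dst, etype in dataset.msi.edges():
            fh.write(f"{src.value}\t{dst.value}\t{etype}\t1.0\n")
    written += [nodes_path, edges_path]

    truth = {
        "disease_modules": {d.value: sorted(t.value for t in m)
                            for d, m in dataset.truth.disease_modules.items()},
        "treatment_targets": {e.value: sorted(t.value for t in m)
                              for e, m in dataset.truth.treatment_targets.items()},
        "provenance": [
            {f"{layer}:{a.value}->{b.value}": flag
             for (layer, (a, b)), flag in prov.items()}
            for prov in dataset.truth.provenance
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1,
                                                      sort_keys=True),
                                           encoding="utf-8")
    written.append(out / "ground_truth.json")
    return written


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the requested stages in dependency order.

    A stage failure halts downstream stages; outputs of completed stages
    are retained and the manifest records the failing stage.
    """
    start = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), version=__version__,
                           seed=cfg.seed)
    written: list[Path] = []
    dataset = None

    def record(paths):
        for p in paths:
            manifest.file_hashes[str(p.relative_to(out))] = _sha256(p)

    try:
        for stage in ALL_STAGES:
            if stage not in cfg.stages:
                continue
            if stage == "generate":
                dataset = generate_all(cfg.synthetic)
                paths = write_fixture_set(dataset, out / "fixtures")
                record(paths)
            else:
                if dataset is None:
                    dataset = generate_all(cfg.synthetic)
                if stage == "consistency":
                    import pandas as pd
                    frames = []
                    for level in ("herb", "compound"):
                        for rep in all_pairs_consistency(dataset.databases,
                                                         level=level):
                            df = rep.rows.copy()
                            df.insert(0, "db_b", rep.db_pair[1])
                            df.insert(0, "db_a", rep.db_pair[0])
                            df.insert(0, "level", level)
                            frames.append(df)
                    full = pd.concat(frames, ignore_index=True)
                    path = out / "consistency.tsv"
                    full.to_csv(path, sep="\t", index=False)
                    record([path])
                elif stage == "targets":
                    import pandas as pd
                    params = DampingParams(cfg.methods.w_hc, cfg.methods.w_ct)
                    frames = []
                    for db in dataset.databases:
                        for h in sorted(db.herbs):
                            df = score_table(db, h, params=params,
                                             threshold=cfg.methods.threshold)
                            df.insert(0, "db", db.db_label)
                            frames.append(df)
                    path = out / "target_scores.tsv"
                    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t",
                                                                index=False)
                    record([path])
                elif stage == "grid":
                    grid = [DampingParams(a, b)
                            for a in cfg.methods.grid_w_hc
                            for b in cfg.methods.grid_w_ct]
                    surface = grid_search_damping(dataset.databases[0],
                                                  dataset.truth.known, grid)
                    path = out / "damping_surface.tsv"
                    surface.to_csv(path, sep="\t", index=False)
                    record([path])
                elif stage == "predict":
                    entity_targets = {e: set(m) for e, m
                                      in dataset.truth.treatment_targets.items()}
                    diseases = {d: set(m) for d, m
                                in dataset.truth.disease_modules.items()}
                    scores = score_all_pairs(
                        entity_targets, diseases,
                        method=cfg.methods.efficacy_method,
                        ppi=dataset.ppi, msi=dataset.msi,
                        alpha=cfg.methods.alpha, epsilon=cfg.methods.epsilon,
                        n_perm=cfg.methods.n_perm, seed=cfg.seed)
                    path = out / "efficacy_scores.tsv"
                    scores.to_csv(path, sep="\t", index=False)
                    ranked = prioritize(scores, top_n=10, known_pairs={
                        (f"TRT-{d.value}", d.value)
                        for d in dataset.truth.disease_modules})
                    rpath = out / "prioritized.tsv"
                    ranked.to_csv(rpath, sep="\t", index=False)
                    record([path, rpath])
                elif stage == "evaluate":
                    reports = benchmark_matrix(dataset.databases,
                                               dataset.truth.known,
                                               seed=cfg.seed)
                    path = out / "benchmark_matrix.tsv"
                    reports_to_frame(reports).to_csv(path, sep="\t", index=False)
                    record([path])
            manifest.stages_run.append(stage)
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.warnings.append(str(exc))
        manifest.wall_time_s = time.time() - start
        manifest.write(out / "manifest.json")
        raise StageError(stage, str(exc)) from exc

    manifest.wall_time_s = time.time() - start
    manifest.write(out / "manifest.json")
    return manifest
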