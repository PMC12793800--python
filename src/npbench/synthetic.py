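"""Synthetic generators for every input the pipeline consumes.

The live herbal network-pharmacology databases (TCMSP, TCM-mesh,
BATMAN-TCM, SymMap, HERB) cannot be redistributed or scraped here, so this
module generates pseudo-database ensembles with the statistical structure
the analyses assume: a latent "true" tripartite herb-compound-target
network with hub-skewed compound degrees, per-database Bernoulli edge
dropout and spurious additions, sparsely planted known-association labels,
a connected PPI with locally grown disease modules, and a multiscale
interactome (protein-function annotations over a rooted function
hierarchy).

Four named signal modes place the planted signal where one analysis method
should find it:

``hub_noise``
    spurious compound-target edges attach preferentially to hubs while
    known associations avoid hub-mediated paths — the regime in which
    degree damping (DWPC) should beat the raw path count;
``proximal``
    treatment target sets sit inside or adjacent to their disease module —
    the regime for network proximity;
``function_mediated``
    treatment targets share biological functions with the disease module
    while being distant in the PPI — the regime for diffusion profiles on
    the multiscale interactome;
``null``
    labels and treatment sets are uniform; no scorer should beat chance.

All randomness flows from one root seed through named child streams, so
adding a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import networkx as nx
import numpy as np

from .model import (
    EntityId,
    KnownAssociations,
    PpiGraph,
    TripartiteNetwork,
    compound,
    disease,
    herb,
    target,
)
from .efficacy import MultiscaleInteractome

logger = logging.getLogger("npbench")

SIGNAL_MODES = ("hub_noise", "proximal", "function_mediated", "null")


class ConfigError(ValueError):
    """An infeasible or invalid synthetic configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    Known-association densities default to the sparsity observed for
    curated labels in real herbal databases (~1.3% ingredient-target,
    ~3.8% herb-target).  ``ct_noise_factor`` scales the spurious-edge rate
    on the compound-target layer relative to the herb-compound layer,
    reflecting that target information (largely model-predicted in the
    real databases) diverges across sources far more than ingredient
    lists do.
    """

    n_herbs: int = 30
    n_compounds: int = 120
    n_targets: int = 200
    n_functions: int = 40
    n_diseases: int = 8
    hub_exponent: float = 1.0
    mean_compounds_per_herb: float = 8.0
    mean_targets_per_compound: float = 5.0
    n_databases: int = 5
    dropout_rate: float = 0.15
    spurious_rate: float = 0.1
    ct_noise_factor: float = 3.0
    known_ct_density: float = 0.013
    known_ht_density: float = 0.038
    disease_module_size: int = 12
    disease_locality: float = 0.8
    treatment_set_size: int = 8
    ppi_attachment: int = 3
    mean_annotations_per_protein: float = 1.0
    signal_mode: str = "hub_noise"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "spurious_rate", "known_ct_density",
                     "known_ht_density", "disease_locality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("n_herbs", "n_compounds", "n_targets", "n_functions",
                     "n_diseases", "n_databases", "disease_module_size",
                     "treatment_set_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.hub_exponent < 0 or self.ct_noise_factor < 0:
            raise ConfigError("hub_exponent and ct_noise_factor must be >= 0")
        if self.signal_mode not in SIGNAL_MODES:
            raise ConfigError(f"signal_mode must be one of {SIGNAL_MODES}")
        if self.mean_compounds_per_herb > self.n_compounds:
            raise ConfigError("mean_compounds_per_herb exceeds n_compounds")
        if self.mean_targets_per_compound > self.n_targets:
            raise ConfigError("mean_targets_per_compound exceeds n_targets")
        if self.disease_module_size > self.n_targets:
            raise ConfigError("disease_module_size exceeds n_targets")

    def to_dict(self) -> dict:
        return asdict(self)


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """A named child stream of the root seed.

    The stream name is hashed (crc32) into a spawn key, so each stage owns
    an independent, reproducible generator regardless of call order.
    """
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must rediscover."""

    latent: TripartiteNetwork
    known: Optional[KnownAssociations] = None
    disease_modules: dict[EntityId, set[EntityId]] = field(default_factory=dict)
    #: one dict per emitted pseudo-database: (layer, edge) -> "true" | "spurious"
    provenance: list[dict] = field(default_factory=list)
    treatment_targets: dict[EntityId, set[EntityId]] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    """The full fixture set for one configuration + seed."""

    config: SyntheticConfig
    truth: GroundTruth
    databases: list[TripartiteNetwork] = field(default_factory=list)
    ppi: Optional[PpiGraph] = None
    msi: Optional[MultiscaleInteractome] = None


# ---------------------------------------------------------------------------
# entity universes
# ---------------------------------------------------------------------------

def _herb_ids(n: int) -> list[EntityId]:
    return [herb(f"H{i:04d}") for i in range(n)]


def _compound_ids(n: int) -> list[EntityId]:
    return [compound(100001 + i) for i in range(n)]


def _target_ids(n: int) -> list[EntityId]:
    return [target(1001 + i) for i in range(n)]


def _disease_ids(n: int) -> list[EntityId]:
    return [disease(f"D{i:03d}") for i in range(n)]


def _weighted_distinct_choice(rng, weights: np.ndarray, k: int,
                              taken: set[int]) -> list[int]:
    """Draw k distinct indices with probability proportional to weights."""
    w = weights.astype(float).copy()
    if taken:
        w[list(taken)] = 0.0
    picked: list[int] = []
    for _ in range(k):
        total = w.sum()
        if total <= 0:
            break
        i = int(rng.choice(len(w), p=w / total))
        picked.append(i)
        w[i] = 0.0
    return picked


# ---------------------------------------------------------------------------
# latent tripartite network
# ---------------------------------------------------------------------------

def generate_latent_network(cfg: SyntheticConfig) -> TripartiteNetwork:
    """Sample the latent "true" tripartite network.

    Per herb, the compound count is 1 + Poisson(mean - 1) so every herb has
    at least one compound; compounds are drawn by preferential attachment
    with weight (current HC-degree + 1)**hub_exponent, producing a few
    promiscuous hub compounds and many herb-specific ones.  Every compound
    that appears in the HC layer then receives 1 + Poisson(mean - 1)
    targets, drawn the same way against target CT-degrees.
    """
    rng = child_rng(cfg.seed, "latent")
    herbs = _herb_ids(cfg.n_herbs)
    compounds = _compound_ids(cfg.n_compounds)
    targets = _target_ids(cfg.n_targets)

    hc_deg_c = np.zeros(cfg.n_compounds)
    hc_edges: set[tuple[EntityId, EntityId]] = set()
    for h in herbs:
        k = 1 + rng.poisson(max(cfg.mean_compounds_per_herb - 1.0, 0.0))
        k = min(k, cfg.n_compounds)
        w = (hc_deg_c + 1.0) ** cfg.hub_exponent
        for i in _weighted_distinct_choice(rng, w, k, set()):
            hc_edges.add((h, compounds[i]))
            hc_deg_c[i] += 1

    used = sorted({c for _, c in hc_edges})
    ct_deg_t = np.zeros(cfg.n_targets)
    ct_edges: set[tuple[EntityId, EntityId]] = set()
    for c in used:
        k = 1 + rng.poisson(max(cfg.mean_targets_per_compound - 1.0, 0.0))
        k = min(k, cfg.n_targets)
        w = (ct_deg_t + 1.0) ** cfg.hub_exponent
        for i in _weighted_distinct_choice(rng, w, k, set()):
            ct_edges.add((c, targets[i]))
            ct_deg_t[i] += 1

    return TripartiteNetwork(db_label="latent", hc_edges=hc_edges, ct_edges=ct_edges)


# ---------------------------------------------------------------------------
# pseudo-database ensemble
# ---------------------------------------------------------------------------

def _spurious_edges(rng, latent_edges, left_pool, right_pool, n_spurious,
                    hub_weighted, left_deg=None, right_deg=None, hub_exponent=1.0):
    """Sample distinct non-latent pairs, optionally hub-weighted."""
    if n_spurious <= 0:
        return set()
    latent = set(latent_edges)
    candidates = [(a, b) for a in left_pool for b in right_pool if (a, b) not in latent]
    if not candidates:
        return set()
    n_spurious = min(n_spurious, len(candidates))
    if hub_weighted:
        w = np.array([
            (left_deg.get(a, 0) + 1.0) ** hub_exponent
            * (right_deg.get(b, 0) + 1.0) ** hub_exponent
            for a, b in candidates
        ])
        p = w / w.sum()
    else:
        p = None
    idx = rng.choice(len(candidates), size=n_spurious, replace=False, p=p)
    return {candidates[i] for i in idx}


def emit_database_ensemble(
    latent: TripartiteNetwork, cfg: SyntheticConfig
) -> tuple[list[TripartiteNetwork], list[dict]]:
    """Emit the pseudo-database ensemble and per-edge provenance flags.

    Each database keeps each latent edge independently with probability
    1 - dropout_rate and adds spurious edges at spurious_rate (CT layer:
    spurious_rate * ct_noise_factor, capped at 1) relative to the latent
    layer size.  In ``hub_noise`` mode spurious CT edges attach
    preferentially to hub compounds and high-degree targets.
    """
    rng = child_rng(cfg.seed, "ensemble")
    spur_hc = cfg.spurious_rate
    spur_ct = min(1.0, cfg.spurious_rate * cfg.ct_noise_factor)
    hub_weighted = cfg.signal_mode == "hub_noise"

    deg_hc_c: dict[EntityId, int] = {}
    for _, c in latent.hc_edges:
        deg_hc_c[c] = deg_hc_c.get(c, 0) + 1
    deg_ct_c: dict[EntityId, int] = {}
    deg_ct_t: dict[EntityId, int] = {}
    for c, t in latent.ct_edges:
        deg_ct_c[c] = deg_ct_c.get(c, 0) + 1
        deg_ct_t[t] = deg_ct_t.get(t, 0) + 1

    herbs = sorted(latent.herbs)
    compounds = sorted(latent.compounds)
    targets = sorted(latent.targets)
    latent_hc = sorted(latent.hc_edges)
    latent_ct = sorted(latent.ct_edges)

    dbs: list[TripartiteNetwork] = []
    provenance: list[dict] = []
    for d in range(cfg.n_databases):
        keep_hc = rng.random(len(latent_hc)) >= cfg.dropout_rate
        keep_ct = rng.random(len(latent_ct)) >= cfg.dropout_rate
        hc = {e for e, keep in zip(latent_hc, keep_hc) if keep}
        ct = {e for e, keep in zip(latent_ct, keep_ct) if keep}

        n_sp_hc = rng.binomial(len(latent_hc), spur_hc)
        n_sp_ct = rng.binomial(len(latent_ct), spur_ct)
        sp_hc = _spurious_edges(rng, latent.hc_edges, herbs, compounds, n_sp_hc,
                                hub_weighted=False)
        sp_ct = _spurious_edges(rng, latent.ct_edges, compounds, targets, n_sp_ct,
                                hub_weighted=hub_weighted,
                                left_deg=deg_hc_c, right_deg=deg_ct_t,
                                hub_exponent=cfg.hub_exponent)
        flags = {("hc", e): "true" for e in hc}
        flags.update({("hc", e): "spurious" for e in sp_hc})
        flags.update({("ct", e): "true" for e in ct})
        flags.update({("ct", e): "spurious" for e in sp_ct})
        dbs.append(TripartiteNetwork(db_label=f"DB{d}", hc_edges=hc | sp_hc,
                                     ct_edges=ct | sp_ct))
        provenance.append(flags)
    return dbs, provenance


# ---------------------------------------------------------------------------
# known-association labels
# ---------------------------------------------------------------------------

def _metaedge_degrees(net: TripartiteNetwork):
    d_hc_h: dict[EntityId, int] = {}
    d_hc_c: dict[EntityId, int] = {}
    d_ct_c: dict[EntityId, int] = {}
    d_ct_t: dict[EntityId, int] = {}
    for h, c in net.hc_edges:
        d_hc_h[h] = d_hc_h.get(h, 0) + 1
        d_hc_c[c] = d_hc_c.get(c, 0) + 1
    for c, t in net.ct_edges:
        d_ct_c[c] = d_ct_c.get(c, 0) + 1
        d_ct_t[t] = d_ct_t.get(t, 0) + 1
    return d_hc_h, d_hc_c, d_ct_c, d_ct_t


def plant_known_associations(
    latent: TripartiteNetwork, cfg: SyntheticConfig
) -> KnownAssociations:
    """Plant sparse known-association labels on the latent network.

    Candidate compound-target labels are the latent CT edges; candidate
    herb-target labels are the metapath-reachable (herb, target) pairs.  In
    ``null`` mode each candidate is labeled Bernoulli(density).  In every
    other mode, labels fall preferentially on associations mediated by
    low-degree (specific) compounds — per-candidate probabilities are
    proportional to inverse metaedge-degree products, rescaled so the mean
    equals the configured density.
    """
    rng = child_rng(cfg.seed, "labels")
    d_hc_h, d_hc_c, d_ct_c, d_ct_t = _metaedge_degrees(latent)

    ct_candidates = sorted(latent.ct_edges)
    ht_weights: dict[tuple[EntityId, EntityId], float] = {}
    for h in sorted(latent.herbs):
        for c in sorted(latent.compounds_of(h)):
            for t in sorted(latent.targets_of(c)):
                w = 1.0 / (d_hc_h[h] * d_hc_c[c] * d_ct_c[c] * d_ct_t[t])
                ht_weights[(h, t)] = ht_weights.get((h, t), 0.0) + w
    ht_candidates = sorted(ht_weights)

    def draw(candidates, weights, density):
        if not candidates or density == 0.0:
            return set()
        if cfg.signal_mode == "null" or weights is None:
            keep = rng.random(len(candidates)) < density
        else:
            w = np.asarray(weights, dtype=float)
            p = np.clip(density * w / w.mean(), 0.0, 1.0)
            keep = rng.random(len(candidates)) < p
        return {candidates[i] for i in np.flatnonzero(keep)}

    ct_w = None
    if cfg.signal_mode != "null":
        ct_w = [1.0 / (d_ct_c[c] * d_ct_t[t]) for c, t in ct_candidates]
    ht_w = None
    if cfg.signal_mode != "null":
        ht_w = [ht_weights[p] for p in ht_candidates]

    return KnownAssociations(
        compound_target=draw(ct_candidates, ct_w, cfg.known_ct_density),
        herb_target=draw(ht_candidates, ht_w, cfg.known_ht_density),
    )


# ---------------------------------------------------------------------------
# PPI and disease modules
# ---------------------------------------------------------------------------

def generate_ppi_and_disease_modules(
    cfg: SyntheticConfig, targets: Optional[set[EntityId]] = None
) -> tuple[PpiGraph, dict[EntityId, set[EntityId]]]:
    """Connected background PPI plus locally grown disease modules.

    The PPI is a preferential-attachment (Barabási–Albert) graph over the
    target universe, giving the heavy-tailed degree distribution real
    interactomes show.  Each disease module grows from a random seed
    protein; each next member is a neighbor of the current members with
    probability ``disease_locality``, else a uniform random protein, so
    locality 1 forces a connected module and locality 0 a random set.
    """
    rng = child_rng(cfg.seed, "ppi")
    nodes = sorted(targets) if targets is not None else _target_ids(cfg.n_targets)
    n = len(nodes)
    m = min(cfg.ppi_attachment, max(1, n - 1))
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    order = rng.permutation(n)  # decorrelate hub identity from id order
    ppi = PpiGraph()
    for u in range(n):
        ppi.add_node(nodes[order[u]])
    for u, v in g.edges:
        ppi.add_edge(nodes[order[u]], nodes[order[v]])

    modules: dict[EntityId, set[EntityId]] = {}
    size = min(cfg.disease_module_size, n)
    for d in _disease_ids(cfg.n_diseases):
        members = {nodes[int(rng.integers(n))]}
        while len(members) < size:
            frontier = sorted(
                {nb for u in members for nb in ppi.neighbors(u)} - members
            )
            if frontier and rng.random() < cfg.disease_locality:
                members.add(frontier[int(rng.integers(len(frontier)))])
            else:
                rest = sorted(set(nodes) - members)
                members.add(rest[int(rng.integers(len(rest)))])
        modules[d] = members
    return ppi, modules


def _ppi_distances_from(ppi: PpiGraph, sources: set[EntityId]) -> dict[EntityId, int]:
    lengths = nx.multi_source_dijkstra_path_length(ppi.nx, sources, weight=None)
    return {k: int(v) for k, v in lengths.items()}


def plant_treatment_sets(
    cfg: SyntheticConfig,
    ppi: PpiGraph,
    modules: dict[EntityId, set[EntityId]],
) -> dict[EntityId, set[EntityId]]:
    """One planted treatment entity per disease, named TRT-<disease>.

    ``proximal`` mode samples the treatment targets from the disease module
    and its PPI neighborhood; ``function_mediated`` picks PPI-distant
    proteins (their shared functions are planted by the interactome
    generator); other modes sample uniformly.
    """
    rng = child_rng(cfg.seed, "treatments")
    nodes = sorted(ppi.nodes())
    out: dict[EntityId, set[EntityId]] = {}
    size = min(cfg.treatment_set_size, len(nodes))
    for d, module in sorted(modules.items(), key=lambda kv: kv[0]):
        ent = herb(f"TRT-{d.value}")
        if cfg.signal_mode == "proximal":
            pool = sorted(module | {nb for u in module for nb in ppi.neighbors(u)})
            idx = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
            chosen = {pool[i] for i in idx}
        elif cfg.signal_mode == "function_mediated":
            dist = _ppi_distances_from(ppi, module)
            ranked = sorted(nodes, key=lambda u: (-dist.get(u, 10**6), u))
            pool = ranked[: max(size * 4, size)]
            idx = rng.choice(len(pool), size=size, replace=False)
            chosen = {pool[i] for i in idx}
        else:
            idx = rng.choice(len(nodes), size=size, replace=False)
            chosen = {nodes[i] for i in idx}
        out[ent] = chosen
    return out


# ---------------------------------------------------------------------------
# multiscale interactome
# ---------------------------------------------------------------------------

def generate_multiscale_interactome(
    cfg: SyntheticConfig,
    ppi: PpiGraph,
    modules: Optional[dict[EntityId, set[EntityId]]] = None,
    treatments: Optional[dict[EntityId, set[EntityId]]] = None,
) -> MultiscaleInteractome:
    """Protein-function annotations over a rooted function hierarchy.

    The hierarchy is a random recursive tree over ``n_functions`` nodes
    (node i > 0 attaches to a uniform earlier node), emitted as paired
    hierarchy_up / hierarchy_down edges; each protein is annotated to a
    Poisson-distributed number of leaf functions.  In ``function_mediated``
    mode each disease gets a dedicated leaf function annotated to both its
    module proteins and its treatment's targets, creating a function-level
    bridge invisible to PPI-distance methods.
    """
    from .model import function as function_id

    rng = child_rng(cfg.seed, "msi")
    n_f = cfg.n_functions
    funcs = [function_id(f"F{i:04d}") for i in range(n_f)]
    parents = {0: None}
    children: dict[int, list[int]] = {i: [] for i in range(n_f)}
    for i in range(1, n_f):
        p = int(rng.integers(i))
        parents[i] = p
        children[p].append(i)
    leaves = [i for i in range(n_f) if not children[i]] or [0]

    msi = MultiscaleInteractome()
    proteins = sorted(ppi.nodes())
    for p in proteins:
        msi.add_node(p, "protein")
    for f in funcs:
        msi.add_node(f, "function")
    for u, v in sorted(ppi.edges()):
        msi.add_edge(u, v, "ppi")
        msi.add_edge(v, u, "ppi")
    for i in range(1, n_f):
        msi.add_edge(funcs[i], funcs[parents[i]], "hierarchy_up")
        msi.add_edge(funcs[parents[i]], funcs[i], "hierarchy_down")

    annotations: dict[EntityId, set[int]] = {p: set() for p in proteins}
    for p in proteins:
        k = rng.poisson(cfg.mean_annotations_per_protein)
        k = min(k, len(leaves))
        if k:
            idx = rng.choice(len(leaves), size=k, replace=False)
            annotations[p].update(leaves[i] for i in idx)

    if cfg.signal_mode == "function_mediated" and modules:
        free = [i for i in leaves]
        for d, module in sorted(modules.items(), key=lambda kv: kv[0]):
            if not free:
                break
            f_d = free.pop(int(rng.integers(len(free))))
            for p in sorted(module):
                annotations[p].add(f_d)
            ent = herb(f"TRT-{d.value}")
            if treatments and ent in treatments:
                for p in sorted(treatments[ent]):
                    annotations[p].add(f_d)

    for p in proteins:
        for i in sorted(annotations[p]):
            msi.add_edge(p, funcs[i], "protein_function")
            msi.add_edge(funcs[i], p, "function_protein")
    return msi


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_all(cfg: SyntheticConfig) -> SyntheticDataset:
    """Run every generator stage and assemble the full fixture set."""
    latent = generate_latent_network(cfg)
    dbs, provenance = emit_database_ensemble(latent, cfg)
    known = plant_known_associations(latent, cfg)
    ppi, modules = generate_ppi_and_disease_modules(cfg, latent.targets | set(_target_ids(cfg.n_targets)))
    treatments = plant_treatment_sets(cfg, ppi, modules)
    msi = generate_multiscale_interactome(cfg, ppi, modules, treatments)
    known.disease_protein = {d: set(m) for d, m in modules.items()}
    truth = GroundTruth(latent=latent, known=known, disease_modules=modules,
                        provenance=provenance, treatment_targets=treatments)
    return SyntheticDataset(config=cfg, truth=truth, databases=dbs, ppi=ppi, msi=msi)
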