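"""Key-target identification: centralities, path count, and DWPC.

The degree-weighted path count scores a (herb, target) pair by summing,
over every herb→compound→target path, a path degree product (PDP) that
penalizes promiscuous hubs: each of the four metaedge-specific degrees
along the path is raised to a negative damping exponent and the results
multiplied.  The two layers carry separate exponents,

    PDP = deg_HC(H)^(−w_HC) · deg_HC(C)^(−w_HC) · deg_CT(C)^(−w_CT) · deg_CT(T)^(−w_CT)
    DWPC(h, t) = Σ_{paths(h,t)} PDP,

so hub damping can be tuned independently for the herb-compound and
compound-target layers; (0, 0) recovers the raw path count exactly.
Degrees are metaedge-specific in the Himmelstein sense: a compound's
HC-degree counts the herbs containing it across the whole database, and
its CT-degree counts its targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import EntityId, KnownAssociations, PpiGraph, TripartiteNetwork

logger = logging.getLogger("npbench")


@dataclass(frozen=True)
class DampingParams:
    """Per-layer damping exponents (w_hc, w_ct), both >= 0."""

    w_hc: float
    w_ct: float

    def __post_init__(self) -> None:
        if self.w_hc < 0 or self.w_ct < 0:
            raise ValueError("damping exponents must be nonnegative")


# ---------------------------------------------------------------------------
# PPI centralities
# ---------------------------------------------------------------------------

def centralities(graph: PpiGraph) -> pd.DataFrame:
    """Degree, betweenness, and closeness per node, with percentile ranks.

    Formulas are the unnormalized textbook ones: degree = edge count;
    betweenness = Σ over unordered pairs s≠v≠t of σ_st(v)/σ_st; closeness
    = 1/Σ_u d(u, v).  Closeness is computed within the node's connected
    component (the distance sum is undefined across components); isolated
    nodes get closeness 0.  Percentiles are midrank/n.
    """
    g = graph.nx
    nodes = sorted(g.nodes)
    if not nodes:
        return pd.DataFrame(columns=["node", "degree", "betweenness", "closeness",
                                     "degree_pct", "betweenness_pct",
                                     "closeness_pct"]).set_index("node")
    deg = {v: g.degree(v) for v in nodes}
    btw = nx.betweenness_centrality(g, normalized=False)  # unordered pairs
    clo = {}
    n_components = nx.number_connected_components(g)
    if n_components > 1:
        logger.info("centralities: %d connected components; closeness computed "
                    "within components", n_components)
    for v in nodes:
        dist_sum = sum(nx.single_source_shortest_path_length(g, v).values())
        clo[v] = 1.0 / dist_sum if dist_sum > 0 else 0.0

    df = pd.DataFrame({
        "node": [v.value for v in nodes],
        "degree": [deg[v] for v in nodes],
        "betweenness": [btw[v] for v in nodes],
        "closeness": [clo[v] for v in nodes],
    }).set_index("node")
    n = len(df)
    for col in ("degree", "betweenness", "closeness"):
        df[f"{col}_pct"] = rankdata(df[col], method="average") / n
    return df


# ---------------------------------------------------------------------------
# path count and DWPC
# ---------------------------------------------------------------------------

def metaedge_degrees(net: TripartiteNetwork):
    """Per-node degrees on each metaedge layer of the tripartite network."""
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


def path_count(net: TripartiteNetwork, herb: EntityId) -> dict[EntityId, int]:
    """Number of distinct herb→compound→target paths per reachable target."""
    if herb not in net.herbs:
        raise KeyError(f"herb {herb} not present in {net.db_label}")
    counts: dict[EntityId, int] = {}
    for c in net.compounds_of(herb):
        for t in net.targets_of(c):
            counts[t] = counts.get(t, 0) + 1
    return counts


@dataclass
class _HerbPaths:
    """Cached per-path degree factors for one herb (for grid sweeps)."""

    targets: list[EntityId]
    target_idx: np.ndarray   # per path
    hc_factor: np.ndarray    # deg_HC(H) * deg_HC(C) per path
    ct_factor: np.ndarray    # deg_CT(C) * deg_CT(T) per path

    def dwpc(self, params: DampingParams) -> dict[EntityId, float]:
        pdp = self.hc_factor ** (-params.w_hc) * self.ct_factor ** (-params.w_ct)
        sums = np.bincount(self.target_idx, weights=pdp,
                           minlength=len(self.targets))
        return {t: float(s) for t, s in zip(self.targets, sums)}


def _herb_paths(net: TripartiteNetwork, herb: EntityId,
                degrees=None) -> _HerbPaths:
    if herb not in net.herbs:
        raise KeyError(f"herb {herb} not present in {net.db_label}")
    if degrees is None:
        degrees = metaedge_degrees(net)
    d_hc_h, d_hc_c, d_ct_c, d_ct_t = degrees
    targets: list[EntityId] = []
    t_index: dict[EntityId, int] = {}
    tidx, hcf, ctf = [], [], []
    for c in sorted(net.compounds_of(herb)):
        for t in sorted(net.targets_of(c)):
            if t not in t_index:
                t_index[t] = len(targets)
                targets.append(t)
            tidx.append(t_index[t])
            hcf.append(d_hc_h[herb] * d_hc_c[c])
            ctf.append(d_ct_c[c] * d_ct_t[t])
    return _HerbPaths(targets=targets,
                      target_idx=np.array(tidx, dtype=int),
                      hc_factor=np.array(hcf, dtype=float),
                      ct_factor=np.array(ctf, dtype=float))


def dwpc(net: TripartiteNetwork, herb: EntityId,
         params: DampingParams) -> dict[EntityId, float]:
    """Degree-weighted path count from one herb to every reachable target."""
    return _herb_paths(net, herb).dwpc(params)


def percentile_threshold(scores: dict[EntityId, float], threshold: float,
                         direction: str = "ge") -> set[EntityId]:
    """Targets whose within-herb midrank percentile is >= the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if direction != "ge":
        raise ValueError("only direction='ge' is defined")
    if not scores:
        raise ValueError("empty score mapping")
    items = sorted(scores.items())
    values = np.array([v for _, v in items], dtype=float)
    pct = rankdata(values, method="average") / len(values)
    return {t for (t, _), p in zip(items, pct) if p >= threshold}


def score_table(net: TripartiteNetwork, herb: EntityId,
                params: Optional[DampingParams] = None,
                threshold: Optional[float] = None) -> pd.DataFrame:
    """Per-target PC and DWPC with midrank percentiles for one herb."""
    params = params or DampingParams(0.0, 0.0)
    pc = path_count(net, herb)
    dw = dwpc(net, herb, params)
    targets = sorted(pc)
    df = pd.DataFrame({
        "herb": herb.value,
        "target": [t.value for t in targets],
        "path_count": [pc[t] for t in targets],
        "dwpc": [dw[t] for t in targets],
    })
    n = len(df)
    df["path_count_pct"] = rankdata(df["path_count"], method="average") / n
    df["dwpc_pct"] = rankdata(df["dwpc"], method="average") / n
    if threshold is not None:
        predicted = percentile_threshold(dw, threshold)
        df["predicted"] = [t in predicted for t in targets]
    return df


# ---------------------------------------------------------------------------
# damping grid search
# ---------------------------------------------------------------------------

def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Midrank Mann–Whitney AUROC (local copy to avoid a module cycle)."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores, method="average")
    u = ranks[labels.astype(bool)].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def grid_search_damping(
    net: TripartiteNetwork,
    known: KnownAssociations,
    grid: Sequence[DampingParams],
    herbs: Optional[Sequence[EntityId]] = None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Mean AUROC of DWPC against known herb-target labels over a grid.

    Per grid cell, each herb's reachable targets are scored and ranked
    against its known labels; herbs lacking either class are skipped
    (logged).  By default per-herb AUROCs are averaged so large herbs do
    not dominate; ``pooled=True`` ranks all (herb, target) pairs together.
    The result carries the argmax cell(s) — all ties — in ``df.attrs``.
    """
    if not grid:
        raise ValueError("empty damping grid")
    if herbs is None:
        herbs = sorted(net.herbs)
    known_ht = known.herb_target

    cached = []
    n_skipped = 0
    for h in herbs:
        paths = _herb_paths(net, h)
        labels = np.array([(h, t) in known_ht for t in paths.targets], dtype=float)
        if labels.size == 0 or labels.sum() == 0 or labels.sum() == labels.size:
            n_skipped += 1
            continue
        cached.append((h, paths, labels))
    if n_skipped:
        logger.info("grid_search_damping: skipped %d herbs lacking both classes",
                    n_skipped)
    if not cached:
        raise ValueError("no herb has both known and unknown reachable targets")

    rows = []
    for params in grid:
        per_herb = []
        pooled_scores, pooled_labels = [], []
        for h, paths, labels in cached:
            pdp = (paths.hc_factor ** (-params.w_hc)
                   * paths.ct_factor ** (-params.w_ct))
            scores = np.bincount(paths.target_idx, weights=pdp,
                                 minlength=len(paths.targets))
            if pooled:
                pooled_scores.append(scores)
                pooled_labels.append(labels)
            else:
                per_herb.append(_auroc(scores, labels))
        if pooled:
            mean_auroc = _auroc(np.concatenate(pooled_scores),
                                np.concatenate(pooled_labels))
        else:
            mean_auroc = float(np.mean(per_herb))
        rows.append({"w_hc": params.w_hc, "w_ct": params.w_ct,
                     "mean_auroc": mean_auroc, "n_herbs": len(cached)})
    df = pd.DataFrame(rows)
    best = df["mean_auroc"].max()
    df.attrs["argmax"] = [
        DampingParams(r.w_hc, r.w_ct)
        for r in df.itertuples() if r.mean_auroc == best
    ]
    return df
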