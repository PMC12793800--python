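"""Network-based therapeutic-effect prediction.

Three scorers for entity–disease association, each with a different
mechanistic premise:

* **protein overlap** — Jaccard similarity |T∩S| / |T∪S| between the drug
  target set T and the disease protein set S;
* **network proximity** — z-score of the average closest shortest-path
  distance d_c(S, T) = (1/|T|) Σ_t min_s d(s, t) against a null of
  degree-matched random sets (negative z ⇒ closer than chance);
* **multiscale-interactome diffusion** — restart random walks from the
  entity and from the disease over a directed protein + biological-function
  graph, compared by correlation distance of their stationary visitation
  profiles.

Ranking orientation is fixed once: higher score = more therapeutic
(Jaccard as-is, −z for proximity, 1 − correlation distance for diffusion),
so AUROC/AUPR are comparable across methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .model import EntityId, PpiGraph

logger = logging.getLogger("npbench")

NODE_TYPES = ("protein", "function", "virtual_entity")
EDGE_TYPES = ("ppi", "protein_function", "function_protein",
              "hierarchy_up", "hierarchy_down", "entity_target")

DEFAULT_EDGE_WEIGHTS = {t: 1.0 for t in EDGE_TYPES}


class UndefinedResultError(ValueError):
    """A score that is mathematically undefined for this input (reported,
    never coerced to a number)."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the tolerance within max_iterations."""


@dataclass
class ProteinSet:
    """A role-tagged set of protein (target) EntityIds."""

    role: str  # "drug_targets" | "disease_proteins"
    members: set[EntityId]

    def __post_init__(self) -> None:
        if self.role not in ("drug_targets", "disease_proteins"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class ProximityResult:
    d_c: float
    mu: float
    sigma: float
    z: float
    n_permutations: int
    seed: Optional[int]


@dataclass
class DiffusionProfile:
    entity: EntityId
    r: np.ndarray            # probability vector over msi.nodes ordering
    alpha: float
    epsilon: float
    iterations_used: int


# ---------------------------------------------------------------------------
# simple scorers
# ---------------------------------------------------------------------------

def protein_overlap(T: ProteinSet, S: ProteinSet) -> float:
    """Jaccard similarity of target and disease-protein sets."""
    if not T.members or not S.members:
        raise ValueError("protein_overlap requires non-empty sets")
    inter = len(T.members & S.members)
    union = len(T.members | S.members)
    return inter / union


# ---------------------------------------------------------------------------
# network proximity
# ---------------------------------------------------------------------------

def ppi_distance_matrix(ppi: PpiGraph) -> tuple[dict[EntityId, int], np.ndarray]:
    """All-pairs unweighted shortest-path distances (inf if unreachable)."""
    nodes = sorted(ppi.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for u, v in ppi.edges():
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    return index, dist


def _closest_distance_idx(t_idx: np.ndarray, s_idx: np.ndarray,
                          dist: np.ndarray) -> float:
    """d_c over index arrays; unreachable targets are excluded."""
    d = dist[np.ix_(t_idx, s_idx)].min(axis=1)
    finite = d[np.isfinite(d)]
    if finite.size == 0:
        raise UndefinedResultError("no drug target reachable from any disease protein")
    if finite.size < d.size:
        logger.debug("closest_distance: excluded %d unreachable targets",
                     d.size - finite.size)
    return float(finite.mean())


def closest_distance(
    T: ProteinSet, S: ProteinSet, ppi: PpiGraph,
    dist: Optional[tuple[dict, np.ndarray]] = None,
) -> float:
    """Average closest distance d_c(S, T) on the PPI.

    Targets absent from the PPI, or unreachable from every disease
    protein, are excluded from the average with a logged count.
    """
    if dist is None:
        dist = ppi_distance_matrix(ppi)
    index, matrix = dist
    t_idx = np.array([index[u] for u in T.members if u in index], dtype=int)
    s_idx = np.array([index[u] for u in S.members if u in index], dtype=int)
    n_missing = len(T.members) - t_idx.size
    if n_missing:
        logger.debug("closest_distance: %d targets absent from PPI", n_missing)
    if t_idx.size == 0 or s_idx.size == 0:
        raise UndefinedResultError("set does not intersect the PPI")
    return _closest_distance_idx(t_idx, s_idx, matrix)


def _degree_bins(ppi: PpiGraph, min_bin_size: int) -> dict[EntityId, np.ndarray]:
    """Logarithmic (log2) degree bins, merged upward until each holds at
    least min_bin_size nodes; returns node -> member array of its bin."""
    nodes = sorted(ppi.nodes())
    key = {u: ppi.degree(u).bit_length() for u in nodes}  # 0->0, 1->1, 2-3->2, ...
    by_bin: dict[int, list[EntityId]] = {}
    for u in nodes:
        by_bin.setdefault(key[u], []).append(u)
    merged: dict[int, int] = {}
    ks = sorted(by_bin)
    carry: list[EntityId] = []
    bins: dict[int, list[EntityId]] = {}
    for k in ks:
        members = carry + by_bin[k]
        if len(members) >= min_bin_size or k == ks[-1]:
            bins[k] = members
            carry = []
        else:
            carry = members
    if carry:  # topmost underfull bin merges down into the last full one
        if bins:
            bins[max(bins)] += carry
        else:
            bins[ks[-1]] = carry
    node_bin: dict[EntityId, np.ndarray] = {}
    for k, members in bins.items():
        arr = np.array(sorted(members), dtype=object)
        for u in members:
            node_bin[u] = arr
    return node_bin


def degree_matched_sets(
    ppi: PpiGraph, template: ProteinSet, n: int,
    seed: Optional[int] = None, min_bin_size: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> list[set[EntityId]]:
    """n random node sets matching the size and degree profile of template.

    Each member is drawn from the (merged log2) degree bin of the
    corresponding template member, without replacement within a set.
    """
    if len(template.members) > len(ppi):
        raise ValueError("template larger than the graph")
    if rng is None:
        rng = np.random.default_rng(seed)
    node_bin = _degree_bins(ppi, min_bin_size)
    members = sorted(template.members & ppi.nodes())
    all_nodes = np.array(sorted(ppi.nodes()), dtype=object)
    out: list[set[EntityId]] = []
    for _ in range(n):
        chosen: set[EntityId] = set()
        for u in members:
            pool = node_bin[u]
            pick = None
            for _attempt in range(30):
                cand = pool[int(rng.integers(len(pool)))]
                if cand not in chosen:
                    pick = cand
                    break
            if pick is None:  # bin exhausted; fall back to any free node
                free = [v for v in all_nodes if v not in chosen]
                pick = free[int(rng.integers(len(free)))]
            chosen.add(pick)
        out.append(chosen)
    return out


def network_proximity(
    T: ProteinSet, S: ProteinSet, ppi: PpiGraph,
    n_perm: int = 1000, seed: Optional[int] = None,
    min_bin_size: int = 10,
    dist: Optional[tuple[dict, np.ndarray]] = None,
) -> ProximityResult:
    """Degree-matched permutation z-score of the average closest distance.

    Both S and T are randomized in the null.  Negative z means the drug
    targets sit closer to the disease proteins than degree-matched chance.
    The benchmarking ranking score is −z.
    """
    if dist is None:
        dist = ppi_distance_matrix(ppi)
    index, matrix = dist
    d_c = closest_distance(T, S, ppi, dist=dist)
    rng = np.random.default_rng(seed)
    null_T = degree_matched_sets(ppi, T, n_perm, min_bin_size=min_bin_size, rng=rng)
    null_S = degree_matched_sets(ppi, S, n_perm, min_bin_size=min_bin_size, rng=rng)
    null_d = []
    for Ti, Si in zip(null_T, null_S):
        t_idx = np.array([index[u] for u in Ti], dtype=int)
        s_idx = np.array([index[u] for u in Si], dtype=int)
        try:
            null_d.append(_closest_distance_idx(t_idx, s_idx, matrix))
        except UndefinedResultError:
            continue
    if len(null_d) < 2:
        raise UndefinedResultError("degenerate null: too few defined permutations")
    mu = float(np.mean(null_d))
    sigma = float(np.std(null_d, ddof=0))
    if sigma == 0.0:
        raise UndefinedResultError("degenerate null: zero variance")
    return ProximityResult(d_c=d_c, mu=mu, sigma=sigma, z=(d_c - mu) / sigma,
                           n_permutations=len(null_d), seed=seed)


# ---------------------------------------------------------------------------
# multiscale interactome + diffusion
# ---------------------------------------------------------------------------

class MultiscaleInteractome:
    """Directed, type-weighted graph of proteins and biological functions.

    Nodes are typed protein / function / virtual_entity; edges are typed
    (ppi in both directions, protein↔function annotations, hierarchy up and
    down, entity→target).  :meth:`build_transition_matrix` applies per-type
    scalar weights and row-normalizes to the biased transition matrix M;
    rows with zero out-weight form the dangling set J.
    """

    def __init__(self):
        self._nodes: list[EntityId] = []
        self._index: dict[EntityId, int] = {}
        self.node_type: dict[EntityId, str] = {}
        self._edges: list[tuple[int, int, str]] = []
        self.M: Optional[sp.csr_matrix] = None
        self.J: Optional[np.ndarray] = None  # bool mask of dangling rows
        self.weights: Optional[dict[str, float]] = None

    # -- construction -------------------------------------------------
    def add_node(self, node: EntityId, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        if node in self._index:
            return
        self._index[node] = len(self._nodes)
        self._nodes.append(node)
        self.node_type[node] = node_type

    def add_edge(self, src: EntityId, dst: EntityId, edge_type: str) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {edge_type!r}")
        for node in (src, dst):
            if node not in self._index:
                # namespace decides the implied type for convenience
                implied = ("protein" if node.namespace == "target"
                           else "function" if node.namespace == "function"
                           else "virtual_entity")
                self.add_node(node, implied)
        self._edges.append((self._index[src], self._index[dst], edge_type))
        self.M = None  # invalidate

    def attach_entity(self, entity: EntityId, targets: Iterable[EntityId]) -> None:
        """Embed an entity (drug/herb/disease) as a virtual node with
        directed edges to its targets."""
        self.add_node(entity, "virtual_entity")
        for t in sorted(set(targets)):
            if t in self._index:
                self.add_edge(entity, t, "entity_target")

    # -- views ---------------------------------------------------------
    @property
    def nodes(self) -> list[EntityId]:
        return list(self._nodes)

    def index_of(self, node: EntityId) -> int:
        return self._index[node]

    def edges(self) -> list[tuple[EntityId, EntityId, str]]:
        return [(self._nodes[a], self._nodes[b], t) for a, b, t in self._edges]

    def __len__(self) -> int:
        return len(self._nodes)


def build_transition_matrix(
    msi: MultiscaleInteractome,
    weights: Optional[dict[str, float]] = None,
) -> MultiscaleInteractome:
    """Populate M (row-stochastic biased transition matrix) and J.

    Each out-edge is scaled by its type weight and rows are normalized to
    sum to 1; rows with zero out-weight are recorded in the dangling set J.
    """
    w = dict(DEFAULT_EDGE_WEIGHTS)
    if weights:
        w.update(weights)
    for t, v in w.items():
        if v <= 0:
            raise ValueError(f"edge-type weight for {t!r} must be positive")
    n = len(msi)
    if msi._edges:
        rows, cols, vals = zip(*[(a, b, w[t]) for a, b, t in msi._edges])
        M = sp.csr_matrix((np.array(vals, float), (rows, cols)), shape=(n, n))
        M.sum_duplicates()
    else:
        M = sp.csr_matrix((n, n))
    out = np.asarray(M.sum(axis=1)).ravel()
    dangling = out == 0
    inv = np.where(dangling, 0.0, 1.0 / np.where(out == 0, 1.0, out))
    M = sp.diags(inv) @ M
    msi.M = sp.csr_matrix(M)
    msi.J = dangling
    msi.weights = w
    return msi


def diffusion_profile(
    entity_targets: ProteinSet,
    msi: MultiscaleInteractome,
    alpha: float = 0.85,
    epsilon: float = 1e-6,
    entity: Optional[EntityId] = None,
    restart: str = "virtual",
    max_iterations: int = 10_000,
) -> DiffusionProfile:
    """Restart random walk r(k+1) = (1−α)s + α(r(k)M + s Σ_{j∈J} r_j(k)).

    With ``restart="virtual"`` the entity must already be attached to the
    interactome as a virtual node (``entity`` names it) and s is its
    indicator; with ``restart="targets"`` s is uniform over the entity's
    targets and no virtual node is needed.  Dangling mass is redistributed
    through s, so Σr = 1 at every iterate.  Iteration stops when the L1
    change falls to ε or below.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if msi.M is None:
        build_transition_matrix(msi)
    n = len(msi)
    s = np.zeros(n)
    if restart == "virtual":
        if entity is None:
            raise ValueError("restart='virtual' requires the entity id")
        s[msi.index_of(entity)] = 1.0
    elif restart == "targets":
        idx = [msi.index_of(t) for t in sorted(entity_targets.members)
               if t in msi._index]
        if not idx:
            raise UndefinedResultError("no entity target present in the interactome")
        s[idx] = 1.0 / len(idx)
    else:
        raise ValueError(f"unknown restart mode {restart!r}")

    M, J = msi.M, msi.J
    r = s.copy()
    for k in range(1, max_iterations + 1):
        dangling_mass = float(r[J].sum()) if J.any() else 0.0
        r_next = (1.0 - alpha) * s + alpha * (r @ M + s * dangling_mass)
        residual = float(np.abs(r_next - r).sum())
        r = r_next
        if residual <= epsilon:
            return DiffusionProfile(entity=entity if entity is not None
                                    else EntityId("herb", "anonymous"),
                                    r=r, alpha=alpha, epsilon=epsilon,
                                    iterations_used=k)
    raise ConvergenceError(
        f"diffusion did not converge in {max_iterations} iterations "
        f"(last residual {residual:.3e})"
    )


def correlation_distance(rc: DiffusionProfile, rd: DiffusionProfile) -> float:
    """1 − centered cosine similarity of two diffusion profiles, in [0, 2]."""
    a = rc.r - rc.r.mean()
    b = rd.r - rd.r.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedResultError("constant diffusion profile: distance undefined")
    return float(1.0 - (a @ b) / (na * nb))


# ---------------------------------------------------------------------------
# all-pairs scoring
# ---------------------------------------------------------------------------

def score_all_pairs(
    entity_targets: dict[EntityId, set[EntityId]],
    disease_proteins: dict[EntityId, set[EntityId]],
    method: str,
    ppi: Optional[PpiGraph] = None,
    msi: Optional[MultiscaleInteractome] = None,
    alpha: float = 0.85,
    epsilon: float = 1e-6,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    min_bin_size: int = 10,
) -> pd.DataFrame:
    """Score every entity–disease pair with one method.

    Returns a dense table (entity, disease, method, score, raw_statistic,
    diagnostics, status).  Pairs whose score is undefined carry status
    "undefined" and a missing score, never a coerced number.
    """
    if method not in ("overlap", "proximity", "msi"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    dist = None
    profiles: dict[EntityId, DiffusionProfile] = {}
    if method == "proximity":
        if ppi is None:
            raise ValueError("proximity requires the PPI")
        dist = ppi_distance_matrix(ppi)
    if method == "msi":
        if msi is None:
            raise ValueError("msi method requires the interactome")
        for ent, tgts in sorted(entity_targets.items()):
            msi.attach_entity(ent, tgts)
        for dis, prots in sorted(disease_proteins.items()):
            msi.attach_entity(dis, prots)
        build_transition_matrix(msi, msi.weights)
        for node, tgts in sorted({**entity_targets, **disease_proteins}.items()):
            profiles[node] = diffusion_profile(
                ProteinSet("drug_targets", set(tgts)), msi,
                alpha=alpha, epsilon=epsilon, entity=node)

    for i, (ent, tgts) in enumerate(sorted(entity_targets.items())):
        for j, (dis, prots) in enumerate(sorted(disease_proteins.items())):
            status, score, raw, diag = "ok", None, None, ""
            try:
                if method == "overlap":
                    raw = protein_overlap(ProteinSet("drug_targets", set(tgts)),
                                          ProteinSet("disease_proteins", set(prots)))
                    score = raw
                elif method == "proximity":
                    pair_seed = None if seed is None else seed + 7919 * i + j
                    res = network_proximity(
                        ProteinSet("drug_targets", set(tgts)),
                        ProteinSet("disease_proteins", set(prots)),
                        ppi, n_perm=n_perm, seed=pair_seed,
                        min_bin_size=min_bin_size, dist=dist)
                    raw, score = res.d_c, -res.z
                    diag = f"z={res.z:.4f};mu={res.mu:.4f};sigma={res.sigma:.4f}"
                else:
                    d = correlation_distance(profiles[ent], profiles[dis])
                    raw, score = d, 1.0 - d
                    diag = (f"iters={profiles[ent].iterations_used}"
                            f"/{profiles[dis].iterations_used}")
            except UndefinedResultError as exc:
                status, diag = "undefined", str(exc)
            rows.append({"entity": ent.value, "disease": dis.value,
                         "method": method, "score": score,
                         "raw_statistic": raw, "diagnostics": diag,
                         "status": status})
    return pd.DataFrame(rows)
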