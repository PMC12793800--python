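"""Cross-database consistency via recall percentiles.

For one herb (or compound) present in two databases, its association set
in each database is encoded as a one-hot vector over a shared universe of
compounds (or targets).  The observed Pearson correlation between the two
vectors is then ranked against a reference distribution — the correlations
of the same query profile against every *other* eligible entity in the
second database.  The recall percentile is the fraction of reference
values strictly below the observed one: a calibrated measure of whether
the same entity looks more alike across databases than different entities
do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import EntityId, TripartiteNetwork

logger = logging.getLogger("npbench")


class UndefinedSimilarityError(ValueError):
    """Pearson correlation of a zero-variance profile is undefined."""


@dataclass
class OneHotProfile:
    """Presence/absence vector of one entity's associations in one database."""

    entity: EntityId
    db_label: str
    universe: tuple[EntityId, ...]
    bits: np.ndarray
    absent: bool = False  # entity missing from the database entirely

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.shape != (len(self.universe),):
            raise ValueError("bits length must equal universe length")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be exactly 0/1")

    @property
    def has_variance(self) -> bool:
        return 0 < int(self.bits.sum()) < self.bits.size


@dataclass
class ConsistencyReport:
    level: str
    db_pair: tuple[str, str]
    rows: pd.DataFrame  # entity, observed, recall, reference_n
    skipped: list[str] = field(default_factory=list)

    @property
    def summary(self) -> Optional[float]:
        """Fraction of entities with recall >= 0.95 (None if < 2 rows)."""
        if len(self.rows) < 2:
            return None
        return float((self.rows["recall"] >= 0.95).mean())


def _association_set(net: TripartiteNetwork, entity: EntityId, level: str):
    if level == "herb":
        return net.compounds_of(entity), entity in net.herbs
    if level == "compound":
        return net.targets_of(entity), entity in net.compounds
    raise ValueError(f"unknown level {level!r}")


def build_profile(
    entity: EntityId,
    network: TripartiteNetwork,
    level: str,
    universe: Sequence[EntityId],
) -> OneHotProfile:
    """One-hot profile of the entity's associations over a fixed universe.

    An entity absent from the network yields an all-zero profile flagged
    ``absent`` rather than an error.
    """
    assoc, present = _association_set(network, entity, level)
    bits = np.fromiter((1 if u in assoc else 0 for u in universe),
                       dtype=np.int8, count=len(universe))
    return OneHotProfile(entity=entity, db_label=network.db_label,
                         universe=tuple(universe), bits=bits, absent=not present)


def pearson_similarity(a: OneHotProfile, b: OneHotProfile) -> float:
    """Pearson correlation of two one-hot profiles on the same universe."""
    if a.universe != b.universe:
        raise ValueError("profiles must share an identically ordered universe")
    if len(a.universe) == 0:
        raise ValueError("empty universe")
    if not a.has_variance or not b.has_variance:
        raise UndefinedSimilarityError(
            f"zero-variance profile ({a.entity} or {b.entity})")
    return float(np.corrcoef(a.bits, b.bits)[0, 1])


def recall_percentile(observed: float, reference: Sequence[float],
                      ties: str = "strict") -> float:
    """Fraction of the reference distribution below the observed value.

    ``strict`` (default) counts only values strictly lower; ``midrank``
    counts ties as half.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    less = float((ref < observed).sum())
    if ties == "midrank":
        less += 0.5 * float((ref == observed).sum())
    elif ties != "strict":
        raise ValueError(f"unknown tie rule {ties!r}")
    return less / ref.size


def _profile_matrix(net: TripartiteNetwork, entities, level, universe):
    uni_index = {u: i for i, u in enumerate(universe)}
    mat = np.zeros((len(entities), len(universe)), dtype=np.int8)
    for r, e in enumerate(entities):
        assoc, _present = _association_set(net, e, level)
        for u in assoc:
            i = uni_index.get(u)
            if i is not None:
                mat[r, i] = 1
    return mat


def db_pair_consistency(
    dbA: TripartiteNetwork,
    dbB: TripartiteNetwork,
    level: str = "herb",
    entities: Optional[Sequence[EntityId]] = None,
    ties: str = "strict",
) -> ConsistencyReport:
    """Recall percentiles for every entity shared by two databases.

    For entity e: observed = Pearson(profile_A(e), profile_B(e)); the
    reference pool is Pearson(profile_A(e), profile_B(x)) over every other
    eligible x in dbB (eligible = nonzero-variance profile).  The universe
    is the union of the relevant entity sets across the two databases.
    Zero-variance entities are skipped and reported, never coerced.
    """
    if level == "herb":
        universe = tuple(sorted(dbA.compounds | dbB.compounds))
        pool_a, pool_b = dbA.herbs, dbB.herbs
    elif level == "compound":
        universe = tuple(sorted(dbA.targets | dbB.targets))
        pool_a, pool_b = dbA.compounds, dbB.compounds
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(universe) == 0:
        raise ValueError("empty universe: nothing to compare")

    if entities is None:
        entities = sorted(pool_a & pool_b)
    entities = list(entities)

    skipped: list[str] = []
    eligible_q = []
    for e in entities:
        if e not in pool_a or e not in pool_b:
            skipped.append(f"{e}: absent from one database")
        else:
            eligible_q.append(e)

    ref_entities = sorted(pool_b)
    A = _profile_matrix(dbA, eligible_q, level, universe).astype(float)
    B = _profile_matrix(dbB, ref_entities, level, universe).astype(float)

    def standardize(m):
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        ok = sd.ravel() > 0
        z = np.zeros_like(m)
        z[ok] = (m[ok] - mu[ok]) / sd[ok]
        return z, ok

    Az, a_ok = standardize(A)
    Bz, b_ok = standardize(B)
    corr = (Az @ Bz.T) / len(universe)
    b_index = {e: i for i, e in enumerate(ref_entities)}

    rows = []
    for r, e in enumerate(eligible_q):
        j = b_index[e]
        if not a_ok[r] or not b_ok[j]:
            skipped.append(f"{e}: zero-variance profile")
            continue
        observed = corr[r, j]
        ref_cols = [b_index[x] for x in ref_entities if x != e and b_ok[b_index[x]]]
        if not ref_cols:
            skipped.append(f"{e}: empty reference pool")
            continue
        reference = corr[r, ref_cols]
        rows.append({
            "entity": e.value,
            "observed": float(observed),
            "recall": recall_percentile(float(observed), reference, ties=ties),
            "reference_n": len(ref_cols),
        })
    if skipped:
        logger.info("db_pair_consistency[%s vs %s]: skipped %d entities",
                    dbA.db_label, dbB.db_label, len(skipped))
    report = ConsistencyReport(
        level=level, db_pair=(dbA.db_label, dbB.db_label),
        rows=pd.DataFrame(rows, columns=["entity", "observed", "recall",
                                         "reference_n"]),
        skipped=skipped)
    if len(report.rows) < 2:
        logger.warning("db_pair_consistency: fewer than 2 eligible entities; "
                       "summary undefined")
    return report


def all_pairs_consistency(
    dbs: Sequence[TripartiteNetwork], level: str = "herb", ties: str = "strict",
) -> list[ConsistencyReport]:
    """db_pair_consistency over every ordered pair of distinct databases."""
    reports = []
    for a in dbs:
        for b in dbs:
            if a.db_label == b.db_label:
                continue
            reports.append(db_pair_consistency(a, b, level=level, ties=ties))
    return reports
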