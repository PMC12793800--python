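"""Evaluation harness: confusion metrics, AUROC/AUPR, benchmark matrices,
and ranked prioritization tables.

Binary predictions are summarized by the Matthews correlation coefficient,
precision, and recall over an explicit candidate universe; a zero
denominator in the MCC (any empty marginal) is reported as 0 and flagged.
Because the source formulas print Coverage and Recall identically, this
module reports both an association-level recall (TP / (TP + FN)) and a
distinct entity-level coverage — the share of entities with at least one
recovered known association.  Continuous predictions are summarized by the
midrank (Mann–Whitney) AUROC and the descending-score step-curve AUPR with
ties processed as blocks.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import EntityId, KnownAssociations, TripartiteNetwork, merge_databases
from .target_scoring import DampingParams, _herb_paths

logger = logging.getLogger("npbench")


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. single-class AUROC)."""


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Metrics for one configuration cell; undefined values stay None."""

    config: dict = field(default_factory=dict)
    counts: Optional[ConfusionCounts] = None
    mcc: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    coverage: Optional[float] = None
    auroc: Optional[float] = None
    aupr: Optional[float] = None
    seed: Optional[int] = None
    notes: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = dict(self.config)
        row.update(mcc=self.mcc, precision=self.precision, recall=self.recall,
                   coverage=self.coverage, auroc=self.auroc, aupr=self.aupr,
                   notes=";".join(self.notes))
        if self.counts is not None:
            row.update(tp=self.counts.tp, tn=self.counts.tn,
                       fp=self.counts.fp, fn=self.counts.fn)
        return row


def mcc_from_counts(c: ConfusionCounts) -> tuple[float, bool]:
    """MCC per the standard formula; (0.0, True-flag) on a zero denominator."""
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0.0:
        return 0.0, True
    return (c.tp * c.tn - c.fp * c.fn) / denom, False


def confusion_metrics(
    predicted: set,
    known: set,
    universe: set,
    entity_of: Optional[Callable] = None,
) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts and binary metrics over an explicit universe.

    All scored-but-unknown pairs in the universe count as negatives.
    ``entity_of`` (e.g. ``lambda pair: pair[0]``) enables the entity-level
    coverage: the fraction of entities with at least one known association
    that have at least one true positive.
    """
    if not universe:
        raise ValueError("empty evaluation universe")
    if not predicted <= universe or not known <= universe:
        raise ValueError("predicted and known must be subsets of the universe")
    tp = len(predicted & known)
    fp = len(predicted - known)
    fn = len(known - predicted)
    tn = len(universe) - tp - fp - fn
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    mcc, degenerate = mcc_from_counts(counts)
    report = MetricsReport(counts=counts, mcc=mcc)
    if degenerate:
        report.notes.append("mcc_zero_denominator")
    report.precision = tp / (tp + fp) if (tp + fp) else None
    if report.precision is None:
        report.notes.append("precision_undefined_no_predictions")
    report.recall = tp / (tp + fn) if (tp + fn) else None
    if report.recall is None:
        report.notes.append("recall_undefined_no_known")
    if entity_of is not None:
        with_known = {entity_of(p) for p in known}
        if with_known:
            recovered = {entity_of(p) for p in predicted & known}
            report.coverage = len(recovered) / len(with_known)
        else:
            report.notes.append("coverage_undefined_no_known")
    report.notes.append("negatives=scored_unknown_pairs")
    return counts, report


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def _split(scores: Sequence[tuple[float, int]]):
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("scores must be (score, label) pairs")
    return arr[:, 0], arr[:, 1].astype(int)


def auroc(scores: Sequence[tuple[float, int]]) -> float:
    """Midrank AUROC: P(random positive outranks random negative), ties half."""
    s, y = _split(scores)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes")
    ranks = rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(scores: Sequence[tuple[float, int]]) -> float:
    """Area under the precision–recall step curve, descending scores,
    tie groups processed as blocks."""
    s, y = _split(scores)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPR needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    area = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = y.size
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(area)


# ---------------------------------------------------------------------------
# benchmark matrices
# ---------------------------------------------------------------------------

def _db_combinations(dbs: Sequence[TripartiteNetwork], modes: Sequence[str],
                     max_combo: int):
    for db in dbs:
        yield db, "single"
    for k in range(2, min(max_combo, len(dbs)) + 1):
        for subset in itertools.combinations(dbs, k):
            for mode in modes:
                yield merge_databases(list(subset), mode=mode, layer="both"), mode


def _recapitulation_cell(net: TripartiteNetwork, known: KnownAssociations,
                         config: dict) -> MetricsReport:
    """Binary recapitulation: the database's reachable herb-target pairs
    are the predictions; known pairs (including ones the database misses)
    are the labels."""
    predicted = {(h, t) for h in net.herbs for t in net.herb_targets(h)}
    known_ht = set(known.herb_target)
    universe = predicted | known_ht
    _counts, report = confusion_metrics(predicted, known_ht, universe,
                                        entity_of=lambda p: p[0])
    report.config = config
    return report


def _ranked_cell(net: TripartiteNetwork, known: KnownAssociations,
                 params: DampingParams, config: dict,
                 per_herb: bool = True) -> MetricsReport:
    """Ranked evaluation of DWPC (PC at (0,0)) against known labels."""
    report = MetricsReport(config=config)
    per_auroc, per_aupr = [], []
    pooled: list[tuple[float, int]] = []
    for h in sorted(net.herbs):
        paths = _herb_paths(net, h)
        if not paths.targets:
            continue
        labels = np.array([(h, t) in known.herb_target for t in paths.targets],
                          dtype=int)
        pdp = paths.hc_factor ** (-params.w_hc) * paths.ct_factor ** (-params.w_ct)
        scores = np.bincount(paths.target_idx, weights=pdp,
                             minlength=len(paths.targets))
        pairs = list(zip(scores.tolist(), labels.tolist()))
        if per_herb:
            if 0 < labels.sum() < labels.size:
                per_auroc.append(auroc(pairs))
                per_aupr.append(aupr(pairs))
        else:
            pooled.extend(pairs)
    try:
        if per_herb:
            if not per_auroc:
                raise UndefinedMetricError("no herb with both classes")
            report.auroc = float(np.mean(per_auroc))
            report.aupr = float(np.mean(per_aupr))
        else:
            report.auroc = auroc(pooled)
            report.aupr = aupr(pooled)
    except UndefinedMetricError as exc:
        report.notes.append(f"undefined:{exc}")
    return report


def benchmark_matrix(
    dbs: Sequence[TripartiteNetwork],
    known: KnownAssociations,
    methods: Sequence[str] = ("recapitulation", "pc", "dwpc"),
    combination_modes: Sequence[str] = ("union", "intersection"),
    max_combo: int = 2,
    dwpc_params: DampingParams = DampingParams(1.0, 0.4),
    per_herb: bool = True,
    seed: Optional[int] = None,
) -> list[MetricsReport]:
    """One MetricsReport per (database-combination, method) cell.

    Combinations enumerate all subsets up to ``max_combo`` under each
    requested mode, plus the singletons.  Cell-level failures are recorded
    in the report's notes and never abort the matrix.
    """
    reports: list[MetricsReport] = []
    for net, combo_mode in _db_combinations(dbs, combination_modes, max_combo):
        for method in methods:
            config = {"db": net.db_label, "combination": combo_mode,
                      "method": method}
            try:
                if method == "recapitulation":
                    rep = _recapitulation_cell(net, known, config)
                elif method == "pc":
                    rep = _ranked_cell(net, known, DampingParams(0.0, 0.0),
                                       config, per_herb=per_herb)
                elif method == "dwpc":
                    config = {**config, "w_hc": dwpc_params.w_hc,
                              "w_ct": dwpc_params.w_ct}
                    rep = _ranked_cell(net, known, dwpc_params, config,
                                       per_herb=per_herb)
                else:
                    raise ValueError(f"unknown method {method!r}")
            except (ValueError, UndefinedMetricError) as exc:
                rep = MetricsReport(config=config, notes=[f"failed:{exc}"])
            rep.seed = seed
            reports.append(rep)
    return reports


def reports_to_frame(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])


# ---------------------------------------------------------------------------
# prioritization
# ---------------------------------------------------------------------------

def prioritize(score_table: pd.DataFrame, top_n: int,
               known_pairs: Optional[set] = None) -> pd.DataFrame:
    """Top-n rows by descending score with a deterministic tie-break
    (score, then entity id, then disease id).  Undefined scores rank last.

    ``known_pairs`` (set of (entity_value, disease_value)) annotates each
    row with a ``known`` column.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    df = score_table.copy()
    df["_sort_score"] = df["score"].fillna(-np.inf)
    df = df.sort_values(["_sort_score", "entity", "disease"],
                        ascending=[False, True, True], kind="stable")
    df = df.drop(columns="_sort_score").head(top_n).reset_index(drop=True)
    if known_pairs is not None:
        df["known"] = [
            (e, d) in known_pairs for e, d in zip(df["entity"], df["disease"])
        ]
    return df
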