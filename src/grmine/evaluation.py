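"""ROC/AUC and confusion metrics with the GR-benchmark stratifications.

Strata mirror the standard benchmark layout: {all GR types, types seen in
training, held-out types} crossed with {all negatives, TF-only negatives}.
Metrics with empty denominators are reported as explicit ``None`` markers
rather than silent zeros or NaNs, since small strata can legitimately be
single-class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import TaxonomyLineage


@dataclass(frozen=True)
class MetricReport:
    """Confusion-matrix metrics plus AUC; ``None`` marks an undefined value."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    f1: float | None
    auc: float | None = None


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) statistic.

    Equals P(score_pos > score_neg) + 0.5 P(tie) over all positive-negative
    pairs. Requires at least one example of each class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    rank_sum = ranks[labels == 1].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> MetricReport:
    """Threshold scores (call = score >= threshold) and report Table-style metrics."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty input")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    accuracy = _ratio(tp + tn, tp + tn + fp + fn)
    if precision is None or sensitivity is None or (precision + sensitivity) == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, sensitivity=sensitivity,
        specificity=specificity, accuracy=accuracy, f1=f1,
    )


def auc_by_taxon(
    scores: Mapping[str, float],
    labels: Mapping[str, int],
    genome_of: Mapping[str, str],
    lineages: Mapping[str, TaxonomyLineage],
    rank: str,
) -> tuple[pd.DataFrame, int]:
    """Per-taxon AUC at a taxonomic rank.

    Both classes are restricted to the taxon; taxa lacking either class are
    excluded. Proteins whose genome has no lineage are skipped and counted.
    Returns (table with columns taxon/n_pos/n_neg/auc, n_skipped).
    """
    probe = TaxonomyLineage("probe")
    probe.rank(rank)  # raises on unknown rank
    groups: dict[str, list[tuple[float, int]]] = {}
    skipped = 0
    for pid, score in scores.items():
        genome = genome_of.get(pid)
        lin = lineages.get(genome) if genome is not None else None
        if lin is None:
            skipped += 1
            continue
        groups.setdefault(lin.rank(rank), []).append((score, labels[pid]))
    rows = []
    for taxon in sorted(groups):
        vals = groups[taxon]
        ss = np.array([v[0] for v in vals])
        yy = np.array([v[1] for v in vals])
        n_pos, n_neg = int((yy == 1).sum()), int((yy == 0).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        rows.append(dict(taxon=taxon, n_pos=n_pos, n_neg=n_neg, auc=roc_auc(ss, yy)))
    return pd.DataFrame(rows, columns=["taxon", "n_pos", "n_neg", "auc"]), skipped


STRATUM_NAMES = (
    "all-all", "all-TF", "seen-all", "seen-TF", "holdout-all", "holdout-TF",
)


def stratified_report(
    scores: Mapping[str, float],
    labels: Mapping[str, str],
    held_out_types: Sequence[str],
    threshold: float = 0.5,
) -> dict[str, MetricReport]:
    """Six benchmark strata: {all, seen, held-out} x {all negatives, TF only}.

    ``labels`` maps protein id -> pipeline label (``gr:<type>``, ``tf``,
    ``other:<cat>``). Strata with a single class get a report whose AUC
    (and any metric with an empty denominator) is the undefined marker.
    """
    holdout = set(held_out_types)
    ids = sorted(scores)
    is_pos = {i: labels[i].startswith("gr:") for i in ids}
    is_holdout_pos = {
        i: is_pos[i] and labels[i][3:] in holdout for i in ids
    }
    is_tf = {i: labels[i] == "tf" for i in ids}

    def stratum(pos_filter, neg_filter) -> MetricReport:
        sel = [
            i for i in ids
            if (is_pos[i] and pos_filter(i)) or (not is_pos[i] and neg_filter(i))
        ]
        ss = np.array([scores[i] for i in sel])
        yy = np.array([1 if is_pos[i] else 0 for i in sel])
        if ss.size == 0 or yy.min() == yy.max():
            return MetricReport(0, 0, 0, 0, None, None, None, None, None, None)
        report = confusion_metrics(ss, yy, threshold)
        return MetricReport(**{**report.__dict__, "auc": roc_auc(ss, yy)})

    any_neg = lambda i: True
    tf_neg = lambda i: is_tf[i]
    return {
        "all-all": stratum(lambda i: True, any_neg),
        "all-TF": stratum(lambda i: True, tf_neg),
        "seen-all": stratum(lambda i: not is_holdout_pos[i], any_neg),
        "seen-TF": stratum(lambda i: not is_holdout_pos[i], tf_neg),
        "holdout-all": stratum(lambda i: is_holdout_pos[i], any_neg),
        "holdout-TF": stratum(lambda i: is_holdout_pos[i], tf_neg),
    }


def report_table(reports: Mapping[str, MetricReport]) -> pd.DataFrame:
    """Metric rows x stratum columns table (benchmark layout) for export."""
    metrics = ["precision", "sensitivity", "specificity", "accuracy", "f1", "auc"]
    data = {
        name: [getattr(rep, m) for m in metrics] for name, rep in reports.items()
    }
    return pd.DataFrame(data, index=metrics)
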