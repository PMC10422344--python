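"""Confusion-matrix metrics and soft-voting selection of the best augmenter.

Five metrics are derived from TP/TN/FP/FN counts: accuracy, precision,
recall, the F-score in its TP / (TP + (FP+FN)/2) form, and the negative
predictive value TN / (TN+FN).  Multiclass problems are scored one-vs-rest
per class and macro-averaged.  A voting table of per-augmenter metric rows is
aggregated either by the unweighted mean of the five metrics or by counting
per-metric wins; evaluation latency is reported but never votes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DegenerateInputError, UsageError

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "npv")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise UsageError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    npv: float | None
    latency_s: float | None = None
    variant: str | None = None
    undefined: dict[str, str] = field(default_factory=dict)

    def values(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d["latency_s"] = self.latency_s
        d["variant"] = self.variant
        if self.undefined:
            d["undefined"] = dict(self.undefined)
        return d


def confusion(y_true, y_pred, positive) -> ConfusionMatrix:
    """Count TP/TN/FP/FN treating ``positive`` as the positive class."""
    t = list(y_true)
    p = list(y_pred)
    if len(t) != len(p):
        raise UsageError(f"label lists differ in length: {len(t)} vs {len(p)}")
    if positive not in set(t) | set(p):
        raise UsageError(f"positive class {positive!r} absent from labels")
    tp = sum(1 for a, b in zip(t, p) if a == positive and b == positive)
    tn = sum(1 for a, b in zip(t, p) if a != positive and b != positive)
    fp = sum(1 for a, b in zip(t, p) if a != positive and b == positive)
    fn = sum(1 for a, b in zip(t, p) if a == positive and b != positive)
    return ConfusionMatrix(tp, tn, fp, fn)


def metrics(cm: ConfusionMatrix, variant: str | None = None) -> MetricReport:
    """Derive the five metrics; zero-denominator ratios come back as None
    with a reason, except the F-score which is 0 when TP=0 but FP+FN>0."""
    if cm.total == 0:
        raise DegenerateInputError("all-zero confusion matrix")
    undefined: dict[str, str] = {}

    def ratio(num, den, name):
        if den == 0:
            undefined[name] = f"denominator {den}: no samples in that margin"
            return None
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    if cm.tp + cm.fp + cm.fn == 0:
        undefined["f1"] = "no positives in truth or prediction"
        f1 = None
    else:
        f1 = cm.tp / (cm.tp + 0.5 * (cm.fp + cm.fn))
    npv = ratio(cm.tn, cm.tn + cm.fn, "npv")
    return MetricReport(accuracy, precision, recall, f1, npv,
                        variant=variant, undefined=undefined)


def macro_metrics(y_true, y_pred, classes=None, variant: str | None = None) -> MetricReport:
    """Macro-averaged one-vs-rest metrics over all classes present."""
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    if not classes:
        raise DataError("no classes to evaluate")
    reports = [metrics(confusion(y_true, y_pred, c)) for c in classes]
    out = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports]
        defined = [v for v in vals if v is not None]
        out[name] = float(np.mean(defined)) if defined else None
    return MetricReport(**out, variant=variant)


def timed_evaluate(model, variant: str, records, predict_fn=None) -> MetricReport:
    """Predict the test records, score them, and record wall-clock latency.

    ``predict_fn(model, records) -> (y_true, y_pred)`` defaults to the
    classifier module's manifest-based prediction.  Latency is informational
    (hardware-dependent) and excluded from all determinism contracts.
    """
    if not records:
        raise DataError("test set is empty")
    if predict_fn is None:
        from .classifier import predict_records
        predict_fn = predict_records
    t0 = time.perf_counter()
    y_true, y_pred = predict_fn(model, records)
    report = macro_metrics(y_true, y_pred, variant=variant)
    report.latency_s = time.perf_counter() - t0
    return report


# ---------------------------------------------------------------------------
# Soft voting
# ---------------------------------------------------------------------------


@dataclass
class VotingResult:
    winner: str
    rule: str
    rankings: dict[str, list[str]]           # per-rule ranked variant lists
    scores: dict[str, dict[str, float]]      # per-rule variant -> aggregate
    tie: bool = False

    def as_dict(self) -> dict:
        return {"winner": self.winner, "rule": self.rule,
                "rankings": self.rankings, "scores": self.scores, "tie": self.tie}


def soft_vote(table: list[MetricReport], rule: str = "mean-of-metrics") -> VotingResult:
    """Select the winning augmenter from a table of per-variant metric rows.

    ``mean-of-metrics`` ranks by the unweighted mean of the five metrics;
    ``metric-wise-wins`` ranks by the number of metrics on which a variant is
    strictly best.  Ties break by accuracy, then lexicographic variant name.
    Both rules' rankings are returned for audit; ``rule`` decides the winner.
    """
    if rule not in ("mean-of-metrics", "metric-wise-wins"):
        raise UsageError(f"unknown voting rule {rule!r}")
    if not table:
        raise UsageError("voting table is empty")
    names = [r.variant for r in table]
    if len(set(names)) != len(names) or any(n is None for n in names):
        raise UsageError("every row needs a unique variant tag")
    vals = {r.variant: {m: getattr(r, m) for m in METRIC_NAMES} for r in table}
    for v, row in vals.items():
        if any(val is None for val in row.values()):
            raise UsageError(f"variant {v} has undefined metrics; cannot vote")

    mean_scores = {v: float(np.mean([row[m] for m in METRIC_NAMES]))
                   for v, row in vals.items()}
    wins = {v: 0 for v in vals}
    for m in METRIC_NAMES:
        col = {v: vals[v][m] for v in vals}
        best = max(col.values())
        top = [v for v, x in col.items() if x == best]
        if len(top) == 1:
            wins[top[0]] += 1

    def order(score_map):
        return sorted(score_map,
                      key=lambda v: (-score_map[v], -vals[v]["accuracy"], v))

    rankings = {"mean-of-metrics": order(mean_scores),
                "metric-wise-wins": order(wins)}
    scores = {"mean-of-metrics": mean_scores,
              "metric-wise-wins": {v: float(w) for v, w in wins.items()}}
    ranked = rankings[rule]
    winner = ranked[0]
    score_map = mean_scores if rule == "mean-of-metrics" else wins
    tie = len(ranked) > 1 and score_map[ranked[0]] == score_map[ranked[1]]
    return VotingResult(winner=winner, rule=rule, rankings=rankings,
                        scores=scores, tie=tie)
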