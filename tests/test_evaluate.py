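"""Confusion counts, the five metrics, latency reports, and soft voting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ganaug.errors import DegenerateInputError, UsageError
from ganaug.evaluate import (ConfusionMatrix, MetricReport, confusion,
                             macro_metrics, metrics, soft_vote, timed_evaluate)

# Published per-augmenter metric table (percent): the soft-vote fixture.
TABLE_ROWS = {
    "pggan": (98.8, 98.45, 97.2, 98.11, 98.09),
    "dcgan": (97.24, 96.14, 95.15, 96.01, 96.55),
    "cyclegan": (96.18, 95.12, 95.88, 96.03, 95.77),
    "infogan": (92.15, 91.22, 91.99, 91.77, 91.05),
    "conditional": (90.24, 88.02, 90.14, 89.33, 89.09),
}


def report(variant, row):
    return MetricReport(*row, variant=variant)


def counting_oracle(y_true, y_pred, positive):
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            tp, fn = (tp + 1, fn) if p == positive else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if p == positive else (fp, tn + 1)
    return tp, tn, fp, fn


# ---------------------------------------------------------------------------
# confusion
# ---------------------------------------------------------------------------


def test_perfect_prediction_counts():
    y = ["pos"] * 5 + ["neg"] * 5
    cm = confusion(y, y, "pos")
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (5, 5, 0, 0)


def test_total_miss_counts():
    cm = confusion(["pos"] * 4, ["neg"] * 4, "pos")
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (0, 0, 0, 4)


def test_confusion_matches_counting_oracle(rng):
    for _ in range(20):
        y_t = rng.choice(["a", "b"], 20).tolist()
        y_p = rng.choice(["a", "b"], 20).tolist()
        cm = confusion(y_t, y_p, "a")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == counting_oracle(y_t, y_p, "a")
        assert cm.total == 20


def test_confusion_usage_errors():
    with pytest.raises(UsageError):
        confusion(["a"], ["a", "b"], "a")
    with pytest.raises(UsageError):
        confusion(["a"], ["a"], "zzz")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_perfect_classifier_scores_all_ones():
    r = metrics(ConfusionMatrix(5, 5, 0, 0))
    assert all(v == 1.0 for v in r.values().values())


def test_hand_computed_case():
    r = metrics(ConfusionMatrix(3, 2, 1, 2))
    assert r.accuracy == 0.625
    assert r.precision == 0.75
    assert r.recall == 0.6
    assert abs(r.f1 - 2 / 3) < 1e-9
    assert r.npv == 0.5


def test_no_positive_predictions():
    r = metrics(ConfusionMatrix(0, 4, 0, 0))
    assert r.precision is None and "precision" in r.undefined
    assert r.npv == 1.0 and r.accuracy == 1.0
    assert r.f1 is None  # no positives anywhere


def test_f1_zero_when_tp_zero_but_errors_exist():
    assert metrics(ConfusionMatrix(0, 3, 2, 1)).f1 == 0.0


def test_all_zero_matrix_degenerate():
    with pytest.raises(DegenerateInputError):
        metrics(ConfusionMatrix(0, 0, 0, 0))


def test_metrics_agree_with_counting_on_random_vectors(rng):
    """Formula implementation vs. independent per-sample tallies."""
    for _ in range(200):
        n = int(rng.integers(4, 30))
        y_t = rng.choice(["pos", "neg"], n).tolist()
        y_p = rng.choice(["pos", "neg"], n).tolist()
        tp, tn, fp, fn = counting_oracle(y_t, y_p, "pos")
        r = metrics(confusion(y_t, y_p, "pos"))
        assert r.accuracy == (tp + tn) / n
        if tp + fp:
            assert r.precision == tp / (tp + fp)
        if tp + fn:
            assert r.recall == tp / (tp + fn)
        if tp + fp + fn:
            assert r.f1 == tp / (tp + 0.5 * (fp + fn))
        if tn + fn:
            assert r.npv == tn / (tn + fn)


def test_accuracy_between_column_rates(rng):
    """Accuracy is a weighted mean of precision and NPV (the two prediction
    columns), so it must lie between them whenever both are defined."""
    for _ in range(100):
        tp, tn, fp, fn = (int(v) for v in rng.integers(0, 10, 4))
        cm = ConfusionMatrix(tp, tn, fp, fn)
        if cm.total == 0:
            continue
        r = metrics(cm)
        if r.precision is not None and r.npv is not None:
            lo, hi = sorted([r.precision, r.npv])
            assert lo - 1e-12 <= r.accuracy <= hi + 1e-12


@settings(derandomize=True, max_examples=100)
@given(st.tuples(st.integers(0, 50), st.integers(0, 50),
                 st.integers(0, 50), st.integers(0, 50)))
def test_metric_ranges_and_f1_rule_hold_for_any_counts(counts):
    tp, tn, fp, fn = counts
    cm = ConfusionMatrix(tp, tn, fp, fn)
    if cm.total == 0:
        return
    r = metrics(cm)
    for v in r.values().values():
        assert v is None or 0.0 <= v <= 1.0
    if tp == 0 and fp + fn > 0:
        assert r.f1 == 0.0


def test_macro_metrics_three_class(rng):
    y_t = rng.choice(["a", "b", "c"], 30).tolist()
    y_p = rng.choice(["a", "b", "c"], 30).tolist()
    r = macro_metrics(y_t, y_p)
    per = [metrics(confusion(y_t, y_p, c)) for c in ("a", "b", "c")]
    assert r.accuracy == pytest.approx(np.mean([p.accuracy for p in per]))


# ---------------------------------------------------------------------------
# timed evaluation
# ---------------------------------------------------------------------------


def test_timed_evaluate_composes_confusion_and_metrics():
    records = [("pos" if i % 3 else "neg") for i in range(10)]

    def fake_predict(model, recs):
        return list(recs), [("pos" if i % 2 else "neg") for i in range(10)]

    r1 = timed_evaluate(None, "dcgan", records, predict_fn=fake_predict)
    r2 = timed_evaluate(None, "dcgan", records, predict_fn=fake_predict)
    assert r1.latency_s > 0
    assert r1.values() == r2.values()  # metrics deterministic, latency not
    manual = macro_metrics(*fake_predict(None, records))
    assert r1.accuracy == manual.accuracy and r1.f1 == manual.f1


# ---------------------------------------------------------------------------
# soft voting
# ---------------------------------------------------------------------------


def table():
    return [report(v, row) for v, row in TABLE_ROWS.items()]


@pytest.mark.parametrize("rule", ["mean-of-metrics", "metric-wise-wins"])
def test_published_table_elects_pggan(rule):
    res = soft_vote(table(), rule)
    assert res.winner == "pggan"
    assert res.rankings[rule][0] == "pggan"
    assert not res.tie


def test_singleton_table():
    res = soft_vote([report("dcgan", TABLE_ROWS["dcgan"])])
    assert res.winner == "dcgan"


def test_identical_rows_tie_lexicographically():
    rows = [report("zeta", (90, 90, 90, 90, 90)),
            report("alpha", (90, 90, 90, 90, 90))]
    res = soft_vote(rows)
    assert res.winner == "alpha" and res.tie


def test_row_order_invariance_and_dominated_row_removal():
    res_fwd = soft_vote(table())
    res_rev = soft_vote(table()[::-1])
    assert res_fwd.winner == res_rev.winner
    assert res_fwd.rankings == res_rev.rankings
    # dropping a strictly dominated row must not change the winner
    rows = [r for r in table() if r.variant != "conditional"]
    assert soft_vote(rows).winner == res_fwd.winner


def test_empty_table_and_undefined_metrics_rejected():
    with pytest.raises(UsageError):
        soft_vote([])
    bad = MetricReport(0.9, None, 0.9, 0.9, 0.9, variant="x")
    with pytest.raises(UsageError):
        soft_vote([bad])
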