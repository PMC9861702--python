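"""Metric correctness against brute-force formulas, aggregation, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from synmoe.evaluation import (
    EvaluationReport,
    ScreenRule,
    aggregate_cv,
    classification_metrics,
    count_support,
    pairwise_score_correlation,
    regression_metrics,
    screen_candidates,
)


# -- regression metrics ----------------------------------------------------------

def test_regression_metrics_perfect_and_reversed():
    y = np.array([1.0, 2.0, 5.0, 3.0])
    m = regression_metrics(y, y)
    assert m == {"rmse": 0.0, "spearman": pytest.approx(1.0), "r2": pytest.approx(1.0)}
    rev = regression_metrics(y, -y)
    assert rev["spearman"] == pytest.approx(-1.0)


def test_regression_metrics_worked_rmse():
    m = regression_metrics([1.0, 2.0], [3.0, 5.0])
    assert m["rmse"] == pytest.approx(np.sqrt(6.5), abs=1e-12)


def test_regression_metrics_match_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(10):
        y = rng.normal(size=30)
        p = 0.7 * y + rng.normal(size=30)
        m = regression_metrics(y, p)
        assert m["rmse"] == pytest.approx(np.sqrt(np.mean((y - p) ** 2)), abs=1e-12)
        assert m["r2"] == pytest.approx(
            1 - np.sum((y - p) ** 2) / np.sum((y - y.mean()) ** 2), abs=1e-12)
        # Spearman via explicit average ranks and Pearson on them
        ry = stats.rankdata(y)
        rp = stats.rankdata(p)
        want = np.corrcoef(ry, rp)[0, 1]
        assert m["spearman"] == pytest.approx(want, abs=1e-10)


def test_regression_metrics_spearman_rank_formula_without_ties():
    rng = np.random.default_rng(1)
    y = rng.permutation(20).astype(float)
    p = rng.permutation(20).astype(float)
    d = stats.rankdata(y) - stats.rankdata(p)
    want = 1 - 6 * np.sum(d**2) / (20 * (20**2 - 1))
    assert regression_metrics(y, p)["spearman"] == pytest.approx(want, abs=1e-12)


def test_regression_metrics_handles_ties_via_average_ranks():
    y = np.array([1.0, 1.0, 2.0, 3.0])
    p = np.array([2.0, 2.0, 3.0, 1.0])
    ry, rp = stats.rankdata(y), stats.rankdata(p)
    want = np.corrcoef(ry, rp)[0, 1]
    assert regression_metrics(y, p)["spearman"] == pytest.approx(want, abs=1e-12)


@given(st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
@settings(derandomize=True, max_examples=30)
def test_spearman_invariant_under_increasing_transforms(scale, shift):
    rng = np.random.default_rng(7)
    y = rng.normal(size=25)
    p = rng.normal(size=25)
    base = regression_metrics(y, p)["spearman"]
    warped = regression_metrics(np.exp(scale * y + shift), scale * p + shift)["spearman"]
    assert warped == pytest.approx(base, abs=1e-10)


def test_regression_metrics_printed_denominator_variant():
    y = np.array([1.0, 2.0, 4.0])
    p = np.array([1.5, 2.5, 3.0])
    alt = regression_metrics(y, p, printed_denominator=True)["r2"]
    want = 1 - np.sum((y - p) ** 2) / np.sum((p - y.mean()) ** 2)
    assert alt == pytest.approx(want, abs=1e-12)


def test_regression_metrics_errors():
    with pytest.raises(ValueError, match="length"):
        regression_metrics([1, 2], [1, 2, 3])
    with pytest.raises(ValueError, match="variance"):
        regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        regression_metrics([1.0], [1.0])


# -- classification metrics --------------------------------------------------------

def test_classification_confusion_worked_example():
    # TP=2, FP=1, FN=1, TN=6 at cutoff 0.5
    labels = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
    probs = [0.9, 0.8, 0.1, 0.7, 0.2, 0.2, 0.3, 0.1, 0.05, 0.4]
    m = classification_metrics(labels, probs)
    assert m["precision"] == pytest.approx(2 / 3)
    assert m["recall"] == pytest.approx(2 / 3)
    assert m["f1"] == pytest.approx(2 / 3)
    assert m["accuracy"] == pytest.approx(0.8)


def test_perfect_separation_gives_unit_ranking_metrics():
    labels = [0, 0, 0, 1, 1]
    probs = [0.1, 0.2, 0.3, 0.8, 0.9]
    m = classification_metrics(labels, probs)
    assert m["auroc"] == pytest.approx(1.0)
    assert m["aupr"] == pytest.approx(1.0)


def test_constant_scores_give_half_auroc():
    m = classification_metrics([0, 1, 0, 1], [0.5] * 4)
    assert m["auroc"] == pytest.approx(0.5)


def _auroc_rank_statistic(labels, probs):
    """U-statistic AUROC: P(pos > neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def _aupr_step_curve(labels, probs):
    """Area under the precision-recall step curve: sum (R_i - R_{i-1}) P_i."""
    order = np.argsort(-np.asarray(probs), kind="stable")
    labels = np.asarray(labels)[order]
    probs_sorted = np.asarray(probs)[order]
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and probs_sorted[j] == probs_sorted[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def test_ranking_metrics_match_brute_force_with_and_without_ties():
    rng = np.random.default_rng(11)
    for tie_frac in (0.0, 0.5):
        for _ in range(5):
            labels = rng.integers(0, 2, 40)
            if labels.sum() in (0, 40):
                labels[0] = 1 - labels[0]
            probs = rng.random(40)
            if tie_frac:
                probs = np.round(probs * 4) / 4  # force many ties
            m = classification_metrics(labels, probs)
            assert m["auroc"] == pytest.approx(
                _auroc_rank_statistic(labels, probs), abs=1e-10)
            assert m["aupr"] == pytest.approx(
                _aupr_step_curve(labels, probs), abs=1e-10)


def test_f1_equals_precision_when_precision_equals_recall():
    labels = [1, 1, 0, 0]
    probs = [0.9, 0.1, 0.8, 0.2]  # TP=1, FN=1, FP=1 -> P = R = 0.5
    m = classification_metrics(labels, probs)
    assert m["precision"] == m["recall"] == m["f1"] == pytest.approx(0.5)


def test_single_class_labels_rejected():
    with pytest.raises(ValueError, match="one class"):
        classification_metrics([1, 1, 1], [0.5, 0.6, 0.7])


# -- cross-validation aggregation ---------------------------------------------------

def _report(**vals):
    return EvaluationReport(per_task={"loewe": vals})


def test_aggregate_cv_two_point_mean_and_sample_variance():
    agg = aggregate_cv([_report(rmse=8.0), _report(rmse=10.0)])
    cell = agg.per_task["loewe"]["rmse"]
    assert cell["mean"] == pytest.approx(9.0)
    assert cell["variance"] == pytest.approx(2.0)


def test_aggregate_cv_identical_folds_have_zero_variance():
    agg = aggregate_cv([_report(rmse=3.3)] * 5)
    cell = agg.per_task["loewe"]["rmse"]
    assert cell["variance"] == 0.0 and cell["ci95_halfwidth"] == 0.0


def test_aggregate_cv_mean_matches_brute_force():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=5)
    agg = aggregate_cv([_report(r2=v) for v in vals])
    assert agg.per_task["loewe"]["r2"]["mean"] == pytest.approx(vals.mean(), abs=1e-12)
    assert agg.per_task["loewe"]["r2"]["variance"] == pytest.approx(
        vals.var(ddof=1), abs=1e-12)


def test_aggregate_cv_rejects_mismatched_rosters():
    with pytest.raises(ValueError, match="roster"):
        aggregate_cv([_report(rmse=1.0),
                      EvaluationReport(per_task={"bliss": {"rmse": 1.0}})])


# -- support counting & consistency ----------------------------------------------

def test_count_support_reproduces_screening_table_rows():
    # predicted scores of two reported high-confidence candidates
    row_full = {"zip": 6.84, "bliss": 7.7, "hsa": 8.48, "s": 20.53, "loewe": 5.66}
    row_partial = {"zip": 3.14, "bliss": 14.22, "hsa": 7.27, "s": 13.53, "loewe": 6.7}
    assert count_support(row_full) == 5
    assert count_support(row_partial) == 4
    assert count_support({t: 0.0 for t in row_full}) == 0
    assert count_support({t: 5.0 for t in row_full}) == 0  # strict inequality


def test_count_support_contract_errors():
    with pytest.raises(KeyError, match="missing"):
        count_support({"zip": 1.0})
    with pytest.raises(ValueError):
        count_support({"zip": np.nan, "bliss": 1, "hsa": 1, "s": 1, "loewe": 1})


@given(st.floats(-10, 40), st.floats(-10, 40))
@settings(derandomize=True, max_examples=40)
def test_count_support_monotone_non_increasing_in_threshold(t1, t2):
    scores = {"loewe": 6.0, "bliss": -3.0, "zip": 31.0, "hsa": 5.0, "s": 12.0}
    lo, hi = min(t1, t2), max(t1, t2)
    assert count_support(scores, lo) >= count_support(scores, hi)


def test_pairwise_correlation_matches_textbook_formula():
    rng = np.random.default_rng(9)
    scores = {t: rng.normal(size=50) for t in ("loewe", "bliss", "zip", "hsa", "s")}
    mat = pairwise_score_correlation(scores)
    assert np.allclose(np.diag(mat.to_numpy()), 1.0)
    for a in scores:
        for b in scores:
            x, y = scores[a], scores[b]
            want = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
            assert mat.loc[a, b] == pytest.approx(want, abs=1e-10)
    exact = pairwise_score_correlation(
        {"a": np.arange(5.0), "b": 2 * np.arange(5.0) + 1})
    assert exact.loc["a", "b"] == pytest.approx(1.0)


def test_pairwise_correlation_subset_mask_and_errors():
    scores = {"a": np.array([1.0, 2.0, 3.0, 4.0]), "b": np.array([1.0, 1.0, 3.0, 5.0])}
    masked = pairwise_score_correlation(scores, subset_mask=[True, True, True, False])
    assert masked.shape == (2, 2)
    with pytest.raises(ValueError, match="'b'"):
        pairwise_score_correlation(
            {"a": np.array([1.0, 2.0, 3.0]), "b": np.ones(3)})


# -- screening --------------------------------------------------------------------

@pytest.fixture
def prediction_rows():
    return pd.DataFrame([
        # all five scores > 30, confident, no DDI risk
        dict(pred_loewe=33.6, pred_bliss=33.2, pred_zip=33.4, pred_hsa=31.4,
             pred_s=39.7, synergy_prob=0.995, ddi_prob=0.05),
        # high scores but adverse-DDI probability 0.93
        dict(pred_loewe=31.5, pred_bliss=33.7, pred_zip=34.1, pred_hsa=32.3,
             pred_s=32.6, synergy_prob=0.992, ddi_prob=0.93),
        # confident probability but mixed scores (support 4)
        dict(pred_loewe=6.7, pred_bliss=14.2, pred_zip=3.1, pred_hsa=7.3,
             pred_s=13.5, synergy_prob=0.95, ddi_prob=0.10),
        # weak everywhere
        dict(pred_loewe=1.0, pred_bliss=2.0, pred_zip=0.5, pred_hsa=-1.0,
             pred_s=3.0, synergy_prob=0.40, ddi_prob=0.02),
    ])


def test_screen_all_scores_threshold_30(prediction_rows):
    out = screen_candidates(prediction_rows,
                            [ScreenRule("all_scores_threshold", threshold=30.0)])
    assert list(out.index) == [0, 1]
    assert list(out["support"]) == [5, 5]


def test_screen_probability_and_ddi_rules(prediction_rows):
    out = screen_candidates(prediction_rows, [
        ScreenRule("prob_threshold", threshold=0.99),
        ScreenRule("ddi_exclude", threshold=0.5),
    ])
    assert list(out.index) == [0]
    removed = screen_candidates(prediction_rows,
                                [ScreenRule("prob_threshold", threshold=0.99)])
    assert 2 not in removed.index  # 0.95 does not clear a 0.99 bar


def test_screen_support_count_rule_and_empty_rules(prediction_rows):
    out = screen_candidates(prediction_rows,
                            [ScreenRule("support_count", threshold=5.0, min_support=4)])
    assert list(out.index) == [0, 1, 2]
    identity = screen_candidates(prediction_rows, [])
    assert list(identity.index) == [0, 1, 2, 3]
    assert list(identity["support"]) == [5, 5, 4, 0]


def test_screen_rules_commute(prediction_rows):
    r1 = ScreenRule("prob_threshold", threshold=0.9)
    r2 = ScreenRule("all_scores_threshold", threshold=30.0)
    a = screen_candidates(prediction_rows, [r1, r2])
    b = screen_candidates(prediction_rows, [r2, r1])
    pd.testing.assert_frame_equal(a, b)


def test_screen_missing_column_raises(prediction_rows):
    with pytest.raises(KeyError, match="ddi_prob"):
        screen_candidates(prediction_rows.drop(columns=["ddi_prob"]),
                          [ScreenRule("ddi_exclude", threshold=0.5)])
    with pytest.raises(KeyError, match="pred_s"):
        screen_candidates(prediction_rows.drop(columns=["pred_s"]), [])
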