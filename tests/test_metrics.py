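"""Confusion matrices, per-class metrics, ROC/AUC, Bland–Altman."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathkit.decision import BreathPhase
from breathkit.metrics import (
    ConfusionMatrix,
    balanced_accuracy,
    bland_altman,
    confusion,
    f1_score,
    multiclass_balanced_accuracy,
    per_class_metrics,
    roc_auc,
)

E, I, N = BreathPhase.EXHALATION, BreathPhase.INHALATION, BreathPhase.NONBREATHING


def test_confusion_hand_tally():
    y_true = [E, E, E, I, I, N, N, N, N]
    y_pred = [E, I, N, I, I, N, N, E, N]
    cm = confusion(y_true, y_pred)
    expected = np.array([[1, 1, 1], [0, 2, 0], [1, 0, 3]])
    assert np.array_equal(cm.counts, expected)
    assert np.array_equal(cm.counts.sum(axis=1), [3, 2, 4])  # row sums = true counts


def test_confusion_perfect_predictions_diagonal():
    y = [E, I, N, E, I, N]
    cm = confusion(y, list(y))
    assert np.array_equal(cm.counts, np.diag([2, 2, 2]))


def test_confusion_length_mismatch():
    with pytest.raises(ValueError):
        confusion([E], [E, I])


def test_per_class_metrics_on_hand_matrix():
    cm = ConfusionMatrix(np.array([[8, 1, 1], [2, 6, 2], [1, 1, 8]]))
    report = per_class_metrics(cm)
    m = report.per_class["exhalation"]
    assert m.precision == pytest.approx(8 / 11)
    assert m.recall == pytest.approx(0.8)
    assert m.specificity == pytest.approx(17 / 20)
    assert m.f1 == pytest.approx(2 * (8 / 11) * 0.8 / (8 / 11 + 0.8))
    assert m.balanced_accuracy == pytest.approx((0.8 + 17 / 20) / 2)


def test_absent_class_yields_nan_with_warning():
    cm = ConfusionMatrix(np.array([[0, 0, 0], [0, 5, 0], [0, 0, 5]]))
    with pytest.warns(UserWarning, match="undefined"):
        report = per_class_metrics(cm)
    assert np.isnan(report.per_class["exhalation"].recall)


def test_published_metric_identities():
    """The printed table rows obey the metric identities they were
    computed with: balanced accuracy from (recall, specificity) and F1
    from (precision, recall)."""
    assert balanced_accuracy(0.71, 0.97) == pytest.approx(0.84, abs=0.005)
    assert f1_score(0.84, 0.66) == pytest.approx(0.74, abs=0.005)
    assert f1_score(0.72, 0.71) == pytest.approx(0.71, abs=0.005)


def test_multiclass_ba_kelleher_is_mean_recall():
    assert multiclass_balanced_accuracy([0.59, 0.40, 0.96], "kelleher") == pytest.approx(0.65)


def test_multiclass_ba_urbanowicz_is_mean_balanced_accuracy():
    bas = [balanced_accuracy(*p) for p in [(0.59, 0.93), (0.40, 0.95), (0.96, 0.63)]]
    assert multiclass_balanced_accuracy(bas, "urbanowicz") == pytest.approx(0.74, abs=0.005)


def test_multiclass_ba_constant_input_and_bad_mode():
    assert multiclass_balanced_accuracy([0.7, 0.7, 0.7], "kelleher") == pytest.approx(0.7)
    assert multiclass_balanced_accuracy([0.7, 0.7, 0.7], "urbanowicz") == pytest.approx(0.7)
    with pytest.raises(ValueError):
        multiclass_balanced_accuracy([0.5], "macro")
    with pytest.raises(ValueError, match="exhalation"):
        multiclass_balanced_accuracy({"exhalation": float("nan")}, "kelleher")


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 50), min_size=9, max_size=9))
def test_balanced_accuracy_identity_on_random_matrices(cells):
    cm = ConfusionMatrix(np.array(cells).reshape(3, 3))
    if cm.total == 0:
        return
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = per_class_metrics(cm)
    for m in report.per_class.values():
        if np.isnan(m.recall) or np.isnan(m.specificity):
            continue
        assert m.balanced_accuracy == (m.recall + m.specificity) / 2


def test_roc_perfect_separation_auc_one():
    curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert curve.auc == 1.0
    assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
    assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)


def test_roc_label_inversion_flips_auc():
    rng = np.random.default_rng(0)
    scores = rng.random(100)
    labels = rng.random(100) < 0.5
    auc = roc_auc(scores, labels).auc
    assert roc_auc(scores, ~labels).auc == pytest.approx(1.0 - auc, abs=1e-9)


def test_roc_auc_equals_mann_whitney_statistic():
    rng = np.random.default_rng(1)
    scores = rng.random(200)
    labels = rng.random(200) < 0.4
    pos, neg = scores[labels], scores[~labels]
    # tie-corrected probability a random positive outscores a random negative
    u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert roc_auc(scores, labels).auc == pytest.approx(
        u / (len(pos) * len(neg)), abs=1e-9
    )


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([0.5, 0.6], [1, 1])


def test_bland_altman_identical_pairs():
    stats = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert stats.mean_difference == 0.0
    assert stats.lower_limit == stats.upper_limit == 0.0


def test_bland_altman_constant_offset():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    stats = bland_altman(x, x + 0.5)
    assert stats.mean_difference == pytest.approx(-0.5)
    assert stats.sd_difference == 0.0


def test_bland_altman_hand_example():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([1.1, 1.8, 3.3, 3.9, 5.2])
    d = x - y
    mean, sd = d.mean(), d.std(ddof=1)
    stats = bland_altman(x, y)
    assert stats.mean_difference == pytest.approx(mean)
    assert stats.sd_difference == pytest.approx(sd)
    assert stats.lower_limit == pytest.approx(mean - 1.96 * sd)
    assert stats.upper_limit == pytest.approx(mean + 1.96 * sd)
    assert stats.lower_limit <= stats.mean_difference <= stats.upper_limit


def test_bland_altman_requires_two_pairs():
    with pytest.raises(ValueError):
        bland_altman([1.0], [1.0])
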