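"""Selectors, metrics, nested LOOCV leakage control and permutation null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nldeeg.evaluation import (ClassifierSpec, SelectorSpec, compute_metrics,
                               grid_summary, permutation_test,
                               run_grid, run_nested_loocv, select_ftest,
                               select_pearson, select_rfe)
from nldeeg.features import CohortLabels, FeatureTable, feature_grid


def toy_table(X, subject_prefix="S"):
    n, p = X.shape
    bands = ("1-3.9Hz", "3.9-7.8Hz", "7.8-15.6Hz", "15.6-31.2Hz",
             "31.2-62.2Hz", "62.5-100Hz")
    measures = ("Power", "DFA", "SampE", "HurstE", "LyapE", "PermE", "SpecE",
                "SVDE", "AppE", "HFD", "KFD", "LZC")
    channels = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "C4",
                "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2")
    ids = feature_grid(channels=channels, band_labels=bands,
                       measures=measures, scales=())[:p]
    return FeatureTable(values=X, feature_ids=ids,
                        subject_ids=[f"{subject_prefix}{i}" for i in range(n)])


def labeled_noise(n_pos, n_neg, p, seed, informative=0, shift=3.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_pos + n_neg, p))
    y = np.array([1] * n_pos + [0] * n_neg)
    X[y == 1, :informative] += shift
    table = toy_table(X)
    labels = CohortLabels({sid: ("positive" if yi else "negative")
                           for sid, yi in zip(table.subject_ids, y)})
    return table, labels, y


# --------------------------------------------------------------------------
# selectors


def test_pearson_hand_computed_toy():
    # feature correlations with y: ~0.9, ~0.1, ~-0.95 -> picks 3rd then 1st
    y = np.array([0, 0, 1, 1, 0, 1])
    f1 = np.array([0.1, 0.0, 1.0, 0.9, 0.2, 1.1])
    f2 = np.array([0.3, -0.2, 0.1, 0.0, 0.1, 0.2])
    f3 = -2.0 * y + np.array([0.01, -0.02, 0.0, 0.02, -0.01, 0.0])
    X = np.column_stack([f1, f2, f3])
    sel = select_pearson(X, y, 2)
    assert set(sel) == {0, 2}
    assert sel[0] == 2  # highest |r| first


def test_pearson_constant_features_rank_last_with_warning():
    X = np.ones((6, 4))
    y = np.array([0, 0, 0, 1, 1, 1])
    with pytest.warns(UserWarning):
        sel = select_pearson(X, y, 10)  # k > p: return all, warn
    assert sel.tolist() == [0, 1, 2, 3]


def test_ftest_zero_between_group_variance():
    X = np.column_stack([np.array([1.0, 1.0, 2.0, 2.0]),
                         np.array([5.0, 6.0, 5.0, 6.0])])
    y = np.array([0, 1, 0, 1])
    sel = select_ftest(X, y, 1)
    assert sel[0] == 1  # first column has zero between-group variance


def test_ftest_hand_computed_four_subjects():
    # groups {0,1}: x = [1,2], {2,3}: x = [3,4]
    # between MS = 4, within MS = 0.5 -> F = 8
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    y = np.array([0, 0, 1, 1])
    grand = 2.5
    between = 2 * (1.5 - grand) ** 2 + 2 * (3.5 - grand) ** 2
    within = (0.5 ** 2) * 4
    f_expected = (between / 1) / (within / 2)
    assert f_expected == 8.0
    assert select_ftest(X, y, 1).tolist() == [0]


def test_ftest_and_pearson_rankings_coincide():
    """For two groups F = t^2, so both criteria order features identically."""
    rng = np.random.default_rng(5)
    for _ in range(5):
        X = rng.standard_normal((30, 40))
        y = (rng.random(30) < 0.4).astype(int)
        if y.sum() < 2 or y.sum() > 28:
            continue
        p_sel = select_pearson(X, y, 40)
        f_sel = select_ftest(X, y, 40)
        assert p_sel.tolist() == f_sel.tolist()


def test_rfe_contract_and_informative_recovery():
    kept = 0
    for seed in range(10):
        table, labels, y = labeled_noise(8, 8, 52, seed, informative=2)
        sel = select_rfe(table.values, y, 10, seed=seed)
        assert len(sel) <= 10
        kept += {0, 1} <= set(sel)
    assert kept >= 9  # both informative features retained in >=90% of seeds


def test_rfe_k_one():
    table, labels, y = labeled_noise(6, 6, 20, 3, informative=1)
    sel = select_rfe(table.values, y, 1)
    assert len(sel) == 1


# --------------------------------------------------------------------------
# metrics


def test_metrics_perfect_prediction():
    y = [1] * 14 + [0] * 40
    m = compute_metrics(y, y)
    assert (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv) == \
        (1.0, 1.0, 1.0, 1.0, 1.0)


def test_metrics_full_sample_arithmetic():
    # TP=1, FN=26, TN=40, FP=0 on n=67
    y_true = [1] * 27 + [0] * 40
    y_pred = [1] + [0] * 26 + [0] * 40
    m = compute_metrics(y_pred, y_true)
    assert m.accuracy == pytest.approx(41 / 67)
    assert round(100 * m.accuracy, 1) == 61.2
    assert round(100 * m.sensitivity, 1) == 3.7
    assert m.specificity == 1.0


def test_metrics_zero_over_zero_is_missing():
    m = compute_metrics([0, 0, 0], [0, 0, 1])
    assert m.ppv is None  # no positive predictions
    assert m.npv == pytest.approx(2 / 3)
    m2 = compute_metrics([1, 1], [1, 1])
    assert m2.specificity is None and m2.npv is None


@settings(max_examples=200, deadline=None, derandomize=True)
@given(tp=st.integers(0, 30), tn=st.integers(0, 30),
       fp=st.integers(0, 30), fn=st.integers(0, 30))
def test_metrics_identities_hold_for_all_confusions(tp, tn, fp, fn):
    n = tp + tn + fp + fn
    if n == 0:
        return
    y_true = [1] * (tp + fn) + [0] * (tn + fp)
    y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
    m = compute_metrics(y_pred, y_true)
    assert m.accuracy == pytest.approx((tp + tn) / n)
    if tp + fn:
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
    else:
        assert m.sensitivity is None
    if tn + fp:
        assert m.specificity == pytest.approx(tn / (tn + fp))
    if tp + fp:
        assert m.ppv == pytest.approx(tp / (tp + fp))
    if tn + fn:
        assert m.npv == pytest.approx(tn / (tn + fn))


# --------------------------------------------------------------------------
# nested LOOCV


def test_loocv_separable_cohort_perfect_accuracy():
    table, labels, _ = labeled_noise(6, 10, 30, 7, informative=3, shift=6.0)
    run = run_nested_loocv(table, labels, SelectorSpec("pearson", 5),
                           ClassifierSpec("svm_rbf"))
    assert run.n_folds == 16
    assert run.metrics.accuracy == 1.0


def test_loocv_fold_count_equals_cohort_size():
    table, labels, _ = labeled_noise(4, 8, 15, 8)
    run = run_nested_loocv(table, labels, SelectorSpec("pearson", 3))
    assert run.n_folds == 12
    assert [f.subject_id for f in run.folds] == table.subject_ids


def test_loocv_selection_leakage_audit():
    """Recomputing each fold's selection from its training split alone
    reproduces the logged feature list exactly."""
    from sklearn.preprocessing import StandardScaler
    table, labels, y = labeled_noise(5, 9, 25, 9, informative=2)
    sel_spec = SelectorSpec("pearson", 6)
    run = run_nested_loocv(table, labels, sel_spec)
    X = table.values
    for i, fold in enumerate(run.folds):
        tr = np.delete(np.arange(len(y)), i)
        X_tr = StandardScaler().fit_transform(X[tr])
        sel = select_pearson(X_tr, y[tr], sel_spec.k_features)
        assert sel.tolist() == fold.selected_idx
        assert [table.feature_ids[j] for j in sel] == fold.selected


def test_loocv_requires_two_subjects_per_class():
    table, labels, _ = labeled_noise(1, 8, 10, 10)
    with pytest.raises(ValueError):
        run_nested_loocv(table, labels)


def test_loocv_every_fold_selects_k_features():
    table, labels, _ = labeled_noise(4, 8, 30, 11)
    run = run_nested_loocv(table, labels, SelectorSpec("ftest", 7))
    assert all(len(f.selected) == 7 for f in run.folds)


def test_knn_k_defaults_to_sqrt_of_sample_size():
    import math
    assert int(math.isqrt(54)) == 7
    assert int(math.isqrt(67)) == 8
    table, labels, _ = labeled_noise(5, 11, 12, 12, informative=2)
    run = run_nested_loocv(table, labels, SelectorSpec("pearson", 4),
                           ClassifierSpec("knn"))
    assert run.metrics.accuracy >= 0.5  # smoke: k=4 fits a 15-subject fold


# --------------------------------------------------------------------------
# permutation test


def test_permutation_null_properties():
    table, labels, _ = labeled_noise(5, 15, 40, 13, informative=3, shift=4.0)
    run = run_nested_loocv(table, labels, SelectorSpec("pearson", 5),
                           ClassifierSpec("gaussian_nb"))
    perm = permutation_test(table, labels, SelectorSpec("pearson", 5),
                            ClassifierSpec("gaussian_nb"),
                            n_permutations=60, seed=0, cv_run=run)
    assert perm.null_accuracies.shape == (60,)
    assert 0.0 < perm.p_empirical <= 1.0
    assert perm.observed == run.metrics.accuracy
    # separable cohort: observed beats nearly every permutation
    assert perm.p_empirical <= 2 / 61
    assert perm.z is not None and perm.z > 2.0
    # determinism
    perm2 = permutation_test(table, labels, SelectorSpec("pearson", 5),
                             ClassifierSpec("gaussian_nb"),
                             n_permutations=60, seed=0, cv_run=run)
    assert np.array_equal(perm.null_accuracies, perm2.null_accuracies)


def test_permutation_p_values_roughly_uniform_on_null_tables():
    """On exchangeable noise cohorts the permutation p-value is
    approximately uniform (coarse KS bound; the null is discrete)."""
    pvals = []
    for c in range(40):
        table, labels, _ = labeled_noise(5, 15, 30, 100 + c)
        run = run_nested_loocv(table, labels, SelectorSpec("pearson", 5),
                               ClassifierSpec("gaussian_nb"))
        perm = permutation_test(table, labels, SelectorSpec("pearson", 5),
                                ClassifierSpec("gaussian_nb"),
                                n_permutations=50, seed=c, cv_run=run)
        pvals.append(perm.p_empirical)
    pvals = np.sort(pvals)
    ks = np.max(np.abs(pvals - np.arange(1, 41) / 41))
    assert ks < 0.3
    assert 0.25 < np.mean(pvals) < 0.75


# --------------------------------------------------------------------------
# grid


def test_grid_runs_all_twelve_cells_deterministically():
    table, labels, _ = labeled_noise(4, 8, 20, 14, informative=2)
    runs = run_grid(table, labels, seed=3)
    assert len(runs) == 12
    summary = grid_summary(runs)
    assert len(summary) == 12
    assert set(summary["selector"]) == {"pearson", "ftest", "rfe"}
    assert set(summary["classifier"]) == {"svm_rbf", "gaussian_nb", "lda",
                                          "knn"}
    runs2 = run_grid(table, labels, seed=3)
    for a, b in zip(runs, runs2):
        assert a.metrics == b.metrics
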