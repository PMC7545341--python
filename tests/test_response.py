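"""Tests for ddCt quantification, the PLS response model and ROC tools."""

import numpy as np
import pandas as pd
import pytest

from ceraxis.response import (
    ResponseModel,
    auc_mann_whitney,
    compare_roc,
    ddct,
    delong_variance,
    evaluate,
    fit_pls,
    label_responders,
    relative_expression_table,
    roc_points,
    youden_threshold,
)

from _oracles import auc_oracle

R, N = "responder", "nonresponder"


# ---------------------------------------------------------------------------
# ddCt


def test_ddct_examples():
    assert ddct(20, 18, 20, 18) == pytest.approx(1.0)
    assert ddct(20, 18, 22, 18) == pytest.approx(4.0)
    # +1 cycle on the sample gene halves the result
    assert ddct(21, 18, 22, 18) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        ddct(20, np.nan, 22, 18)
    with pytest.raises(ValueError):
        ddct(20, 18, None, 18)


def test_relative_expression_table():
    ct = pd.DataFrame(
        {"G": [20.0, 22.0], "CTRL": [18.0, 18.0]}, index=["s1", "ref"]
    )
    rel = relative_expression_table(ct, ["G"], "CTRL", "ref")
    assert rel.at["s1", "G"] == pytest.approx(4.0)
    assert rel.at["ref", "G"] == pytest.approx(1.0)
    with pytest.raises(KeyError):
        relative_expression_table(ct, ["G"], "NOPE", "ref")


# ---------------------------------------------------------------------------
# AUC / ROC primitives


def test_auc_trivial_rankings():
    labels = [R] * 3 + [N] * 3
    assert auc_mann_whitney([6, 5, 4, 3, 2, 1], labels) == pytest.approx(1.0)
    assert auc_mann_whitney([1, 2, 3, 4, 5, 6], labels) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        auc_mann_whitney([1, 2], [R, R])


def test_auc_matches_concordance_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(4, 40))
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            continue
        s = np.round(rng.normal(size=n), 1)  # coarse values force ties
        labels = np.where(y == 1, R, N)
        assert auc_mann_whitney(s, labels) == pytest.approx(auc_oracle(s, y))


def test_auc_invariant_under_monotone_transform(rng):
    y = rng.integers(0, 2, size=50)
    y[0], y[1] = 0, 1
    s = rng.normal(size=50)
    labels = np.where(y == 1, R, N)
    a1 = auc_mann_whitney(s, labels)
    for f in (np.exp, np.tanh, lambda v: 3 * v + 7, lambda v: v**3):
        assert auc_mann_whitney(f(s), labels) == pytest.approx(a1)


def test_youden_threshold_separates_perfectly():
    labels = [R, R, N, N]
    t = youden_threshold([4.0, 3.0, 1.0, 0.0], labels)
    assert 1.0 < t < 3.0


def test_roc_points_monotone(rng):
    y = np.r_[np.ones(10), np.zeros(10)]
    s = rng.normal(size=20)
    labels = np.where(y == 1, R, N)
    thr, sens, spec = roc_points(s, labels)
    assert (np.diff(sens) >= 0).all()
    assert (np.diff(spec) <= 0).all()


# ---------------------------------------------------------------------------
# PLS model


def _separable_data(rng, n_per=10):
    X1 = rng.normal(0, 1, size=(n_per, 3)) + np.array([3, -3, 3])
    X0 = rng.normal(0, 1, size=(n_per, 3))
    X = np.vstack([X1, X0])
    labels = np.array([R] * n_per + [N] * n_per)
    return X, labels


def test_fit_pls_separable_training_auc_one(rng):
    X, labels = _separable_data(rng)
    model = fit_pls(X, labels, 2)
    assert auc_mann_whitney(model.decision_scores(X), labels) == pytest.approx(1.0)
    # Youden threshold classifies the training set perfectly
    assert (model.predict_labels(X) == labels).all()


def test_fit_pls_validation_and_capping(rng):
    X, labels = _separable_data(rng)
    with pytest.raises(ValueError):
        fit_pls(X, [R] * 20, 2)
    with pytest.warns(UserWarning, match="capping"):
        model = fit_pls(X, labels, 10)
    assert model.n_components == 3
    with pytest.raises(ValueError):
        fit_pls(np.hstack([X, np.ones((20, 1))]), labels, 2)  # constant feature


def test_fit_pls_noise_feature_gets_small_weight(rng):
    n = 500
    y01 = rng.integers(0, 2, size=n)
    X = np.column_stack([
        y01 * 2.0 + rng.normal(0, 1, n),
        -y01 * 2.0 + rng.normal(0, 1, n),
        rng.normal(0, 1, n),  # pure noise
    ])
    labels = np.where(y01 == 1, R, N)
    model = fit_pls(X, labels, 2)
    coef = np.abs(model.coef)
    assert coef[2] < 0.1 * coef[:2].max()


def test_fit_pls_permutation_null(rng):
    X, labels = _separable_data(rng, n_per=15)
    X_test, labels_test = _separable_data(rng, n_per=15)
    aucs = []
    for _ in range(100):
        perm = rng.permutation(len(labels))
        model = fit_pls(X, labels[perm], 2)
        aucs.append(auc_mann_whitney(model.decision_scores(X_test), labels_test))
    assert 0.4 <= float(np.mean(aucs)) <= 0.6


def test_model_dict_roundtrip(rng):
    X, labels = _separable_data(rng)
    model = fit_pls(X, labels, 2, feature_names=["a", "b", "c"])
    clone = ResponseModel.from_dict(model.to_dict())
    assert np.allclose(clone.decision_scores(X), model.decision_scores(X))
    with pytest.raises(ValueError):
        model.decision_scores(X[:, :2])


def test_evaluate_independent_cohort(rng):
    X, labels = _separable_data(rng)
    model = fit_pls(X, labels, 2)
    X_te, labels_te = _separable_data(rng)
    roc = evaluate(model, X_te, labels_te)
    assert roc.auc > 0.95 and roc.accuracy > 0.9
    assert roc.operating_point == model.threshold
    with pytest.raises(ValueError):
        evaluate(model, X_te, [R] * len(labels_te))


# ---------------------------------------------------------------------------
# DeLong comparison


def test_compare_roc_identical_scores_p_one(rng):
    s = rng.normal(size=30)
    labels = np.where(rng.integers(0, 2, size=30) == 1, R, N)
    labels[0], labels[1] = R, N
    assert compare_roc(s, s, labels) == 1.0
    with pytest.raises(ValueError):
        compare_roc(s, s[:10], labels)


def test_compare_roc_power_against_random_marker():
    hits = 0
    for seed in range(100):
        r = np.random.default_rng(seed)
        y = np.r_[np.ones(50), np.zeros(50)]
        labels = np.where(y == 1, R, N)
        panel = y + r.normal(0, 1e-6, size=100)  # AUC 1.0
        single = r.normal(size=100)
        if compare_roc(panel, single, labels) < 0.05:
            hits += 1
    assert hits >= 95


def test_delong_variance_close_to_bootstrap():
    r = np.random.default_rng(42)
    n = 200
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    labels = np.where(y == 1, R, N)
    a = y + r.normal(0, 1.0, n)
    b = y + r.normal(0, 2.0, n)
    aucs, cov = delong_variance(a, b, labels)
    var_delong = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diffs = []
    for _ in range(2000):
        idx = r.integers(0, n, size=n)
        yy = y[idx]
        if yy.sum() in (0, n):
            continue
        ll = np.where(yy == 1, R, N)
        diffs.append(auc_mann_whitney(a[idx], ll) - auc_mann_whitney(b[idx], ll))
    var_boot = float(np.var(diffs, ddof=1))
    assert abs(var_delong - var_boot) <= 0.10 * var_boot


# ---------------------------------------------------------------------------
# responder labeling


def test_label_responders_rule():
    labels = label_responders([8, 5, 6], [5, 5, 7])
    assert list(labels) == [R, N, N]
    with pytest.raises(ValueError):
        label_responders([1, 2], [1])


def test_label_responders_half_split(rng):
    before = np.arange(22, dtype=float)
    after = before.copy()
    after[:11] -= 1.0  # exactly half improve
    labels = label_responders(before, after)
    assert (labels == R).sum() == 11 and (labels == N).sum() == 11
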