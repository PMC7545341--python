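"""Response quantification and prediction from the nominated ceRNA axis.

Covers the comparative-Ct relative quantification (2^-ddCt), a partial
least squares (PLS) discriminant model on the three axis RNAs, independent
test-set evaluation (Mann-Whitney AUC, accuracy at a training-derived
operating point), DeLong's test for comparing correlated ROC curves, and
the responder labeling rule for paired before/after severity scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .containers import NONRESPONDER, RESPONDER


def ddct(
    ct_gene_sample: float,
    ct_ctrl_sample: float,
    ct_gene_ref: float,
    ct_ctrl_ref: float,
) -> float:
    """Relative expression 2^-ddCt.

    ddCt = (Ct_gene - Ct_control)_sample - (Ct_gene - Ct_control)_reference.
    """
    vals = (ct_gene_sample, ct_ctrl_sample, ct_gene_ref, ct_ctrl_ref)
    if any(v is None or not np.isfinite(v) for v in vals):
        raise ValueError("all four Ct values must be present and finite")
    delta_delta = (ct_gene_sample - ct_ctrl_sample) - (ct_gene_ref - ct_ctrl_ref)
    return float(2.0 ** (-delta_delta))


def relative_expression_table(
    ct: pd.DataFrame, genes, control: str, reference_sample: str
) -> pd.DataFrame:
    """Per-sample 2^-ddCt for each gene against one internal control."""
    if control not in ct.columns:
        raise KeyError(f"control gene {control!r} absent from Ct table")
    if reference_sample not in ct.index:
        raise KeyError(f"reference sample {reference_sample!r} absent from Ct table")
    out = {}
    for g in genes:
        out[g] = [
            ddct(
                ct.at[s, g],
                ct.at[s, control],
                ct.at[reference_sample, g],
                ct.at[reference_sample, control],
            )
            for s in ct.index
        ]
    return pd.DataFrame(out, index=ct.index)


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray(
        [1.0 if str(v) == RESPONDER else 0.0 if str(v) == NONRESPONDER else np.nan
         for v in labels]
    )
    if np.isnan(y).any():
        raise ValueError(
            f"labels must be {RESPONDER!r}/{NONRESPONDER!r}"
        )
    return y


@dataclass
class ResponseModel:
    """Fitted PLS discriminant model on the axis RNA panel."""

    feature_names: list[str]
    n_components: int
    x_mean: np.ndarray
    x_std: np.ndarray
    coef: np.ndarray  # regression coefficients on the standardized scale
    intercept: float
    threshold: float  # training-set Youden-J operating point
    training_cohort: str = ""
    x_weights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def decision_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected an (n, {len(self.feature_names)}) matrix, got {X.shape}"
            )
        Z = (X - self.x_mean) / self.x_std
        return Z @ self.coef + self.intercept

    def predict_labels(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return np.where(s >= self.threshold, RESPONDER, NONRESPONDER)

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
            "training_cohort": self.training_cohort,
            "x_weights": np.asarray(self.x_weights).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseModel":
        return cls(
            feature_names=list(d["feature_names"]),
            n_components=int(d["n_components"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_std=np.asarray(d["x_std"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            threshold=float(d["threshold"]),
            training_cohort=d.get("training_cohort", ""),
            x_weights=np.asarray(d.get("x_weights", []), dtype=float),
        )


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = _encode_labels(labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: test set contains a single class")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def youden_threshold(scores, labels) -> float:
    """Score threshold maximizing sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores
    (plus outer sentinels); ties broken toward the lowest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = _encode_labels(labels)
    uniq = np.unique(s)
    cands = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_t, best_j = cands[0], -np.inf
    n1, n0 = y.sum(), (1 - y).sum()
    for t in cands:
        pred = s >= t
        sens = (pred & (y == 1)).sum() / n1
        spec = (~pred & (y == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def fit_pls(
    X_train,
    labels,
    n_components: int = 2,
    feature_names=None,
    training_cohort: str = "",
) -> ResponseModel:
    """PLS regression of the 0/1 response label on the RNA panel.

    Features are centered and unit-scaled using the training data only; the
    operating threshold is the training-score Youden-J point.  The number of
    components is capped at min(n_features, n_train - 1) with a warning.
    """
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2:
        raise ValueError("X_train must be 2-D (samples x features)")
    y = _encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    n, p = X.shape
    cap = min(p, n - 1)
    if n_components > cap:
        warnings.warn(
            f"n_components={n_components} exceeds min(n_features, n-1)={cap}; capping",
            stacklevel=2,
        )
        n_components = cap
    if n_components < 1:
        raise ValueError("need at least one PLS component")
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    if (x_std <= 0).any():
        raise ValueError("constant training feature: cannot scale")
    Z = (X - x_mean) / x_std
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Z, y)
    coef = pls.coef_.reshape(-1)
    intercept = float(np.asarray(pls.intercept_).reshape(-1)[0])
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(p)]
    model = ResponseModel(
        feature_names=list(feature_names),
        n_components=n_components,
        x_mean=x_mean,
        x_std=x_std,
        coef=coef,
        intercept=intercept,
        threshold=0.0,
        training_cohort=training_cohort,
        x_weights=pls.x_weights_,
    )
    model.threshold = youden_threshold(model.decision_scores(X), labels)
    return model


@dataclass
class ROCResult:
    """ROC evaluation of a score vector against binary response labels."""

    auc: float
    accuracy: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    operating_point: float
    comparison_p: dict[str, float] = field(default_factory=dict)


def roc_points(scores, labels):
    """Sensitivity/specificity over all distinct-score thresholds."""
    s = np.asarray(scores, dtype=float)
    y = _encode_labels(labels)
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    sens = tps / y.sum()
    spec = 1.0 - fps / (1 - y).sum()
    thr = s_sorted[distinct]
    return thr, np.r_[0.0, sens], np.r_[1.0, spec]


def evaluate(model: ResponseModel, X_test, test_labels,
             operating_point: float | None = None) -> ROCResult:
    """Independent-dataset test: Mann-Whitney AUC plus accuracy at the
    training-derived operating point (never re-tuned on the test set)."""
    scores = model.decision_scores(X_test)
    y = _encode_labels(test_labels)
    auc = auc_mann_whitney(scores, test_labels)
    thr = model.threshold if operating_point is None else float(operating_point)
    pred = (scores >= thr).astype(float)
    accuracy = float((pred == y).mean())
    thresholds, sens, spec = roc_points(scores, test_labels)
    return ROCResult(
        auc=auc,
        accuracy=accuracy,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        operating_point=thr,
    )


# ---------------------------------------------------------------------------
# DeLong's test for two correlated ROC curves


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_variance(scores_a, scores_b, labels):
    """AUCs and the DeLong covariance matrix of two correlated score vectors."""
    y = _encode_labels(labels)
    pos = y == 1
    neg = ~pos
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong test requires both classes")
    aucs = []
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for k, s in enumerate((np.asarray(scores_a, float), np.asarray(scores_b, float))):
        tx = _midrank(s[pos])
        ty = _midrank(s[neg])
        tz = _midrank(s)
        auc = (tz[pos].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[k] = (tz[pos] - tx) / n
        v01[k] = 1.0 - (tz[neg] - ty) / m
        aucs.append(auc)
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    return np.asarray(aucs), cov


def compare_roc(scores_panel, scores_single, labels) -> float:
    """Two-sided DeLong p-value for AUC(panel) vs AUC(single marker)."""
    a = np.asarray(scores_panel, dtype=float)
    b = np.asarray(scores_single, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must cover identical samples")
    if np.array_equal(a, b):
        return 1.0
    aucs, cov = delong_variance(a, b, labels)
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0:
        return 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def label_responders(score_before, score_after) -> np.ndarray:
    """Responder iff the severity score improved (before - after > 0);
    a zero difference is labeled nonresponder."""
    before = np.asarray(score_before, dtype=float)
    after = np.asarray(score_after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after score vectors differ in length")
    return np.where(before - after > 0, RESPONDER, NONRESPONDER)
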