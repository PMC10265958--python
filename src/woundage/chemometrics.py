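"""Multivariate pattern-recognition core: PCA, NIPALS PLS, OPLS-DA, VIP, Q2.

This module provides the projection methods commonly used for metabolomics
profiling.  ``opls_fit`` implements orthogonal projections to latent structures
discriminant analysis: class-uncorrelated (orthogonal) X variation is removed
by orthogonal signal correction before a NIPALS PLS model is fitted to the
one-hot class matrix, so the predictive components concentrate between-class
variation.  With zero orthogonal components the model reduces exactly to
NIPALS PLS.

Model quality is summarized by R²Y (fraction of class-matrix variance explained
in fit) and Q² (1 − PRESS/SS from stratified k-fold cross-validation), with a
label permutation test and a CV-ANOVA style F-test guarding against overfit.
Per-feature variable importance in projection (VIP) is computed over the
predictive components and satisfies mean(VIP²) = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "pca",
    "pls_nipals",
    "PlsModel",
    "opls_fit",
    "OplsResult",
    "vip",
    "q2_crossval",
    "CrossvalResult",
    "cv_anova",
    "permutation_test",
    "PermutationReport",
    "one_hot",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 1000


def _as_array(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix contains non-finite values")
    return arr


def one_hot(labels, classes: list | None = None) -> tuple[np.ndarray, list]:
    """Indicator (dummy) matrix for class labels; column order follows ``classes``.

    When ``classes`` is None the sorted unique labels are used.
    """
    labels = [str(l) for l in labels]
    if classes is None:
        classes = sorted(set(labels))
    else:
        classes = [str(c) for c in classes]
        unknown = set(labels) - set(classes)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in class list {classes}")
    index = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y, classes


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(X, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal component analysis of the column-centered matrix.

    Returns ``(scores (n×k), loadings (p×k), explained_fraction (k,))`` with
    components ordered by decreasing explained variance.
    """
    X = _as_array(X)
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    total = float(np.sum(s**2))
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, loadings, explained


# ---------------------------------------------------------------------------
# NIPALS PLS (PLS2)
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """NIPALS PLS model of Y on X (both centered internally)."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    T: np.ndarray  # x-scores, n×A
    W: np.ndarray  # x-weights (unit norm), p×A
    P: np.ndarray  # x-loadings, p×A
    C: np.ndarray  # y-loadings, m×A
    coef: np.ndarray  # regression coefficients, p×m

    @property
    def n_components(self) -> int:
        return self.T.shape[1]

    def x_rotation(self) -> np.ndarray:
        """R = W (PᵀW)⁻¹ so that T = (X − x̄) R for any X."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def transform(self, X) -> np.ndarray:
        X = _as_array(X)
        return (X - self.x_mean) @ self.x_rotation()

    def predict(self, X) -> np.ndarray:
        X = _as_array(X)
        return (X - self.x_mean) @ self.coef + self.y_mean

    def r2y(self, X, Y) -> float:
        Y = _as_array(Y)
        resid = Y - self.predict(X)
        ss_tot = float(np.sum((Y - Y.mean(axis=0)) ** 2))
        if ss_tot == 0:
            raise ValueError("response matrix has zero variance")
        return 1.0 - float(np.sum(resid**2)) / ss_tot


def pls_nipals(X, Y, A: int) -> PlsModel:
    """Fit an ``A``-component PLS2 model by NIPALS with X-deflation.

    Y may have one or several columns (e.g. a one-hot class matrix).
    """
    X = _as_array(X)
    Y = _as_array(Y)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if A < 1:
        raise ValueError("A must be ≥ 1")
    if A > np.linalg.matrix_rank(X - X.mean(axis=0)):
        raise ValueError(f"A={A} exceeds the rank of centered X")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean
    if float(np.sum(E**2)) == 0.0:
        raise ValueError("X has zero variance")
    n, p = E.shape
    m = F.shape[1]
    T = np.zeros((n, A))
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    C = np.zeros((m, A))
    for a in range(A):
        # start from the Y column with the largest remaining variance
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if float(u @ u) == 0.0:
            u = E[:, int(np.argmax(E.var(axis=0)))].copy()
        t_old = None
        for _ in range(_NIPALS_MAX_ITER):
            w = E.T @ u / float(u @ u)
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("NIPALS degenerated to a zero weight vector")
            w /= norm
            t = E @ w
            c = F.T @ t / float(t @ t)
            denom = float(c @ c)
            if denom == 0:
                break
            u = F @ c / denom
            if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        p_load = E.T @ t / float(t @ t)
        E = E - np.outer(t, p_load)
        F = F - np.outer(t, c)
        T[:, a], W[:, a], P[:, a], C[:, a] = t, w, p_load, c
    coef = W @ np.linalg.inv(P.T @ W) @ C.T
    return PlsModel(x_mean=x_mean, y_mean=y_mean, T=T, W=W, P=P, C=C, coef=coef)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsResult:
    """Fitted OPLS-DA model: predictive + orthogonal decomposition of X."""

    classes: list
    x_mean: np.ndarray
    x_scale: np.ndarray  # per-feature divisor (1s when scale=False)
    pls: PlsModel  # predictive PLS model on the orthogonal-filtered matrix
    W_ortho: np.ndarray  # p×A_orth orthogonal weights
    P_ortho: np.ndarray  # p×A_orth orthogonal loadings
    T_ortho: np.ndarray  # n×A_orth orthogonal scores (training)
    r2y: float
    a_pred: int
    a_orth: int
    feature_ids: list | None = None
    vip_: np.ndarray | None = field(default=None, repr=False)

    @property
    def T(self) -> np.ndarray:
        """Predictive x-scores of the training data (n×A_pred)."""
        return self.pls.T

    def _preprocess(self, X) -> np.ndarray:
        X = _as_array(X)
        return (X - self.x_mean) / self.x_scale

    def filter_orthogonal(self, X) -> np.ndarray:
        """Remove the fitted orthogonal components from new (preprocessed) data."""
        Xw = self._preprocess(X)
        for a in range(self.a_orth):
            t_o = Xw @ self.W_ortho[:, a]
            Xw = Xw - np.outer(t_o, self.P_ortho[:, a])
        return Xw

    def transform(self, X) -> np.ndarray:
        """Predictive scores for new data."""
        return self.filter_orthogonal(X) @ self.pls.x_rotation()

    def predict_y(self, X) -> np.ndarray:
        """Predicted (continuous) class-indicator matrix for new data."""
        Xf = self.filter_orthogonal(X)
        return Xf @ self.pls.coef + self.pls.y_mean

    def predict_labels(self, X) -> list:
        yhat = self.predict_y(X)
        return [self.classes[j] for j in np.argmax(yhat, axis=1)]


def opls_fit(
    X,
    labels,
    a_pred: int | None = None,
    a_orth: int = 1,
    scale: bool = True,
    classes: list | None = None,
) -> OplsResult:
    """Fit an OPLS-DA model of class labels on X.

    ``a_pred`` defaults to (number of classes − 1).  When ``scale`` is true the
    columns are unit-variance scaled (population SD) after centering, the usual
    convention for peak-area matrices.  Orthogonal components are extracted by
    orthogonal signal correction: each candidate loading is stripped of its
    projection onto the PLS predictive weight space, so the removed variation is
    uncorrelated with the class matrix.  With ``a_orth=0`` the predictive
    subspace equals a plain NIPALS PLS fit.
    """
    X = _as_array(X)
    if a_orth < 0:
        raise ValueError("a_orth must be ≥ 0")
    Y, classes = one_hot(labels, classes)
    counts = Y.sum(axis=0)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        lone = [c for c, n in zip(classes, counts) if n < 2]
        raise ValueError(f"degenerate class(es) with a single sample: {lone}")
    if a_pred is None:
        a_pred = len(classes) - 1
    if a_pred < 1:
        raise ValueError("a_pred must be ≥ 1")

    x_mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        if (sd == 0).any():
            raise ValueError("cannot unit-variance scale constant feature columns")
        x_scale = sd
    else:
        x_scale = np.ones(X.shape[1])
    Xw = (X - x_mean) / x_scale
    Yc = Y - Y.mean(axis=0)

    p = Xw.shape[1]
    W_o = np.zeros((p, a_orth))
    P_o = np.zeros((p, a_orth))
    T_o = np.zeros((X.shape[0], a_orth))
    for a in range(a_orth):
        pls_a = pls_nipals(Xw, Y, a_pred)
        # orthonormal basis of the predictive weight space
        Q, _ = np.linalg.qr(pls_a.W)
        p1 = pls_a.P[:, 0]
        w_o = p1 - Q @ (Q.T @ p1)
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            # no Y-uncorrelated structure left; keep zero component
            warnings.warn("no orthogonal variation left to extract", stacklevel=2)
            break
        w_o /= norm
        t_o = Xw @ w_o
        p_o = Xw.T @ t_o / float(t_o @ t_o)
        Xw = Xw - np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o

    pls = pls_nipals(Xw, Y, a_pred)
    r2y = pls.r2y(Xw, Y)
    feature_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    result = OplsResult(
        classes=classes,
        x_mean=x_mean,
        x_scale=x_scale,
        pls=pls,
        W_ortho=W_o,
        P_ortho=P_o,
        T_ortho=T_o,
        r2y=r2y,
        a_pred=a_pred,
        a_orth=a_orth,
        feature_ids=feature_ids,
    )
    result.vip_ = vip(result)
    return result


def vip(opls: OplsResult) -> np.ndarray:
    """Variable importance in projection over the predictive components.

    VIP_j = sqrt(p · Σ_a SS_a w_ja² / Σ_a SS_a) with SS_a the Y sum of squares
    explained by component a; satisfies mean(VIP²) = 1 because each weight
    vector has unit norm.
    """
    pls = opls.pls
    p = pls.W.shape[0]
    ss = np.array(
        [float(pls.T[:, a] @ pls.T[:, a]) * float(pls.C[:, a] @ pls.C[:, a])
         for a in range(pls.n_components)]
    )
    total = ss.sum()
    if total == 0:
        return np.ones(p)
    contrib = (pls.W**2) @ ss
    return np.sqrt(p * contrib / total)


# ---------------------------------------------------------------------------
# Cross-validated Q2 and CV-ANOVA
# ---------------------------------------------------------------------------

@dataclass
class CrossvalResult:
    """Stratified k-fold cross-validation summary for an OPLS-DA model."""

    q2: float
    press: float
    ss_total: float
    residuals: np.ndarray  # n×m cross-validated Y residuals
    n_components: int  # a_pred + a_orth of the model
    n_samples: int

    def __float__(self) -> float:
        return self.q2


def q2_crossval(
    X,
    labels,
    a_pred: int | None = None,
    a_orth: int = 1,
    folds: int = 7,
    seed: int = 0,
    scale: bool = True,
) -> CrossvalResult:
    """Q² = 1 − PRESS/SS by stratified k-fold cross-validation.

    Each fold's model is refitted from scratch on the training part; held-out
    rows are preprocessed and orthogonal-filtered with the training parameters.
    Raises when a fold's training part would lose a class entirely.
    """
    X = _as_array(X)
    labels = [str(l) for l in labels]
    if folds < 2:
        raise ValueError("folds must be ≥ 2")
    Y_full, classes = one_hot(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        # a class smaller than the fold count cannot appear in every test fold,
        # and below 2 samples it cannot be fitted at all
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds; "
            "use fewer folds"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    residuals = np.zeros_like(Y_full)
    y_arr = np.asarray(labels)
    for train_idx, test_idx in splitter.split(X, y_arr):
        train_classes = set(y_arr[train_idx])
        if train_classes != set(classes):
            missing = sorted(set(classes) - train_classes)
            raise ValueError(
                f"class(es) {missing} absent from a training fold; use fewer folds"
            )
        model = opls_fit(
            X[train_idx], y_arr[train_idx], a_pred=a_pred, a_orth=a_orth,
            scale=scale, classes=classes,
        )
        yhat = model.predict_y(X[test_idx])
        residuals[test_idx] = Y_full[test_idx] - yhat
    press = float(np.sum(residuals**2))
    ss_total = float(np.sum((Y_full - Y_full.mean(axis=0)) ** 2))
    if ss_total == 0:
        raise ValueError("class matrix has zero variance")
    a_p = (len(classes) - 1) if a_pred is None else a_pred
    return CrossvalResult(
        q2=1.0 - press / ss_total,
        press=press,
        ss_total=ss_total,
        residuals=residuals,
        n_components=a_p + a_orth,
        n_samples=X.shape[0],
    )


def cv_anova(cv: CrossvalResult) -> float:
    """CV-ANOVA style model p-value from cross-validated residuals.

    F-test of the cross-validated predictive residual variance against the
    total Y variation around the mean: F = ((SS_tot − PRESS)/df_model) /
    (PRESS/df_resid) with df_model = number of model components and
    df_resid = N − 1 − df_model.  Returns 1.0 when cross-validation does not
    improve on the mean (PRESS ≥ SS_tot).
    """
    if cv.ss_total <= 0:
        raise ValueError("total Y variation is zero")
    df_model = cv.n_components
    df_resid = cv.n_samples - 1 - df_model
    if df_resid <= 0:
        raise ValueError("not enough samples for the residual degrees of freedom")
    if cv.press >= cv.ss_total:
        return 1.0
    f_stat = ((cv.ss_total - cv.press) / df_model) / (cv.press / df_resid)
    return float(stats.f.sf(f_stat, df_model, df_resid))


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationReport:
    """Label-permutation diagnostics for an OPLS-DA model."""

    original_r2y: float
    original_q2: float
    permuted: list[tuple[float, float, float]]  # (label correlation, R2Y, Q2)

    @property
    def n_perm(self) -> int:
        return len(self.permuted)

    def q2_quantile(self) -> float:
        """Fraction of permuted fits whose Q² falls below the original Q²."""
        if not self.permuted:
            return float("nan")
        below = sum(1 for (_, _, q2) in self.permuted if q2 < self.original_q2)
        return below / self.n_perm


def permutation_test(
    X,
    labels,
    n_perm: int = 200,
    seed: int = 0,
    a_pred: int | None = None,
    a_orth: int = 1,
    folds: int = 7,
    scale: bool = True,
) -> PermutationReport:
    """Assess OPLS-DA overfit by refitting under shuffled class labels.

    For each permutation the labels are shuffled, the model refitted and R²Y /
    cross-validated Q² recorded together with the correlation between the
    permuted and original one-hot class matrices.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be ≥ 0")
    X = _as_array(X)
    labels = [str(l) for l in labels]
    Y0, classes = one_hot(labels)
    Y0c = (Y0 - Y0.mean(axis=0)).ravel()
    model = opls_fit(X, labels, a_pred=a_pred, a_orth=a_orth, scale=scale)
    cv = q2_crossval(X, labels, a_pred=a_pred, a_orth=a_orth, folds=folds,
                     seed=seed, scale=scale)
    rng = np.random.default_rng(seed)
    permuted = []
    for k in range(n_perm):
        perm = rng.permutation(len(labels))
        labs = [labels[i] for i in perm]
        Yp, _ = one_hot(labs, classes)
        Ypc = (Yp - Yp.mean(axis=0)).ravel()
        denom = np.linalg.norm(Y0c) * np.linalg.norm(Ypc)
        corr = float(Y0c @ Ypc / denom) if denom > 0 else 0.0
        m_p = opls_fit(X, labs, a_pred=a_pred, a_orth=a_orth, scale=scale)
        cv_p = q2_crossval(X, labs, a_pred=a_pred, a_orth=a_orth, folds=folds,
                           seed=seed + 1 + k, scale=scale)
        permuted.append((corr, m_p.r2y, cv_p.q2))
    return PermutationReport(original_r2y=model.r2y, original_q2=cv.q2, permuted=permuted)
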