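"""NIPALS PLS1 regression with cross-validation, prediction metrics and
VIP variable selection.

For a centered predictor matrix X and centered response y, each component
extracts the score t = X w with weight w proportional to X^T y (the
covariance-maximizing direction), deflates X by t p^T with p = X^T t / t^T t,
and takes the y-loading q = y^T t / t^T t. The deflated-space weights W are
mapped back to the undeflated predictors through R = W (P^T W)^{-1}, so that
T = X R and the regression coefficients are b = R q; predictions from scores
(y_hat = T q) and from coefficients (y_hat = X b) coincide.

Because NIPALS components are nested, a model fitted with F components
contains every smaller model: truncating R and q to the first f columns
yields exactly the f-component coefficients. Cross-validation exploits this
(one fit per fold, predictions for every candidate component count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls1",
    "predict",
    "coefficients_per_lv",
    "venetian_folds",
    "cross_validate",
    "metrics",
    "vip",
    "select_by_vip",
]


@dataclass
class PLSModel:
    """A fitted PLS1 model.

    ``weights_deflated`` (W) are the per-component NIPALS weights in the
    deflated spaces (unit norm); ``weights`` (R) map undeflated centered
    predictors to scores, ``T = X_c R``; ``coef`` is ``b = R q``.
    """

    weights_deflated: np.ndarray  # W, (p, F)
    weights: np.ndarray  # R, (p, F)
    scores: np.ndarray  # T, (n, F)
    x_loadings: np.ndarray  # P, (p, F)
    y_loadings: np.ndarray  # q, (F,)
    coef: np.ndarray  # b, (p,)
    n_lv: int
    x_mean: np.ndarray
    y_mean: float

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


@dataclass
class CVResult:
    rmsecv_per_lv: np.ndarray  # index f-1 -> RMSECV at f components
    chosen_lv: int
    folds: int
    fold_assignment: np.ndarray
    predictions_per_lv: np.ndarray = field(repr=False, default=None)  # (n, max_lv)


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` components by NIPALS.

    X and y are centered internally; the centering state is stored on the
    model, so pre-centered input simply stores (near-)zero means.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yc = y - y_mean
    if not np.any(np.abs(yc) > 0):
        raise ValueError("zero-variance response")
    if not np.any(np.abs(Xd) > 0):
        raise ValueError("zero-variance predictors")
    Xc = Xd.copy()

    n, p = X.shape
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    T = np.empty((n, n_lv))
    q = np.empty(n_lv)
    scale = float(np.linalg.norm(Xd.T @ yc)) or 1.0
    for f in range(n_lv):
        w = Xd.T @ yc
        nw = float(np.linalg.norm(w))
        if nw <= 1e-12 * scale:
            raise ValueError(f"rank exhausted after {f} components (requested {n_lv})")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        pvec = Xd.T @ t / tt
        W[:, f] = w
        P[:, f] = pvec
        T[:, f] = t
        q[f] = float(yc @ t) / tt
        Xd = Xd - np.outer(t, pvec)

    R = W @ np.linalg.inv(P.T @ W)
    b = R @ q
    return PLSModel(
        weights_deflated=W,
        weights=R,
        scores=Xc @ R,
        x_loadings=P,
        y_loadings=q,
        coef=b,
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the response for new samples: center with the training
    means, apply b, add back the training response mean."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} columns, got {X_new.shape[1]}"
        )
    return (X_new - model.x_mean) @ model.coef + model.y_mean


def coefficients_per_lv(model: PLSModel) -> np.ndarray:
    """Coefficient vectors of every nested sub-model: column f-1 holds the
    coefficients of the f-component model (p, F)."""
    # R truncates consistently: R[:, :f] equals the f-component R because
    # P^T W is upper triangular.
    return np.cumsum(model.weights * model.y_loadings, axis=1)


def venetian_folds(y: np.ndarray, folds: int) -> np.ndarray:
    """Deterministic fold assignment: samples sorted by response, dealt
    round-robin ("venetian blinds" over the sorted order), spreading the
    response range across folds."""
    y = np.asarray(y, float).ravel()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > y.size:
        raise ValueError("more folds than samples")
    order = np.argsort(y, kind="stable")
    assignment = np.empty(y.size, dtype=int)
    assignment[order] = np.arange(y.size) % folds
    return assignment


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 8,
    max_lv: int = 15,
    fold_assignment: np.ndarray | None = None,
) -> CVResult:
    """K-fold cross-validation over candidate component counts 1..max_lv.

    Centering is recomputed inside each fold from the training portion
    only. The chosen count is the first minimizer of RMSECV.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if fold_assignment is None:
        fold_assignment = venetian_folds(y, folds)
    else:
        fold_assignment = np.asarray(fold_assignment, int)
        folds = int(fold_assignment.max()) + 1
    max_feasible = max_lv
    preds = np.full((y.size, max_lv), np.nan)
    for k in range(folds):
        test_mask = fold_assignment == k
        if not test_mask.any():
            raise ValueError(f"fold {k} has no samples")
        train_mask = ~test_mask
        cap = min(max_lv, int(train_mask.sum()) - 1, X.shape[1])
        model = _fit_max_rank(X[train_mask], y[train_mask], cap)
        max_feasible = min(max_feasible, model.n_lv)
        coefs = coefficients_per_lv(model)  # (p, F)
        Xc_test = X[test_mask] - model.x_mean
        preds[test_mask, : model.n_lv] = Xc_test @ coefs + model.y_mean
    preds = preds[:, :max_feasible]
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = int(np.argmin(rmsecv)) + 1  # argmin takes the first minimum
    return CVResult(
        rmsecv_per_lv=rmsecv,
        chosen_lv=chosen,
        folds=folds,
        fold_assignment=fold_assignment,
        predictions_per_lv=preds,
    )


def _fit_max_rank(X: np.ndarray, y: np.ndarray, cap: int) -> PLSModel:
    """Fit with as many components as the data supports, up to ``cap``."""
    while cap >= 1:
        try:
            return fit_pls1(X, y, cap)
        except ValueError as err:
            if "rank exhausted" not in str(err):
                raise
            cap -= 1
    raise ValueError("no components fittable")


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """Prediction figures of merit: (rmse, bias, r2).

    rmse = sqrt(mean((y_hat - y)^2)); bias = mean(y_hat - y);
    r2 = 1 - sum((y_hat - y)^2) / sum((y - y_bar)^2).
    """
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    if y_true.size < 2:
        raise ValueError("need at least two samples")
    err = y_pred - y_true
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in y_true: R^2 undefined")
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(err.mean())
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return rmse, bias, r2


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_f ssy_f * (w_jf / ||w_f||)^2 / sum_f ssy_f) with
    ssy_f = q_f^2 t_f^T t_f, using the deflated-space NIPALS weights W
    (the classical definition). The squared scores average to 1.
    """
    W = model.weights_deflated
    p, F = W.shape
    # scores of the fitted model are in the undeflated space but t_f^T t_f
    # matches the deflated-space score norms (same vectors).
    tt = np.einsum("ij,ij->j", model.scores, model.scores)
    ssy = model.y_loadings**2 * tt
    w_norm2 = W**2 / np.sum(W**2, axis=0)
    return np.sqrt(p * (w_norm2 @ ssy) / ssy.sum())


def select_by_vip(
    X: np.ndarray, scores: np.ndarray, threshold: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Retain the columns with VIP strictly greater than ``threshold``,
    preserving column order; returns (reduced X, kept indices)."""
    X = np.asarray(X, float)
    scores = np.asarray(scores, float).ravel()
    if scores.size != X.shape[1]:
        raise ValueError("one VIP score per column required")
    kept = np.flatnonzero(scores > threshold)
    if kept.size == 0:
        raise ValueError("no columns exceed the VIP threshold")
    return X[:, kept], kept
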