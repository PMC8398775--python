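"""Multi-block calibration: mid-level score fusion, SO-PLS and SO-CovSel.

Sequential orthogonalized PLS (SO-PLS) fits the response to the first
block X by PLS, orthogonalizes the second block Z against the X-scores
(removing between-block redundancy), fits the step-1 response residuals to
the orthogonalized block Z_orth by a second PLS, and combines the two
contributions additively:

    y_hat = X b + Z_orth c

New-sample prediction reuses the training-time linear map from X-scores to
Z (so only raw, preprocessed blocks are needed at prediction time).

SO-CovSel follows the same sequential-orthogonalized scheme but replaces
the latent-variable compression with CovSel — a forward selection of
individual variables that repeatedly picks the column with maximal squared
covariance with the (deflated) response and deflates both predictors and
response by projection on the orthogonal complement of the pick — followed
by ordinary least squares on the few selected columns.

Model complexity for both sequential methods is chosen on a full
(first-block, second-block) grid of cross-validated errors, the diagnostic
usually drawn as a Måge plot (RMSECV against total complexity, labelled by
the per-block pair). Zero-component / zero-variable cells are defined as
the fold-train-mean null predictor, making the grid total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import pls as _pls

__all__ = [
    "SOPLSModel",
    "MaageGrid",
    "CovSelSelection",
    "SOCovSelModel",
    "midlevel_fusion",
    "sopls_fit",
    "sopls_predict",
    "sopls_select",
    "sopls_order_check",
    "covsel",
    "socovsel_fit",
    "socovsel_predict",
    "socovsel_select",
]


# ---------------------------------------------------------------------------
# SO-PLS
# ---------------------------------------------------------------------------


@dataclass
class SOPLSModel:
    """Two-block sequential orthogonalized PLS model (first block X,
    second block Z)."""

    first_block_model: _pls.PLSModel | None  # None when lvX = 0
    second_block_model: _pls.PLSModel | None  # None when lvZ = 0
    orthogonalizer: np.ndarray | None  # G: (lvX, pZ), Z_orth = Z_c - T_X G
    lv_pair: tuple[int, int]
    x_mean: np.ndarray
    z_mean: np.ndarray
    y_mean: float
    block_order: tuple[str, str] = ("X", "Z")

    @property
    def coef_first(self) -> np.ndarray | None:
        """b of the combined predictor (on centered X)."""
        return None if self.first_block_model is None else self.first_block_model.coef

    @property
    def coef_second(self) -> np.ndarray | None:
        """c of the combined predictor (on Z_orth)."""
        return None if self.second_block_model is None else self.second_block_model.coef


def sopls_fit(X: np.ndarray, Z: np.ndarray, y: np.ndarray, lvX: int, lvZ: int) -> SOPLSModel:
    """Fit SO-PLS with ``lvX`` components on the first block and ``lvZ``
    on the orthogonalized second block.

    Either count may be zero: ``lvX = 0`` skips the first block (Z is then
    only centered), ``lvZ = 0`` reduces the model to single-block PLS on X.
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size or Z.shape[0] != y.size:
        raise ValueError("blocks and response disagree on sample count")
    x_mean = X.mean(axis=0)
    z_mean = Z.mean(axis=0)
    y_mean = float(y.mean())
    Zc = Z - z_mean

    if lvX >= 1:
        m1 = _pls.fit_pls1(X, y, lvX)
        T = m1.scores  # columns orthogonal
        # least-squares projection of Zc on span(T); TtT is diagonal but a
        # solve keeps the contract exact under roundoff
        G = np.linalg.solve(T.T @ T, T.T @ Zc)
        Zorth = Zc - T @ G
        resid = y - _pls.predict(m1, X)
    else:
        m1, G, Zorth, resid = None, None, Zc, y - y_mean

    if lvZ >= 1:
        if np.linalg.norm(Zorth) <= 1e-10 * max(float(np.linalg.norm(Zc)), 1.0):
            raise ValueError(
                "second block carries no variation orthogonal to the first-block scores"
            )
        m2 = _pls.fit_pls1(Zorth, resid, lvZ)
    else:
        m2 = None
    return SOPLSModel(
        first_block_model=m1,
        second_block_model=m2,
        orthogonalizer=G,
        lv_pair=(lvX, lvZ),
        x_mean=x_mean,
        z_mean=z_mean,
        y_mean=y_mean,
    )


def sopls_predict(model: SOPLSModel, X_new: np.ndarray, Z_new: np.ndarray) -> np.ndarray:
    """Predict new samples from raw (preprocessed) blocks.

    New X-scores come from the first-block weights; the new Z rows are
    orthogonalized with the training-time regression of Z on the X-scores.
    """
    X_new = np.atleast_2d(np.asarray(X_new, float))
    Z_new = np.atleast_2d(np.asarray(Z_new, float))
    Zc = Z_new - model.z_mean
    if model.first_block_model is not None:
        m1 = model.first_block_model
        if X_new.shape[1] != m1.n_features:
            raise ValueError("first-block column mismatch")
        T_new = (X_new - m1.x_mean) @ m1.weights
        yhat = _pls.predict(m1, X_new)
        Zorth = Zc - T_new @ model.orthogonalizer
    else:
        yhat = np.full(X_new.shape[0], model.y_mean)
        Zorth = Zc
    if model.second_block_model is not None:
        if Z_new.shape[1] != model.second_block_model.n_features:
            raise ValueError("second-block column mismatch")
        yhat = yhat + _pls.predict(model.second_block_model, Zorth)
    return yhat


@dataclass
class MaageGrid:
    """Cross-validated error surface over per-block complexity pairs."""

    rmsecv: np.ndarray  # (maxX+1, maxZ+1); [i, j] -> i first-block, j second-block
    chosen_pair: tuple[int, int]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"lv_first": i, "lv_second": j, "total": i + j, "rmsecv": self.rmsecv[i, j]}
            for i in range(self.rmsecv.shape[0])
            for j in range(self.rmsecv.shape[1])
        ]
        return pd.DataFrame(rows)

    def plot(self, path) -> None:
        """Måge plot: RMSECV vs total components, labelled by the pair."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        for i in range(self.rmsecv.shape[0]):
            for j in range(self.rmsecv.shape[1]):
                ax.scatter(i + j, self.rmsecv[i, j], c="steelblue", s=12)
                ax.annotate(f"{i},{j}", (i + j, self.rmsecv[i, j]), fontsize=5)
        ax.set_xlabel("total components")
        ax.set_ylabel("RMSECV")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _choose_pair(rmsecv: np.ndarray) -> tuple[int, int]:
    """Grid minimum; ties -> smallest total complexity, then smallest
    first-block count."""
    best = np.nanmin(rmsecv)
    candidates = np.argwhere(np.isclose(rmsecv, best, rtol=0.0, atol=1e-12))
    key = sorted(candidates, key=lambda ij: (ij[0] + ij[1], ij[0]))
    return int(key[0][0]), int(key[0][1])


def sopls_select(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    max_lv_per_block: int = 12,
    folds: int = 8,
    fold_assignment: np.ndarray | None = None,
) -> MaageGrid:
    """Cross-validate every (lvX, lvZ) pair up to a per-block maximum.

    Per fold, the first-block PLS is fitted once at the maximal feasible
    count; nested NIPALS sub-models and the score-wise orthogonalization
    then give every grid cell without refitting the first block per cell.
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float).ravel()
    n = y.size
    if fold_assignment is None:
        fold_assignment = _pls.venetian_folds(y, folds)
    n_folds = int(fold_assignment.max()) + 1
    mx = mz = max_lv_per_block
    sq_err = np.zeros((mx + 1, mz + 1))
    for k in range(n_folds):
        te = fold_assignment == k
        tr = ~te
        n_tr = int(tr.sum())
        capx = min(mx, n_tr - 1, X.shape[1])
        for lvx in range(mx + 1):
            lvx_eff = min(lvx, capx)
            m = sopls_fit_nested(X[tr], Z[tr], y[tr], lvx_eff, min(mz, n_tr - 1, Z.shape[1]))
            preds = m.predict_per_lvz(X[te], Z[te], mz)
            err = preds - y[te][:, None]
            sq_err[lvx] += (err**2).sum(axis=0)
    rmsecv = np.sqrt(sq_err / n)
    return MaageGrid(rmsecv=rmsecv, chosen_pair=_choose_pair(rmsecv))


@dataclass
class _NestedSOPLS:
    model: SOPLSModel
    coefs_z: np.ndarray | None  # (pZ, lvZ_max) nested coefficients

    def predict_per_lvz(self, X_new, Z_new, mz: int) -> np.ndarray:
        """Predictions for every second-block count 0..mz (columns)."""
        X_new = np.atleast_2d(np.asarray(X_new, float))
        Z_new = np.atleast_2d(np.asarray(Z_new, float))
        m = self.model
        Zc = Z_new - m.z_mean
        if m.first_block_model is not None:
            m1 = m.first_block_model
            T_new = (X_new - m1.x_mean) @ m1.weights
            base = _pls.predict(m1, X_new)
            Zorth = Zc - T_new @ m.orthogonalizer
        else:
            base = np.full(X_new.shape[0], m.y_mean)
            Zorth = Zc
        out = np.tile(base[:, None], (1, mz + 1))
        if self.coefs_z is not None and self.coefs_z.shape[1] > 0:
            m2 = m.second_block_model
            contrib = (Zorth - m2.x_mean) @ self.coefs_z + m2.y_mean
            avail = self.coefs_z.shape[1]
            out[:, 1 : avail + 1] += contrib
            if avail < mz:  # rank-capped: reuse the deepest model
                out[:, avail + 1 :] += contrib[:, [-1]]
        return out


def sopls_fit_nested(X, Z, y, lvX: int, lvZ_max: int) -> _NestedSOPLS:
    """Fit SO-PLS whose second block supports nested truncation (used by
    the grid search)."""
    model = sopls_fit(X, Z, y, lvX, 0)
    y = np.asarray(y, float).ravel()
    if model.first_block_model is not None:
        resid = y - _pls.predict(model.first_block_model, X)
        T = model.first_block_model.scores
        Zorth = (np.asarray(Z, float) - model.z_mean) - T @ model.orthogonalizer
    else:
        resid = y - model.y_mean
        Zorth = np.asarray(Z, float) - model.z_mean
    coefs = None
    z_scale = float(np.linalg.norm(np.asarray(Z, float) - model.z_mean))
    if np.linalg.norm(Zorth) <= 1e-10 * max(z_scale, 1.0):
        lvZ_max = 0
    if lvZ_max >= 1 and np.any(np.abs(resid - resid.mean()) > 1e-12):
        m2 = _pls._fit_max_rank(Zorth, resid, lvZ_max)
        model.second_block_model = m2
        model.lv_pair = (model.lv_pair[0], m2.n_lv)
        coefs = _pls.coefficients_per_lv(m2)
    return _NestedSOPLS(model=model, coefs_z=coefs)


def sopls_order_check(
    X, Z, y, X_test, Z_test, y_test, max_lv_per_block: int = 12, folds: int = 8
) -> dict:
    """Fit SO-PLS in both block orders and report the test RMSE of each.

    The sequential model should not depend materially on block order; the
    report carries both errors and their relative difference.
    """
    out = {}
    for tag, (A, B, A_te, B_te) in {
        "forward": (X, Z, X_test, Z_test),
        "reversed": (Z, X, Z_test, X_test),
    }.items():
        grid = sopls_select(A, B, y, max_lv_per_block=max_lv_per_block, folds=folds)
        model = sopls_fit(A, B, y, *grid.chosen_pair)
        rmse, bias, r2 = _pls.metrics(y_test, sopls_predict(model, A_te, B_te))
        out[tag] = {"lv_pair": grid.chosen_pair, "rmsep": rmse, "bias": bias, "r2": r2}
    lo = min(out["forward"]["rmsep"], out["reversed"]["rmsep"])
    out["relative_difference"] = abs(out["forward"]["rmsep"] - out["reversed"]["rmsep"]) / lo
    return out


# ---------------------------------------------------------------------------
# Mid-level fusion
# ---------------------------------------------------------------------------


def midlevel_fusion(
    scoresX_train: np.ndarray,
    scoresZ_train: np.ndarray,
    y: np.ndarray,
    scoresX_test: np.ndarray,
    scoresZ_test: np.ndarray,
    folds: int = 8,
    max_lv: int | None = None,
) -> tuple[_pls.PLSModel, _pls.CVResult, np.ndarray]:
    """Mid-level data fusion: PLS on column-concatenated per-block model
    scores, complexity chosen by cross-validation.

    The test scores must come from projecting test spectra through the
    trained block models. Returns (model, cv_result, test predictions).
    """
    Xtr = np.hstack([np.asarray(scoresX_train, float), np.asarray(scoresZ_train, float)])
    Xte = np.hstack([np.atleast_2d(scoresX_test), np.atleast_2d(scoresZ_test)])
    if Xtr.shape[0] != np.asarray(y).size:
        raise ValueError("row misalignment between scores and response")
    y = np.asarray(y, float).ravel()
    if max_lv is None:
        max_lv = min(Xtr.shape[1], Xtr.shape[0] - 2, 10)
    cv = _pls.cross_validate(Xtr, y, folds=folds, max_lv=max_lv)
    model = _pls.fit_pls1(Xtr, y, cv.chosen_lv)
    return model, cv, _pls.predict(model, Xte)


# ---------------------------------------------------------------------------
# CovSel / SO-CovSel
# ---------------------------------------------------------------------------


@dataclass
class CovSelSelection:
    block: str
    selected_indices: list[int]
    step_values: list[float]  # squared covariance at each selection step


def covsel(X: np.ndarray, y: np.ndarray, n_var: int, block: str = "X") -> CovSelSelection:
    """CovSel forward variable selection.

    Repeatedly selects the column with the largest squared covariance
    (x_j^T y)^2 with the current deflated response, then deflates both X
    and y by projecting onto the orthogonal complement of the selected
    column. Returns the ordered selected column indices.
    """
    Xd = np.array(X, float, copy=True)
    yd = np.array(y, float, copy=True).ravel()
    if n_var < 1:
        raise ValueError("n_var must be >= 1")
    selected: list[int] = []
    values: list[float] = []
    scale = float(np.abs(Xd).max()) or 1.0
    for _ in range(n_var):
        cov2 = (Xd.T @ yd) ** 2
        j = int(np.argmax(cov2))
        if np.linalg.norm(Xd[:, j]) <= 1e-12 * scale:
            raise ValueError("remaining columns are numerically zero")
        selected.append(j)
        values.append(float(cov2[j]))
        v = Xd[:, j] / np.linalg.norm(Xd[:, j])
        Xd -= np.outer(v, v @ Xd)
        yd -= v * (v @ yd)
    return CovSelSelection(block=block, selected_indices=selected, step_values=values)


@dataclass
class SOCovSelModel:
    """Sequential orthogonalized CovSel model (two blocks)."""

    selection_first: CovSelSelection | None
    selection_second: CovSelSelection | None
    coef_first: np.ndarray  # on selected centered X columns
    coef_second: np.ndarray  # on selected Z_orth columns
    orthogonalizer: np.ndarray | None  # B: (nX, pZ), Z_orth = Z_c - X_sel B
    x_mean: np.ndarray
    z_mean: np.ndarray
    y_mean: float
    n_pair: tuple[int, int] = (0, 0)
    block_order: tuple[str, str] = ("X", "Z")
    selected_first: list[int] = field(default_factory=list)
    selected_second: list[int] = field(default_factory=list)


def socovsel_fit(X: np.ndarray, Z: np.ndarray, y: np.ndarray, nX: int, nZ: int) -> SOCovSelModel:
    """Fit SO-CovSel: CovSel + least squares on the first block, Z
    orthogonalized against the selected X columns, CovSel + least squares
    of the residuals on the orthogonalized second block."""
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float).ravel()
    if nX + nZ < 1:
        raise ValueError("select at least one variable overall")
    x_mean = X.mean(axis=0)
    z_mean = Z.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    Zc = Z - z_mean
    yc = y - y_mean

    if nX >= 1:
        sel1 = covsel(Xc, yc, nX, block="X")
        Xsel = Xc[:, sel1.selected_indices]
        coef1, *_ = np.linalg.lstsq(Xsel, yc, rcond=None)
        resid = yc - Xsel @ coef1
        B, *_ = np.linalg.lstsq(Xsel, Zc, rcond=None)
        Zorth = Zc - Xsel @ B
    else:
        sel1, coef1, resid, B, Zorth = None, np.zeros(0), yc.copy(), None, Zc

    if nZ >= 1:
        sel2 = covsel(Zorth, resid, nZ, block="Z")
        Zsel = Zorth[:, sel2.selected_indices]
        coef2, *_ = np.linalg.lstsq(Zsel, resid, rcond=None)
    else:
        sel2, coef2 = None, np.zeros(0)

    return SOCovSelModel(
        selection_first=sel1,
        selection_second=sel2,
        coef_first=coef1,
        coef_second=coef2,
        orthogonalizer=B,
        x_mean=x_mean,
        z_mean=z_mean,
        y_mean=y_mean,
        n_pair=(nX, nZ),
        selected_first=sel1.selected_indices if sel1 else [],
        selected_second=sel2.selected_indices if sel2 else [],
    )


def socovsel_predict(model: SOCovSelModel, X_new: np.ndarray, Z_new: np.ndarray) -> np.ndarray:
    """Predict new samples; new Z rows are orthogonalized with the
    training-time regression of Z on the selected X columns."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    Z_new = np.atleast_2d(np.asarray(Z_new, float))
    Xc = X_new - model.x_mean
    Zc = Z_new - model.z_mean
    yhat = np.full(X_new.shape[0], model.y_mean)
    if model.selected_first:
        Xsel = Xc[:, model.selected_first]
        yhat = yhat + Xsel @ model.coef_first
        Zorth = Zc - Xsel @ model.orthogonalizer
    else:
        Zorth = Zc
    if model.selected_second:
        yhat = yhat + Zorth[:, model.selected_second] @ model.coef_second
    return yhat


def socovsel_select(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    max_var_per_block: int = 6,
    folds: int = 8,
    fold_assignment: np.ndarray | None = None,
) -> MaageGrid:
    """Grid search over (nX, nZ) selection sizes by cross-validated RMSECV,
    with the SO-PLS tie rule (smallest total, then smallest first-block)."""
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float).ravel()
    if fold_assignment is None:
        fold_assignment = _pls.venetian_folds(y, folds)
    n_folds = int(fold_assignment.max()) + 1
    m = max_var_per_block
    sq_err = np.zeros((m + 1, m + 1))
    for k in range(n_folds):
        te = fold_assignment == k
        tr = ~te
        for nx in range(m + 1):
            for nz in range(m + 1):
                if nx + nz == 0:
                    pred = np.full(int(te.sum()), float(y[tr].mean()))
                else:
                    mdl = socovsel_fit(X[tr], Z[tr], y[tr], nx, nz)
                    pred = socovsel_predict(mdl, X[te], Z[te])
                sq_err[nx, nz] += float(((pred - y[te]) ** 2).sum())
    rmsecv = np.sqrt(sq_err / y.size)
    return MaageGrid(rmsecv=rmsecv, chosen_pair=_choose_pair(rmsecv))
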