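"""Fusion strategies: mid-level score fusion, SO-PLS, CovSel, SO-CovSel."""

import numpy as np
import pytest

from chiralspec import multiblock as mb
from chiralspec import pls


@pytest.fixture
def two_blocks(rng):
    """Two blocks sharing one latent factor plus one factor unique to each."""
    n = 24
    t_shared = rng.normal(size=n)
    t_x = rng.normal(size=n)
    t_z = rng.normal(size=n)
    X = np.column_stack([t_shared, t_x]) @ rng.normal(size=(2, 7))
    X += 0.02 * rng.normal(size=X.shape)
    Z = np.column_stack([t_shared, t_z]) @ rng.normal(size=(2, 6))
    Z += 0.02 * rng.normal(size=Z.shape)
    y = 2.0 * t_shared + 1.0 * t_x + 0.5 * t_z
    return X, Z, y


class TestSOPLSFit:
    def test_lvz_zero_reduces_to_single_block_pls(self, two_blocks):
        X, Z, y = two_blocks
        model = mb.sopls_fit(X, Z, y, 2, 0)
        single = pls.fit_pls1(X, y, 2)
        np.testing.assert_allclose(model.coef_first, single.coef, atol=1e-12)
        np.testing.assert_allclose(
            mb.sopls_predict(model, X, Z), pls.predict(single, X), atol=1e-12
        )

    def test_orthogonalization_contract(self, two_blocks):
        X, Z, y = two_blocks
        model = mb.sopls_fit(X, Z, y, 2, 2)
        T = model.first_block_model.scores
        Zc = Z - model.z_mean
        Zorth = Zc - T @ model.orthogonalizer
        assert np.max(np.abs(T.T @ Zorth)) <= 1e-8 * np.linalg.norm(Z)

    def test_already_orthogonal_block_unchanged(self, rng):
        X = rng.normal(size=(20, 4))
        y = X @ rng.normal(size=4) + 0.1 * rng.normal(size=20)
        model_x = pls.fit_pls1(X, y, 2)
        T = model_x.scores
        Z = rng.normal(size=(20, 5))
        Z -= Z.mean(axis=0)
        Z -= T @ np.linalg.solve(T.T @ T, T.T @ Z)  # construct Z orthogonal to T
        model = mb.sopls_fit(X, Z, y, 2, 1)
        Zorth = (Z - model.z_mean) - model.first_block_model.scores @ model.orthogonalizer
        np.testing.assert_allclose(Zorth, Z - Z.mean(axis=0), atol=1e-10)

    def test_duplicated_block_adds_nothing_at_full_rank(self, rng):
        """Orthogonalizing a copy of X against the full X-score space
        leaves no usable variation: the combined training fit equals the
        first-step fit."""
        X = rng.normal(size=(15, 4))
        y = X @ rng.normal(size=4) + 0.05 * rng.normal(size=15)
        m_full = mb.sopls_fit(X, X.copy(), y, 4, 0)
        fit1 = mb.sopls_predict(m_full, X, X)
        try:
            m_both = mb.sopls_fit(X, X.copy(), y, 4, 1)
            fit2 = mb.sopls_predict(m_both, X, X)
        except ValueError:  # orthogonalized copy may be exactly rank-zero
            fit2 = fit1
        np.testing.assert_allclose(fit1, fit2, atol=1e-6)

    def test_training_fit_decomposes_additively(self, two_blocks):
        X, Z, y = two_blocks
        model = mb.sopls_fit(X, Z, y, 2, 2)
        step1 = pls.predict(model.first_block_model, X)
        T = model.first_block_model.scores
        Zorth = (Z - model.z_mean) - T @ model.orthogonalizer
        step3 = pls.predict(model.second_block_model, Zorth)
        np.testing.assert_allclose(
            mb.sopls_predict(model, X, Z), step1 + step3, atol=1e-8
        )


class TestSOPLSPredict:
    def test_two_route_agreement_on_new_samples(self, two_blocks, rng):
        """Compact prediction equals the explicit project-orthogonalize-add
        computation."""
        X, Z, y = two_blocks
        model = mb.sopls_fit(X, Z, y, 2, 1)
        Xn = rng.normal(size=(5, X.shape[1]))
        Zn = rng.normal(size=(5, Z.shape[1]))
        m1 = model.first_block_model
        T_new = (Xn - m1.x_mean) @ m1.weights
        Zorth_new = (Zn - model.z_mean) - T_new @ model.orthogonalizer
        explicit = pls.predict(m1, Xn) + pls.predict(model.second_block_model, Zorth_new)
        np.testing.assert_allclose(mb.sopls_predict(model, Xn, Zn), explicit, atol=1e-10)

    def test_column_mismatch(self, two_blocks):
        X, Z, y = two_blocks
        model = mb.sopls_fit(X, Z, y, 1, 1)
        with pytest.raises(ValueError):
            mb.sopls_predict(model, X[:, :-1], Z)


class TestSOPLSSelect:
    def test_noiseless_single_block_response_drops_second_block(self, rng):
        X = rng.normal(size=(24, 5))
        y = X @ rng.normal(size=5)
        Z = rng.normal(size=(24, 4))
        grid = mb.sopls_select(X, Z, y, max_lv_per_block=4, folds=8)
        assert grid.chosen_pair[1] == 0

    def test_both_blocks_needed(self, two_blocks):
        X, Z, y = two_blocks
        grid = mb.sopls_select(X, Z, y, max_lv_per_block=3, folds=8)
        assert grid.chosen_pair[0] >= 1
        assert grid.chosen_pair[1] >= 1

    def test_null_cell_is_fold_mean_baseline(self, two_blocks):
        X, Z, y = two_blocks
        grid = mb.sopls_select(X, Z, y, max_lv_per_block=2, folds=8)
        folds = pls.venetian_folds(y, 8)
        errs = []
        for k in range(8):
            te = folds == k
            errs.extend(y[te] - y[~te].mean())
        np.testing.assert_allclose(
            grid.rmsecv[0, 0], np.sqrt(np.mean(np.square(errs))), atol=1e-10
        )

    def test_grid_shape_and_frame(self, two_blocks):
        X, Z, y = two_blocks
        grid = mb.sopls_select(X, Z, y, max_lv_per_block=2, folds=6)
        assert grid.rmsecv.shape == (3, 3)
        frame = grid.to_frame()
        assert len(frame) == 9
        assert set(frame.columns) == {"lv_first", "lv_second", "total", "rmsecv"}


class TestOrderCheck:
    def test_identical_blocks_give_identical_errors(self, rng):
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + 0.1 * rng.normal(size=20)
        Xt = rng.normal(size=(6, 5))
        yt = Xt @ rng.normal(size=5)
        rep = mb.sopls_order_check(
            X, X.copy(), y, Xt, Xt.copy(), yt, max_lv_per_block=3, folds=5
        )
        assert rep["forward"]["rmsep"] == pytest.approx(rep["reversed"]["rmsep"], rel=1e-8)


class TestCovSel:
    def test_single_step_picks_max_squared_covariance(self, rng):
        X = rng.normal(size=(30, 6))
        y = X[:, 4] + 0.01 * rng.normal(size=30)
        sel = mb.covsel(X - X.mean(0), y - y.mean(), 1)
        cov2 = ((X - X.mean(0)).T @ (y - y.mean())) ** 2
        assert sel.selected_indices == [int(np.argmax(cov2))]

    def test_orthogonal_columns_selected_in_covariance_order(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(20, 4)))
        X = q  # orthonormal columns; deflation leaves the others untouched
        y = q @ np.array([0.5, -3.0, 1.5, 0.1])
        sel = mb.covsel(X, y, 4)
        cov2 = (X.T @ y) ** 2
        assert sel.selected_indices == list(np.argsort(-cov2))

    def test_never_selects_twice(self, rng):
        X = rng.normal(size=(15, 5))
        y = rng.normal(size=15)
        sel = mb.covsel(X, y, 5)
        assert len(set(sel.selected_indices)) == 5


class TestSOCovSel:
    def test_nz_zero_is_ols_on_selected_columns(self, rng):
        X = rng.normal(size=(18, 6))
        y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=18)
        Z = rng.normal(size=(18, 4))
        model = mb.socovsel_fit(X, Z, y, 3, 0)
        Xc = X - X.mean(axis=0)
        sel = model.selected_first
        b, *_ = np.linalg.lstsq(Xc[:, sel], y - y.mean(), rcond=None)
        np.testing.assert_allclose(model.coef_first, b, atol=1e-10)

    def test_exact_recovery_of_generating_columns(self, rng):
        """Noiseless y built from two X columns and one Z column: the
        (2, 1) model finds those columns and fits to machine precision."""
        X = rng.normal(size=(25, 8))
        Z = rng.normal(size=(25, 6))
        y = 2.0 * X[:, 1] - 1.5 * X[:, 5] + 1.0 * Z[:, 2]
        model = mb.socovsel_fit(X, Z, y, 2, 1)
        assert set(model.selected_first) == {1, 5}
        assert model.selected_second == [2]
        resid = mb.socovsel_predict(model, X, Z) - y
        assert np.sqrt(np.mean(resid**2)) < 1e-8

    def test_full_selection_full_rank_equals_joint_least_squares(self, rng):
        X = rng.normal(size=(20, 3))
        Z = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        model = mb.socovsel_fit(X, Z, y, 3, 2)
        fitted = mb.socovsel_predict(model, X, Z)
        XZ = np.hstack([X - X.mean(0), Z - Z.mean(0)])
        beta, *_ = np.linalg.lstsq(XZ, y - y.mean(), rcond=None)
        np.testing.assert_allclose(fitted, XZ @ beta + y.mean(), atol=1e-8)

    def test_orthogonalization_contract(self, rng):
        X = rng.normal(size=(20, 5))
        Z = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        model = mb.socovsel_fit(X, Z, y, 2, 2)
        Xsel = (X - model.x_mean)[:, model.selected_first]
        Zorth = (Z - model.z_mean) - Xsel @ model.orthogonalizer
        assert np.max(np.abs(Xsel.T @ Zorth)) <= 1e-8 * np.linalg.norm(Z)

    def test_select_noiseless_one_x_column(self, rng):
        X = rng.normal(size=(24, 5))
        Z = rng.normal(size=(24, 4))
        y = 3.0 * X[:, 2]
        grid = mb.socovsel_select(X, Z, y, max_var_per_block=2, folds=8)
        assert grid.chosen_pair == (1, 0)

    def test_select_needs_both_blocks(self, rng):
        X = rng.normal(size=(24, 5))
        Z = rng.normal(size=(24, 4))
        y = 2.0 * X[:, 0] + 2.0 * Z[:, 1]
        grid = mb.socovsel_select(X, Z, y, max_var_per_block=2, folds=8)
        assert grid.chosen_pair[0] >= 1
        assert grid.chosen_pair[1] >= 1


class TestMidLevelFusion:
    def test_degenerate_second_block_matches_single_block(self, rng):
        sX = rng.normal(size=(20, 3))
        y = sX @ np.array([1.0, 0.5, -0.2]) + 0.05 * rng.normal(size=20)
        sZ = np.zeros((20, 2))
        model, cv, pred = mb.midlevel_fusion(sX, sZ, y, sX[:5], sZ[:5], folds=5)
        single = pls.fit_pls1(sX, y, cv.chosen_lv)
        np.testing.assert_allclose(pred, pls.predict(single, sX[:5]), atol=1e-8)

    def test_duplicated_block_preserves_predictions(self, rng):
        sX = rng.normal(size=(20, 3))
        y = sX @ np.array([1.0, 0.5, -0.2])
        _, _, pred_dup = mb.midlevel_fusion(sX, sX.copy(), y, sX[:5], sX[:5], folds=5)
        _, _, pred_one = mb.midlevel_fusion(sX, np.zeros((20, 1)), y, sX[:5], np.zeros((5, 1)), folds=5)
        np.testing.assert_allclose(pred_dup, pred_one, atol=1e-6)

    def test_noiseless_scores_give_tiny_test_error(self, rng):
        sX = rng.normal(size=(22, 3))
        sZ = rng.normal(size=(22, 2))
        beta = np.array([2.0, -1.0, 0.5, 1.0, 0.3])
        y = np.hstack([sX, sZ]) @ beta
        Xt = rng.normal(size=(6, 3))
        Zt = rng.normal(size=(6, 2))
        _, _, pred = mb.midlevel_fusion(sX, sZ, y, Xt, Zt, folds=8)
        truth = np.hstack([Xt, Zt]) @ beta
        assert np.sqrt(np.mean((pred - truth) ** 2)) < 1e-6

    def test_row_misalignment_rejected(self, rng):
        with pytest.raises(ValueError):
            mb.midlevel_fusion(
                rng.normal(size=(10, 2)),
                rng.normal(size=(10, 2)),
                rng.normal(size=9),
                rng.normal(size=(3, 2)),
                rng.normal(size=(3, 2)),
            )
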