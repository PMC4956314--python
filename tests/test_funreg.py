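"""Basis construction, quadrature scores, ridge fits, LOOCV, ensembling."""

import numpy as np
import pytest

from hydrofda.errors import (
    AlignmentError,
    DegenerateResponseError,
    InsufficientDataError,
    ParameterError,
)
from hydrofda.funreg import (
    ensemble_predict,
    compute_scores,
    fit_per_stream_models,
    fit_scalar_on_function,
    loocv_score,
    make_basis,
    reconstruct_beta,
    select_lambda,
    ScoreMatrix,
)
from hydrofda.gmrf import LatentDischarge
from hydrofda.responses import LaggedDesignRow, SeasonalResponse

from conftest import design_rows_from_dataset


def _rows_from_curves(curves_by_season, streams=("s1",)):
    """Design rows with given per-season curves (same for every stream)."""
    rows = []
    for s, curve in sorted(curves_by_season.items()):
        covs = {
            st: LatentDischarge(st, s - 1, mean=np.asarray(curve, float),
                                sd=np.zeros(len(curve)))
            for st in streams
        }
        rows.append(
            LaggedDesignRow(SeasonalResponse("ppr", s, 1.0, 1), covs)
        )
    return rows


class TestBasis:
    def test_fourier_constant_function(self, grid):
        b = make_basis("fourier", 1, grid)
        np.testing.assert_allclose(
            b.values[0], 1.0 / np.sqrt(grid.T), rtol=1e-12
        )
        assert b.gram()[0, 0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("family,K", [("fourier", 3), ("fourier", 5),
                                          ("fourier", 8), ("bspline", 4),
                                          ("bspline", 7)])
    def test_orthonormal_on_grid(self, grid, family, K):
        b = make_basis(family, K, grid)
        err = np.abs(b.gram() - np.eye(K)).max()
        # B-splines are orthonormalised exactly; Fourier is exact under the
        # left-sum (DFT) quadrature
        assert err < 1e-10

    def test_super_resolution_rejected(self, grid):
        with pytest.raises(ParameterError):
            make_basis("fourier", grid.M + 1, grid)

    def test_unknown_family_rejected(self, grid):
        with pytest.raises(ParameterError):
            make_basis("wavelet", 4, grid)


class TestScores:
    def test_constant_curve_integrates_to_sqrt_T(self, grid):
        b = make_basis("fourier", 1, grid)
        rows = _rows_from_curves({2000: np.ones(grid.n_nodes)})
        Z = compute_scores(rows, b).Z
        # left Riemann sum over M terms: M*dt/sqrt(T) = sqrt(61)
        assert Z[0, 0] == pytest.approx(np.sqrt(61.0), rel=1e-12)

    def test_basis_function_recovers_unit_vector(self, grid):
        b = make_basis("fourier", 4, grid)
        rows = _rows_from_curves({2000: b.values[1]})
        Z = compute_scores(rows, b).Z[0]
        assert abs(Z[1] - 1.0) < 0.02
        assert np.abs(np.delete(Z, 1)).max() < 0.02

    def test_matches_bruteforce_summation(self):
        from hydrofda.io_ingest import SeasonGrid

        g = SeasonGrid(2000, np.arange(10, dtype=float), 1.0)
        rng = np.random.default_rng(4)
        b = make_basis("fourier", 3, g)
        x = rng.normal(size=10)
        rows = _rows_from_curves({2000: x})
        Z = compute_scores(rows, b).Z[0]
        brute = np.zeros(3)
        for k in range(3):
            for m in range(g.M):  # m = 0..M-1
                brute[k] += b.values[k, m] * x[m] * g.dt
        np.testing.assert_allclose(Z, brute, atol=1e-12)

    def test_grid_mismatch_rejected(self, grid):
        b = make_basis("fourier", 3, grid)
        rows = _rows_from_curves({2000: np.ones(10)})
        with pytest.raises(AlignmentError):
            compute_scores(rows, b)

    def test_stream_major_column_order(self, grid):
        b = make_basis("fourier", 2, grid)
        rows = []
        curves = {"a": np.ones(grid.n_nodes), "b": 2 * np.ones(grid.n_nodes)}
        covs = {
            st: LatentDischarge(st, 1999, mean=c, sd=np.zeros_like(c))
            for st, c in curves.items()
        }
        rows.append(LaggedDesignRow(SeasonalResponse("ppr", 2000, 1.0, 1), covs))
        sm = compute_scores(rows, b)
        assert sm.streams == ("a", "b")
        # columns 0..1 belong to stream a, 2..3 to stream b (twice as large)
        np.testing.assert_allclose(sm.Z[0, 2:], 2 * sm.Z[0, :2], atol=1e-12)


def _random_problem(rng, n=20, p=3, noise=0.0):
    Z = rng.normal(size=(n, p))
    gamma = rng.normal(size=p)
    alpha = rng.normal()
    y = alpha + Z @ gamma + noise * rng.normal(size=n)
    return y, Z, alpha, gamma


def _score_matrix(Z):
    return ScoreMatrix(
        Z=Z, streams=("s",), K=Z.shape[1], seasons=tuple(range(Z.shape[0]))
    )


class TestFit:
    def test_exact_recovery_zero_noise(self, grid):
        rng = np.random.default_rng(6)
        basis = make_basis("fourier", 3, grid)
        y, Z, alpha, gamma = _random_problem(rng)
        fit = fit_scalar_on_function(y, _score_matrix(Z), 0.0, basis)
        assert abs(fit.alpha - alpha) < 1e-8
        np.testing.assert_allclose(fit.gamma, gamma, atol=1e-8)

    def test_matches_normal_equations_oracle(self, grid):
        """lambda=0 fits equal an explicit least-squares solve."""
        rng = np.random.default_rng(7)
        basis = make_basis("fourier", 4, grid)
        for _ in range(30):
            y, Z, *_ = _random_problem(rng, n=15, p=4, noise=0.6)
            fit = fit_scalar_on_function(y, _score_matrix(Z), 0.0, basis)
            X = np.column_stack([np.ones(15), Z])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert abs(fit.alpha - coef[0]) < 1e-8
            np.testing.assert_allclose(fit.gamma, coef[1:], atol=1e-8)

    def test_residual_identity_and_orthogonality(self, grid):
        rng = np.random.default_rng(8)
        basis = make_basis("fourier", 3, grid)
        y, Z, *_ = _random_problem(rng, noise=1.0)
        fit = fit_scalar_on_function(y, _score_matrix(Z), 0.0, basis)
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-12)
        np.testing.assert_allclose(Z.T @ fit.residuals, 0.0, atol=1e-8)
        assert 0.0 <= fit.r2 <= 1.0

    def test_infinite_penalty_shrinks_to_mean(self, grid):
        rng = np.random.default_rng(9)
        basis = make_basis("fourier", 3, grid)
        y, Z, *_ = _random_problem(rng, noise=1.0)
        fit = fit_scalar_on_function(y, _score_matrix(Z), 1e12, basis)
        np.testing.assert_allclose(fit.gamma, 0.0, atol=1e-8)
        np.testing.assert_allclose(fit.fitted, y.mean(), atol=1e-6)
        assert fit.r2 == pytest.approx(0.0, abs=1e-8)

    def test_constant_response_rejected(self, grid):
        basis = make_basis("fourier", 3, grid)
        Z = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(DegenerateResponseError):
            fit_scalar_on_function(np.full(10, 2.5), _score_matrix(Z), 0.0, basis)

    def test_too_few_rows_rejected(self, grid):
        basis = make_basis("fourier", 3, grid)
        with pytest.raises(InsufficientDataError):
            fit_scalar_on_function(
                np.array([1.0, 2.0]), _score_matrix(np.ones((2, 3))), 0.0, basis
            )

    def test_negative_penalty_rejected(self, grid):
        basis = make_basis("fourier", 3, grid)
        with pytest.raises(ParameterError):
            fit_scalar_on_function(
                np.arange(5.0), _score_matrix(np.ones((5, 3))), -1.0, basis
            )

    def test_permutation_invariance(self, grid):
        rng = np.random.default_rng(10)
        basis = make_basis("fourier", 3, grid)
        y, Z, *_ = _random_problem(rng, noise=0.5)
        perm = rng.permutation(y.size)
        a = fit_scalar_on_function(y, _score_matrix(Z), 0.0, basis)
        b = fit_scalar_on_function(y[perm], _score_matrix(Z[perm]), 0.0, basis)
        assert a.alpha == pytest.approx(b.alpha, abs=1e-10)
        np.testing.assert_allclose(a.gamma, b.gamma, atol=1e-10)
        assert a.r2 == pytest.approx(b.r2, abs=1e-12)

    def test_scale_equivariance(self, grid):
        rng = np.random.default_rng(11)
        basis = make_basis("fourier", 3, grid)
        y, Z, *_ = _random_problem(rng, noise=0.5)
        c = 3.7
        a = fit_scalar_on_function(y, _score_matrix(Z), 0.0, basis)
        b = fit_scalar_on_function(y, _score_matrix(c * Z), 0.0, basis)
        np.testing.assert_allclose(b.gamma, a.gamma / c, atol=1e-10)
        np.testing.assert_allclose(b.fitted, a.fitted, atol=1e-10)

    def test_r2_monotone_in_nested_fourier_bases(self, grid, default_dataset):
        rows = design_rows_from_dataset(default_dataset)
        y = np.array([r.response.y for r in rows])
        r2s = []
        for K in (1, 3, 5):
            b = make_basis("fourier", K, grid)
            sc = compute_scores(rows, b)
            r2s.append(fit_scalar_on_function(y, sc, 0.0, b).r2)
        assert r2s[0] <= r2s[1] + 1e-10 <= r2s[2] + 2e-10


class TestSelectLambda:
    def test_singleton_grid_returned(self):
        rng = np.random.default_rng(12)
        y, Z, *_ = _random_problem(rng, noise=0.5)
        assert select_lambda(y, _score_matrix(Z), [3.5]) == 3.5

    def test_zero_noise_prefers_unpenalised(self):
        rng = np.random.default_rng(13)
        y, Z, *_ = _random_problem(rng, n=25, noise=0.0)
        assert select_lambda(y, _score_matrix(Z), [0.0, 1.0, 10.0]) == 0.0

    def test_pure_noise_prefers_shrinkage(self):
        rng = np.random.default_rng(14)
        wins = 0
        for _ in range(50):
            n, p = 12, 6
            Z = rng.normal(size=(n, p))
            y = rng.normal(size=n)  # response unrelated to Z
            wins += select_lambda(y, _score_matrix(Z), [0.0, 10.0]) == 10.0
        assert wins >= 40

    def test_loocv_identity_matches_explicit_refits(self):
        """Closed-form LOOCV equals brute-force leave-one-out refitting."""
        rng = np.random.default_rng(15)
        n, p = 12, 3
        Z = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        for lam in (0.0, 0.5, 5.0):
            sse = 0.0
            for i in range(n):
                keep = np.arange(n) != i
                Zi, yi = Z[keep], y[keep]
                zb = Zi.mean(axis=0)
                Zc = Zi - zb
                g = np.linalg.solve(
                    Zc.T @ Zc + lam * np.eye(p), Zc.T @ (yi - yi.mean())
                )
                a = yi.mean() - zb @ g
                sse += (y[i] - (a + Z[i] @ g)) ** 2
            assert loocv_score(y, Z, lam) == pytest.approx(sse / n, rel=1e-8)


class TestReconstructAndEnsemble:
    def test_single_coefficient_gives_constant_beta(self, grid):
        basis = make_basis("fourier", 3, grid)
        rng = np.random.default_rng(16)
        rows = _rows_from_curves(
            {2000 + i: rng.normal(size=grid.n_nodes) for i in range(6)}
        )
        y = rng.normal(size=6)
        sc = compute_scores(rows, basis)
        fit = fit_scalar_on_function(y, sc, 0.0, basis)
        fit.gamma[:] = [1.0, 0.0, 0.0]
        betas = reconstruct_beta(fit, basis)
        np.testing.assert_allclose(betas["s1"], 1.0 / np.sqrt(grid.T))

    def test_quadrature_identity(self, grid):
        """<beta_j, X> reproduces the fitted contribution Z gamma."""
        basis = make_basis("fourier", 4, grid)
        rng = np.random.default_rng(17)
        curves = {2000 + i: rng.normal(size=grid.n_nodes) for i in range(8)}
        rows = _rows_from_curves(curves)
        y = rng.normal(size=8)
        sc = compute_scores(rows, basis)
        fit = fit_scalar_on_function(y, sc, 0.0, basis)
        beta = reconstruct_beta(fit, basis)["s1"]
        for i, (s, x) in enumerate(sorted(curves.items())):
            contrib = np.sum(beta[:-1] * np.asarray(x)[:-1]) * grid.dt
            assert contrib == pytest.approx(float(sc.Z[i] @ fit.gamma), abs=1e-10)

    def test_per_stream_cardinality_and_symmetry(self, grid, default_dataset):
        rows = design_rows_from_dataset(default_dataset)
        basis = make_basis("fourier", 5, grid)
        fits = fit_per_stream_models(rows, basis, lam=0.0)
        assert set(fits) == set(default_dataset.scenario.streams)
        # identical covariates across streams -> identical R^2
        rng = np.random.default_rng(18)
        rows_same = []
        for i in range(8):
            x = rng.normal(size=grid.n_nodes)
            covs = {
                st: LatentDischarge(st, 1999 + i, x, np.zeros_like(x))
                for st in ("a", "b", "c")
            }
            rows_same.append(
                LaggedDesignRow(
                    SeasonalResponse("ppr", 2000 + i, float(rng.normal()), 1),
                    covs,
                )
            )
        fits_same = fit_per_stream_models(rows_same, basis, lam=0.0)
        r2s = [f.r2 for f in fits_same.values()]
        assert max(r2s) - min(r2s) < 1e-10

    def test_signal_stream_outscores_noise_stream(self, grid):
        """Only stream A carries signal: its per-stream R^2 wins almost
        always."""
        basis = make_basis("fourier", 3, grid)
        rng = np.random.default_rng(19)
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            rows = []
            ys = []
            for i in range(12):
                xa = rng.normal(size=grid.n_nodes)
                xb = rng.normal(size=grid.n_nodes)
                covs = {
                    "a": LatentDischarge("a", 1999 + i, xa, np.zeros_like(xa)),
                    "b": LatentDischarge("b", 1999 + i, xb, np.zeros_like(xb)),
                }
                y_i = float(xa[:-1].sum() * grid.dt / grid.T + 0.1 * rng.normal())
                rows.append(
                    LaggedDesignRow(
                        SeasonalResponse("ppr", 2000 + i, y_i, 1), covs
                    )
                )
            fits = fit_per_stream_models(rows, basis, lam=0.0)
            wins += fits["a"].r2 > fits["b"].r2
        assert wins >= int(0.9 * n_rep)

    def test_ensemble_of_identical_fits_is_identity(self, grid, default_dataset):
        rows = design_rows_from_dataset(default_dataset)
        basis = make_basis("fourier", 5, grid)
        fits = fit_per_stream_models(rows, basis, lam=1.0)
        one = fits["canada"]
        ens = ensemble_predict({"x": one, "y": one, "z": one})
        np.testing.assert_allclose(ens.predicted, one.fitted)
        np.testing.assert_allclose(ens.se, one.se_fit)
        assert ens.r2_avg == pytest.approx(one.r2)

    def test_averaged_r2_is_arithmetic_mean(self, grid, default_dataset):
        rows = design_rows_from_dataset(default_dataset)
        basis = make_basis("fourier", 5, grid)
        fits = fit_per_stream_models(rows, basis, lam=0.0)
        ens = ensemble_predict(fits)
        assert ens.r2_avg == pytest.approx(
            np.mean([f.r2 for f in fits.values()])
        )
        np.testing.assert_allclose(ens.upper - ens.predicted, 2 * ens.se)
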