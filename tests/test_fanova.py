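import numpy as np
import pandas as pd
import pytest
from scipy.linalg import cho_factor, cho_solve

from phenofda import (
    SynthGrowthConfig,
    TraitMatrix,
    build_design,
    coef_covariance,
    fanova_fit,
    gcv_score,
    make_basis,
    parse_formula,
    penalty_matrix,
    predict_curve,
    synth_growth,
)
from phenofda.fanova import DEFAULT_LAMBDA_GRID, RankError
from conftest import spline_truth_config


class TestBasis:
    def test_knot_rule_rank(self):
        assert make_basis(np.arange(28)).K == 14  # degree 3, 10 interior knots
        assert make_basis(np.arange(8)).K == 4    # boundary of the rule: pure cubic

    def test_too_few_days_requires_explicit_knots(self):
        with pytest.raises(ValueError, match="n_interior"):
            make_basis(np.arange(6))
        assert make_basis(np.arange(6), n_interior=0).K == 4

    def test_partition_of_unity(self, rng):
        basis = make_basis(np.linspace(0, 44, 28))
        t = rng.uniform(0, 44, 100)
        assert np.allclose(basis.design(t).sum(axis=1), 1.0)

    def test_no_extrapolation(self):
        basis = make_basis(np.linspace(0, 10, 12), n_interior=2)
        with pytest.raises(ValueError, match="domain"):
            basis.design([-0.1])


@pytest.fixture(scope="module")
def basis():
    return make_basis(np.linspace(1, 44, 28))


class TestPenalty:

    def test_symmetric_psd(self, basis):
        omega = penalty_matrix(basis)
        assert np.allclose(omega, omega.T)
        assert np.linalg.eigvalsh(omega).min() > -1e-10

    def test_constants_and_linears_in_null_space(self, basis):
        omega = penalty_matrix(basis)
        ones = np.ones(basis.K)  # partition of unity represents the constant 1
        assert np.abs(omega @ ones).max() < 1e-9
        # Greville abscissae represent the identity function t
        knots = basis.knots
        greville = np.array(
            [knots[v + 1 : v + 1 + basis.degree].mean() for v in range(basis.K)]
        )
        t = np.linspace(1, 44, 50)
        assert np.allclose(basis.design(t) @ greville, t)
        assert np.abs(omega @ greville).max() < 1e-6

    def test_matches_dense_trapezoid_quadrature(self, basis):
        omega = penalty_matrix(basis)
        breaks = np.unique(basis.knots)
        dense = np.zeros_like(omega)
        for a, b in zip(breaks[:-1], breaks[1:]):
            t = np.linspace(a, b, 20001)
            d2 = basis.deriv2(t)
            w = np.full(t.size, (b - a) / (t.size - 1))
            w[0] *= 0.5
            w[-1] *= 0.5
            dense += (d2.T * w) @ d2
        assert np.abs(omega - dense).max() < 1e-8

    def test_degree_too_low(self):
        basis = make_basis(np.linspace(0, 1, 10), degree=1, n_interior=2)
        with pytest.raises(ValueError):
            penalty_matrix(basis)


class TestDesign:
    def test_two_factor_interaction_dimensions(self):
        fac = pd.DataFrame({"A": ["a1", "a1", "a2", "a2"], "B": ["b1", "b2", "b1", "b2"]})
        X, names = build_design(fac, parse_formula("y ~ A + B + A:B"))
        assert X.shape == (4, 4)
        assert names == ["intercept", "A[a2]", "B[b2]", "A[a2]:B[b2]"]
        # interaction column = product of the two indicator columns
        assert np.array_equal(X[:, 3], X[:, 1] * X[:, 2])

    def test_rcbd_140_genotypes_3_blocks(self):
        # randomized complete block design: 140 genotypes x 3 blocks, one
        # replicate per cell -> 1 + 139 + 2 = 142 columns, blocks last
        fac = pd.DataFrame(
            {
                "genotype": [f"g{g:03d}" for g in range(1, 141) for _ in range(3)],
                "block": [f"b{b}" for _ in range(140) for b in (1, 2, 3)],
            }
        )
        X, names = build_design(fac, parse_formula("size ~ genotype + block"))
        assert X.shape == (420, 142)
        assert names[0] == "intercept"
        assert names[140] == "block[b2]" and names[141] == "block[b3]"
        # a baseline-everything plant's row is e_1
        assert np.array_equal(X[0], np.eye(142)[0])

    def test_single_level_factor_rejected(self):
        fac = pd.DataFrame({"A": ["a", "a", "a"]})
        with pytest.raises(ValueError, match="single level"):
            build_design(fac, parse_formula("y ~ A"))

    def test_unknown_factor_rejected(self):
        fac = pd.DataFrame({"A": ["a", "b"]})
        with pytest.raises(ValueError, match="unknown factor"):
            build_design(fac, parse_formula("y ~ A + C"))


@pytest.fixture(scope="module")
def problem():
    rng = np.random.default_rng(5)
    Z = rng.normal(size=(60, 8))
    y = rng.normal(size=60)
    L = rng.normal(size=(8, 8))
    D = L @ L.T
    return Z, y, D


class TestGCV:

    def test_matches_dense_hat_matrix(self, problem):
        Z, y, D = problem
        for lam in (0.1, 1.0, 10.0):
            H = Z @ np.linalg.solve(Z.T @ Z + lam * D, Z.T)
            rss = np.sum((y - H @ y) ** 2)
            expected = y.size * rss / (y.size - np.trace(H)) ** 2
            assert np.isclose(gcv_score(lam, y, Z, D), expected)

    def test_trace_monotone_in_lambda(self, problem):
        Z, y, D = problem
        traces = []
        for lam in np.logspace(-3, 4, 15):
            f = cho_factor(Z.T @ Z + lam * D)
            traces.append(np.trace(cho_solve(f, Z.T @ Z)))
        assert np.all(np.diff(traces) <= 1e-9)

    def test_negative_lambda_rejected(self, problem):
        Z, y, D = problem
        with pytest.raises(ValueError):
            gcv_score(-1.0, y, Z, D)


class TestFit:
    def test_constant_response_intercept_only(self):
        days = np.linspace(0, 10, 12)
        meta = pd.DataFrame(
            {"plant_id": [f"p{i}" for i in range(6)], "genotype": list("aaabbb"), "block": "b1"}
        )
        Y = TraitMatrix(np.full((6, 12), 7.5), days, meta)
        for lam in (1e-6, 1.0, 1e6):
            fit = fanova_fit(Y, "size ~ genotype", lam_grid=[lam], n_interior=0)
            curve = predict_curve(fit, np.eye(fit.p)[0], np.linspace(0, 10, 40))
            assert np.allclose(curve, 7.5, atol=1e-8)

    def test_superposition_at_fixed_lambda(self):
        cfg = SynthGrowthConfig(n_genotypes=4, seed=9)
        Y, fac, _ = synth_growth(cfg)
        fit1 = fanova_fit(Y, "size ~ genotype + block", lam_grid=[1.0])
        Y2 = TraitMatrix(2 * Y.values, Y.days, Y.meta)
        fit2 = fanova_fit(Y2, "size ~ genotype + block", lam_grid=[1.0])
        assert np.allclose(fit2.beta, 2 * fit1.beta, rtol=1e-10)

    def test_noiseless_spline_truth_recovered_exactly(self):
        cfg = spline_truth_config()
        Y, fac, truth = synth_growth(cfg)
        fit = fanova_fit(Y, "size ~ genotype + block", lam_grid=[0.0, 1e-6, 1e-2])
        assert fit.lam == 0.0  # GCV: zero RSS needs no smoothing
        tg = np.linspace(*cfg.day_range, 150)
        curves = [truth["mu"]] + truth["genotype"] + truth["block"]
        for j, curve in enumerate(curves):
            est = predict_curve(fit, np.eye(fit.p)[j], tg)
            assert np.abs(est - np.asarray(curve(tg))).max() < 1e-6

    def test_gcv_selected_lambda_is_grid_argmin(self):
        Y, fac, _ = synth_growth(SynthGrowthConfig(seed=21))
        fit = fanova_fit(Y, "size ~ genotype + block")
        best = np.argmin(fit.gcv)
        assert fit.lam == fit.lam_grid[best]
        assert np.all(fit.gcv[best] <= fit.gcv)
        # ties break toward the smaller lambda
        assert best == np.flatnonzero(fit.gcv == fit.gcv[best])[0]

    def test_large_lambda_drives_curves_linear(self):
        Y, fac, _ = synth_growth(SynthGrowthConfig(seed=4))
        fit = fanova_fit(Y, "size ~ genotype + block", lam_grid=[1e8])
        t = np.linspace(*fit.basis.domain, 200)
        d2 = fit.basis.deriv2(t)
        curvature = np.abs(d2 @ fit.beta_blocks.T).max()
        scale = np.abs(fit.y).max()
        assert curvature < 1e-4 * scale

    def test_trace_bounds(self):
        Y, fac, _ = synth_growth(SynthGrowthConfig(seed=4))
        for lam in (1e-6, 1.0, 1e8):
            fit = fanova_fit(Y, "size ~ genotype + block", lam_grid=[lam])
            assert 2 * fit.p - 1e-6 <= fit.trH <= fit.p * fit.K + 1e-6

    def test_plant_order_invariance(self):
        cfg = SynthGrowthConfig(n_genotypes=4, seed=2)
        Y, fac, _ = synth_growth(cfg)
        # pin factor level order so permuting plants keeps the same coding
        meta = Y.meta.copy()
        for col in ("genotype", "block"):
            meta[col] = pd.Categorical(meta[col], sorted(meta[col].unique()))
        perm = np.random.default_rng(0).permutation(Y.n_plants)
        Yp = TraitMatrix(Y.values[perm], Y.days, meta.iloc[perm].reset_index(drop=True))
        Y1 = TraitMatrix(Y.values, Y.days, meta)
        fit1 = fanova_fit(Y1, "size ~ genotype + block", lam_grid=[1.0])
        fit2 = fanova_fit(Yp, "size ~ genotype + block", lam_grid=[1.0])
        assert np.allclose(fit1.beta, fit2.beta, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        days = np.linspace(0, 10, 10)
        meta = pd.DataFrame(
            {
                "plant_id": [f"p{i}" for i in range(4)],
                "genotype": ["g1", "g1", "g2", "g2"],
                "block": ["b1", "b1", "b2", "b2"],  # block aliased with genotype
            }
        )
        Y = TraitMatrix(np.ones((4, 10)), days, meta)
        with pytest.raises(RankError):
            fanova_fit(Y, "size ~ genotype + block", n_interior=0)

    def test_empty_lambda_grid_rejected(self):
        Y, fac, _ = synth_growth(SynthGrowthConfig(seed=2))
        with pytest.raises(ValueError):
            fanova_fit(Y, "size ~ genotype + block", lam_grid=[])

    def test_mise_decreases_with_more_plants(self):
        # with AR(1) noise, doubling replication shrinks effect-curve MISE
        tg = np.linspace(1, 44, 100)

        def mean_mise(n_reps, seeds):
            mises = []
            for s in seeds:
                cfg = SynthGrowthConfig(n_genotypes=10, n_replicates=n_reps, seed=s)
                Y, fac, truth = synth_growth(cfg)
                fit = fanova_fit(Y, "size ~ genotype + block")
                errs = []
                curves = [truth["mu"]] + truth["genotype"] + truth["block"]
                for j, curve in enumerate(curves):
                    est = predict_curve(fit, np.eye(fit.p)[j], tg)
                    errs.append(np.mean((est - np.asarray(curve(tg))) ** 2))
                mises.append(np.mean(errs))
            return np.mean(mises)

        seeds = range(100, 108)
        assert mean_mise(2, seeds) < mean_mise(1, seeds)


class TestCovariance:
    def test_zero_residuals_zero_covariance(self):
        cfg = spline_truth_config()
        Y, fac, _ = synth_growth(cfg)
        fit = fanova_fit(Y, "size ~ genotype + block", lam_grid=[0.0])
        cov = coef_covariance(fit)
        assert np.abs(cov).max() < 1e-12

    def test_iid_errors_match_closed_form(self):
        # common grid, iid N(0, sigma^2): Cov(beta) ~= sigma^2 A A'.  The
        # coefficient variances match to <10% at 200 plants; the full-matrix
        # Frobenius error is dominated by sqrt(m/n) sampling noise of the
        # covariance surface and must shrink as plants are added.
        sigma = 0.4

        def rel_errors(reps, seed=8):
            cfg = SynthGrowthConfig(
                n_genotypes=5, n_blocks=2, n_replicates=reps,
                retention=1.0, sigma=sigma, rho=0.0, seed=seed,
            )
            Y, fac, _ = synth_growth(cfg)
            fit = fanova_fit(Y, "size ~ genotype + block", lam_grid=[1.0])
            cov = coef_covariance(fit)
            closed = sigma**2 * fit.A @ fit.A.T
            frob = np.linalg.norm(cov - closed) / np.linalg.norm(closed)
            diag = np.abs(np.diag(cov) / np.diag(closed) - 1).mean()
            return frob, diag

        frob200, diag200 = rel_errors(20)
        frob800, _ = rel_errors(80)
        assert diag200 < 0.10
        assert frob800 < frob200
        assert frob800 < 0.15

    def test_monte_carlo_coefficient_covariance(self):
        # simulation oracle: estimator's average output tracks the MC
        # covariance of beta-hat on the diagonal
        days = np.linspace(0, 10, 10)
        meta = pd.DataFrame(
            {"plant_id": [f"p{i}" for i in range(40)], "genotype": ["g1", "g2"] * 20, "block": "b1"}
        )
        rng = np.random.default_rng(17)
        betas, est_diags = [], []
        for _ in range(400):
            values = 1.0 + 0.3 * rng.normal(size=(40, 10))
            Y = TraitMatrix(values, days, meta)
            fit = fanova_fit(Y, "size ~ genotype", lam_grid=[1.0], n_interior=0)
            betas.append(fit.beta)
            est_diags.append(np.diag(coef_covariance(fit)))
        mc = np.cov(np.asarray(betas).T)
        avg_est = np.mean(est_diags, axis=0)
        ratio = avg_est / np.diag(mc)
        assert np.all(ratio > 0.7) and np.all(ratio < 1.4)


class TestPredict:
    def test_selector_gives_intercept_curve(self):
        Y, fac, _ = synth_growth(SynthGrowthConfig(seed=6))
        fit = fanova_fit(Y, "size ~ genotype + block")
        tg = Y.days
        mu = fit.basis.design(tg) @ fit.beta_blocks[0]
        assert np.allclose(predict_curve(fit, np.eye(fit.p)[0], tg), mu)

    def test_interpolates_noiseless_fit_at_observed_days(self):
        cfg = spline_truth_config()
        Y, fac, _ = synth_growth(cfg)
        fit = fanova_fit(Y, "size ~ genotype + block", lam_grid=[0.0])
        i = 7  # arbitrary plant
        pred = predict_curve(fit, fit.design[i], Y.days)
        assert np.allclose(pred, Y.values[i], atol=1e-8)

    def test_linear_in_design_row(self, rng):
        Y, fac, _ = synth_growth(SynthGrowthConfig(seed=6))
        fit = fanova_fit(Y, "size ~ genotype + block", lam_grid=[1.0])
        r1, r2 = rng.normal(size=fit.p), rng.normal(size=fit.p)
        tg = np.linspace(*fit.basis.domain, 30)
        assert np.allclose(
            predict_curve(fit, r1 + r2, tg),
            predict_curve(fit, r1, tg) + predict_curve(fit, r2, tg),
        )

    def test_outside_domain_rejected(self):
        Y, fac, _ = synth_growth(SynthGrowthConfig(seed=6))
        fit = fanova_fit(Y, "size ~ genotype + block", lam_grid=[1.0])
        with pytest.raises(ValueError):
            predict_curve(fit, np.eye(fit.p)[0], [100.0])
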