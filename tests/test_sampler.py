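"""Gibbs sampler conditionals: truncated-normal augmentation, conjugate
(B, Gamma) draw against a covariance-side oracle, rho/V behaviour, residual
variance recovery, determinism and scaling invariance."""

import numpy as np
import pandas as pd
import pytest

from trawljsdm.data_model import CommunityTable, TraitMatrix, taxonomy_to_correlation
from trawljsdm.gibbs import (
    GibbsModel,
    McmcConfig,
    fit_hurdle,
    truncnorm_above,
    truncnorm_below,
)


class TestTruncatedNormal:
    def test_half_normal_mean(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(size=200_000)
        z = truncnorm_below(np.zeros_like(u), u)
        assert abs(z.mean() - np.sqrt(2 / np.pi)) < 0.01
        assert (z > 0).all()

    def test_negligible_truncation_far_from_bound(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(size=50_000)
        z = truncnorm_below(np.full_like(u, -10.0), u)
        assert abs(z.mean()) < 0.02
        assert abs(z.std() - 1) < 0.02

    def test_extreme_bound_uses_tail_approximation(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(size=10_000)
        z = truncnorm_below(np.full_like(u, 12.0), u)
        assert np.isfinite(z).all()
        assert (z >= 12.0).all()
        assert z.mean() - 12.0 < 0.2  # tail mean ~ a + 1/a

    def test_upper_truncation_mirrors_lower(self):
        rng = np.random.default_rng(3)
        u = rng.uniform(size=50_000)
        assert (truncnorm_above(np.zeros_like(u), u) < 0).all()
        assert abs(truncnorm_above(np.zeros_like(u), u).mean() + np.sqrt(2 / np.pi)) < 0.01


def _flat_setup(n, S, p, seed, family="gaussian", sigma=0.7):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [rng.normal(0, 1, n) for _ in range(p - 1)])
    B = rng.normal(0, 1, (p, S))
    Y = X @ B + rng.standard_normal((n, S)) * sigma
    if family == "probit":
        Y = (X @ B + rng.standard_normal((n, S)) > 0).astype(float)
    return X, B, Y


class TestBetaGammaConditional:
    def test_matches_covariance_side_oracle(self):
        """The joint (B, Gamma) draw must match a Gaussian-conditioning
        oracle built from covariance (not precision) algebra."""
        rng = np.random.default_rng(7)
        n, S, p = 12, 3, 2
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        T = np.column_stack([np.ones(S), rng.normal(0, 1, S)])
        C = np.array([[1, 0.8, 0.2], [0.8, 1, 0.2], [0.2, 0.2, 1.0]])
        V = np.array([[0.5, 0.1], [0.1, 0.3]])
        rho, tau, s2 = 0.5, 1.0, 0.7
        cfg = McmcConfig(
            n_chains=1, n_iterations=10, n_burnin=1, thin=1, seed=0,
            rho_grid=np.array([0.0, 0.5, 1.0]), gamma_prior_var=tau, fix_v=V, fix_rho=rho,
        )
        Y = rng.normal(0, 1, (n, S))
        m = GibbsModel(X, Y, "gaussian", T, C, cfg)
        st = m.init_state(np.random.default_rng(1))
        st.sigma2 = np.full(S, s2)
        st.z = Y.copy()

        P = rho * C + (1 - rho) * np.eye(S)
        A = np.kron(T, np.eye(p))
        d, q = S * p, T.shape[1] * p
        cov_prior = np.block([[A @ A.T * tau + np.kron(P, V), tau * A], [tau * A.T, tau * np.eye(q)]])
        H = np.zeros((n * S, d + q))
        yv = np.zeros(n * S)
        for j in range(S):
            H[j * n : (j + 1) * n, j * p : (j + 1) * p] = X
            yv[j * n : (j + 1) * n] = Y[:, j]
        K = cov_prior @ H.T @ np.linalg.inv(H @ cov_prior @ H.T + s2 * np.eye(n * S))
        mean_oracle = K @ yv
        sd_oracle = np.sqrt(np.diag(cov_prior - K @ H @ cov_prior))

        r = np.random.default_rng(2)
        draws = []
        for _ in range(4000):
            m.update_beta_gamma(st, r)
            draws.append(np.concatenate([st.B.T.ravel(), st.Gmat.T.ravel()]))
        draws = np.array(draws)
        assert np.abs(draws.mean(0) - mean_oracle).max() < 0.05
        assert np.abs(draws.std(0) - sd_oracle).max() < 0.03


class TestPosteriorBehaviour:
    def test_probit_recovery_against_independent_mle(self):
        """With no latent factors and rho = 0 the model is a per-species
        Bayesian probit; posterior means must track the independent
        maximum-likelihood fit."""
        import statsmodels.api as sm

        X, B, Y = _flat_setup(900, 3, 3, seed=4, family="probit")
        cfg = McmcConfig(n_chains=2, n_iterations=500, n_burnin=150, thin=4, seed=5, fix_rho=0.0)
        post = GibbsModel(X, Y, "probit", np.ones((3, 1)), np.eye(3), cfg).run()
        Bm = post.stacked("beta").mean(axis=0)
        Bsd = post.stacked("beta").std(axis=0)
        for j in range(3):
            mle = sm.Probit(Y[:, j], X).fit(disp=0).params
            assert np.all(np.abs(Bm[:, j] - mle) < 3.5 * np.maximum(Bsd[:, j], 0.02))
        # truth within ~3 posterior sd for nearly all entries
        cover = np.abs(Bm - B) <= 3 * Bsd
        assert cover.mean() >= 0.85

    def test_rho_posterior_equals_prior_when_C_identity(self):
        X, B, Y = _flat_setup(200, 3, 2, seed=6)
        grid = np.linspace(0, 1, 11)
        cfg = McmcConfig(n_chains=2, n_iterations=800, n_burnin=200, thin=2, seed=7, rho_grid=grid)
        post = GibbsModel(X, Y, "gaussian", np.ones((3, 1)), np.eye(3), cfg).run()
        rho = post.stacked("rho")
        # uniform prior on the grid: mean 0.5, sd ~0.316
        assert abs(rho.mean() - 0.5) < 0.06
        assert abs(rho.std() - np.sqrt(np.mean((grid - 0.5) ** 2))) < 0.06

    def test_V_draws_always_psd_and_fixable(self):
        X, B, Y = _flat_setup(150, 2, 2, seed=8)
        cfg = McmcConfig(n_chains=1, n_iterations=300, n_burnin=100, thin=2, seed=9)
        post = GibbsModel(X, Y, "gaussian", np.ones((2, 1)), np.eye(2), cfg).run()
        for Vd in post.stacked("V"):
            assert np.linalg.eigvalsh(Vd).min() > 0
        Vfix = np.diag([0.3, 0.6])
        cfg2 = McmcConfig(n_chains=1, n_iterations=120, n_burnin=20, thin=1, seed=9, fix_v=Vfix)
        post2 = GibbsModel(X, Y, "gaussian", np.ones((2, 1)), np.eye(2), cfg2).run()
        assert np.allclose(post2.stacked("V"), Vfix)

    def test_sigma_recovery(self):
        X, B, Y = _flat_setup(5000, 2, 2, seed=10, sigma=0.5)
        cfg = McmcConfig(n_chains=1, n_iterations=400, n_burnin=100, thin=3, seed=11, fix_rho=0.0)
        post = GibbsModel(X, Y, "gaussian", np.ones((2, 1)), np.eye(2), cfg).run()
        sig = post.stacked("sigma").mean(axis=0)
        assert np.all(np.abs(sig / 0.5 - 1) < 0.10)

    def test_planted_block_covariance_recovered_by_loadings(self):
        """A two-block residual correlation pattern must appear in the
        posterior of Lambda' Lambda."""
        from trawljsdm.synthetic import exponential_kernel

        rng = np.random.default_rng(12)
        n, S = 400, 6
        lam_true = np.array([[1.0, 1.0, 1.0, -1.0, -1.0, -1.0]])
        coords = rng.uniform(0, 100, (n, 2))
        K = exponential_kernel(coords, 40.0)
        K[np.diag_indices_from(K)] += 1e-6
        f = np.linalg.cholesky(K) @ rng.standard_normal(n)  # smooth spatial field
        Y = np.outer(f, lam_true[0]) + rng.standard_normal((n, S)) * 0.5
        X = np.ones((n, 1))
        cfg = McmcConfig(
            n_chains=1, n_iterations=500, n_burnin=200, thin=3, seed=13,
            fix_rho=0.0, n_factors_max=2, gp_mode="predictive", n_knots=25,
            alpha_grid_km=np.array([5.0, 20.0, 60.0]),
        )
        post = GibbsModel(X, Y, "gaussian", np.ones((S, 1)), np.eye(S), cfg,
                          coords_km=coords).run()
        lam = post.level("spatial").lam.reshape(-1, 2, S)
        assoc = np.einsum("dks,dkt->st", lam, lam) / lam.shape[0]
        within = [assoc[a, b] for a in range(3) for b in range(3) if a < b]
        across = [assoc[a, b] for a in range(3) for b in range(3, 6)]
        assert np.mean(within) > 0.3
        assert np.mean(across) < -0.3

    def test_same_seed_identical_draws(self):
        X, B, Y = _flat_setup(120, 2, 2, seed=14, family="probit")
        cfg = McmcConfig(n_chains=2, n_iterations=120, n_burnin=40, thin=2, seed=15)
        a = GibbsModel(X, Y, "probit", np.ones((2, 1)), np.eye(2), cfg).run()
        b = GibbsModel(X, Y, "probit", np.ones((2, 1)), np.eye(2), cfg).run()
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.rho, b.rho)

    def test_rank_deficient_design_names_columns(self):
        n = 50
        x = np.random.default_rng(16).normal(0, 1, n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        cfg = McmcConfig(n_chains=1, n_iterations=20, n_burnin=5, thin=1, seed=0)
        with pytest.raises(ValueError, match="rank deficient"):
            GibbsModel(X, np.zeros((n, 2)), "gaussian", np.ones((2, 1)), np.eye(2), cfg,
                       covariates=["intercept", "a", "b"])


class TestScalingInvariance:
    def test_multiplying_counts_leaves_scaled_posterior_unchanged(self, toy_hauls):
        rng = np.random.default_rng(17)
        n = 150
        hauls = toy_hauls(n, seed=18)
        counts = pd.DataFrame(
            {"A": rng.poisson(4, n), "B": rng.poisson(3, n)}
        )
        counts.iloc[:4] += 1
        traits = TraitMatrix(
            pd.DataFrame(
                {"age_maturity": [3.0, 6.0], "repro_mode": [0, 1], "trophic_level": [3.5, 4.0]},
                index=["A", "B"],
            )
        )
        tx = pd.DataFrame(
            {
                "species": ["A", "B"],
                "phylum": ["P", "P"], "class": ["C", "C"], "order": ["O", "O"],
                "family": ["F", "F"], "genus": ["G1", "G2"], "species_epithet": ["a", "b"],
            }
        )
        phylo = taxonomy_to_correlation(tx)
        cfg = McmcConfig(n_chains=1, n_iterations=25, n_burnin=5, thin=1, seed=19,
                         n_factors_max=1, gp_mode="predictive", n_knots=9)
        fit1 = fit_hurdle(CommunityTable(hauls, counts), traits, phylo, cfg)
        scaled = counts.copy()
        scaled["A"] = scaled["A"] * 3
        fit2 = fit_hurdle(CommunityTable(hauls.copy(), scaled), traits, phylo, cfg)
        # the standardized response is invariant up to float rounding ...
        assert np.allclose(fit1.hurdle.Y_abu, fit2.hurdle.Y_abu, atol=1e-12, equal_nan=True)
        # ... so the short-chain posterior draws coincide to numerical noise
        assert np.allclose(fit1.abu.beta, fit2.abu.beta, atol=1e-6)
        assert np.allclose(fit1.abu.level("spatial").lam, fit2.abu.level("spatial").lam, atol=1e-6)
        # only the log-scale location m shifts, by ln 3
        assert np.isclose(
            fit2.hurdle.scale_params.loc["A", "m"] - fit1.hurdle.scale_params.loc["A", "m"],
            np.log(3),
        )
        assert np.isclose(fit2.hurdle.scale_params.loc["A", "s"], fit1.hurdle.scale_params.loc["A", "s"])
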