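"""Gridded prediction products against brute-force references."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from trawljsdm.gibbs import LevelSamples, PosteriorSamples
from trawljsdm.prediction import (
    abundance_index,
    cell_areas,
    cwm_traits,
    expected_abundance,
    factor_values_at,
    predict_conditional_abundance,
    predict_occurrence,
    richness_and_any,
)

COVS = ["intercept", "log_depth", "bot_temp", "seabed_sand", "log_swept_area", "year_centered"]


def _post(beta_draws, sigma_draws=None, family="probit", levels=()):
    beta = np.asarray(beta_draws, dtype=float)[None]
    nd, p, S = beta.shape[1:]
    sigma = np.ones((1, nd, S)) if sigma_draws is None else np.asarray(sigma_draws, float)[None]
    return PosteriorSamples(
        family=family,
        beta=beta,
        gamma=np.zeros((1, nd, 2, p)),
        V=np.tile(np.eye(p), (1, nd, 1, 1)),
        rho=np.zeros((1, nd)),
        sigma=sigma,
        levels=list(levels),
        covariates=list(COVS),
        species=[f"sp{j}" for j in range(S)],
        trait_names=["intercept", "t1"],
        origin=(14.0, 43.5),
        year_mean=2000.0,
    )


def _grid(n=3):
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "lon": np.linspace(13.5, 14.5, n),
            "lat": np.linspace(43.0, 44.0, n),
            "year": 2000,
            "depth": np.linspace(30, 120, n),
            "bot_temp": np.linspace(12, 18, n),
            "seabed": ["sand", "mud_to_muddy_sand", "sand"][:n],
        }
    )


class TestOccurrence:
    def test_matches_direct_probit_on_three_cells(self):
        rng = np.random.default_rng(0)
        B = rng.normal(0, 0.5, (5, 6, 2))
        post = _post(B)
        grid = _grid(3)
        p = predict_occurrence(post, grid, swept_area=0.047)
        X = np.column_stack(
            [
                np.ones(3),
                np.log(grid["depth"]),
                grid["bot_temp"],
                (grid["seabed"] == "sand").astype(float),
                np.full(3, np.log(0.047)),
                grid["year"] - 2000.0,
            ]
        )
        want = ndtr(np.einsum("np,dpj->dnj", X, B))
        assert np.allclose(p, want)

    def test_extreme_linear_predictors(self):
        B = np.zeros((2, 6, 1))
        B[:, 0, 0] = [-40.0, 0.0]
        p = predict_occurrence(_post(B), _grid(2))
        assert np.allclose(p[0], 0.0)
        assert np.allclose(p[1], 0.5)


class TestConditionalAbundance:
    def test_lognormal_mean_matches_monte_carlo(self):
        m, s, sigma, mu = 1.2, 0.8, 0.5, 0.3
        B = np.zeros((1, 6, 1))
        B[0, 0, 0] = mu
        post = _post(B, sigma_draws=np.full((1, 1), sigma), family="gaussian")
        scale = pd.DataFrame({"m": [m], "s": [s]}, index=["sp0"])
        grid = _grid(1)
        cond = predict_conditional_abundance(post, grid, scale)[0, 0, 0]
        rng = np.random.default_rng(1)
        mc = np.exp(m + s * (mu + sigma * rng.standard_normal(1_000_000))).mean()
        assert abs(cond / mc - 1) < 0.01

    def test_degenerate_scales(self):
        B = np.zeros((1, 6, 1))
        post = _post(B, sigma_draws=np.zeros((1, 1)), family="gaussian")
        scale = pd.DataFrame({"m": [1.5], "s": [0.0]}, index=["sp0"])
        cond = predict_conditional_abundance(post, _grid(2), scale)
        assert np.allclose(cond, np.exp(1.5))

    def test_correction_toggle(self):
        B = np.zeros((1, 6, 1))
        post = _post(B, sigma_draws=np.full((1, 1), 0.7), family="gaussian")
        scale = pd.DataFrame({"m": [0.0], "s": [1.0]}, index=["sp0"])
        on = predict_conditional_abundance(post, _grid(1), scale, lognormal_correction=True)
        off = predict_conditional_abundance(post, _grid(1), scale, lognormal_correction=False)
        assert np.allclose(on, off * np.exp(0.5 * 0.49))

    def test_missing_scale_params_error(self):
        with pytest.raises(ValueError, match="scale_params"):
            predict_conditional_abundance(_post(np.zeros((1, 6, 1))), _grid(1), None)


class TestHurdleProducts:
    def test_expected_abundance_arithmetic(self):
        p = np.array([[[0.0, 1.0, 0.5]]])
        cond = np.array([[[7.0, 3.0, 4.0]]])
        assert np.allclose(expected_abundance(p, cond), [[[0.0, 3.0, 2.0]]])

    def test_richness_and_any_brute_force(self):
        p = np.array([[[0.5, 0.5]]])
        rich, pr_any = richness_and_any(p)
        assert np.isclose(rich[0, 0], 1.0)
        assert np.isclose(pr_any[0, 0], 0.75)  # 1 - 0.5*0.5

    def test_certain_and_empty_cells(self):
        p = np.array([[[1.0, 1.0, 0.0], [0.0, 0.0, 0.0]]])
        rich, pr_any = richness_and_any(p)
        assert np.allclose(rich[0], [2.0, 0.0])
        assert np.allclose(pr_any[0], [1.0, 0.0])

    def test_pr_any_dominates_max_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=(4, 5, 3))
        rich, pr_any = richness_and_any(p)
        assert (pr_any >= p.max(axis=-1) - 1e-12).all()
        assert (rich >= pr_any - 1e-12).all()

    def test_monotone_in_p(self):
        cond = np.full((1, 2, 2), 3.0)
        lo = expected_abundance(np.full((1, 2, 2), 0.2), cond)
        hi = expected_abundance(np.full((1, 2, 2), 0.6), cond)
        assert (hi > lo).all()


class TestCellAreas:
    def test_equator_and_sixty_degrees(self):
        grid = pd.DataFrame({"lat": [0.0, 60.0]})
        a = cell_areas(grid)
        assert abs(a[0] - (0.05 * 111.32) ** 2) < 1e-9
        assert np.isclose(a[1], a[0] / 2)

    def test_monotone_in_latitude(self):
        grid = pd.DataFrame({"lat": np.linspace(0, 80, 9)})
        assert (np.diff(cell_areas(grid)) < 0).all()


class TestCwm:
    def test_single_species_returns_its_traits(self):
        a = np.zeros((1, 1, 3))
        a[0, 0, 1] = 5.0
        traits = pd.DataFrame(
            {"age_maturity": [2.0, 6.0, 9.0], "repro_mode": [0, 1, 0], "trophic_level": [3.1, 3.9, 4.2]},
            index=["sp0", "sp1", "sp2"],
        )
        cwm = cwm_traits(a, traits, ["sp0", "sp1", "sp2"])
        assert np.allclose(cwm[0, 0], [6.0, 1.0, 3.9])

    def test_weighted_mean_arithmetic(self):
        a = np.array([[[1.0, 3.0]]])
        traits = pd.DataFrame({"age_maturity": [2.0, 6.0]}, index=["sp0", "sp1"])
        cwm = cwm_traits(a, traits, ["sp0", "sp1"])
        assert np.isclose(cwm[0, 0, 0], 5.0)

    def test_equal_abundance_of_fixture_species_matches_table_means(self):
        from trawljsdm.synthetic import load_fixture_traits

        tm = load_fixture_traits()
        a = np.ones((1, 1, 9))
        cwm = cwm_traits(a, tm.traits, tm.species)
        assert np.isclose(np.round(cwm[0, 0, 0], 1), 7.1)
        assert np.isclose(np.round(cwm[0, 0, 2], 2), 3.78)

    def test_zero_abundance_cell_is_missing(self):
        a = np.zeros((1, 2, 2))
        a[0, 1] = [1.0, 1.0]
        traits = pd.DataFrame({"age_maturity": [2.0, 4.0]}, index=["sp0", "sp1"])
        cwm = cwm_traits(a, traits, ["sp0", "sp1"])
        assert np.isnan(cwm[0, 0, 0])
        assert np.isclose(cwm[0, 1, 0], 3.0)

    def test_convexity(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 2, size=(6, 4, 3))
        traits = pd.DataFrame({"age_maturity": [2.0, 6.0, 9.0]}, index=["sp0", "sp1", "sp2"])
        cwm = cwm_traits(a, traits, ["sp0", "sp1", "sp2"])
        assert (cwm >= 2.0 - 1e-12).all() and (cwm <= 9.0 + 1e-12).all()


class TestAbundanceIndex:
    def _index(self, shift=0.0):
        rng = np.random.default_rng(4)
        B = rng.normal(0, 0.2, (30, 6, 2))
        B[:, 0, :] += shift
        post_pa = _post(rng.normal(0, 0.2, (30, 6, 2)))
        post_abu = _post(B, sigma_draws=np.full((30, 2), 0.4), family="gaussian")
        scale = pd.DataFrame({"m": [1.0, 1.0], "s": [0.8, 0.8]}, index=["sp0", "sp1"])
        grid = _grid(3)
        return abundance_index(post_pa, post_abu, grid, [1999, 2000, 2001], scale, baseline_year=1999)

    def test_baseline_mean_is_one(self):
        idx = self._index()
        assert np.allclose(idx.index[:, 0, :].mean(axis=0), 1.0)

    def test_scaling_invariance(self):
        # shifting the ABU intercept multiplies all abundances by a constant
        a = self._index(0.0)
        b = self._index(0.9)
        assert np.allclose(a.index, b.index, rtol=1e-9)

    def test_trend_probability_direction(self):
        idx = self._index()
        assert set(idx.trend_probability["direction"]) <= {"increase", "decrease"}
        assert ((idx.trend_probability["probability"] >= 0) & (idx.trend_probability["probability"] <= 1)).all()


class TestFactorInterpolation:
    def test_temporal_factors_index_years(self):
        U = np.zeros((1, 4, 3, 1))
        U[0, :, :, 0] = [[1.0, 2.0, 3.0]] * 4
        lev = LevelSamples(
            name="temporal", kind="temporal",
            lam=np.zeros((1, 4, 1, 2)), U=U, alpha=np.full((1, 4, 1), np.inf),
            knot_coords=np.zeros((3, 2)), alpha_grid=np.array([np.inf]),
            year_values=np.array([1999, 2000, 2001]),
        )
        eta = factor_values_at(lev, years=np.array([2000, 1999, 2050]))
        assert np.allclose(eta[:, 0, 0], 2.0)
        assert np.allclose(eta[:, 1, 0], 1.0)
        assert np.allclose(eta[:, 2, 0], 0.0)  # outside the register -> prior mean

    def test_spatial_conditional_mean_interpolates_exactly_at_knots(self):
        rng = np.random.default_rng(5)
        knots = rng.uniform(0, 50, (6, 2))
        U = rng.normal(size=(1, 8, 6, 1))
        lev = LevelSamples(
            name="spatial", kind="spatial_full",
            lam=np.zeros((1, 8, 1, 2)), U=U, alpha=np.full((1, 8, 1), 25.0),
            knot_coords=knots, alpha_grid=np.array([25.0]),
        )
        eta = factor_values_at(lev, coords_km=knots)
        assert np.allclose(eta[:, :, 0], U.reshape(8, 6), atol=1e-3)
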