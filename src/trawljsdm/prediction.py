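"""Gridded posterior prediction and derived community products.

Per posterior draw, occurrence probability comes from the probit
presence-absence sub-model and conditional abundance from the gaussian
scaled-log sub-model, back-transformed to counts per haul-equivalent with an
optional lognormal mean correction.  Expected abundance is their elementwise
product (hurdle expectation).  On top of these, the module computes species
richness and the probability of encountering any species per cell, yearly
abundance indices (density-weighted sums over the grid, scaled to a baseline
year), and community-weighted mean (CWM) traits with their temporal trends.

Spatial latent factors are carried to unsampled locations through the
Gaussian-process conditional mean given the posterior knot values (the maps
are deterministic per draw); the temporal factor of the target year is used
as is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .gibbs import LevelSamples, PosteriorSamples
from .synthetic import exponential_kernel, project_to_km

__all__ = [
    "STANDARD_SWEPT_AREA",
    "GRID_RESOLUTION_DEG",
    "factor_values_at",
    "linear_predictor_samples",
    "grid_design",
    "grid_from_hauls",
    "predict_occurrence",
    "predict_conditional_abundance",
    "expected_abundance",
    "richness_and_any",
    "cell_areas",
    "abundance_index",
    "AbundanceIndex",
    "cwm_traits",
    "cwm_trend",
    "CwmTrend",
]

def grid_from_hauls(hauls: pd.DataFrame, resolution: float = 0.05, year: int | None = None) -> pd.DataFrame:
    """Build a prediction grid from surveyed hauls.

    Hauls are binned into resolution x resolution degree cells; each
    occupied cell gets the mean depth, the survey-period mean bottom
    temperature and the modal seabed class of its hauls.  The ``year``
    column is set to the requested target year (default: last survey year).
    """
    gx = np.floor(hauls["lon"].to_numpy() / resolution).astype(int)
    gy = np.floor(hauls["lat"].to_numpy() / resolution).astype(int)
    df = hauls.assign(_gx=gx, _gy=gy)
    agg = df.groupby(["_gx", "_gy"]).agg(
        depth=("depth", "mean"),
        bot_temp=("bot_temp", "mean"),
        seabed=("seabed", lambda s: s.mode().iloc[0]),
    )
    agg = agg.reset_index()
    agg["lon"] = (agg["_gx"] + 0.5) * resolution
    agg["lat"] = (agg["_gy"] + 0.5) * resolution
    agg["cell_id"] = [f"c{gx_}_{gy_}" for gx_, gy_ in zip(agg["_gx"], agg["_gy"])]
    agg["year"] = int(year if year is not None else hauls["year"].max())
    return agg[["cell_id", "lon", "lat", "year", "depth", "bot_temp", "seabed"]]


#: Swept area (km^2) to which all grid predictions are standardized.
STANDARD_SWEPT_AREA = 0.047

#: Default prediction-grid resolution in degrees.
GRID_RESOLUTION_DEG = 0.05

KM_PER_DEGREE = 111.32


def factor_values_at(
    level: LevelSamples,
    coords_km: np.ndarray | None = None,
    years: np.ndarray | None = None,
) -> np.ndarray:
    """Latent factor values at target locations/years, per stacked draw.

    Spatial levels use the GP conditional mean
    ``w_cross(alpha) W_knots(alpha)^{-1} U`` per draw; temporal levels index
    the per-year factors (years outside the fitted register get the prior
    mean 0).  Returns (n_samples, n_targets, K).
    """
    lam = level.lam
    n_samples = lam.shape[0] * lam.shape[1]
    K = lam.shape[2]
    U = level.U.reshape(n_samples, level.U.shape[2], K)
    alpha = level.alpha.reshape(n_samples, K)
    if level.kind == "temporal":
        if years is None:
            raise ValueError("temporal level needs target years")
        years = np.asarray(years)
        reg = level.year_values
        eta = np.zeros((n_samples, len(years), K))
        for yi, y in enumerate(reg):
            sel = years == y
            if sel.any():
                eta[:, sel, :] = U[:, yi, :][:, None, :]
        return eta
    if coords_km is None:
        raise ValueError("spatial level needs target coordinates")
    eta = np.empty((n_samples, coords_km.shape[0], K))
    proj_cache: dict[float, np.ndarray] = {}
    for a in np.unique(alpha):
        if a not in proj_cache:
            W = exponential_kernel(level.knot_coords, a)
            W[np.diag_indices_from(W)] += 1e-6
            cross = exponential_kernel(coords_km, a, level.knot_coords)
            proj_cache[a] = cross @ np.linalg.inv(W)
        M = proj_cache[a]
        s_idx, k_idx = np.where(alpha == a)
        cols = U[s_idx, :, k_idx]  # (n_sel, m)
        eta[s_idx, :, k_idx] = cols @ M.T
    return eta


def linear_predictor_samples(
    post: PosteriorSamples,
    X: np.ndarray,
    coords_km: np.ndarray | None = None,
    years: np.ndarray | None = None,
) -> np.ndarray:
    """Per-draw linear predictor X B + sum_levels eta Lambda at arbitrary
    rows; (n_samples, n_rows, S)."""
    B = post.stacked("beta")  # (samples, p, S)
    L = np.einsum("np,spj->snj", np.asarray(X, dtype=float), B)
    for lv in post.levels:
        eta = factor_values_at(lv, coords_km=coords_km, years=years)
        lam = lv.lam.reshape(-1, lv.lam.shape[2], lv.lam.shape[3])
        L += np.einsum("snk,skj->snj", eta, lam)
    return L


def grid_design(
    post: PosteriorSamples,
    grid: pd.DataFrame,
    swept_area: float = STANDARD_SWEPT_AREA,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build (X, coords_km, years) for a prediction grid.

    The grid table needs lon, lat, year, depth, bot_temp and seabed columns;
    swept area is fixed to the configured standard.  Warns when grid
    covariates fall outside the fitted covariate ranges (extrapolation).
    """
    required = ["lon", "lat", "year", "depth", "bot_temp", "seabed"]
    missing = [c for c in required if c not in grid.columns]
    if missing:
        raise ValueError(f"prediction grid is missing columns {missing}")
    if (grid["depth"] <= 0).any():
        raise ValueError("grid depth must be strictly positive")
    year_mean = post.year_mean if post.year_mean is not None else float(grid["year"].mean())
    X = np.column_stack(
        [
            np.ones(len(grid)),
            np.log(grid["depth"].to_numpy(dtype=float)),
            grid["bot_temp"].to_numpy(dtype=float),
            (grid["seabed"] == "sand").to_numpy(dtype=float),
            np.full(len(grid), np.log(swept_area)),
            grid["year"].to_numpy(dtype=float) - year_mean,
        ]
    )
    ranges = getattr(post, "covariate_ranges", None)
    if ranges is not None:
        lo, hi = np.asarray(ranges)
        out = (X < lo[None, :] - 1e-9) | (X > hi[None, :] + 1e-9)
        if out[:, [1, 2]].any():
            warnings.warn("grid covariates fall outside the fitted covariate range; extrapolating")
    coords = project_to_km(grid["lon"].to_numpy(), grid["lat"].to_numpy(), post.origin)
    years = grid["year"].to_numpy()
    return X, coords, years


def predict_occurrence(
    post_pa: PosteriorSamples,
    grid: pd.DataFrame,
    swept_area: float = STANDARD_SWEPT_AREA,
) -> np.ndarray:
    """Occurrence probability Phi(linear predictor) per draw, cell and
    species; (n_samples, n_cells, S)."""
    X, coords, years = grid_design(post_pa, grid, swept_area)
    return ndtr(linear_predictor_samples(post_pa, X, coords, years))


def predict_conditional_abundance(
    post_abu: PosteriorSamples,
    grid: pd.DataFrame,
    scale_params: pd.DataFrame,
    swept_area: float = STANDARD_SWEPT_AREA,
    lognormal_correction: bool = True,
) -> np.ndarray:
    """Conditional abundance (individuals per haul-equivalent) per draw.

    The latent mean mu on the scaled log scale is back-transformed as
    exp(m_j + s_j mu + 0.5 s_j^2 sigma_j^2) — the lognormal mean — or as
    plain exp(m_j + s_j mu) when the correction is switched off.
    """
    if scale_params is None:
        raise ValueError("scale_params (per-species m, s) are required for back-transformation")
    m = scale_params.loc[post_abu.species, "m"].to_numpy()
    s = scale_params.loc[post_abu.species, "s"].to_numpy()
    X, coords, years = grid_design(post_abu, grid, swept_area)
    mu = linear_predictor_samples(post_abu, X, coords, years)
    log_a = m[None, None, :] + s[None, None, :] * mu
    if lognormal_correction:
        sig = post_abu.stacked("sigma")  # (samples, S)
        log_a = log_a + 0.5 * (s[None, None, :] ** 2) * (sig[:, None, :] ** 2)
    return np.exp(log_a)


def expected_abundance(p: np.ndarray, conditional: np.ndarray) -> np.ndarray:
    """Hurdle expectation: elementwise product per draw (never a product of
    posterior means)."""
    p = np.asarray(p, dtype=float)
    conditional = np.asarray(conditional, dtype=float)
    if p.shape != conditional.shape:
        raise ValueError("occurrence and conditional abundance must align")
    return p * conditional


def richness_and_any(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected species richness sum_j p_j and probability of finding at
    least one species 1 - prod_j (1 - p_j), per draw and cell."""
    p = np.asarray(p, dtype=float)
    richness = p.sum(axis=-1)
    pr_any = 1.0 - np.prod(1.0 - p, axis=-1)
    return richness, pr_any


def cell_areas(grid: pd.DataFrame, resolution: float = GRID_RESOLUTION_DEG) -> np.ndarray:
    """Area (km^2) of each grid cell: a resolution x resolution degree box
    shrinking with cos(latitude)."""
    lat = grid["lat"].to_numpy(dtype=float)
    return (resolution * KM_PER_DEGREE) * (resolution * KM_PER_DEGREE * np.cos(np.radians(lat)))


@dataclass
class AbundanceIndex:
    """Yearly abundance index per species, scaled so the baseline-year
    posterior mean equals 1."""

    years: np.ndarray
    species: list[str]
    totals: np.ndarray  # samples x years x S
    index: np.ndarray  # samples x years x S
    baseline_year: int
    trend_probability: pd.DataFrame  # species, direction, probability

    def summary(self) -> pd.DataFrame:
        rows = []
        for yi, y in enumerate(self.years):
            for j, sp in enumerate(self.species):
                d = self.index[:, yi, j]
                rows.append(
                    {
                        "species": sp,
                        "year": int(y),
                        "mean": d.mean(),
                        "q25": np.quantile(d, 0.25),
                        "q75": np.quantile(d, 0.75),
                        "q025": np.quantile(d, 0.025),
                        "q975": np.quantile(d, 0.975),
                    }
                )
        return pd.DataFrame(rows)


def abundance_index(
    post_pa: PosteriorSamples,
    post_abu: PosteriorSamples,
    grid: pd.DataFrame,
    years: list[int],
    scale_params: pd.DataFrame,
    baseline_year: int | None = None,
    swept_area: float = STANDARD_SWEPT_AREA,
    resolution: float = GRID_RESOLUTION_DEG,
    lognormal_correction: bool = True,
) -> AbundanceIndex:
    """Density-weighted yearly abundance index over a prediction grid.

    Per draw, year and species the predicted per-haul expectation is
    converted to a density (divided by the standard swept area), multiplied
    by the cell area and summed over cells.  The index divides these totals
    by the posterior-mean total of the baseline year; the trend probability
    is the posterior probability that the last year exceeds (or falls below,
    for decreasing posterior-mean trends) the first year.
    """
    years = np.asarray(sorted(years))
    if baseline_year is None:
        baseline_year = int(years[0])
    if baseline_year not in years:
        raise ValueError(f"baseline year {baseline_year} not among prediction years")
    areas = cell_areas(grid, resolution)
    totals = None
    for yi, y in enumerate(years):
        g = grid.copy()
        g["year"] = int(y)
        p = predict_occurrence(post_pa, g, swept_area)
        cond = predict_conditional_abundance(post_abu, g, scale_params, swept_area, lognormal_correction)
        a = expected_abundance(p, cond)
        tot = np.einsum("scj,c->sj", a, areas / swept_area)
        if totals is None:
            totals = np.empty((a.shape[0], len(years), a.shape[2]))
        totals[:, yi, :] = tot
    base = totals[:, list(years).index(baseline_year), :].mean(axis=0)
    if np.any(base <= 0):
        raise ValueError("baseline-year total abundance is zero for some species")
    index = totals / base[None, None, :]
    rows = []
    for j, sp in enumerate(post_pa.species):
        first = index[:, 0, j]
        last = index[:, -1, j]
        increasing = last.mean() >= first.mean()
        pr = float(np.mean(last > first)) if increasing else float(np.mean(last < first))
        rows.append({"species": sp, "direction": "increase" if increasing else "decrease", "probability": pr})
    return AbundanceIndex(
        years=years,
        species=list(post_pa.species),
        totals=totals,
        index=index,
        baseline_year=int(baseline_year),
        trend_probability=pd.DataFrame(rows),
    )


def cwm_traits(a: np.ndarray, traits: pd.DataFrame, species: list[str]) -> np.ndarray:
    """Community-weighted mean traits per draw and cell.

    CWM_i = sum_j a_ij t_j / sum_j a_ij for each trait column (for the
    binary reproductive mode this is the viviparous fraction).  Cells with
    zero total abundance get NaN.  Returns (samples, cells, n_traits).
    """
    t = traits.loc[species].to_numpy(dtype=float)  # S x n_traits
    tot = a.sum(axis=-1)  # samples x cells
    with np.errstate(invalid="ignore", divide="ignore"):
        cwm = np.einsum("scj,jt->sct", a, t) / tot[..., None]
    cwm[tot == 0] = np.nan
    return cwm


@dataclass
class CwmTrend:
    """Abundance-weighted community trend of CWM traits over years."""

    years: np.ndarray
    trait_names: list[str]
    values: np.ndarray  # samples x years x n_traits
    decline_probability: pd.DataFrame  # trait, Pr(last < first)

    def summary(self) -> pd.DataFrame:
        rows = []
        for yi, y in enumerate(self.years):
            for ti, tr in enumerate(self.trait_names):
                d = self.values[:, yi, ti]
                rows.append(
                    {
                        "trait": tr,
                        "year": int(y),
                        "mean": d.mean(),
                        "q25": np.quantile(d, 0.25),
                        "q75": np.quantile(d, 0.75),
                        "q025": np.quantile(d, 0.025),
                        "q975": np.quantile(d, 0.975),
                    }
                )
        return pd.DataFrame(rows)


def cwm_trend(
    post_pa: PosteriorSamples,
    post_abu: PosteriorSamples,
    grid: pd.DataFrame,
    years: list[int],
    scale_params: pd.DataFrame,
    traits: pd.DataFrame,
    swept_area: float = STANDARD_SWEPT_AREA,
    lognormal_correction: bool = True,
) -> CwmTrend:
    """Yearly community trend of CWM traits: the abundance-weighted mean of
    cell-level CWM values, per draw, with Pr(last year < first year)."""
    years = np.asarray(sorted(years))
    trait_names = list(traits.columns)
    values = None
    for yi, y in enumerate(years):
        g = grid.copy()
        g["year"] = int(y)
        p = predict_occurrence(post_pa, g, swept_area)
        cond = predict_conditional_abundance(post_abu, g, scale_params, swept_area, lognormal_correction)
        a = expected_abundance(p, cond)
        cwm = cwm_traits(a, traits, post_pa.species)  # samples x cells x T
        w = a.sum(axis=-1)  # samples x cells
        comm = np.nansum(cwm * w[..., None], axis=1) / w.sum(axis=1)[..., None]
        if values is None:
            values = np.empty((comm.shape[0], len(years), comm.shape[1]))
        values[:, yi, :] = comm
    rows = []
    for ti, tr in enumerate(trait_names):
        pr = float(np.mean(values[:, -1, ti] < values[:, 0, ti]))
        rows.append({"trait": tr, "pr_decline": pr})
    return CwmTrend(
        years=years,
        trait_names=trait_names,
        values=values,
        decline_probability=pd.DataFrame(rows),
    )
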