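"""Blocked Gibbs sampler for the hierarchical joint species distribution model.

Model (one sub-model; the hurdle fits two of these independently)
-----------------------------------------------------------------
For haul i and species j, on the latent scale::

    z_ij = x_i' beta_j + sum_levels  eta_i^(l) . lambda_j^(l) + eps_ij

* presence/absence sub-model: y_ij = 1[z_ij > 0], eps ~ N(0, 1) (probit);
* abundance sub-model: z_ij is the observed scaled log abundance at
  presence rows only, eps ~ N(0, sigma_j^2).

Hierarchy:

* beta_j stacked as B (covariates x species) with the matrix-normal prior
  B ~ MN(Gamma' T', V, rho*C + (1 - rho)*I): the expected niche is a linear
  function of species traits (Gamma), V is the covariate-wise residual
  covariance, and rho in [0, 1] mixes the phylogenetic correlation C with
  independence;
* Gamma entries i.i.d. N(0, gamma_prior_var);
* V ~ InvWishart(I, p + 1); rho uniform on a discrete grid;
* latent factors: spatially structured levels use a zero-mean, unit-variance
  Gaussian process with exponential covariance exp(-d / alpha) over haul
  locations (full covariance at small n, otherwise a predictive process
  through inducing knots); temporal levels use i.i.d. standard-normal yearly
  factors; loadings Lambda carry a multiplicative-gamma shrinkage prior;
  the spatial range alpha is sampled on a discrete grid;
* sigma_j^2 ~ InvGamma(shape, rate) (abundance sub-model only).

All conditional updates are conjugate (probit via truncated-normal data
augmentation; rho and alpha via discrete grids), so a sweep is a fixed
sequence of exact Gibbs blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri

from .data_model import DesignMatrix, HurdleData, PhyloCorrelation, TraitMatrix
from .synthetic import exponential_kernel

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "LevelSamples",
    "HurdleFit",
    "GibbsModel",
    "fit",
    "fit_hurdle",
    "truncnorm_below",
    "truncnorm_above",
]


# --- configuration ----------------------------------------------------------

def _default_rho_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, 101)


@dataclass
class McmcConfig:
    """Sampler settings.

    The default run length (2 chains x 3000 iterations, burn-in 1000,
    thin 10) is a desk-scale protocol for simulation studies; production
    surveys would use something like 4 x 37500 / 12500 / 100, reachable by
    overriding these fields.
    """

    n_chains: int = 2
    n_iterations: int = 3000
    n_burnin: int = 1000
    thin: int = 10
    seed: int = 0
    rho_grid: np.ndarray = field(default_factory=_default_rho_grid)
    n_factors_max: int = 3
    gp_mode: str = "auto"  # "auto" | "full" | "predictive"
    n_knots: int = 64
    gp_full_threshold: int = 200
    alpha_grid_km: np.ndarray | None = None  # default: data-adaptive
    gamma_prior_var: float = 100.0
    v_prior_df: int | None = None  # default p + 1
    sigma_prior_shape: float = 1.0
    sigma_prior_rate: float = 1.0
    shrinkage_nu: float = 3.0
    shrinkage_a1: float = 2.1
    shrinkage_a2: float = 3.1
    fix_v: np.ndarray | None = None  # test mode: hold V fixed
    fix_rho: float | None = None  # test mode: hold rho fixed

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        grid = np.asarray(self.rho_grid, dtype=float)
        if self.fix_rho is None and (0.0 not in grid or 1.0 not in grid):
            raise ValueError("rho_grid must include 0 and 1")
        self.rho_grid = grid
        if self.gp_mode not in ("auto", "full", "predictive"):
            raise ValueError("gp_mode must be auto, full or predictive")
        if self.n_knots < 4:
            raise ValueError("at least 4 predictive-process knots are required")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


# --- robust truncated-normal draws -----------------------------------------

def truncnorm_below(a: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of X ~ N(0,1) conditional on X > a, using the
    low-mass tail for numerical stability; ``u`` is uniform(0,1)."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    hi = a > 8.0  # extreme tail: exponential approximation X ~ a + Exp(a)
    pos = (a >= 0.0) & ~hi
    neg = a < 0.0
    out[hi] = a[hi] + (-np.log1p(-u[hi])) / a[hi]
    out[pos] = -ndtri(np.maximum(ndtr(-a[pos]) * (1.0 - u[pos]), 1e-300))
    lo = ndtr(a[neg])
    out[neg] = ndtri(np.minimum(lo + u[neg] * (1.0 - lo), 1.0 - 1e-16))
    return out


def truncnorm_above(b: np.ndarray, u: np.ndarray) -> np.ndarray:
    """X ~ N(0,1) conditional on X < b (mirror of :func:`truncnorm_below`)."""
    return -truncnorm_below(-np.asarray(b, dtype=float), u)


# --- random-effect levels ---------------------------------------------------

class RandomLevel:
    """One structured random-effect level.

    Holds, per value of the spatial-range grid, the haul-to-factor design
    G(alpha) such that the level's contribution to the linear predictor is
    ``G(alpha_k) U[:, k] Lambda[k, :]`` summed over factors, with latent
    values U at the level's knots having prior N(0, W(alpha)) per factor.

    kinds:
      * ``spatial_full``  - knots are the haul locations themselves; G is the
        identity and only the prior depends on alpha;
      * ``spatial_pp``    - predictive process: knots on a regular grid,
        G(alpha) = W_cross(alpha) W_knots(alpha)^{-1};
      * ``temporal``      - units are years, W = I (i.i.d. factors), G is the
        year-indicator matrix and alpha is absent.
    """

    def __init__(self, name: str, kind: str, n_rows: int, n_factors: int,
                 knot_coords: np.ndarray, alpha_grid: np.ndarray,
                 G_per_alpha: list[np.ndarray],
                 chol_W: list[np.ndarray], year_values: np.ndarray | None = None):
        self.name = name
        self.kind = kind
        self.n_factors = n_factors
        self.knot_coords = knot_coords
        self.alpha_grid = np.asarray(alpha_grid, dtype=float)
        self.G_per_alpha = G_per_alpha  # len(alpha_grid) dense (n x m)
        self.chol_W = chol_W  # Cholesky of W(alpha) at the knots
        self.year_values = year_values
        self.n_knots = knot_coords.shape[0]
        self.n_rows = n_rows
        self._gram_cache: dict[tuple, np.ndarray] = {}

    @property
    def has_alpha(self) -> bool:
        return self.kind in ("spatial_full", "spatial_pp")

    def G(self, a_idx: int) -> np.ndarray:
        return self.G_per_alpha[min(a_idx, len(self.G_per_alpha) - 1)]

    def prior_solve(self, a_idx: int, U_col: np.ndarray) -> np.ndarray:
        L = self.chol_W[min(a_idx, len(self.chol_W) - 1)]
        half = np.linalg.solve(L, U_col)
        return np.linalg.solve(L.T, half)

    def prior_logpdf(self, a_idx: int, U_col: np.ndarray) -> float:
        L = self.chol_W[min(a_idx, len(self.chol_W) - 1)]
        half = np.linalg.solve(L, U_col)
        return -0.5 * float(half @ half) - float(np.log(np.diag(L)).sum())

    def prior_precision(self, a_idx: int) -> np.ndarray:
        L = self.chol_W[min(a_idx, len(self.chol_W) - 1)]
        Linv = np.linalg.solve(L, np.eye(self.n_knots))
        return Linv.T @ Linv

    def gram(self, a_k: int, a_l: int, rows: np.ndarray | slice, key) -> np.ndarray:
        """Cached G(a_k)[rows]' G(a_l)[rows] (m x m)."""
        ck = (min(a_k, a_l), max(a_k, a_l), key)
        got = self._gram_cache.get(ck)
        if got is None:
            Gk = self.G(ck[0])[rows]
            Gl = self.G(ck[1])[rows]
            got = Gk.T @ Gl
            self._gram_cache[ck] = got
        return got if a_k <= a_l else got.T


def _regular_knots(coords: np.ndarray, n_knots: int) -> np.ndarray:
    """Regular grid of ~n_knots covering the coordinate bounding box."""
    side = max(2, int(round(np.sqrt(n_knots))))
    xs = np.linspace(coords[:, 0].min(), coords[:, 0].max(), side)
    ys = np.linspace(coords[:, 1].min(), coords[:, 1].max(), side)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def build_spatial_level(coords_km: np.ndarray, config: McmcConfig, n_factors: int) -> RandomLevel:
    n = coords_km.shape[0]
    mode = config.gp_mode
    if mode == "auto":
        mode = "full" if n <= config.gp_full_threshold else "predictive"
    if config.alpha_grid_km is not None:
        alpha_grid = np.asarray(config.alpha_grid_km, dtype=float)
    else:
        extent = np.sqrt(((coords_km.max(axis=0) - coords_km.min(axis=0)) ** 2).sum())
        extent = max(extent, 1e-3)
        alpha_grid = extent * np.array([0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5])
    if (alpha_grid <= 0).any():
        raise ValueError("spatial ranges must be positive")
    jit = 1e-6
    if mode == "full":
        knots = coords_km
        G = [np.eye(n)]  # independent of alpha when knots == units
        chol = []
        for a in alpha_grid:
            W = exponential_kernel(knots, a)
            W[np.diag_indices_from(W)] += jit
            chol.append(np.linalg.cholesky(W))
        return RandomLevel("spatial", "spatial_full", n, n_factors, knots, alpha_grid, G, chol)
    knots = _regular_knots(coords_km, config.n_knots)
    if knots.shape[0] < 4:
        raise ValueError("at least 4 predictive-process knots are required")
    G, chol = [], []
    for a in alpha_grid:
        W = exponential_kernel(knots, a)
        W[np.diag_indices_from(W)] += jit
        L = np.linalg.cholesky(W)
        cross = exponential_kernel(coords_km, a, knots)  # n x m
        G.append(np.linalg.solve(L.T, np.linalg.solve(L, cross.T)).T)
        chol.append(L)
    return RandomLevel("spatial", "spatial_pp", n, n_factors, knots, alpha_grid, G, chol)


def build_temporal_level(years: np.ndarray, year_values: np.ndarray, n_factors: int) -> RandomLevel:
    year_values = np.asarray(year_values)
    idx = np.searchsorted(year_values, years)
    if not np.array_equal(year_values[idx], years):
        raise ValueError("haul years not found in the year register")
    m = len(year_values)
    G = np.zeros((len(years), m))
    G[np.arange(len(years)), idx] = 1.0
    coords = np.column_stack([year_values.astype(float), np.zeros(m)])
    return RandomLevel("temporal", "temporal", len(years), n_factors, coords,
                       np.array([np.inf]), [G], [np.eye(m)], year_values=year_values)


# --- state ------------------------------------------------------------------

@dataclass
class _LevelState:
    U: np.ndarray  # knots x K
    lam: np.ndarray  # K x S
    alpha_idx: np.ndarray  # per factor
    phi: np.ndarray  # K x S local shrinkage
    delta: np.ndarray  # K global shrinkage increments


@dataclass
class _State:
    B: np.ndarray
    Gmat: np.ndarray  # p x (t+1), = Gamma' with Gamma trait x covariate
    V: np.ndarray
    rho_idx: int
    sigma2: np.ndarray
    z: np.ndarray  # latent (probit) or observed (gaussian) response, NaN at missing
    levels: list[_LevelState]


# --- posterior container ----------------------------------------------------

@dataclass
class LevelSamples:
    name: str
    kind: str
    lam: np.ndarray  # chain x draw x K x S
    U: np.ndarray  # chain x draw x m x K
    alpha: np.ndarray  # chain x draw x K (km; inf for temporal)
    knot_coords: np.ndarray
    alpha_grid: np.ndarray
    year_values: np.ndarray | None = None


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws of one sub-model, all chains."""

    family: str
    beta: np.ndarray  # chain x draw x p x S
    gamma: np.ndarray  # chain x draw x (t+1) x p
    V: np.ndarray  # chain x draw x p x p
    rho: np.ndarray  # chain x draw
    sigma: np.ndarray  # chain x draw x S (residual sd; ones for probit)
    levels: list[LevelSamples]
    covariates: list[str]
    species: list[str]
    trait_names: list[str]
    groups: list[str] | None = None
    origin: tuple[float, float] | None = None
    year_mean: float | None = None  # centering constant of the year covariate
    covariate_ranges: np.ndarray | None = None  # 2 x p fitted min/max (extrapolation warning)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Array with chains and draws merged into one leading axis."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def level(self, name: str) -> LevelSamples:
        for lv in self.levels:
            if lv.name == name:
                return lv
        raise KeyError(name)

    def to_dataset(self):
        import xarray as xr

        p = len(self.covariates)
        S = len(self.species)
        data = {
            "beta": (("chain", "draw", "covariate", "species"), self.beta),
            "gamma": (("chain", "draw", "trait", "covariate"), self.gamma),
            "V": (("chain", "draw", "covariate", "covariate2"), self.V),
            "rho": (("chain", "draw"), self.rho),
            "sigma": (("chain", "draw", "species"), self.sigma),
        }
        coords = {
            "covariate": self.covariates,
            "covariate2": self.covariates,
            "species": self.species,
            "trait": self.trait_names,
        }
        attrs = {"family": self.family}
        if self.groups is not None:
            attrs["groups"] = ",".join(self.groups)
        if self.origin is not None:
            attrs["origin_lon"] = self.origin[0]
            attrs["origin_lat"] = self.origin[1]
        if self.year_mean is not None:
            attrs["year_mean"] = float(self.year_mean)
        if self.covariate_ranges is not None:
            attrs["covariate_min"] = np.asarray(self.covariate_ranges)[0]
            attrs["covariate_max"] = np.asarray(self.covariate_ranges)[1]
        for lv in self.levels:
            nm = lv.name
            data[f"lambda_{nm}"] = (("chain", "draw", f"factor_{nm}", "species"), lv.lam)
            data[f"U_{nm}"] = (("chain", "draw", f"knot_{nm}", f"factor_{nm}"), lv.U)
            data[f"alpha_{nm}"] = (("chain", "draw", f"factor_{nm}"), lv.alpha)
            data[f"knots_{nm}"] = ((f"knot_{nm}", "xy"), lv.knot_coords)
            attrs[f"kind_{nm}"] = lv.kind
            attrs[f"alpha_grid_{nm}"] = np.asarray(lv.alpha_grid, dtype=float)
            if lv.year_values is not None:
                attrs[f"years_{nm}"] = np.asarray(lv.year_values, dtype=np.int32)
        assert p == self.beta.shape[2] and S == self.beta.shape[3]
        return xr.Dataset(data, coords=coords, attrs=attrs)

    def save(self, path: str) -> None:
        ds = self.to_dataset()
        # replace inf (temporal "range") with a sentinel: netCDF3 stores it fine,
        # but keep files portable
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def load(cls, path: str) -> "PosteriorSamples":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        levels = []
        for nm in ("spatial", "temporal"):
            if f"lambda_{nm}" in ds:
                years = ds.attrs.get(f"years_{nm}")
                levels.append(
                    LevelSamples(
                        name=nm,
                        kind=str(ds.attrs[f"kind_{nm}"]),
                        lam=ds[f"lambda_{nm}"].values,
                        U=ds[f"U_{nm}"].values,
                        alpha=ds[f"alpha_{nm}"].values,
                        knot_coords=ds[f"knots_{nm}"].values,
                        alpha_grid=np.atleast_1d(np.asarray(ds.attrs[f"alpha_grid_{nm}"], dtype=float)),
                        year_values=None if years is None else np.atleast_1d(np.asarray(years)),
                    )
                )
        origin = None
        if "origin_lon" in ds.attrs:
            origin = (float(ds.attrs["origin_lon"]), float(ds.attrs["origin_lat"]))
        groups = ds.attrs.get("groups")
        return cls(
            family=str(ds.attrs["family"]),
            beta=ds["beta"].values,
            gamma=ds["gamma"].values,
            V=ds["V"].values,
            rho=ds["rho"].values,
            sigma=ds["sigma"].values,
            levels=levels,
            covariates=[str(c) for c in ds["covariate"].values],
            species=[str(s) for s in ds["species"].values],
            trait_names=[str(t) for t in ds["trait"].values],
            groups=str(groups).split(",") if groups is not None else None,
            origin=origin,
            year_mean=float(ds.attrs["year_mean"]) if "year_mean" in ds.attrs else None,
            covariate_ranges=(
                np.vstack([ds.attrs["covariate_min"], ds.attrs["covariate_max"]])
                if "covariate_min" in ds.attrs
                else None
            ),
        )


# --- the sampler ------------------------------------------------------------

class GibbsModel:
    """One sub-model (probit or gaussian) bound to data, ready to sample."""

    def __init__(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        family: str,
        trait_design: np.ndarray,
        C: np.ndarray,
        config: McmcConfig,
        coords_km: np.ndarray | None = None,
        years: np.ndarray | None = None,
        year_values: np.ndarray | None = None,
        covariates: list[str] | None = None,
        species: list[str] | None = None,
        trait_names: list[str] | None = None,
        groups: list[str] | None = None,
    ) -> None:
        if family not in ("probit", "gaussian"):
            raise ValueError("family must be 'probit' or 'gaussian'")
        self.family = family
        self.X = np.asarray(X, dtype=float)
        self.Y = np.asarray(Y, dtype=float)
        self.n, self.p = self.X.shape
        self.S = self.Y.shape[1]
        self.T = np.asarray(trait_design, dtype=float)  # S x (t+1)
        self.t1 = self.T.shape[1]
        self.config = config
        self.covariates = covariates or [f"x{k}" for k in range(self.p)]
        self.species = species or [f"sp{j}" for j in range(self.S)]
        self.trait_names = trait_names or [f"t{k}" for k in range(self.t1)]
        self.groups = groups

        C = np.asarray(C, dtype=float)
        eig, Q = np.linalg.eigh((C + C.T) / 2)
        if eig.min() < -1e-8:
            raise ValueError("phylogenetic correlation matrix is not positive semi-definite")
        self.C = C
        self.C_eval = np.clip(eig, 0.0, None)
        self.C_evec = Q

        DesignMatrix(self.X, columns=list(self.covariates),
                     groups=self.groups or ["g"] * self.p).check_full_rank()

        if family == "probit":
            if not np.isin(self.Y[~np.isnan(self.Y)], [0, 1]).all():
                raise ValueError("probit responses must be binary")
            self.obs_mask = ~np.isnan(self.Y)
        else:
            self.obs_mask = ~np.isnan(self.Y)
        self.rows_j = [np.where(self.obs_mask[:, j])[0] for j in range(self.S)]
        self.n_obs_j = np.array([len(r) for r in self.rows_j])
        if (self.n_obs_j < 2).any():
            bad = [self.species[j] for j in np.where(self.n_obs_j < 2)[0]]
            raise ValueError(f"species {bad} have fewer than 2 observed rows")
        self.XtX_j = [self.X[r].T @ self.X[r] for r in self.rows_j]

        self.levels: list[RandomLevel] = []
        if coords_km is not None:
            K = min(config.n_factors_max, self.n)
            self.levels.append(build_spatial_level(np.asarray(coords_km, dtype=float), config, K))
        if years is not None:
            yv = np.unique(years) if year_values is None else np.asarray(year_values)
            K = min(config.n_factors_max, len(yv))
            self.levels.append(build_temporal_level(np.asarray(years), yv, K))

        self.Akron = np.kron(self.T, np.eye(self.p))  # (S p) x (t1 p)

    # -- initialisation and prior draws -------------------------------------

    def init_state(self, rng: np.random.Generator) -> _State:
        levels = []
        for lv in self.levels:
            K = lv.n_factors
            levels.append(
                _LevelState(
                    U=np.zeros((lv.n_knots, K)),
                    lam=0.01 * rng.standard_normal((K, self.S)),
                    alpha_idx=np.zeros(K, dtype=int),
                    phi=np.ones((K, self.S)),
                    delta=np.ones(K),
                )
            )
        st = _State(
            B=np.zeros((self.p, self.S)),
            Gmat=np.zeros((self.p, self.t1)),
            V=np.eye(self.p) if self.config.fix_v is None else np.asarray(self.config.fix_v, float),
            rho_idx=0,
            sigma2=np.ones(self.S),
            z=np.where(self.obs_mask, np.nan_to_num(self.Y), np.nan),
            levels=levels,
        )
        if self.family == "probit":
            st.z = np.where(self.obs_mask, 0.0, np.nan)
            self.update_z(st, rng)
        return st

    def sample_prior_state(self, rng: np.random.Generator) -> _State:
        """Draw every parameter from its prior (for sampler validation)."""
        cfg = self.config
        Gmat = rng.normal(0.0, np.sqrt(cfg.gamma_prior_var), size=(self.p, self.t1))
        if cfg.fix_v is not None:
            V = np.asarray(cfg.fix_v, dtype=float)
        else:
            V = stats.invwishart.rvs(df=self.p + 1, scale=np.eye(self.p), random_state=rng)
            V = np.atleast_2d(V)
        rho_idx = 0 if cfg.fix_rho is not None else int(rng.integers(len(cfg.rho_grid)))
        rho = cfg.fix_rho if cfg.fix_rho is not None else cfg.rho_grid[rho_idx]
        P = rho * self.C + (1 - rho) * np.eye(self.S)
        Lp = np.linalg.cholesky(P + 1e-12 * np.eye(self.S))
        Lv = np.linalg.cholesky(V + 1e-12 * np.eye(self.p))
        B = self.Gmat_mean(Gmat) + Lv @ rng.standard_normal((self.p, self.S)) @ Lp.T
        levels = []
        for lv in self.levels:
            K = lv.n_factors
            delta = np.concatenate(
                [rng.gamma(self.config.shrinkage_a1, 1.0, 1), rng.gamma(self.config.shrinkage_a2, 1.0, K - 1)]
            )
            tau = np.cumprod(delta)
            phi = rng.gamma(self.config.shrinkage_nu / 2, 2.0 / self.config.shrinkage_nu, (K, self.S))
            lam = rng.standard_normal((K, self.S)) / np.sqrt(phi * tau[:, None])
            alpha_idx = rng.integers(len(lv.alpha_grid), size=K) if lv.has_alpha else np.zeros(K, dtype=int)
            U = np.empty((lv.n_knots, K))
            for k in range(K):
                L = lv.chol_W[min(alpha_idx[k], len(lv.chol_W) - 1)]
                U[:, k] = L @ rng.standard_normal(lv.n_knots)
            levels.append(_LevelState(U=U, lam=lam, alpha_idx=alpha_idx, phi=phi, delta=delta))
        sigma2 = np.ones(self.S)
        if self.family == "gaussian":
            sigma2 = 1.0 / rng.gamma(self.config.sigma_prior_shape, 1.0 / self.config.sigma_prior_rate, self.S)
        return _State(B=B, Gmat=Gmat, V=V, rho_idx=rho_idx, sigma2=sigma2,
                      z=np.full_like(self.Y, np.nan), levels=levels)

    def Gmat_mean(self, Gmat: np.ndarray) -> np.ndarray:
        return Gmat @ self.T.T  # p x S

    def rho_value(self, st: _State) -> float:
        if self.config.fix_rho is not None:
            return float(self.config.fix_rho)
        return float(self.config.rho_grid[st.rho_idx])

    # -- linear predictor pieces ---------------------------------------------

    def factor_contribution(self, st: _State, skip: tuple[int, int] | None = None) -> np.ndarray:
        """Sum over levels of G(alpha_k) U[:,k] lambda_k; ``skip`` = (level,
        factor) to leave one factor out."""
        out = np.zeros((self.n, self.S))
        for li, (lv, ls) in enumerate(zip(self.levels, st.levels)):
            for k in range(lv.n_factors):
                if skip is not None and skip == (li, k):
                    continue
                out += np.outer(lv.G(ls.alpha_idx[k]) @ ls.U[:, k], ls.lam[k])
        return out

    def linear_predictor(self, st: _State) -> np.ndarray:
        return self.X @ st.B + self.factor_contribution(st)

    # -- data resimulation (for validation) ----------------------------------

    def simulate_response(self, st: _State, rng: np.random.Generator) -> None:
        """Redraw the response (and latent z) given the current parameters,
        respecting the observation mask."""
        L = self.linear_predictor(st)
        if self.family == "probit":
            z = L + rng.standard_normal(L.shape)
            self.Y = np.where(self.obs_mask, (z > 0).astype(float), np.nan)
            st.z = np.where(self.obs_mask, z, np.nan)
        else:
            z = L + rng.standard_normal(L.shape) * np.sqrt(st.sigma2)
            self.Y = np.where(self.obs_mask, z, np.nan)
            st.z = self.Y.copy()

    # -- conditional updates --------------------------------------------------

    def update_z(self, st: _State, rng: np.random.Generator) -> None:
        """Truncated-normal draw of the probit latent response."""
        if self.family != "probit":
            return
        L = self.linear_predictor(st)
        u = rng.uniform(size=L.shape)
        pres = self.obs_mask & (self.Y == 1)
        absn = self.obs_mask & (self.Y == 0)
        z = st.z
        z[pres] = L[pres] + truncnorm_below(-L[pres], u[pres])
        z[absn] = L[absn] + truncnorm_above(-L[absn], u[absn])

    def update_beta_gamma(self, st: _State, rng: np.random.Generator) -> None:
        """Joint conjugate draw of (B, Gamma)."""
        p, S, t1 = self.p, self.S, self.t1
        rho = self.rho_value(st)
        lam_c = rho * self.C_eval + (1 - rho)
        Pinv = (self.C_evec / lam_c) @ self.C_evec.T
        Vj = st.V + 1e-10 * np.eye(p)
        Vinv = np.linalg.inv(Vj)
        Sig_inv = np.kron(Pinv, Vinv)  # (Sp x Sp), species-major blocks

        R = st.z - self.factor_contribution(st)
        d = np.empty(S * p)
        Qd = np.zeros((S * p, S * p))
        for j in range(S):
            rows = self.rows_j[j]
            w = 1.0 / st.sigma2[j]
            Qd[j * p : (j + 1) * p, j * p : (j + 1) * p] = self.XtX_j[j] * w
            d[j * p : (j + 1) * p] = self.X[rows].T @ R[rows, j] * w

        A = self.Akron
        SA = Sig_inv @ A
        top = np.hstack([Qd + Sig_inv, -SA])
        bot = np.hstack([-SA.T, A.T @ SA + np.eye(t1 * p) / self.config.gamma_prior_var])
        Q = np.vstack([top, bot])
        rhs = np.concatenate([d, np.zeros(t1 * p)])
        try:
            Lc = np.linalg.cholesky(Q)
        except np.linalg.LinAlgError:
            Q[np.diag_indices_from(Q)] += 1e-8
            Lc = np.linalg.cholesky(Q)
        mean = np.linalg.solve(Lc.T, np.linalg.solve(Lc, rhs))
        draw = mean + np.linalg.solve(Lc.T, rng.standard_normal(len(rhs)))
        st.B = draw[: S * p].reshape(S, p).T
        st.Gmat = draw[S * p :].reshape(t1, p).T

    def update_rho(self, st: _State, rng: np.random.Generator) -> None:
        """Discrete draw of the phylogenetic mixing weight on its grid."""
        if self.config.fix_rho is not None:
            return
        resid = st.B - self.Gmat_mean(st.Gmat)  # p x S
        Rt = resid @ self.C_evec  # rotate into the eigenbasis of C
        Vinv = np.linalg.inv(st.V + 1e-10 * np.eye(self.p))
        quad = np.einsum("pi,pq,qi->i", Rt, Vinv, Rt)
        grid = self.config.rho_grid
        lam = grid[:, None] * self.C_eval[None, :] + (1 - grid)[:, None]  # grid x S
        if (lam <= 0).all():
            raise ValueError("all rho grid values give a degenerate prior")
        logp = -0.5 * self.p * np.log(lam).sum(axis=1) - 0.5 * (quad[None, :] / lam).sum(axis=1)
        logp -= logp.max()
        w = np.exp(logp)
        st.rho_idx = int(rng.choice(len(grid), p=w / w.sum()))

    def update_V(self, st: _State, rng: np.random.Generator) -> None:
        """Inverse-Wishart conjugate draw of the niche residual covariance."""
        if self.config.fix_v is not None:
            return
        rho = self.rho_value(st)
        resid = st.B - self.Gmat_mean(st.Gmat)
        Rt = resid @ self.C_evec
        lam = rho * self.C_eval + (1 - rho)
        Sn = (Rt / lam) @ Rt.T
        df0 = self.config.v_prior_df or (self.p + 1)
        V = stats.invwishart.rvs(df=df0 + self.S, scale=np.eye(self.p) + Sn, random_state=rng)
        st.V = np.atleast_2d(V)

    def update_sigma(self, st: _State, rng: np.random.Generator) -> None:
        """Per-species inverse-gamma draw of the gaussian residual variance."""
        if self.family != "gaussian":
            return
        E = st.z - self.X @ st.B - self.factor_contribution(st)
        for j in range(self.S):
            rows = self.rows_j[j]
            ssr = float(np.sum(E[rows, j] ** 2))
            shape = self.config.sigma_prior_shape + 0.5 * len(rows)
            rate = self.config.sigma_prior_rate + 0.5 * ssr
            st.sigma2[j] = 1.0 / rng.gamma(shape, 1.0 / rate)

    # factor machinery ------------------------------------------------------

    def _eta(self, lv: RandomLevel, ls: _LevelState) -> np.ndarray:
        """Haul-level factor values, n x K."""
        cols = [lv.G(ls.alpha_idx[k]) @ ls.U[:, k] for k in range(lv.n_factors)]
        return np.column_stack(cols) if cols else np.zeros((self.n, 0))

    def update_factors(self, st: _State, rng: np.random.Generator) -> None:
        for li, (lv, ls) in enumerate(zip(self.levels, st.levels)):
            self._update_lambda(st, li, lv, ls, rng)
            self._update_U(st, li, lv, ls, rng)
            if lv.has_alpha and len(lv.alpha_grid) > 1:
                self._update_alpha(st, li, lv, ls, rng)
            self._update_shrinkage(ls, rng)

    def _residual_without_level(self, st: _State, li: int) -> np.ndarray:
        R = st.z - self.X @ st.B
        for lj, (lv, ls) in enumerate(zip(self.levels, st.levels)):
            if lj == li:
                continue
            H = self._eta(lv, ls)
            R -= H @ ls.lam
        return R

    def _update_lambda(self, st: _State, li: int, lv: RandomLevel, ls: _LevelState, rng: np.random.Generator) -> None:
        E = self._residual_without_level(st, li)
        H = self._eta(lv, ls)
        K = lv.n_factors
        tau = np.cumprod(ls.delta)
        for j in range(self.S):
            rows = self.rows_j[j]
            Hj = H[rows]
            w = 1.0 / st.sigma2[j]
            prec = Hj.T @ Hj * w + np.diag(ls.phi[:, j] * tau)
            Lc = np.linalg.cholesky(prec + 1e-10 * np.eye(K))
            rhs = Hj.T @ E[rows, j] * w
            mean = np.linalg.solve(Lc.T, np.linalg.solve(Lc, rhs))
            ls.lam[:, j] = mean + np.linalg.solve(Lc.T, rng.standard_normal(K))

    def _update_U(self, st: _State, li: int, lv: RandomLevel, ls: _LevelState, rng: np.random.Generator) -> None:
        E = self._residual_without_level(st, li)
        K = lv.n_factors
        m = lv.n_knots
        prec = np.zeros((K * m, K * m))
        rhs = np.zeros(K * m)
        w = 1.0 / st.sigma2
        if self.family == "probit" or np.all(self.obs_mask):
            # all species share the full row set
            for k in range(K):
                Gk = lv.G(ls.alpha_idx[k])
                rhs[k * m : (k + 1) * m] = Gk.T @ (E @ (ls.lam[k] * w))
                for l in range(k, K):
                    gram = lv.gram(ls.alpha_idx[k], ls.alpha_idx[l], slice(None), "all")
                    a_kl = float(np.sum(ls.lam[k] * ls.lam[l] * w))
                    blk = a_kl * gram
                    prec[k * m : (k + 1) * m, l * m : (l + 1) * m] += blk
                    if l != k:
                        prec[l * m : (l + 1) * m, k * m : (k + 1) * m] += blk.T
        else:
            Ew = np.where(self.obs_mask, E, 0.0) * w[None, :]
            for k in range(K):
                Gk = lv.G(ls.alpha_idx[k])
                rhs[k * m : (k + 1) * m] = Gk.T @ (Ew @ ls.lam[k])
                for l in range(k, K):
                    blk = np.zeros((m, m))
                    for j in range(self.S):
                        gram = lv.gram(ls.alpha_idx[k], ls.alpha_idx[l], self.rows_j[j], j)
                        blk += (ls.lam[k, j] * ls.lam[l, j] * w[j]) * gram
                    prec[k * m : (k + 1) * m, l * m : (l + 1) * m] += blk
                    if l != k:
                        prec[l * m : (l + 1) * m, k * m : (k + 1) * m] += blk.T
        for k in range(K):
            prec[k * m : (k + 1) * m, k * m : (k + 1) * m] += lv.prior_precision(ls.alpha_idx[k])
        Lc = np.linalg.cholesky(prec + 1e-10 * np.eye(K * m))
        mean = np.linalg.solve(Lc.T, np.linalg.solve(Lc, rhs))
        draw = mean + np.linalg.solve(Lc.T, rng.standard_normal(K * m))
        ls.U = draw.reshape(K, m).T

    def _update_alpha(self, st: _State, li: int, lv: RandomLevel, ls: _LevelState, rng: np.random.Generator) -> None:
        """Per-factor discrete draw of the spatial range, conditional on U."""
        E = self._residual_without_level(st, li)
        w = 1.0 / st.sigma2
        for k in range(lv.n_factors):
            Ek = E - self._eta_skip(lv, ls, k)
            lam_k = ls.lam[k]
            logp = np.empty(len(lv.alpha_grid))
            for a in range(len(lv.alpha_grid)):
                c = lv.G(a) @ ls.U[:, k]
                if self.family == "probit" or np.all(self.obs_mask):
                    lin = float(c @ (Ek @ (lam_k * w)))
                    quad = float(c @ c) * float(np.sum(lam_k**2 * w))
                else:
                    Ekw = np.where(self.obs_mask, Ek, 0.0)
                    lin = float(c @ (Ekw @ (lam_k * w)))
                    quad = float(np.sum((c[:, None] ** 2) * self.obs_mask * (lam_k**2 * w)[None, :]))
                logp[a] = lin - 0.5 * quad + lv.prior_logpdf(a, ls.U[:, k])
            logp -= logp.max()
            pr = np.exp(logp)
            ls.alpha_idx[k] = int(rng.choice(len(pr), p=pr / pr.sum()))

    def _eta_skip(self, lv: RandomLevel, ls: _LevelState, k_skip: int) -> np.ndarray:
        out = np.zeros((self.n, self.S))
        for k in range(lv.n_factors):
            if k == k_skip:
                continue
            out += np.outer(lv.G(ls.alpha_idx[k]) @ ls.U[:, k], ls.lam[k])
        return out

    def _update_shrinkage(self, ls: _LevelState, rng: np.random.Generator) -> None:
        cfg = self.config
        K, S = ls.lam.shape
        tau = np.cumprod(ls.delta)
        # local precisions
        shape = (cfg.shrinkage_nu + 1.0) / 2.0
        rate = (cfg.shrinkage_nu + tau[:, None] * ls.lam**2) / 2.0
        ls.phi = rng.gamma(shape, 1.0 / rate)
        # global multiplicative increments
        sums = np.sum(ls.phi * ls.lam**2, axis=1)  # per factor h
        for l in range(K):
            tau = np.cumprod(ls.delta)
            tau_wo = tau[l:] / ls.delta[l]
            a = (cfg.shrinkage_a1 if l == 0 else cfg.shrinkage_a2) + 0.5 * S * (K - l)
            b = 1.0 + 0.5 * float(np.sum(tau_wo * sums[l:]))
            ls.delta[l] = rng.gamma(a, 1.0 / b)

    # -- sweep and chains -----------------------------------------------------

    def sweep(self, st: _State, rng: np.random.Generator) -> None:
        self.update_z(st, rng)
        self.update_beta_gamma(st, rng)
        self.update_rho(st, rng)
        self.update_V(st, rng)
        self.update_factors(st, rng)
        self.update_sigma(st, rng)

    def run(self, progress: bool = False) -> PosteriorSamples:
        cfg = self.config
        n_keep = cfg.n_draws_per_chain
        beta = np.empty((cfg.n_chains, n_keep, self.p, self.S))
        gamma = np.empty((cfg.n_chains, n_keep, self.t1, self.p))
        V = np.empty((cfg.n_chains, n_keep, self.p, self.p))
        rho = np.empty((cfg.n_chains, n_keep))
        sigma = np.empty((cfg.n_chains, n_keep, self.S))
        lev_store = [
            dict(
                lam=np.empty((cfg.n_chains, n_keep, lv.n_factors, self.S)),
                U=np.empty((cfg.n_chains, n_keep, lv.n_knots, lv.n_factors)),
                alpha=np.empty((cfg.n_chains, n_keep, lv.n_factors)),
            )
            for lv in self.levels
        ]
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        for c in range(cfg.n_chains):
            rng = np.random.default_rng(seeds[c])
            st = self.init_state(rng)
            keep = 0
            for it in range(cfg.n_iterations):
                self.sweep(st, rng)
                if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0 and keep < n_keep:
                    beta[c, keep] = st.B
                    gamma[c, keep] = st.Gmat.T
                    V[c, keep] = st.V
                    rho[c, keep] = self.rho_value(st)
                    sigma[c, keep] = np.sqrt(st.sigma2)
                    for li, lv in enumerate(self.levels):
                        ls = st.levels[li]
                        lev_store[li]["lam"][c, keep] = ls.lam
                        lev_store[li]["U"][c, keep] = ls.U
                        lev_store[li]["alpha"][c, keep] = (
                            lv.alpha_grid[ls.alpha_idx] if lv.has_alpha else np.full(lv.n_factors, np.inf)
                        )
                    keep += 1
        levels = [
            LevelSamples(
                name=lv.name,
                kind=lv.kind,
                lam=store["lam"],
                U=store["U"],
                alpha=store["alpha"],
                knot_coords=lv.knot_coords,
                alpha_grid=lv.alpha_grid,
                year_values=lv.year_values,
            )
            for lv, store in zip(self.levels, lev_store)
        ]
        return PosteriorSamples(
            family=self.family,
            beta=beta,
            gamma=gamma,
            V=V,
            rho=rho,
            sigma=sigma,
            levels=levels,
            covariates=list(self.covariates),
            species=list(self.species),
            trait_names=list(self.trait_names),
            groups=self.groups,
        )


def fit(
    X: np.ndarray,
    Y: np.ndarray,
    family: str,
    trait_design: np.ndarray,
    C: np.ndarray,
    config: McmcConfig,
    coords_km: np.ndarray | None = None,
    years: np.ndarray | None = None,
    **names,
) -> PosteriorSamples:
    """Fit one sub-model and return thinned post-burn-in posterior draws."""
    model = GibbsModel(X, Y, family, trait_design, C, config, coords_km=coords_km, years=years, **names)
    return model.run()


# --- hurdle wrapper ---------------------------------------------------------

@dataclass
class HurdleFit:
    """Joint result of the two independently fitted sub-models plus the data
    objects needed by downstream summaries and predictions."""

    pa: PosteriorSamples
    abu: PosteriorSamples
    design: DesignMatrix
    hurdle: HurdleData
    traits: TraitMatrix
    phylo: PhyloCorrelation
    origin: tuple[float, float]
    hauls: "object" = None  # pd.DataFrame of haul covariates (fit-time rows)


def fit_hurdle(
    table,
    traits: TraitMatrix,
    phylo: PhyloCorrelation,
    config: McmcConfig,
) -> HurdleFit:
    """Fit the full hurdle model (probit presence-absence plus gaussian
    scaled-log conditional abundance) to a community table."""
    from .data_model import build_design, make_hurdle
    from .synthetic import project_to_km

    species = table.species
    traits_o = TraitMatrix(traits.traits.loc[species])
    phylo_o = phylo.reorder(species)
    design = build_design(table)
    hurdle = make_hurdle(table)
    lon = table.hauls["lon"].to_numpy()
    lat = table.hauls["lat"].to_numpy()
    origin = (float(lon.mean()), float(lat.mean()))
    coords = project_to_km(lon, lat, origin)
    years = table.hauls["year"].to_numpy()

    common = dict(
        trait_design=traits_o.design(),
        C=phylo_o.C,
        coords_km=coords,
        years=years,
        covariates=list(design.columns),
        species=species,
        trait_names=traits_o.design_columns,
        groups=list(design.groups),
    )
    pa = fit(design.X, hurdle.Y_pa.astype(float), "probit", config=config, **common)
    abu = fit(design.X, hurdle.Y_abu, "gaussian", config=config, **common)
    pa.origin = origin
    abu.origin = origin
    pa.year_mean = float(years.mean())
    abu.year_mean = float(years.mean())
    ranges = np.vstack([design.X.min(axis=0), design.X.max(axis=0)])
    pa.covariate_ranges = ranges
    abu.covariate_ranges = ranges
    return HurdleFit(pa=pa, abu=abu, design=design, hurdle=hurdle, traits=traits_o,
                     phylo=phylo_o, origin=origin, hauls=table.hauls.copy())
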