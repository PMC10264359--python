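"""Convergence and explanatory-power diagnostics.

Convergence is monitored with the split-chain potential scale reduction
factor (PSRF); explanatory power with Tjur's coefficient of discrimination
and the area under the ROC curve (AUC) for the presence-absence sub-model
and the squared Pearson correlation for the conditional-abundance sub-model.
All fit metrics are explanatory (in-sample), computed from posterior-mean
predictions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtr
from sklearn.metrics import roc_auc_score

from .gibbs import HurdleFit, PosteriorSamples

__all__ = ["psrf", "psrf_table", "tjur_r2", "auc", "abu_r2", "fit_metrics"]


def psrf(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Each chain is halved, the between- and within-(half-)chain variances are
    compared, and sqrt(((n-1)/n W + B/n) / W) is returned.  Values near 1
    indicate that the chains are sampling the same distribution.

    Parameters
    ----------
    chains
        Array (n_chains, n_draws) of one scalar parameter; at least 2 chains
        with at least 10 draws each.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ValueError("psrf needs >= 2 chains with >= 10 draws each")
    half = chains.shape[1] // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = split.shape
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        if B == 0.0:
            warnings.warn("zero within- and between-chain variance; returning PSRF = 1")
            return 1.0
        return np.inf
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def psrf_table(post: PosteriorSamples) -> pd.DataFrame:
    """PSRF summary per parameter block (max and mean over elements)."""
    rows = []

    def block(name: str, arr: np.ndarray) -> None:
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        vals = [psrf(flat[:, :, k]) for k in range(flat.shape[2])]
        rows.append({"block": name, "psrf_mean": float(np.mean(vals)), "psrf_max": float(np.max(vals))})

    block("beta", post.beta)
    block("gamma", post.gamma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        block("rho", post.rho[:, :, None])
        if post.family == "gaussian":
            block("sigma", post.sigma)
    for lv in post.levels:
        # loadings are sign/rotation unidentified; monitor the identified
        # species-by-species product Lambda' Lambda instead
        lam = lv.lam
        prod = np.einsum("cdks,cdkt->cdst", lam, lam)
        block(f"lambda2_{lv.name}", prod)
    return pd.DataFrame(rows)


def tjur_r2(p: np.ndarray, y: np.ndarray) -> float:
    """Tjur's coefficient of discrimination: mean(p | y=1) - mean(p | y=0)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError("p and y must have the same length")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        return np.nan
    return float(p[y == 1].mean() - p[y == 0].mean())


def auc(p: np.ndarray, y: np.ndarray) -> float:
    """Probability that a random presence outranks a random absence
    (Mann-Whitney form; ties count one half)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        return np.nan
    return float(roc_auc_score(y, p))


def abu_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation between prediction and observation."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    keep = ~np.isnan(obs) & ~np.isnan(pred)
    if keep.sum() < 3:
        return np.nan
    r = np.corrcoef(pred[keep], obs[keep])[0, 1]
    return float(r**2)


def fit_metrics(fit: HurdleFit) -> pd.DataFrame:
    """Per-species explanatory metrics of a fitted hurdle model.

    Tjur R^2 and AUC from the posterior-mean occurrence probability;
    conditional-abundance R^2 from the posterior-mean latent prediction at
    presence rows.  The last row holds the community (arithmetic) means.
    """
    from .prediction import linear_predictor_samples
    from .synthetic import project_to_km

    if fit.hauls is None:
        raise ValueError("fit carries no haul table; refit with fit_hurdle")
    X = fit.design.X
    coords = project_to_km(fit.hauls["lon"].to_numpy(), fit.hauls["lat"].to_numpy(), fit.origin)
    years = fit.hauls["year"].to_numpy()
    L_pa = linear_predictor_samples(fit.pa, X, coords, years)
    p_mean = ndtr(L_pa).mean(axis=0)
    L_abu = linear_predictor_samples(fit.abu, X, coords, years).mean(axis=0)
    rows = []
    for j, sp in enumerate(fit.pa.species):
        y = fit.hurdle.Y_pa[:, j]
        rows.append(
            {
                "species": sp,
                "tjur_r2": tjur_r2(p_mean[:, j], y),
                "auc": auc(p_mean[:, j], y),
                "abu_r2": abu_r2(L_abu[:, j], fit.hurdle.Y_abu[:, j]),
            }
        )
    df = pd.DataFrame(rows).set_index("species")
    df.loc["community_mean"] = df.mean(axis=0, skipna=True)
    return df
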