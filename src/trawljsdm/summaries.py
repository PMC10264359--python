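"""Posterior summaries: support of niche and trait-niche coefficients,
variance partitioning, trait-explained niche variance, phylogenetic signal.

Support classification follows the convention of reporting a coefficient as
positive (negative) when at least a given fraction of posterior draws —
default 95% — lies above (below) zero.  Variance partitioning is computed
per draw and species, then averaged, so the reported shares propagate
posterior uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import PosteriorSamples

__all__ = [
    "SupportTable",
    "beta_support",
    "gamma_support",
    "VariancePartition",
    "variance_partition",
    "trait_r2",
    "phylo_signal",
]

DEFAULT_SUPPORT = 0.95


@dataclass
class SupportTable:
    """Long-format posterior support: one row per (row label, covariate)."""

    table: pd.DataFrame  # columns: row, covariate, mean, pr_positive, sign
    threshold: float

    def sign_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="row", columns="covariate", values="sign")


def _support(draws: np.ndarray, row_names: list[str], col_names: list[str], threshold: float) -> SupportTable:
    if draws.shape[0] < 100:
        raise ValueError("support classification needs at least 100 posterior draws")
    mean = draws.mean(axis=0)
    pr_pos = (draws > 0).mean(axis=0)
    sign = np.where(pr_pos >= threshold, "+", np.where(1.0 - pr_pos >= threshold, "-", "0"))
    rows = []
    for a, rn in enumerate(row_names):
        for b, cn in enumerate(col_names):
            rows.append(
                {"row": rn, "covariate": cn, "mean": mean[a, b], "pr_positive": pr_pos[a, b], "sign": sign[a, b]}
            )
    return SupportTable(pd.DataFrame(rows), threshold)


def beta_support(post: PosteriorSamples, threshold: float = DEFAULT_SUPPORT) -> SupportTable:
    """Species-by-covariate support of the niche coefficients B."""
    draws = np.transpose(post.stacked("beta"), (0, 2, 1))  # samples x species x covariate
    return _support(draws, post.species, post.covariates, threshold)


def gamma_support(post: PosteriorSamples, threshold: float = DEFAULT_SUPPORT) -> SupportTable:
    """Trait-by-covariate support of the trait-niche coefficients Gamma."""
    return _support(post.stacked("gamma"), post.trait_names, post.covariates, threshold)


@dataclass
class VariancePartition:
    """Per-species fractions of explained variance by covariate group and
    random-effect level; fractions sum to one per species."""

    fractions: pd.DataFrame  # index species, one column per component
    components: list[str]

    def community_mean(self) -> pd.Series:
        return self.fractions.mean(axis=0)


def variance_partition(post: PosteriorSamples, X: np.ndarray, groups: list[str] | None = None) -> VariancePartition:
    """Partition explained variance among fixed-effect covariate groups and
    latent random levels.

    Per draw and species: the fixed component of group g is the variance
    over hauls of X_g B_gj (columns of g jointly); each random level
    contributes sum_h Lambda_hj^2 (the latent factors have unit marginal
    variance).  Fractions are averaged over draws, then renormalized.
    """
    X = np.asarray(X, dtype=float)
    groups = list(groups if groups is not None else (post.groups or []))
    if len(groups) != X.shape[1]:
        raise ValueError("one group label per design column is required")
    B = post.stacked("beta")  # samples x p x S
    uniq = [g for i, g in enumerate(groups) if g not in groups[:i]]
    comps = []
    names = []
    for g in uniq:
        cols = [k for k, gg in enumerate(groups) if gg == g]
        # Var_hauls(X_g B_gj) = B_gj' Cov(X_g) B_gj
        cov_g = np.atleast_2d(np.cov(X[:, cols].T, bias=True))
        var_g = np.einsum("skj,kl,slj->sj", B[:, cols, :], cov_g, B[:, cols, :])
        if np.all(var_g == 0):
            continue  # constant columns (intercept) carry no variance
        comps.append(var_g)
        names.append(g)
    for lv in post.levels:
        lam = lv.lam.reshape(-1, lv.lam.shape[2], lv.lam.shape[3])
        comps.append((lam**2).sum(axis=1))
        names.append(f"random_{lv.name}")
    if not comps:
        raise ValueError("no variance components: intercept-only fixed effects and no latent factors")
    stack = np.stack(comps, axis=-1)  # samples x S x n_comp
    total = stack.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("zero total explained variance for some draw/species")
    frac = (stack / total).mean(axis=0)  # S x n_comp
    frac = frac / frac.sum(axis=1, keepdims=True)
    return VariancePartition(pd.DataFrame(frac, index=post.species, columns=names), names)


def trait_r2(post: PosteriorSamples, trait_design: np.ndarray, X: np.ndarray) -> pd.Series:
    """Fraction of among-species niche variance explained by traits.

    Per draw and covariate k: R2_k = Var_j(mu_kj) / Var_j(B_kj), with
    mu = Gamma' T' the trait-predicted niche, clipped to [0, 1].  The
    overall value is the weighted mean of the per-covariate fractions, the
    weight of covariate k being its mean share of the fixed-effect explained
    variance.  Returns a series indexed by covariate plus ``overall``.
    """
    if len(post.species) < 2:
        raise ValueError("trait R2 is undefined with a single species")
    B = post.stacked("beta")  # samples x p x S
    G = post.stacked("gamma")  # samples x (t+1) x p
    T = np.asarray(trait_design, dtype=float)  # S x (t+1)
    mu = np.einsum("stp,jt->spj", G, T)  # samples x p x S
    var_b = B.var(axis=2)
    var_mu = mu.var(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.clip(var_mu / var_b, 0.0, 1.0)
    r2 = np.nan_to_num(r2, nan=0.0)
    r2_mean = r2.mean(axis=0)  # per covariate
    X = np.asarray(X, dtype=float)
    var_x = X.var(axis=0)  # per covariate; Var_hauls(X_k B_kj) = B_kj^2 Var(X_k)
    share = (B**2 * var_x[None, :, None]).mean(axis=2)  # samples x p
    w = share.mean(axis=0)
    w_sum = w.sum()
    overall = float((r2_mean * w).sum() / w_sum) if w_sum > 0 else float(r2_mean.mean())
    out = pd.Series(r2_mean, index=post.covariates)
    out["overall"] = overall
    return out


def phylo_signal(post: PosteriorSamples) -> dict[str, float]:
    """Posterior mean of the phylogenetic mixing weight rho and the
    posterior probability that rho exceeds zero."""
    rho = post.stacked("rho")
    return {"mean": float(rho.mean()), "pr_positive": float((rho > 0).mean())}
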