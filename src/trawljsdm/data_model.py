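"""Core domain types for hurdle joint species distribution modelling.

This module holds the containers and deterministic transformations shared by
every stage of the pipeline: the haul-level community table, the species
trait matrix, the taxonomy-derived phylogenetic correlation matrix, the
fixed-effect design matrix, and the two-part (hurdle) response built from
zero-inflated counts.

Conventions
-----------
* Counts are individuals per trawl haul (non-negative integers).
* All logarithms are natural logs.
* The seabed substrate is a binary factor with ``mud_to_muddy_sand`` as the
  reference level, so the design matrix carries a single ``seabed_sand``
  indicator.
* Survey year enters the fixed effects centred on its mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HAUL_COLUMNS",
    "SEABED_LEVELS",
    "TRAIT_COLUMNS",
    "TAXONOMY_RANKS",
    "CommunityTable",
    "TraitMatrix",
    "PhyloCorrelation",
    "DesignMatrix",
    "HurdleData",
    "filter_species",
    "build_design",
    "make_hurdle",
    "taxonomy_to_correlation",
]

#: Required haul-level covariate columns of a community table.
HAUL_COLUMNS = ["haul_id", "lon", "lat", "year", "depth", "bot_temp", "seabed", "swept_area"]

#: Admissible seabed substrate classes; the first one is the reference level.
SEABED_LEVELS = ["mud_to_muddy_sand", "sand"]

#: Species trait columns (fixed order).
TRAIT_COLUMNS = ["age_maturity", "repro_mode", "trophic_level"]

#: Taxonomic ranks used to build the phylogenetic correlation, root to tip.
TAXONOMY_RANKS = ["phylum", "class", "order", "family", "genus", "species_epithet"]


@dataclass
class CommunityTable:
    """Haul-by-species survey table.

    Parameters
    ----------
    hauls
        One row per haul with columns :data:`HAUL_COLUMNS`.
    counts
        Integer counts, same row order as ``hauls``, one column per species.
    """

    hauls: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in HAUL_COLUMNS if c not in self.hauls.columns]
        if missing:
            raise ValueError(f"community table is missing haul columns {missing}")
        if len(self.hauls) != len(self.counts):
            raise ValueError("hauls and counts have different numbers of rows")
        if self.hauls["haul_id"].duplicated().any():
            dup = self.hauls.loc[self.hauls["haul_id"].duplicated(), "haul_id"].iloc[0]
            raise ValueError(f"duplicate haul_id {dup!r}")
        if (self.hauls["depth"] <= 0).any():
            raise ValueError("depth must be strictly positive")
        if (self.hauls["swept_area"] <= 0).any():
            raise ValueError("swept_area must be strictly positive")
        bad_seabed = set(self.hauls["seabed"].unique()) - set(SEABED_LEVELS)
        if bad_seabed:
            raise ValueError(f"unknown seabed level(s) {sorted(bad_seabed)}; expected {SEABED_LEVELS}")
        arr = self.counts.to_numpy()
        if np.isnan(arr.astype(float)).any():
            raise ValueError("counts contain missing values")
        if (arr < 0).any() or not np.allclose(arr, np.round(arr.astype(float))):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(int).reset_index(drop=True)
        self.hauls = self.hauls.reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_hauls(self) -> int:
        return len(self.hauls)

    def occurrence_fraction(self) -> pd.Series:
        """Fraction of hauls in which each species was caught."""
        return (self.counts > 0).mean(axis=0)

    def total_individuals(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class TraitMatrix:
    """Species-by-trait table: age at first maturity (years), reproductive
    mode (1 = viviparous, 0 = oviparous), trophic level (unitless)."""

    traits: pd.DataFrame  # index: species, columns: TRAIT_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in self.traits.columns]
        if missing:
            raise ValueError(f"trait matrix is missing columns {missing}")
        t = self.traits[TRAIT_COLUMNS]
        if t.isna().any().any():
            raise ValueError("trait matrix contains missing values")
        if (t["age_maturity"] <= 0).any():
            raise ValueError("age_maturity must be positive")
        if not t["repro_mode"].isin([0, 1]).all():
            raise ValueError("repro_mode must be binary (1 = viviparous)")
        if ((t["trophic_level"] <= 2) | (t["trophic_level"] >= 5)).any():
            raise ValueError("trophic_level must lie in (2, 5)")
        self.traits = t.astype(float)

    @property
    def species(self) -> list[str]:
        return list(self.traits.index)

    def design(self) -> np.ndarray:
        """Species x (1 + n_traits) design with a leading intercept column."""
        t = self.traits.to_numpy(dtype=float)
        return np.column_stack([np.ones(len(t)), t])

    @property
    def design_columns(self) -> list[str]:
        return ["intercept"] + TRAIT_COLUMNS

    def correlated_pairs(self, threshold: float = 0.7) -> list[tuple[str, str, float]]:
        """Trait pairs with |Pearson r| at or above ``threshold`` (flagged,
        not fatal: strongly collinear traits make the trait regression
        ill-conditioned)."""
        corr = self.traits.corr().to_numpy()
        out = []
        for a in range(corr.shape[0]):
            for b in range(a + 1, corr.shape[0]):
                if abs(corr[a, b]) >= threshold:
                    out.append((TRAIT_COLUMNS[a], TRAIT_COLUMNS[b], float(corr[a, b])))
        return out


@dataclass
class PhyloCorrelation:
    """Species-by-species phylogenetic correlation matrix C.

    Symmetric, positive semi-definite, unit diagonal, entries in [0, 1].
    C enters the niche prior as the mixture rho*C + (1-rho)*I.
    """

    C: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (len(self.species), len(self.species)):
            raise ValueError("correlation matrix shape does not match species list")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have a unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        self.C = C

    def reorder(self, species: list[str]) -> "PhyloCorrelation":
        idx = [self.species.index(s) for s in species]
        return PhyloCorrelation(self.C[np.ix_(idx, idx)], list(species))


#: Design-matrix column names in fixed order.
DESIGN_COLUMNS = ["intercept", "log_depth", "bot_temp", "seabed_sand", "log_swept_area", "year_centered"]

#: Variance-partitioning group label of each design column.
DESIGN_GROUPS = ["intercept", "depth", "temperature", "seabed", "effort", "year"]


@dataclass
class DesignMatrix:
    """Fixed-effect design: hauls x covariates, with group labels used by
    the variance partitioning."""

    X: np.ndarray
    columns: list[str] = field(default_factory=lambda: list(DESIGN_COLUMNS))
    groups: list[str] = field(default_factory=lambda: list(DESIGN_GROUPS))

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("design matrix shape does not match column metadata")
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing entries")
        if len(self.groups) != len(self.columns):
            raise ValueError("one group label per column is required")

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def check_full_rank(self) -> None:
        """Raise naming the collinear columns if X is rank deficient."""
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            # identify columns whose removal restores full column rank
            bad = []
            for k in range(self.X.shape[1]):
                keep = [i for i in range(self.X.shape[1]) if i != k]
                if np.linalg.matrix_rank(self.X[:, keep]) == rank:
                    bad.append(self.columns[k])
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


@dataclass
class HurdleData:
    """Two-part response: presence/absence and scaled log abundance.

    ``Y_abu`` holds (ln y - m_j) / s_j at presences and NaN at absences,
    where (m_j, s_j) are the per-species mean and sample standard deviation
    of ln y over presence hauls.  The scaling makes the conditional
    abundance response zero-mean unit-variance per species, matching the
    default priors of the abundance sub-model.
    """

    Y_pa: np.ndarray  # hauls x species, {0, 1}
    Y_abu: np.ndarray  # hauls x species, NaN at absences
    scale_params: pd.DataFrame  # index species, columns ['m', 's']
    species: list[str]

    def __post_init__(self) -> None:
        if self.Y_pa.shape != self.Y_abu.shape:
            raise ValueError("Y_pa and Y_abu must have identical shapes")
        if not np.isin(self.Y_pa, [0, 1]).all():
            raise ValueError("Y_pa must be binary")
        if (np.isnan(self.Y_abu) != (self.Y_pa == 0)).any():
            raise ValueError("Y_abu must be defined exactly where Y_pa = 1")

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        """Map scaled log abundance back to counts: exp(s_j * v + m_j)."""
        m = self.scale_params["m"].to_numpy()
        s = self.scale_params["s"].to_numpy()
        return np.exp(s * scaled + m)


def filter_species(table: CommunityTable, min_occ_frac: float = 0.02, min_total: int = 150) -> CommunityTable:
    """Drop species that are too scarce to model.

    A species is retained when it occurs in at least ``min_occ_frac`` of the
    hauls *and* at least ``min_total`` individuals were caught in total.
    Haul rows are never dropped.  Idempotent.
    """
    if not 0 <= min_occ_frac <= 1:
        raise ValueError("min_occ_frac must lie in [0, 1]")
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    occ = table.occurrence_fraction()
    tot = table.total_individuals()
    keep = [s for s in table.species if occ[s] >= min_occ_frac and tot[s] >= min_total]
    if not keep:
        raise ValueError(
            f"no species survive filtering (occurrence >= {min_occ_frac:.2%} "
            f"and total individuals >= {min_total})"
        )
    return CommunityTable(table.hauls.copy(), table.counts[keep].copy())


def build_design(table: CommunityTable) -> DesignMatrix:
    """Build the fixed-effect design matrix from haul covariates.

    Columns: intercept, ln(depth), bottom temperature, sand-seabed
    indicator (reference: mud to muddy sand), ln(swept area), and survey
    year centred on its mean.
    """
    h = table.hauls
    if (h["depth"] <= 0).any() or (h["swept_area"] <= 0).any():
        raise ValueError("depth and swept_area must be strictly positive")
    X = np.column_stack(
        [
            np.ones(len(h)),
            np.log(h["depth"].to_numpy(dtype=float)),
            h["bot_temp"].to_numpy(dtype=float),
            (h["seabed"] == "sand").to_numpy(dtype=float),
            np.log(h["swept_area"].to_numpy(dtype=float)),
            h["year"].to_numpy(dtype=float) - h["year"].to_numpy(dtype=float).mean(),
        ]
    )
    return DesignMatrix(X)


def make_hurdle(table: CommunityTable) -> HurdleData:
    """Split counts into presence/absence and scaled log conditional abundance."""
    Y = table.counts.to_numpy(dtype=float)
    Y_pa = (Y > 0).astype(int)
    n_pres = Y_pa.sum(axis=0)
    thin = [s for s, n in zip(table.species, n_pres) if n < 2]
    if thin:
        raise ValueError(
            f"species {thin} have fewer than 2 presence hauls, so the log-abundance "
            "standard deviation is undefined; filter species more strictly first"
        )
    Y_abu = np.full_like(Y, np.nan)
    m = np.empty(len(table.species))
    s = np.empty(len(table.species))
    for j in range(Y.shape[1]):
        pres = Y_pa[:, j] == 1
        logy = np.log(Y[pres, j])
        m[j] = logy.mean()
        s[j] = logy.std(ddof=1)
        if s[j] == 0:
            # constant positive counts: degenerate but legal; avoid 0/0
            s[j] = 1.0
        Y_abu[pres, j] = (logy - m[j]) / s[j]
    scale = pd.DataFrame({"m": m, "s": s}, index=table.species)
    return HurdleData(Y_pa, Y_abu, scale, list(table.species))


def taxonomy_to_correlation(taxonomy: pd.DataFrame) -> PhyloCorrelation:
    """Convert a ranked taxonomy into a phylogenetic correlation matrix.

    The taxonomy is read as a tree rooted above the phylum level with one
    edge of unit length per rank (phylum, class, order, family, genus,
    species), so every tip sits at depth ``len(TAXONOMY_RANKS)``.  The
    correlation between two species is the shared root-to-tip path length
    divided by the total tip depth — the classic Brownian-motion covariance
    of an ultrametric tree, normalised to a unit diagonal.

    Parameters
    ----------
    taxonomy
        DataFrame with a ``species`` column (or species index) and the rank
        columns :data:`TAXONOMY_RANKS`.
    """
    tx = taxonomy.copy()
    if "species" in tx.columns:
        tx = tx.set_index("species")
    missing = [r for r in TAXONOMY_RANKS if r not in tx.columns]
    if missing:
        raise ValueError(f"taxonomy is missing rank columns {missing}")
    if tx[TAXONOMY_RANKS].isna().any().any():
        raise ValueError("taxonomy contains missing ranks")
    species = list(tx.index)
    paths = [tuple(tx.loc[s, TAXONOMY_RANKS]) for s in species]
    depth = len(TAXONOMY_RANKS)
    n = len(species)
    C = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            shared = 0
            for ra, rb in zip(paths[a], paths[b]):
                if ra == rb:
                    shared += 1
                else:
                    break
            if shared == depth:
                raise ValueError(
                    f"species {species[a]!r} and {species[b]!r} have identical full "
                    "taxonomies; they would be indistinguishable on the tree"
                )
            C[a, b] = C[b, a] = shared / depth
    return PhyloCorrelation(C, species)
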