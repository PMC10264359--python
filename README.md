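# trawljsdm

Hurdle joint species distribution modelling (JSDM) for bottom-trawl survey
communities, with species traits, phylogeny, and spatio-temporal latent
factors.

## Who this is for

Fisheries and community ecologists analysing haul-level count data from
standardized trawl surveys — many species, many zeros, strong spatial
structure — who want to ask: *how do species' occurrences and abundances
respond to environment, how much of those responses do traits and phylogeny
explain, and how have community composition and trait structure changed over
time?*  The motivating use case is a demersal elasmobranch (shark and ray)
community in a heavily exploited shelf basin, but nothing in the package is
specific to that system.

## The model

Counts are zero-inflated, so a hurdle is used: a probit presence–absence
(PA) model and a gaussian model for standardized log abundance conditional
on presence (ABU), fitted independently.  For haul *i* and species *j*:

```
PA :  Pr(y_ij > 0) = Φ(L_ij)
ABU:  (ln y_ij − m_j)/s_j = L_ij + ε_ij ,   ε ~ N(0, σ_j²)   (y_ij > 0)

L_ij = x_i' β_j + Σ_l η_i^(l) · λ_j^(l)
B = [β_1 … β_S] ~ MN( Γ'T' , V , ρC + (1−ρ)I )
```

Covariates are ln depth, bottom temperature, seabed class, ln swept area
(effort) and a linear year term.  Species niches `β_j` are pulled toward a
trait regression (`Γ` = trait-by-covariate effects; traits: age at first
maturity, reproductive mode, trophic level), with residual correlation
across species mixing a taxonomy-derived phylogenetic correlation `C` with
independence through the signal `ρ ∈ [0,1]`.  Latent factors `η` are
unit-variance Gaussian processes over haul locations (exponential
covariance, range sampled on a grid; predictive-process approximation at
survey scale) plus i.i.d. yearly factors, with shrinkage-priored loadings
`λ_j`.  Inference is a blocked Gibbs sampler (truncated-normal probit
augmentation; all other updates conjugate or discrete).  See
`docs/methods.md` for the full specification, priors and validation.

Downstream products mirror a complete survey analysis: Tjur R² / AUC / R²
fit metrics, split-chain PSRF convergence checks, posterior support tables
for `β` and `Γ`, variance partitioning across covariate groups and random
levels, trait-explained niche variance, gridded occurrence/abundance maps,
species richness and Pr(any species), yearly abundance indices scaled to a
baseline year, and community-weighted mean (CWM) traits with trends.

Because the survey data this kind of analysis uses are typically
access-restricted, the package ships a synthetic survey generator
(`trawljsdm.synthetic`) with known ground truth — 9 species with the
packaged trait/taxonomy fixture, ~4000 hauls, depths 10–270 m, swept area
≈ 0.047 km², planted phylogenetic signal ρ = 0.85 and a negative
viviparity × depth trait effect — so the whole pipeline is testable end to
end.

## Worked example

```python
import numpy as np
from trawljsdm import (McmcConfig, default_scenario, simulate_counts,
                       filter_species, fit_hurdle, taxonomy_to_correlation,
                       load_fixture_taxonomy)
from trawljsdm.diagnostics import fit_metrics
from trawljsdm.summaries import phylo_signal, variance_partition

scenario = default_scenario(seed=1, n_hauls=1500)      # 9-species synthetic survey
result = simulate_counts(scenario)
table = filter_species(result.community)               # 2% / 150-individual rule
phylo = taxonomy_to_correlation(load_fixture_taxonomy())
fit = fit_hurdle(table, scenario.traits, phylo, McmcConfig(seed=11))

print("PA phylogenetic signal:", phylo_signal(fit.pa))
print(fit_metrics(fit).round(3).loc["community_mean"])
print(variance_partition(fit.pa, fit.design.X).community_mean().round(3))
```

prints (about four minutes on one core):

```
PA phylogenetic signal: {'mean': 0.9005500000000001, 'pr_positive': 1.0}
tjur_r2    0.398
auc        0.900
abu_r2     0.692
Name: community_mean, dtype: float64
depth              0.295
temperature        0.094
seabed             0.032
effort             0.004
year               0.004
random_spatial     0.524
random_temporal    0.047
dtype: float64
```

Read: the planted phylogenetic signal (ρ = 0.85) is recovered
(E[ρ] = 0.90, Pr[ρ>0] = 1); the PA model discriminates presences from
absences (community-mean Tjur R² 0.40, AUC 0.90); and the spatial latent
factors dominate the partitioned variance (52%), with depth the strongest
fixed effect (30%) — exactly the structure the generator planted.

A YAML-driven command line wraps the same pipeline
(`trawljsdm simulate|fit|diagnose|summarize|predict|index|cwm|all`):

```
trawljsdm all --config config.yml
```

Each stage persists its outputs (posteriors as NetCDF, tables as CSV) and a
manifest with the seed, config digest and library versions; stages resume
from persisted posteriors, so `fit` runs only once per dataset.

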