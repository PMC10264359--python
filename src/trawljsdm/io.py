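"""Readers and writers for the pipeline's tabular formats.

Community tables, traits, taxonomies and prediction grids travel as CSV
with strict schemas; trees as Newick; posteriors as NetCDF (see
:class:`trawljsdm.gibbs.PosteriorSamples`).  Count columns in the community
CSV carry a ``sp_`` prefix to keep them distinguishable from covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import (
    HAUL_COLUMNS,
    TAXONOMY_RANKS,
    TRAIT_COLUMNS,
    CommunityTable,
    PhyloCorrelation,
    TraitMatrix,
)

__all__ = [
    "read_community",
    "write_community",
    "read_traits",
    "write_traits",
    "read_taxonomy",
    "read_tree_newick",
    "read_grid",
    "write_grid",
]

SPECIES_PREFIX = "sp_"


def read_community(path) -> CommunityTable:
    """Read a community CSV: haul covariates plus ``sp_``-prefixed counts."""
    df = pd.read_csv(path)
    missing = [c for c in HAUL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"community file {path} is missing columns {missing}")
    sp_cols = [c for c in df.columns if c.startswith(SPECIES_PREFIX)]
    if not sp_cols:
        raise ValueError(f"community file {path} has no '{SPECIES_PREFIX}' count columns")
    counts = df[sp_cols].copy()
    for c in sp_cols:
        if not np.issubdtype(counts[c].dtype, np.number):
            raise ValueError(f"count column {c} is not numeric")
    counts.columns = [c[len(SPECIES_PREFIX) :] for c in sp_cols]
    return CommunityTable(df[HAUL_COLUMNS].copy(), counts)


def write_community(table: CommunityTable, path) -> None:
    out = table.hauls.copy()
    for sp in table.species:
        out[SPECIES_PREFIX + sp] = table.counts[sp].to_numpy()
    out.to_csv(path, index=False)


def read_traits(path) -> TraitMatrix:
    """Read a trait CSV; ``repro_mode`` accepts viviparous/oviparous strings
    (mapped to 1/0) or the binary codes directly."""
    df = pd.read_csv(path)
    missing = [c for c in ["species"] + TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait file {path} is missing columns {missing}")
    rm = df["repro_mode"]
    if rm.dtype == object:
        lut = {"viviparous": 1, "oviparous": 0}
        bad = set(rm.unique()) - set(lut)
        if bad:
            raise ValueError(f"unknown repro_mode level(s) {sorted(bad)}; expected {sorted(lut)}")
        df["repro_mode"] = rm.map(lut)
    return TraitMatrix(df.set_index("species")[TRAIT_COLUMNS])


def write_traits(traits: TraitMatrix, path) -> None:
    out = traits.traits.copy()
    out["repro_mode"] = np.where(out["repro_mode"] == 1, "viviparous", "oviparous")
    out.to_csv(path, index_label="species")


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["species"] + TAXONOMY_RANKS if c not in df.columns]
    if missing:
        raise ValueError(f"taxonomy file {path} is missing columns {missing}")
    return df


def read_tree_newick(path) -> PhyloCorrelation:
    """Phylogenetic correlation from a Newick tree with branch lengths.

    The correlation of two tips is the shared root-to-tip path length
    normalised by the geometric mean of the two tip depths (for an
    ultrametric tree this is the usual shared fraction of the total depth).
    """
    import dendropy

    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    depth = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    C = np.eye(n)
    tx = {t.label: t for t in tree.taxon_namespace}
    for a in range(n):
        for b in range(a + 1, n):
            d = pdm.patristic_distance(tx[taxa[a]], tx[taxa[b]])
            shared = 0.5 * (depth[taxa[a]] + depth[taxa[b]] - d)
            C[a, b] = C[b, a] = shared / np.sqrt(depth[taxa[a]] * depth[taxa[b]])
    return PhyloCorrelation(C, taxa)


GRID_COLUMNS = ["cell_id", "lon", "lat", "year", "depth", "bot_temp", "seabed"]


def read_grid(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GRID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"grid file {path} is missing columns {missing}")
    return df


def write_grid(grid: pd.DataFrame, path) -> None:
    grid.to_csv(path, index=False)
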