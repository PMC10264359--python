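"""Domain types, species filtering, design construction, hurdle scaling,
taxonomy-to-correlation conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trawljsdm.data_model import (
    TAXONOMY_RANKS,
    CommunityTable,
    TraitMatrix,
    build_design,
    filter_species,
    make_hurdle,
    taxonomy_to_correlation,
)


class TestFilterSpecies:
    def test_two_threshold_rule(self, toy_hauls):
        # A: 3% occurrence, 200 individuals -> kept; B: 5% but 100 < 150 ->
        # dropped; C: comfortably above both -> kept
        n = 100
        counts = pd.DataFrame(0, index=range(n), columns=["A", "B", "C"])
        counts.loc[:2, "A"] = [66, 67, 67]
        counts.loc[:4, "B"] = 20
        counts.loc[:29, "C"] = 500 // 30 + 1
        table = CommunityTable(toy_hauls(n), counts)
        out = filter_species(table, 0.02, 150)
        assert out.species == ["A", "C"]
        assert out.n_hauls == n

    def test_identity_when_all_pass(self, toy_table):
        table = toy_table({"A": [5] * 40, "B": [4] * 40})
        out = filter_species(table, 0.02, 150)
        assert out.species == table.species
        pd.testing.assert_frame_equal(out.counts, table.counts)

    def test_zero_thresholds_identity(self, toy_table):
        table = toy_table({"A": [0, 1, 0, 2], "B": [0, 0, 0, 1]})
        out = filter_species(table, 0.0, 0)
        assert out.species == ["A", "B"]

    def test_idempotent(self, toy_hauls):
        n = 100
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(2, size=(n, 4)), columns=list("ABCD"))
        table = CommunityTable(toy_hauls(n), counts)
        once = filter_species(table, 0.3, 100)
        twice = filter_species(once, 0.3, 100)
        assert once.species == twice.species
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_empty_result_errors(self, toy_table):
        table = toy_table({"A": [1, 0, 0, 0]})
        with pytest.raises(ValueError, match="150"):
            filter_species(table, 0.9, 150)


class TestBuildDesign:
    def test_columns_and_values(self, toy_table):
        table = toy_table({"A": [1, 2, 3, 4]})
        table.hauls.loc[:, "depth"] = 100.0
        table.hauls.loc[:, "swept_area"] = 0.047
        table.hauls.loc[:, "seabed"] = ["sand", "mud_to_muddy_sand", "sand", "sand"]
        d = build_design(table)
        assert d.columns == ["intercept", "log_depth", "bot_temp", "seabed_sand", "log_swept_area", "year_centered"]
        assert d.groups == ["intercept", "depth", "temperature", "seabed", "effort", "year"]
        assert np.allclose(d.X[:, 0], 1.0)
        assert np.allclose(d.X[:, 1], np.log(100.0))
        # mud to muddy sand is the reference level
        assert list(d.X[:, 3]) == [1.0, 0.0, 1.0, 1.0]
        assert np.allclose(d.X[:, 4], np.log(0.047))
        assert abs(d.X[:, 4][0] - (-3.0576)) < 1e-3
        assert np.isclose(d.X[:, 5].mean(), 0.0)

    def test_rejects_unknown_seabed(self, toy_table):
        table = toy_table({"A": [1, 1]})
        with pytest.raises(ValueError, match="seabed"):
            table.hauls.loc[0, "seabed"] = "gravel"
            CommunityTable(table.hauls, table.counts)


class TestMakeHurdle:
    def test_scaling_on_geometric_counts(self, toy_table):
        table = toy_table({"A": [1, int(round(np.e)), 0, 20]})
        # use exact counts 1, e, e^2 via direct construction on floats:
        counts = pd.DataFrame({"A": [1, 3, 0, 7]})
        table = toy_table({"A": [1, 3, 0, 7]})
        h = make_hurdle(table)
        logy = np.log(np.array([1, 3, 7]))
        assert np.isclose(h.scale_params.loc["A", "m"], logy.mean())
        assert np.isclose(h.scale_params.loc["A", "s"], logy.std(ddof=1))
        assert list(h.Y_pa[:, 0]) == [1, 1, 0, 1]
        assert np.isnan(h.Y_abu[2, 0])

    def test_unit_moments_and_roundtrip(self, toy_hauls):
        rng = np.random.default_rng(1)
        n = 60
        counts = pd.DataFrame({"A": rng.poisson(5, n) + 1, "B": rng.poisson(3, n)})
        table = CommunityTable(toy_hauls(n, 1), counts)
        h = make_hurdle(table)
        for j, sp in enumerate(h.species):
            v = h.Y_abu[:, j][h.Y_pa[:, j] == 1]
            assert abs(v.mean()) < 1e-8
            assert abs(v.std(ddof=1) - 1) < 1e-8
        # exact round trip at presences
        back = h.inverse_transform(h.Y_abu)
        pres = h.Y_pa == 1
        assert np.allclose(back[pres], table.counts.to_numpy()[pres], atol=1e-9)

    def test_too_few_presences_errors(self, toy_table):
        table = toy_table({"A": [5, 0, 0, 0]})
        with pytest.raises(ValueError, match="presence"):
            make_hurdle(table)


def _taxonomy(rows):
    return pd.DataFrame(rows, columns=["species"] + TAXONOMY_RANKS)


class TestTaxonomyCorrelation:
    def test_congeners_and_distant_pairs(self):
        tx = _taxonomy(
            [
                ["s1", "P1", "C1", "O1", "F1", "G1", "e1"],
                ["s2", "P1", "C1", "O1", "F1", "G1", "e2"],
                ["s3", "P1", "C2", "O2", "F2", "G2", "e3"],
            ]
        )
        out = taxonomy_to_correlation(tx)
        i = {s: k for k, s in enumerate(out.species)}
        assert np.isclose(out.C[i["s1"], i["s1"]], 1.0)
        assert np.isclose(out.C[i["s1"], i["s2"]], 5 / 6)
        assert np.isclose(out.C[i["s1"], i["s3"]], 1 / 6)

    def test_duplicate_full_taxonomy_errors(self):
        tx = _taxonomy(
            [
                ["s1", "P1", "C1", "O1", "F1", "G1", "e1"],
                ["s2", "P1", "C1", "O1", "F1", "G1", "e1"],
            ]
        )
        with pytest.raises(ValueError, match="identical"):
            taxonomy_to_correlation(tx)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(*[st.integers(0, 2) for _ in range(6)]), min_size=2, max_size=12, unique=True))
    def test_random_taxonomies_psd(self, paths):
        rows = []
        for i, path in enumerate(paths):
            # enforce nesting by making each rank value encode its ancestry
            nested = ["/".join(str(x) for x in path[: k + 1]) for k in range(5)]
            rows.append([f"s{i}"] + nested + [f"s{i}"])
        out = taxonomy_to_correlation(_taxonomy(rows))
        assert np.linalg.eigvalsh(out.C).min() >= -1e-10


class TestTraitMatrix:
    def test_design_has_intercept(self):
        tm = TraitMatrix(
            pd.DataFrame(
                {"age_maturity": [2.0, 5.0], "repro_mode": [0, 1], "trophic_level": [3.5, 4.0]},
                index=["a", "b"],
            )
        )
        D = tm.design()
        assert D.shape == (2, 4)
        assert np.allclose(D[:, 0], 1.0)

    def test_rejects_out_of_range_trophic(self):
        with pytest.raises(ValueError, match="trophic"):
            TraitMatrix(
                pd.DataFrame(
                    {"age_maturity": [2.0], "repro_mode": [0], "trophic_level": [5.5]}, index=["a"]
                )
            )
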