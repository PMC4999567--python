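"""Mixed-type distances: Wu-Palmer concept similarity, extended Jaccard,
normalized Euclidean, and their Gower-style combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from ontokdd.distances import (
    categorical_dissimilarity,
    concept_similarity,
    mixed_distance_matrix,
    numeric_dissimilarity,
)
from ontokdd.errors import ContractError, UnknownConceptError
from ontokdd.ontology import AttributeSpec, ConceptHierarchy


@pytest.fixture(scope="module")
def flat_hierarchy():
    return ConceptHierarchy.from_dict(
        "flat", {"id": "root", "children": [{"id": "a"}, {"id": "b"}, {"id": "c"}]}
    )


class TestConceptSimilarity:
    def test_identity_is_one(self, location_hierarchy):
        assert concept_similarity(location_hierarchy, "MCA", "MCA") == 1.0
        assert concept_similarity(location_hierarchy, "cerebral_vasculature", "cerebral_vasculature") == 1.0

    def test_cross_branch_concepts_have_zero_similarity(self, location_hierarchy):
        assert concept_similarity(location_hierarchy, "AComm", "BasilarTip") == 0.0

    def test_siblings_at_depth_two_score_half(self, location_hierarchy):
        assert concept_similarity(location_hierarchy, "AComm", "Pericallosal") == 0.5

    def test_symmetric(self, location_hierarchy):
        pairs = [("AComm", "MCA"), ("MCA", "PComm"), ("ICA", "anterior_circulation")]
        for a, b in pairs:
            assert concept_similarity(location_hierarchy, a, b) == concept_similarity(
                location_hierarchy, b, a
            )

    def test_unknown_concept_is_lookup_error(self, location_hierarchy):
        with pytest.raises(UnknownConceptError):
            concept_similarity(location_hierarchy, "MCA", "Ophthalmic")


class TestCategoricalDissimilarity:
    SPECS = [
        AttributeSpec(name="R.C1", kind="categorical", categories=("x", "y")),
        AttributeSpec(name="R.C2", kind="categorical", categories=("u", "v")),
    ]

    def test_all_flat_attributes_equal_gives_zero(self):
        row = {"R.C1": "x", "R.C2": "u"}
        assert categorical_dissimilarity(row, dict(row), self.SPECS) == 0.0

    def test_all_flat_attributes_different_gives_one(self):
        x = {"R.C1": "x", "R.C2": "u"}
        y = {"R.C1": "y", "R.C2": "v"}
        assert categorical_dissimilarity(x, y, self.SPECS) == 1.0

    def test_hierarchical_siblings_give_half(self, location_hierarchy):
        specs = [
            AttributeSpec(name="R.Loc", kind="hierarchical", hierarchy="cerebral_locations")
        ]
        x, y = {"R.Loc": "AComm"}, {"R.Loc": "Pericallosal"}
        d = categorical_dissimilarity(x, y, specs, {"cerebral_locations": location_hierarchy})
        assert d == 0.5


class TestNumericDissimilarity:
    def test_identical_rows_give_zero(self):
        assert numeric_dissimilarity([0.2, 0.7], [0.2, 0.7]) == 0.0

    def test_single_attribute_extremes_give_one(self):
        assert numeric_dissimilarity([0.0], [1.0]) == 1.0

    def test_two_attribute_hand_value(self):
        assert numeric_dissimilarity([0.3, 0.0], [0.0, 0.4]) == pytest.approx(
            np.sqrt(0.125), abs=1e-12
        )

    def test_unnormalized_input_is_contract_error(self):
        with pytest.raises(ContractError):
            numeric_dissimilarity([0.0, 5.0], [1.0, 0.5])


class TestMixedDistanceMatrix:
    def make_three_record_fixture(self, location_hierarchy):
        rows = pd.DataFrame(
            {
                "R.X": [0.0, 0.5, 1.0],
                "R.Y": [0.2, 0.2, 1.0],
                "R.Loc": ["AComm", "Pericallosal", "BasilarTip"],
            },
            index=["r1", "r2", "r3"],
        )
        return make_table(
            None, rows, numeric=["R.X", "R.Y"], hierarchical=[("R.Loc", location_hierarchy)]
        )

    def test_three_record_fixture_matches_hand_computation(self, location_hierarchy):
        table = self.make_three_record_fixture(location_hierarchy)
        D = mixed_distance_matrix(table, ["R.X", "R.Y", "R.Loc"])
        # numeric part sqrt(sum diff^2 / 2); categorical part 1 - Wu-Palmer;
        # combined (2*d_num + 1*d_cat) / 3
        expected = {
            (0, 1): (2 * np.sqrt(0.125) + 0.5) / 3,
            (0, 2): (2 * np.sqrt(0.82) + 1.0) / 3,
            (1, 2): (2 * np.sqrt(0.445) + 1.0) / 3,
        }
        assert expected[(0, 1)] == pytest.approx(0.40236892706218254)
        assert expected[(0, 2)] == pytest.approx(0.9370256758758278)
        assert expected[(1, 2)] == pytest.approx(0.7780554688042111)
        for (i, j), val in expected.items():
            assert D.values[i, j] == pytest.approx(val, abs=1e-12)
            assert D.values[j, i] == pytest.approx(val, abs=1e-12)

    def test_duplicate_rows_have_zero_distance(self, location_hierarchy):
        rows = pd.DataFrame(
            {"R.X": [0.3, 0.3], "R.Loc": ["MCA", "MCA"]}, index=["a", "b"]
        )
        table = make_table(None, rows, numeric=["R.X"], hierarchical=[("R.Loc", location_hierarchy)])
        D = mixed_distance_matrix(table, ["R.X", "R.Loc"])
        assert D.values[0, 1] == 0.0

    def test_purely_numeric_features_collapse_to_euclidean(self):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame({"R.X": rng.random(6), "R.Y": rng.random(6)})
        table = make_table(None, rows, numeric=["R.X", "R.Y"])
        D = mixed_distance_matrix(table, ["R.X", "R.Y"])
        x = rows.to_numpy()
        for i in range(6):
            for j in range(6):
                expected = np.sqrt(((x[i] - x[j]) ** 2).sum() / 2)
                assert D.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_empty_features_and_single_record_are_errors(self):
        rows = pd.DataFrame({"R.X": [0.1, 0.2]})
        table = make_table(None, rows, numeric=["R.X"])
        with pytest.raises(ContractError):
            mixed_distance_matrix(table, [])
        single = make_table(None, rows.iloc[:1], numeric=["R.X"])
        with pytest.raises(ContractError):
            mixed_distance_matrix(single, ["R.X"])

    def test_pair_with_no_comparable_attribute_gets_distance_one(self, caplog):
        rows = pd.DataFrame({"R.X": [0.1, np.nan, 0.5], "R.Y": [np.nan, 0.2, 0.5]})
        table = make_table(None, rows, numeric=["R.X", "R.Y"])
        with caplog.at_level("WARNING"):
            D = mixed_distance_matrix(table, ["R.X", "R.Y"])
        assert D.values[0, 1] == 1.0
        assert any("no comparable" in m for m in caplog.messages)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 12))
    def test_pseudometric_properties_on_random_data(self, location_hierarchy, seed, n):
        rng = np.random.default_rng(seed)
        leaves = location_hierarchy.leaf_ids()
        rows = pd.DataFrame(
            {
                "R.X": rng.random(n),
                "R.Loc": rng.choice(leaves, n),
                "R.C": rng.choice(["p", "q", "r"], n),
            }
        )
        table = make_table(
            None,
            rows,
            numeric=["R.X"],
            hierarchical=[("R.Loc", location_hierarchy)],
            categorical=[("R.C", ["p", "q", "r"])],
        )
        D = mixed_distance_matrix(table, ["R.X", "R.Loc", "R.C"])
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0.0)
        assert D.values.min() >= 0.0 and D.values.max() <= 1.0


class TestFlatHierarchyReduction:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_depth_one_hierarchy_equals_simple_matching(self, flat_hierarchy, seed):
        """A root+leaves hierarchy makes the extended Jaccard collapse to
        the plain matching dissimilarity."""
        rng = np.random.default_rng(seed)
        n = 8
        rows = pd.DataFrame(
            {"R.H": rng.choice(["a", "b", "c"], n), "R.C": rng.choice(["a", "b", "c"], n)}
        )
        rows["R.C"] = rows["R.H"]  # same values through both code paths
        as_hier = make_table(None, rows[["R.H"]], hierarchical=[("R.H", flat_hierarchy)])
        as_flat = make_table(None, rows[["R.C"]], categorical=[("R.C", ["a", "b", "c"])])
        Dh = mixed_distance_matrix(as_hier, ["R.H"])
        Df = mixed_distance_matrix(as_flat, ["R.C"])
        assert np.array_equal(Dh.values, Df.values)
        assert set(np.unique(Dh.values)) <= {0.0, 1.0}

    def test_agreeing_categorical_attribute_never_increases_distance(self, location_hierarchy):
        rng = np.random.default_rng(7)
        n = 10
        rows = pd.DataFrame(
            {
                "R.X": rng.random(n),
                "R.Loc": rng.choice(location_hierarchy.leaf_ids(), n),
                "R.Same": ["same"] * n,
            }
        )
        base = make_table(
            None,
            rows[["R.X", "R.Loc"]],
            numeric=["R.X"],
            hierarchical=[("R.Loc", location_hierarchy)],
        )
        more = make_table(
            None,
            rows,
            numeric=["R.X"],
            hierarchical=[("R.Loc", location_hierarchy)],
            categorical=[("R.Same", ["same"])],
        )
        D0 = mixed_distance_matrix(base, ["R.X", "R.Loc"])
        D1 = mixed_distance_matrix(more, ["R.X", "R.Loc", "R.Same"])
        assert (D1.values <= D0.values + 1e-12).all()
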