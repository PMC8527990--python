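"""Diversity and dissimilarity metrics against hand values and brute force."""

import io as _io

import numpy as np
import pytest
from skbio import TreeNode

from distdecay.metrics import (
    alpha_diversity,
    beta_dissimilarity,
    env_difference_matrix,
    geographic_distance_km,
    haversine_km,
    weighted_unifrac,
)
from distdecay.model import DataModelError

from conftest import make_count_table, make_design


def brute_force_wunifrac(tree: TreeNode, counts_a: dict, counts_b: dict,
                         normalized: bool) -> float:
    """Independent per-branch evaluation of weighted UniFrac.

    For every branch, weight its length by |p_A − p_B| where p_X is the
    fraction of community X's individuals on leaves below the branch; the
    normalized variant divides by the abundance-weighted root-to-tip sum.
    """
    total_a = sum(counts_a.values()) or 1
    total_b = sum(counts_b.values()) or 1
    raw = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        pa = sum(counts_a.get(t, 0) for t in tips) / total_a
        pb = sum(counts_b.get(t, 0) for t in tips) / total_b
        raw += (node.length or 0.0) * abs(pa - pb)
    if not normalized:
        return raw
    denom = 0.0
    for tip in tree.tips():
        depth = sum(n.length or 0.0
                    for n in tip.ancestors() if n.parent is not None)
        depth += tip.length or 0.0
        denom += depth * (counts_a.get(tip.name, 0) / total_a
                          + counts_b.get(tip.name, 0) / total_b)
    return raw / denom


class TestAlphaDiversity:
    def test_richness_counts_nonzero(self):
        t = make_count_table({"a": [2], "b": [1], "c": [1], "d": [0]}, ["S"])
        assert alpha_diversity(t).loc["S", "richness"] == 3

    @pytest.mark.parametrize("k", [2, 5, 17])
    def test_uniform_maximizes_shannon(self, k):
        t = make_count_table({f"t{i}": [10] for i in range(k)}, ["S"])
        assert alpha_diversity(t).loc["S", "shannon"] == pytest.approx(np.log(k))

    def test_hand_shannon(self):
        t = make_count_table({"a": [2], "b": [1], "c": [1]}, ["S"])
        assert alpha_diversity(t).loc["S", "shannon"] == pytest.approx(
            1.039721, abs=1e-6)


class TestBetaDissimilarity:
    def test_identity_and_disjoint_extremes(self):
        t = make_count_table({"a": [5, 5, 5, 0], "b": [3, 3, 0, 4]},
                             ["x", "y", "p", "q"])
        for metric in ("braycurtis", "sorensen"):
            dm = beta_dissimilarity(t, metric)
            assert dm["x", "y"] == pytest.approx(0.0)
            assert dm["p", "q"] == pytest.approx(1.0)

    def test_hand_values(self):
        t = make_count_table({"t1": [10, 0], "t2": [0, 10], "t3": [5, 5]},
                             ["X", "Y"])
        assert beta_dissimilarity(t, "braycurtis")["X", "Y"] == pytest.approx(
            0.666667, abs=1e-6)
        t2 = make_count_table(
            {"t1": [1, 0], "t2": [1, 1], "t3": [1, 1], "t4": [0, 1]},
            ["X", "Y"])
        assert beta_dissimilarity(t2, "sorensen")["X", "Y"] == pytest.approx(
            0.333333, abs=1e-6)

    def test_binarized_braycurtis_equals_sorensen(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            counts = rng.integers(0, 6, size=(5, 12))
            counts[:, 0] += 1  # keep rows nonzero
            t = make_count_table(
                {f"t{i}": counts[:, i].tolist() for i in range(12)},
                [f"s{j}" for j in range(5)])
            binary = make_count_table(
                {f"t{i}": (counts[:, i] > 0).astype(int).tolist()
                 for i in range(12)},
                [f"s{j}" for j in range(5)])
            np.testing.assert_allclose(
                beta_dissimilarity(binary, "braycurtis").data,
                beta_dissimilarity(t, "sorensen").data, atol=1e-12)

    def test_zero_total_sample_rejected(self):
        t = make_count_table({"a": [5, 0]}, ["x", "y"])
        with pytest.raises(DataModelError):
            beta_dissimilarity(t, "braycurtis")


class TestWeightedUnifrac:
    TREE = "((A:1,B:1):1,C:2);"

    def _tree(self, newick=None):
        return TreeNode.read(_io.StringIO(newick or self.TREE))

    def test_identical_samples_zero(self):
        t = make_count_table({"A": [4, 4], "B": [2, 2], "C": [6, 6]},
                             ["x", "y"])
        dm = weighted_unifrac(t, self._tree())
        assert dm["x", "y"] == pytest.approx(0.0)

    def test_two_leaf_star_maximal(self):
        t = make_count_table({"A": [8, 0], "B": [0, 8]}, ["x", "y"])
        dm = weighted_unifrac(t, self._tree("(A:1,B:1);"), normalized=True)
        assert dm["x", "y"] == pytest.approx(1.0)

    def test_hand_traversal_values(self):
        t = make_count_table({"A": [4, 0], "B": [0, 2], "C": [4, 6]},
                             ["X", "Y"])
        raw = weighted_unifrac(t, self._tree(), normalized=False)
        norm = weighted_unifrac(t, self._tree(), normalized=True)
        assert raw["X", "Y"] == pytest.approx(1.5)
        assert norm["X", "Y"] == pytest.approx(0.375)

    def test_matches_brute_force_on_random_trees(self):
        from distdecay.synth import _random_clade_newick
        rng = np.random.default_rng(5)
        for case in range(25):
            n_leaves = int(rng.integers(3, 6))
            names = [f"L{i}" for i in range(n_leaves)]
            tree = TreeNode.read(
                _io.StringIO(_random_clade_newick(names, rng) + ";"))
            counts = rng.integers(0, 9, size=(2, n_leaves))
            counts[:, 0] += 1
            t = make_count_table(
                {names[i]: counts[:, i].tolist() for i in range(n_leaves)},
                ["u", "v"])
            for normalized in (False, True):
                got = weighted_unifrac(t, tree, normalized=normalized)["u", "v"]
                want = brute_force_wunifrac(
                    tree, dict(zip(names, counts[0])),
                    dict(zip(names, counts[1])), normalized)
                assert got == pytest.approx(want, abs=1e-10), (case, normalized)

    def test_taxon_missing_from_tree_named(self):
        t = make_count_table({"A": [1, 1], "Z": [1, 1]}, ["x", "y"])
        with pytest.raises(DataModelError, match="Z"):
            weighted_unifrac(t, self._tree())


class TestGeographicDistance:
    def test_same_point_zero(self):
        assert haversine_km(45.0, -93.0, 45.0, -93.0) == pytest.approx(0.0)

    def test_one_degree_meridian(self):
        assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(111.195, abs=1e-3)

    def test_antipodal(self):
        assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(20015.1, abs=0.1)

    def test_matrix_from_design(self):
        d = make_design({"S": ("A", "A1", 0)},
                        {"A": {"latitude": 0.0, "longitude": 0.0},
                         "B": {"latitude": 1.0, "longitude": 0.0}})
        geo = geographic_distance_km(d)
        assert geo["A", "B"] == pytest.approx(111.195, abs=1e-3)


class TestEnvDifference:
    def _design(self, tkn):
        return make_design(
            {"S": ("A", "A1", 0)},
            {f: {"latitude": 45.0, "longitude": -93.0, "TKN_in": v}
             for f, v in tkn.items()})

    def test_hand_differences(self):
        dm, excluded = env_difference_matrix(
            self._design({"A": 1.0, "B": 4.0, "C": 6.0}), "TKN_in")
        assert excluded == []
        assert dm["A", "B"] == 3 and dm["A", "C"] == 5 and dm["B", "C"] == 2

    def test_constant_field_zero(self):
        dm, _ = env_difference_matrix(
            self._design({"A": 2.0, "B": 2.0}), "TKN_in")
        assert dm["A", "B"] == 0.0

    def test_missing_facility_reported_not_zeroed(self):
        dm, excluded = env_difference_matrix(
            self._design({"A": 1.0, "B": np.nan, "C": 6.0}), "TKN_in")
        assert excluded == ["B"]
        assert "B" not in dm.ids

    def test_unknown_variable(self):
        with pytest.raises(DataModelError, match="unknown"):
            env_difference_matrix(self._design({"A": 1.0, "B": 2.0}), "bogus")
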