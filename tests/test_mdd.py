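import numpy as np
import pytest
from scipy.stats import chi2_contingency

from acetylsite import fixtures, mdd
from acetylsite.mdd import GROUP_ORDER, PROPERTY_GROUPS
from acetylsite.seqio import STANDARD_AA, Fragment

from conftest import make_fragment


def _uniform_fragments(count, seed, n=7):
    rng = np.random.default_rng(seed)
    letters = list(STANDARD_AA)
    frags = []
    for _ in range(count):
        flanks = rng.choice(letters, size=2 * n)
        window = "".join(flanks[:n]) + "K" + "".join(flanks[n:])
        frags.append(Fragment("U", n + 1, window))
    return frags


def test_property_groups_partition_the_standard_alphabet():
    letters = "".join(PROPERTY_GROUPS.values())
    assert sorted(letters) == sorted(STANDARD_AA)
    assert [len(PROPERTY_GROUPS[g]) for g in GROUP_ORDER] == [6, 2, 3, 6, 3]


class TestContingencyTable:
    def test_single_cell(self):
        frags = [make_fragment("KKKKKKK")] * 4  # every position basic
        table = mdd.contingency_table(frags, -1, 1)
        basic = GROUP_ORDER.index("basic")
        assert table.counts[basic, basic] == 4
        assert table.total == 4

    def test_pads_and_ambiguous_excluded(self):
        frags = [make_fragment("-KKKX--")] * 3
        # offset -3 is pad, offset +1 ambiguous
        assert mdd.contingency_table(frags, -3, -1).total == 0
        assert mdd.contingency_table(frags, 1, -1).total == 0
        assert mdd.contingency_table(frags, -2, -1).total == 3

    def test_matches_direct_enumeration(self):
        """Mixed toy set tallied by independent direct enumeration."""
        frags = _uniform_fragments(10, seed=42, n=2)
        table = mdd.contingency_table(frags, -2, 2)
        expected = np.zeros((5, 5))
        for frag in frags:
            a, b = frag.window[0], frag.window[4]
            ga = next(i for i, g in enumerate(GROUP_ORDER) if a in PROPERTY_GROUPS[g])
            gb = next(i for i, g in enumerate(GROUP_ORDER) if b in PROPERTY_GROUPS[g])
            expected[ga, gb] += 1
        assert np.array_equal(table.counts, expected)

    def test_same_position_rejected(self):
        with pytest.raises(ValueError):
            mdd.contingency_table([make_fragment("AAAKAAA")], 2, 2)


class TestChiSquare:
    def _table(self, counts):
        return mdd.ContingencyTable(np.asarray(counts, dtype=float), -1, 1)

    def test_uniform_table_is_zero(self):
        assert mdd.chi_square(self._table(np.full((5, 5), 3.0))) == pytest.approx(0.0)

    def test_two_group_diagonal(self):
        # Collapsed 2x2 with perfect association: 4 cells of (10-5)^2/5.
        counts = np.zeros((5, 5))
        counts[0, 0] = counts[1, 1] = 10
        assert mdd.chi_square(self._table(counts)) == pytest.approx(20.0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            counts = rng.integers(1, 25, size=(5, 5)).astype(float)
            ours = mdd.chi_square(self._table(counts))
            reference = chi2_contingency(counts, correction=False).statistic
            assert ours == pytest.approx(reference, abs=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mdd.chi_square(self._table(np.zeros((5, 5))))

    def test_degrees_of_freedom(self):
        assert self._table(np.ones((5, 5))).degrees_of_freedom == 16


class TestBestSplit:
    def test_recovers_planted_dependence(self, default_benchmark):
        """The chosen split maximizes S_i among eligible positions."""
        pos = default_benchmark["positives"]
        result = mdd.best_split(pos)
        assert result is not None
        position, group, chi2_value = result
        assert chi2_value > mdd.DEFAULT_CHI2_THRESHOLD
        # The planted motifs couple the basic downstream / acidic upstream
        # blocks, so the winner must be one of those positions.
        assert (position, group) in {
            (1, "basic"), (2, "basic"), (3, "basic"),
            (-1, "acidic"), (-2, "acidic"), (-3, "acidic"),
        }
        # Exhaustive oracle: recompute S_i for every offset.
        offsets = [o for o in range(-7, 8) if o != 0]
        s = {}
        eligible = set()
        for i in offsets:
            values = []
            for j in offsets:
                if i == j:
                    continue
                value = mdd.chi_square(mdd.contingency_table(pos, i, j))
                values.append(value)
                if value > mdd.DEFAULT_CHI2_THRESHOLD:
                    eligible.add(i)
            s[i] = sum(values)
        assert position in eligible
        assert s[position] == pytest.approx(max(s[i] for i in eligible))

    def test_null_fragments_not_split(self):
        assert mdd.best_split(_uniform_fragments(1000, seed=1)) is None

    def test_two_fragments_never_significant(self):
        frags = [make_fragment("KKKKKKK"), make_fragment("DDDKDDD")]
        assert mdd.best_split(frags) is None


class TestMddCluster:
    def test_large_max_cluster_size_single_leaf(self, default_benchmark):
        pos = default_benchmark["positives"]
        tree = mdd.mdd_cluster(pos, max_cluster_size=len(pos) + 1)
        assert len(tree.leaves()) == 1
        assert tree.leaves()[0].members == list(pos)

    def test_leaves_partition_input(self, default_benchmark):
        pos = default_benchmark["positives"]
        tree = mdd.mdd_cluster(pos, max_cluster_size=100)
        leaf_members = [f for leaf in tree.leaves() for f in leaf.members]
        assert sorted(leaf_members, key=id) == sorted(pos, key=id)
        assert len(leaf_members) == len(pos)

    def test_recovers_planted_partition(self, default_benchmark):
        pos = default_benchmark["positives"]
        truth = default_benchmark["truth"]
        tree = mdd.mdd_cluster(pos, max_cluster_size=100)
        correct = 0
        for leaf in tree.leaves():
            motifs = [truth[(f.protein_id, f.center)] for f in leaf.members]
            correct += max(motifs.count(m) for m in set(motifs))
        assert correct / len(pos) >= 0.95

    def test_deterministic(self, default_benchmark):
        pos = default_benchmark["positives"]
        a = mdd.mdd_cluster(pos, max_cluster_size=100)
        b = mdd.mdd_cluster(pos, max_cluster_size=100)
        assert a.to_dict() == b.to_dict()

    def test_internal_nodes_significant(self, default_benchmark):
        tree = mdd.mdd_cluster(default_benchmark["positives"], max_cluster_size=100)

        def walk(node):
            if isinstance(node, mdd.MddNode):
                assert node.chi2 >= tree.chi2_threshold
                walk(node.with_branch)
                walk(node.without_branch)

        walk(tree.root)


class TestAssignSubgroup:
    def test_training_fragments_route_to_their_leaf(self, default_benchmark):
        pos = default_benchmark["positives"]
        tree = mdd.mdd_cluster(pos, max_cluster_size=100)
        for leaf in tree.leaves():
            for frag in leaf.members[:10]:
                assert mdd.assign_subgroup(tree, frag) == leaf.id

    def test_all_pad_fragment_routes_without(self, default_benchmark):
        tree = mdd.mdd_cluster(default_benchmark["positives"], max_cluster_size=100)
        frag = make_fragment("-" * 7 + "K" + "-" * 7)
        leaf_id = mdd.assign_subgroup(tree, frag)
        assert leaf_id in {leaf.id for leaf in tree.leaves()}

    def test_json_roundtrip_preserves_routing(self, default_benchmark, tmp_path):
        import json

        pos = default_benchmark["positives"]
        tree = mdd.mdd_cluster(pos, max_cluster_size=100)
        tree.save_json(tmp_path / "tree.json")
        with open(tmp_path / "tree.json") as handle:
            rebuilt = mdd.MddTree.from_dict(json.load(handle))
        for frag in pos[::20]:
            assert mdd.assign_subgroup(rebuilt, frag) == mdd.assign_subgroup(tree, frag)


class TestSubgroupPfm:
    def test_identical_members(self):
        pfm = mdd.subgroup_pfm([make_fragment("AKA")] * 4)
        a_row = STANDARD_AA.index("A")
        k_row = STANDARD_AA.index("K")
        assert pfm[a_row, 0] == 1.0
        assert pfm[k_row, 1] == 1.0
        assert pfm[a_row, 2] == 1.0

    def test_columns_sum_to_one_and_match_hand_tally(self):
        members = [
            make_fragment("AKC"), make_fragment("AKD"), make_fragment("CKD"),
            make_fragment("XKD"), make_fragment("-KD", center=1),
        ]
        pfm = mdd.subgroup_pfm(members)
        assert np.allclose(pfm.sum(axis=0), 1.0)
        assert pfm[STANDARD_AA.index("A"), 0] == pytest.approx(2 / 5)
        assert pfm[20, 0] == pytest.approx(2 / 5)  # X and pad pooled
        assert pfm[STANDARD_AA.index("D"), 2] == pytest.approx(4 / 5)
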