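"""Supermatrix assembly, distances, neighbor joining, bootstrap, clade
assignment and tree-comparison utilities."""

import io as _io
import itertools

import numpy as np
import pytest
from skbio.tree import TreeNode
from skbio.tree import nj as skbio_nj
from skbio import DistanceMatrix as SkbioDM

from mtrscan.forge import random_tree, simulate_alignment
from mtrscan.phylo import (
    DistanceMatrix,
    Supermatrix,
    assign_groups,
    bootstrap_support,
    classify_mtrC_subfamily,
    concatenate,
    monophyly_fraction,
    nj_tree,
    nontrivial_bipartitions,
    protein_distance,
    rf_distance,
)


def _tree(nwk: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(nwk))


def _sm(rows: dict[str, str]) -> Supermatrix:
    leaves = sorted(rows)
    return Supermatrix(
        leaves=leaves,
        partitions=[("x", (0, len(next(iter(rows.values())))))],
        matrix=np.array([list(rows[l]) for l in leaves], dtype="<U1"),
    )


class TestConcatenate:
    def test_three_one_column_alignments(self):
        alignments = {g: {"s1": "A", "s2": "C"} for g in ("mtrA", "mtrB", "mtrC")}
        index = {"cl1": {g: "s1" for g in alignments}, "cl2": {g: "s2" for g in alignments}}
        sm = concatenate(alignments, index)
        assert sm.n_columns == 3
        assert sm.leaves == ["cl1", "cl2"]
        assert sm.row("cl1") == "AAA"

    def test_width_is_sum_of_partition_widths(self):
        rng = np.random.default_rng(0)
        widths = {"mtrA": 30, "mtrB": 20, "mtrC": 25}
        alignments = {
            g: {f"s{i}": "".join(rng.choice(list("ACDE"), w)) for i in range(10)}
            for g, w in widths.items()
        }
        index = {f"cl{i}": {g: f"s{i}" for g in widths} for i in range(10)}
        sm = concatenate(alignments, index)
        assert sm.matrix.shape == (10, 75)
        assert [gene for gene, _ in sm.partitions] == ["mtrA", "mtrB", "mtrC"]
        spans = [span for _, span in sm.partitions]
        assert spans == [(0, 30), (30, 50), (50, 75)]

    def test_cluster_missing_one_gene_excluded_with_warning(self):
        alignments = {
            "mtrA": {"a1": "AA"}, "mtrB": {"b1": "AA"}, "mtrC": {},
        }
        index = {"cl1": {"mtrA": "a1", "mtrB": "b1", "mtrC": "c1"}}
        with pytest.warns(UserWarning, match="missing genes"):
            sm = concatenate(alignments, index)
        assert sm.leaves == []

    def test_ragged_alignment_is_error(self):
        alignments = {"mtrA": {"a1": "AA", "a2": "AAA"}, "mtrB": {}, "mtrC": {}}
        with pytest.raises(ValueError, match="unequal row lengths"):
            concatenate(alignments, {})


class TestProteinDistance:
    def test_identical_rows_zero(self):
        dm = protein_distance(_sm({"a": "ACDE", "b": "ACDE"}), "p")
        assert dm.d[0, 1] == 0.0

    def test_hand_counted_p_distance(self):
        dm = protein_distance(_sm({"a": "ACDE", "b": "ACDF"}), "p")
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_gap_columns_excluded_from_comparison(self):
        dm = protein_distance(_sm({"a": "AC-E", "b": "ACDF"}), "p")
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_poisson_correction(self):
        dm = protein_distance(_sm({"a": "ACDE", "b": "ACDF"}), "poisson")
        assert dm.d[0, 1] == pytest.approx(-np.log(0.75))

    def test_all_gap_overlap_is_error(self):
        with pytest.raises(ValueError, match="no comparable columns"):
            protein_distance(_sm({"a": "A--", "b": "-CC"}), "p")

    def test_saturation_error_under_poisson(self):
        with pytest.raises(ValueError, match="saturated"):
            protein_distance(_sm({"a": "AAAA", "b": "CCCC"}), "poisson")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        # l_a = (3+4-5)/2 = 1, l_b = (3+5-4)/2 = 2, l_c = (4+5-3)/2 = 3
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_labels_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        truth = _tree("((a:1,b:2):1.5,(c:3,d:1):2,e:4);")
        dm = truth.tip_tip_distances()
        est = nj_tree(DistanceMatrix(list(dm.ids), dm.data))
        assert rf_distance(est, truth) == 0
        est_dm = est.tip_tip_distances()
        for i in dm.ids:
            for j in dm.ids:
                assert est_dm[i, j] == pytest.approx(dm[i, j], abs=1e-9)

    def test_label_permutation_gives_same_tree(self):
        truth = _tree("((a:1,b:2):1.5,(c:3,d:1):2,e:4);")
        dm = truth.tip_tip_distances()
        ids = list(dm.ids)
        est1 = nj_tree(DistanceMatrix(ids, dm.data))
        perm = [3, 1, 4, 0, 2]
        d2 = dm.data[np.ix_(perm, perm)]
        est2 = nj_tree(DistanceMatrix([ids[i] for i in perm], d2))
        assert rf_distance(est1, est2) == 0

    def test_agrees_with_skbio_nj_on_random_additive_matrices(self):
        for seed in range(5):
            nwk = random_tree(7, seed=seed)
            truth = _tree(nwk)
            dm = truth.tip_tip_distances()
            mine = nj_tree(DistanceMatrix(list(dm.ids), dm.data))
            theirs = skbio_nj(SkbioDM(dm.data, ids=list(dm.ids)))
            assert rf_distance(mine, theirs) == 0


class TestBipartitionsAndRF:
    def test_rf_of_tree_with_itself_is_zero(self):
        t = _tree("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        assert rf_distance(t, t) == 0

    def test_two_distinct_quartet_topologies_have_rf_2(self):
        topologies = [
            "((a:1,b:1):1,c:1,d:1);",
            "((a:1,c:1):1,b:1,d:1);",
            "((a:1,d:1):1,b:1,c:1);",
        ]
        for s1, s2 in itertools.combinations(topologies, 2):
            assert rf_distance(_tree(s1), _tree(s2)) == 2

    def test_caterpillar_vs_balanced_six_leaves_matches_brute_force(self):
        cat = _tree("(((((a:1,b:1):1,c:1):1,d:1):1,e:1):1,f:1);")
        bal = _tree("(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):1);")
        b1, b2 = nontrivial_bipartitions(cat), nontrivial_bipartitions(bal)
        assert rf_distance(cat, bal) == len(b1 ^ b2)
        # independent check against scikit-bio's unrooted RF
        assert rf_distance(cat, bal) == int(cat.compare_rfd(bal, rooted=False))

    def test_leaf_set_mismatch_error(self):
        with pytest.raises(ValueError, match="leaf sets"):
            rf_distance(_tree("(a:1,b:1,c:1);"), _tree("(a:1,b:1,d:1);"))


class TestMonophyly:
    def test_perfectly_sorted_tree_is_one(self):
        t = _tree("((a1:1,a2:1):1,(b1:1,b2:1):1,c:1);")
        taxa = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c": "C"}
        assert monophyly_fraction(t, taxa) == 1.0

    def test_one_split_label_of_two_gives_half(self):
        t = _tree("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        taxa = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert monophyly_fraction(t, taxa) == 0.0
        t2 = _tree("((a1:1,a2:1):1,(b1:1,c1:1):1,(b2:1,c2:1):1);")
        taxa2 = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
        assert monophyly_fraction(t2, taxa2) == pytest.approx(1 / 3)

    def test_all_singletons_undefined(self):
        t = _tree("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="undefined"):
            monophyly_fraction(t, {"a": "A", "b": "B", "c": "C"})

    def test_invariant_under_within_class_relabeling(self):
        t = _tree("((a1:1,a2:1):1,(b1:1,b2:1):1,c:1);")
        taxa = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c": "C"}
        swapped = {"a1": "A", "a2": "A", "b2": "B", "b1": "B", "c": "C"}
        assert monophyly_fraction(t, taxa) == monophyly_fraction(t, swapped)


class TestBootstrap:
    def _clean_split_sm(self, n_sites=300):
        # two 2-leaf blocks separated by many fixed differences
        left, right = "A" * n_sites, "C" * n_sites
        noise = {"a1": 0, "a2": 1, "b1": 0, "b2": 1}
        rows = {}
        rng = np.random.default_rng(4)
        for leaf, flip in noise.items():
            base = left if leaf.startswith("a") else right
            s = list(base)
            idx = rng.choice(n_sites, 5 + flip, replace=False)
            for i in idx:
                s[i] = "DEFG"[int(rng.integers(4))]
            rows[leaf] = "".join(s)
        return _sm(rows)

    def test_central_split_gets_full_support(self):
        tree = bootstrap_support(self._clean_split_sm(), n=25, seed=0, correction="p")
        supports = [n.support for n in tree.traverse(include_self=False)
                    if n.children and getattr(n, "support", None) is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        tree = bootstrap_support(self._clean_split_sm(), n=1, seed=3, correction="p")
        for node in tree.traverse(include_self=False):
            if node.children and getattr(node, "support", None) is not None:
                assert node.support in (0.0, 100.0)

    def test_same_seed_identical_supports(self):
        sm = self._clean_split_sm()
        t1 = bootstrap_support(sm, n=10, seed=5, correction="p")
        t2 = bootstrap_support(sm, n=10, seed=5, correction="p")
        assert str(t1) == str(t2)

    def test_point_topology_independent_of_seed(self):
        sm = self._clean_split_sm()
        t1 = bootstrap_support(sm, n=5, seed=1, correction="p")
        t2 = bootstrap_support(sm, n=5, seed=99, correction="p")
        assert rf_distance(t1, t2) == 0


class TestCladeAssignment:
    def _seven_clade_tree(self, per_clade=3):
        blocks = []
        for g in range(7):
            tips = ",".join(f"g{g}x{i}:0.05" for i in range(per_clade))
            blocks.append(f"({tips}):1.0")
        return _tree("(" + ",".join(blocks) + ");")

    def test_planted_clades_recovered_from_one_exemplar_each(self):
        t = self._seven_clade_tree()
        exemplars = {f"g{g}x0": str(g + 1) for g in range(7)}
        assignment = assign_groups(t, exemplars)
        for g in range(7):
            for i in range(3):
                assert assignment.groups[f"g{g}x{i}"] == str(g + 1)
        assert all(assignment.monophyletic.values())

    def test_equidistant_leaf_unassigned(self):
        t = _tree("((e1:1.0,e2:1.0):1.0,x:2.0);")
        assignment = assign_groups(t, {"e1": "1", "e2": "2"})
        assert assignment.groups["x"] == "unassigned"

    def test_missing_exemplar_error(self):
        t = _tree("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="absent from tree"):
            assign_groups(t, {"zz": "1"})

    def test_subfamily_classification_recovers_planted_clades(self):
        subs = ["MtrC", "MtrF", "OmcA", "UndA", "MtrG", "MtrH"]
        blocks = [
            f"({sub}ref:0.05,{sub}q1:0.05,{sub}q2:0.05):1.0" for sub in subs
        ]
        t = _tree("(" + ",".join(blocks) + ");")
        refs = {f"{sub}ref": sub for sub in subs}
        assignment, mono = classify_mtrC_subfamily(t, refs)
        for sub in subs:
            assert assignment[f"{sub}q1"] == sub and assignment[f"{sub}q2"] == sub
            assert mono[sub]

    def test_sister_subfamilies_both_monophyletic(self):
        # MtrF sister clade to MtrC
        t = _tree(
            "(((MtrCref:0.1,MtrCq:0.1):0.5,(MtrFref:0.1,MtrFq:0.1):0.5):1.0,"
            "(OmcAref:0.1,UndAref:0.1):1.0,(MtrGref:0.1,MtrHref:0.1):1.0);"
        )
        refs = {f"{s}ref": s for s in ["MtrC", "MtrF", "OmcA", "UndA", "MtrG", "MtrH"]}
        assignment, mono = classify_mtrC_subfamily(t, refs)
        assert assignment["MtrCq"] == "MtrC" and assignment["MtrFq"] == "MtrF"
        assert mono["MtrC"] and mono["MtrF"]

    def test_missing_subfamily_reference_error(self):
        t = _tree("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="MtrH"):
            classify_mtrC_subfamily(t, {"a": "MtrC", "b": "MtrF", "c": "OmcA"})


class TestTopologyRecovery:
    def test_simulated_alignment_recovers_five_leaf_tree(self):
        nwk = random_tree(5, seed=12)
        truth = _tree(nwk)
        aln = simulate_alignment(nwk, 10000, subst_rate=1.0, seed=99)
        sm = _sm(aln)
        est = nj_tree(protein_distance(sm, "poisson"))
        assert rf_distance(est, truth) == 0
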