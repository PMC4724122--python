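"""Distances, corrections, NJ/UPGMA, tree surgery, Newick, bootstrap."""

import math

import numpy as np
import pytest

from alnkit.fixtures import planted_msa, random_tree_and_matrix
from alnkit.msa_io import MultipleAlignment
from alnkit.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap,
    corrected_distance,
    distance_matrix,
    export_distance_matrix,
    fractional_difference,
    from_newick,
    import_distance_matrix,
    nj_tree,
    reroot,
    robinson_foulds,
    scoredist,
    swap_children,
    to_newick,
    upgma_tree,
)


def matrices_match(t1, t2, atol=1e-9):
    m1, m2 = t1.path_length_matrix(), t2.path_length_matrix()
    idx = [m2.labels.index(l) for l in m1.labels]
    return np.allclose(m1.d, m2.d[np.ix_(idx, idx)], atol=atol)


class TestFractionalDifference:
    def test_examples(self):
        assert fractional_difference("AAAA", "AAAA") == 0.0
        assert fractional_difference("AAAA", "AAAC") == 0.25

    def test_intersection_rule(self):
        # shared non-gap columns are positions 1 and 2 only
        assert fractional_difference("A-AA", "AAA-") == 0.0
        assert fractional_difference("A-CA", "AAA-") == 0.5

    def test_no_shared_columns_error(self):
        with pytest.raises(ValueError, match="shared"):
            fractional_difference("A--", "-AA")


class TestCorrections:
    @pytest.mark.parametrize(
        "method", ["uncorrected", "jukes_cantor", "kimura", "scoredist"]
    )
    def test_identical_rows_give_zero(self, method):
        assert corrected_distance("ACDEFGHIKL", "ACDEFGHIKL", method) == 0.0

    def test_jukes_cantor_protein_closed_form(self):
        # 3 mismatches in 10 columns: p = 0.3
        d = corrected_distance("A" * 10, "A" * 7 + "C" * 3, "jukes_cantor")
        expected = -(19 / 20) * math.log(1 - (20 / 19) * 0.3)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == pytest.approx(0.3605, abs=5e-5)

    def test_jukes_cantor_nucleotide_alphabet_size(self):
        d = corrected_distance(
            "A" * 10, "A" * 7 + "C" * 3, "jukes_cantor", kind="nucleotide"
        )
        assert d == pytest.approx(-(3 / 4) * math.log(1 - (4 / 3) * 0.3), abs=1e-12)

    def test_kimura_closed_form(self):
        d = corrected_distance("A" * 10, "A" * 7 + "C" * 3, "kimura")
        assert d == pytest.approx(-math.log(1 - 0.3 - 0.2 * 0.09), abs=1e-12)
        assert d == pytest.approx(0.38273, abs=5e-5)

    @pytest.mark.parametrize("method", ["jukes_cantor", "kimura"])
    def test_monotone_in_p_and_zero_at_zero(self, method):
        n = 20
        prev = -1.0
        for k in range(0, 13):
            a = "A" * n
            b = "A" * (n - k) + "C" * k
            d = corrected_distance(a, b, method)
            assert d > prev or (k == 0 and d == 0.0)
            prev = d
        assert corrected_distance("A" * n, "A" * n, method) == 0.0

    def test_saturation_capped(self):
        d = corrected_distance("A" * 10, "C" * 10, "kimura", cap=7.5)
        assert d == 7.5

    def test_storm_sonnhammer_not_implemented(self):
        with pytest.raises(NotImplementedError):
            corrected_distance("AC", "AC", "storm_sonnhammer")

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            corrected_distance("AC", "AC", "nope")


class TestScoredist:
    def test_self_distance_zero_and_symmetric(self):
        a = "MKVLAWCDEFGHIKNNQRST"
        b = "MKVLAYCDEFGHWKNNQRSA"
        assert scoredist(a, a) == 0.0
        assert scoredist(a, b) == pytest.approx(scoredist(b, a), abs=1e-12)
        assert scoredist(a, b) > 0.0

    def test_more_divergent_pairs_score_larger(self):
        a = "MKVLAWCDEFGHIKNNQRST"
        close = "MKVLAWCDEFGHIKNNQRSA"
        far = "MKVLAYCDWFGHWKNNARSA"
        assert scoredist(a, close) < scoredist(a, far)

    def test_unrelated_rows_capped(self):
        assert scoredist("W" * 8, "P" * 8, cap=10.0) == 10.0


class TestTreeConstruction:
    def test_nj_two_leaves(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert to_newick(nj_tree(dm)) == "(A:1,B:1);"

    def test_nj_three_leaf_linear_system(self):
        dm = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        assert to_newick(nj_tree(dm)) == "(A:1,B:1,C:3);"

    def test_upgma_two_leaves(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert to_newick(upgma_tree(dm)) == "(A:1,B:1);"

    @pytest.mark.parametrize("seed", range(15))
    def test_nj_exact_on_additive_matrices(self, seed):
        tree, dm = random_tree_and_matrix(6 + seed % 3, seed)
        rec = nj_tree(dm)
        assert robinson_foulds(tree, rec) == 0
        assert matrices_match(tree, rec)

    @pytest.mark.parametrize("seed", range(15))
    def test_upgma_exact_on_ultrametric_matrices(self, seed):
        tree, dm = random_tree_and_matrix(6 + seed % 3, seed, ultrametric=True)
        rec = upgma_tree(dm)
        assert robinson_foulds(tree, rec) == 0
        assert matrices_match(tree, rec)

    @pytest.mark.parametrize("seed", range(8))
    def test_upgma_output_always_ultrametric(self, seed):
        # even on non-ultrametric input, all root-to-leaf depths are equal
        _, dm = random_tree_and_matrix(7, seed, ultrametric=False)
        tree = upgma_tree(dm)

        def depths(node, acc):
            if node.is_leaf:
                return [acc]
            out = []
            for c in node.children:
                out.extend(depths(c, acc + c.length))
            return out

        ds = depths(tree, 0.0)
        assert max(ds) - min(ds) < 1e-9

    def test_distance_matrix_matches_pairwise_loop(self):
        aln, _ = planted_msa(5, 30, seed=7)
        dm = distance_matrix(aln, "kimura")
        for i in range(5):
            for j in range(5):
                expected = (
                    0.0
                    if i == j
                    else corrected_distance(
                        aln.rows[i].residues, aln.rows[j].residues, "kimura"
                    )
                )
                assert dm.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identical_rows_zero_matrix(self):
        aln = MultipleAlignment.from_rows([("a", "ACDE"), ("b", "ACDE")])
        dm = distance_matrix(aln, "uncorrected")
        assert (dm.d == 0).all()


class TestTreeSurgery:
    def test_reroot_preserves_path_lengths(self):
        for seed in range(5):
            tree, _ = random_tree_and_matrix(6, seed)
            for leaf in tree.leaf_names():
                assert matrices_match(tree, reroot(tree, leaf))

    def test_reroot_at_leaf_makes_leaf_root_child(self):
        tree, _ = random_tree_and_matrix(6, 1)
        r = reroot(tree, "t2")
        assert any(c.is_leaf and c.label == "t2" for c in r.children)

    def test_reroot_then_back_is_metric_identity(self):
        tree, _ = random_tree_and_matrix(7, 2)
        once = reroot(tree, "t4")
        again = reroot(once, "t1")
        assert matrices_match(tree, again)

    def test_reroot_at_root_is_identity(self):
        tree, _ = random_tree_and_matrix(5, 0)
        assert to_newick(reroot(tree, tree)) == to_newick(tree)

    def _internal_path(self, tree):
        for path in [(0,), (1,), (2,), (0, 0), (0, 1), (1, 0), (1, 1)]:
            node = tree
            try:
                for i in path:
                    node = node.children[i]
            except IndexError:
                continue
            if not node.is_leaf:
                return path
        raise AssertionError("no internal node found")

    def test_swap_is_involution_and_metric_preserving(self):
        tree, _ = random_tree_and_matrix(6, 5)
        path = self._internal_path(tree)
        once = swap_children(tree, path)
        assert to_newick(once) != to_newick(tree)
        assert to_newick(swap_children(once, path)) == to_newick(tree)
        assert matrices_match(tree, once)

    def test_swap_reverses_leaf_order_within_clade(self):
        tree = from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        out = swap_children(tree, (0,))
        assert out.leaf_names() == ["b", "a", "c", "d"]

    def test_swap_leaf_rejected(self):
        tree = from_newick("(a:1,b:1);")
        with pytest.raises(ValueError):
            swap_children(tree, "a")


class TestNewick:
    def test_round_trip_topology_lengths_supports(self):
        text = "((a:0.1,b:0.2)87:0.5,(c:0.3,d:0.4)55:0.6);"
        tree = from_newick(text)
        assert to_newick(tree) == text
        assert tree.children[0].support == 87

    def test_support_rendering(self):
        tree = from_newick("((a:1,b:1):0.5,c:1);")
        tree.children[0].support = 87.0
        assert ")87:0.5" in to_newick(tree)

    def test_random_tree_round_trips(self):
        for seed in range(5):
            tree, _ = random_tree_and_matrix(7, seed)
            text = to_newick(tree)
            assert to_newick(from_newick(text)) == text

    def test_dendropy_reads_our_newick(self):
        dendropy = pytest.importorskip("dendropy")
        tree, dm = random_tree_and_matrix(6, 8)
        dt = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        dm.d[i, j], abs=1e-6
                    )

    def test_parse_error_reports_position(self):
        with pytest.raises(ValueError, match="position"):
            from_newick("((a:1,b:1;")


class TestMatrixIO:
    def test_round_trip_identity(self):
        _, dm = random_tree_and_matrix(6, 3)
        dm2 = import_distance_matrix(export_distance_matrix(dm))
        assert dm2.labels == dm.labels
        assert np.allclose(dm2.d, dm.d, atol=1e-9)

    def test_reconstructed_tree_equals_original(self):
        _, dm = random_tree_and_matrix(7, 6)
        t1 = nj_tree(dm)
        t2 = nj_tree(import_distance_matrix(export_distance_matrix(dm)))
        assert to_newick(t1) == to_newick(t2)

    def test_whitespace_variants_parse_identically(self):
        _, dm = random_tree_and_matrix(4, 1)
        text = export_distance_matrix(dm)
        spaced = "\n".join("   ".join(l.split("\t")) for l in text.splitlines())
        dm2 = import_distance_matrix(spaced)
        assert np.allclose(dm2.d, dm.d)

    def test_asymmetric_input_rejected(self):
        text = "a\tb\na\t0\t1\nb\t2\t0\n"
        with pytest.raises(ValueError):
            import_distance_matrix(text)


def two_clade_alignment():
    rows = [(f"a{i}", "AAAAAAAAAACCCCCWWWWW") for i in range(3)]
    rows += [(f"b{i}", "WWWWWWWWWWGGGGGAAAAA") for i in range(3)]
    return MultipleAlignment.from_rows(rows)


class TestBootstrap:
    def test_fixed_seed_bit_identical(self):
        aln = two_clade_alignment()
        t1, a1 = bootstrap(aln, 20, seed=7)
        t2, a2 = bootstrap(aln, 20, seed=7)
        assert [to_newick(t) for t in t1] == [to_newick(t) for t in t2]
        assert to_newick(a1) == to_newick(a2)

    def test_two_clade_alignment_has_full_support(self):
        aln = two_clade_alignment()
        _, annotated = bootstrap(aln, 50, seed=1)
        split = frozenset(
            (frozenset(("a0", "a1", "a2")), frozenset(("b0", "b1", "b2")))
        )
        supports = [
            n.support for n in annotated.walk() if n.support is not None
        ]
        assert supports and all(s == 100.0 for s in supports)
        assert split in bipartitions(annotated)

    def test_single_replicate_supports_binary(self):
        aln = two_clade_alignment()
        _, annotated = bootstrap(aln, 1, seed=3)
        for n in annotated.walk():
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_supports_bounded(self):
        aln, _ = planted_msa(6, 30, seed=13)
        _, annotated = bootstrap(aln, 10, seed=5)
        for n in annotated.walk():
            if n.support is not None:
                assert 0.0 <= n.support <= 100.0
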