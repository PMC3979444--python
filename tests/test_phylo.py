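"""p-distance, neighbor joining, bootstrap, group delineation, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peroxevol.phylo import (
    DistanceMatrix,
    Msa,
    PhyloError,
    align_progressive,
    bootstrap_support,
    count_informative,
    delineate_groups,
    nj_tree,
    pdistance,
    species_monophyly_index,
)
from peroxevol.seqcore import ProteinRecord

from conftest import four_point_additive, tree_path_distances


class TestPdistance:
    def test_single_mismatch_in_five(self):
        dm = pdistance(Msa({"a": "ACDEF", "b": "ACDFF"}))
        assert dm.get("a", "b") == pytest.approx(0.2)
        assert dm.v[0, 1] == 5

    def test_gap_column_excluded(self):
        dm = pdistance(Msa({"a": "ACD-F", "b": "ACDEF"}))
        assert dm.get("a", "b") == 0.0
        assert dm.v[0, 1] == 4

    def test_identity_and_symmetry(self):
        dm = pdistance(Msa({"a": "ACDEF", "b": "AWDEF", "c": "ACDEF"}))
        assert np.allclose(np.diag(dm.d), 0)
        assert np.allclose(dm.d, dm.d.T)
        assert dm.get("a", "c") == 0.0

    def test_all_gap_pair_errors(self):
        with pytest.raises(PhyloError, match="a.*b|b.*a"):
            pdistance(Msa({"a": "AC---", "b": "---EF", "c": "ACDEF"}))

    def test_x_treated_as_missing(self):
        dm = pdistance(Msa({"a": "AXDEF", "b": "ACDEF"}))
        assert dm.v[0, 1] == 4 and dm.get("a", "b") == 0.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]])
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        lengths = {n.name: n.length for n in tree.leaves}
        assert lengths == pytest.approx({"A": 0.1, "B": 0.1, "C": 0.3})

    def test_four_taxon_additive_matrix_recovered(self):
        ids = ["A", "B", "C", "D"]
        vals = {("A", "B"): 3, ("C", "D"): 7, ("A", "C"): 5,
                ("A", "D"): 6, ("B", "C"): 6, ("B", "D"): 7}
        d = np.zeros((4, 4))
        for (a, b), v in vals.items():
            i, j = ids.index(a), ids.index(b)
            d[i, j] = d[j, i] = v
        assert four_point_additive(d)
        tree = nj_tree(DistanceMatrix(ids, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        rec = tree_path_distances(tree)
        for (a, b), v in vals.items():
            assert rec.get(a, b) == pytest.approx(v, abs=1e-12)

    def test_additive_fixture_set_recovered_exactly(self, additive_fixture_set):
        """NJ reproduces every additive 4-6 taxon matrix: topology and all
        path lengths to 1e-9 (four-point condition verified on each input)."""
        for true_tree, dm in additive_fixture_set:
            assert four_point_additive(dm.d)
            est = nj_tree(dm)
            assert est.bipartitions() == true_tree.bipartitions()
            rec = tree_path_distances(est)
            assert np.max(np.abs(rec.d - dm.d)) < 1e-9

    def test_star_matrix_all_internal_branches_zero(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0)
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        internal = [n for n in tree.postorder()
                    if not n.is_leaf and n is not tree.root]
        assert all(abs(n.length) < 1e-12 for n in internal)

    def test_leaf_set_preserved_and_nonnegative_lengths(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.1, 0.9, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(6)]
        tree = nj_tree(DistanceMatrix(ids, d))
        assert tree.leaf_names == frozenset(ids)
        assert all((n.length or 0) >= 0 for n in tree.postorder()
                   if n is not tree.root)

    def test_agrees_with_dendropy_nj_on_random_matrices(self):
        """Independent-library cross-check: same topologies as dendropy's
        neighbor joining on generic (non-additive) distance matrices."""
        import dendropy

        rng = np.random.default_rng(11)
        for trial in range(5):
            n = int(rng.integers(4, 7))
            ids = [f"s{i}" for i in range(n)]
            d = rng.uniform(0.05, 0.9, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            ours = nj_tree(DistanceMatrix(ids, d))

            csv = "," + ",".join(ids) + "\n" + "\n".join(
                ids[i] + "," + ",".join(f"{d[i, j]:.10f}" for j in range(n))
                for i in range(n)
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=__import__("io").StringIO(csv)
            )
            theirs = pdm.nj_tree()
            theirs_bips = set()
            all_names = frozenset(ids)
            ref = min(ids)
            for edge in theirs.preorder_edge_iter():
                node = edge.head_node
                side = frozenset(
                    lf.taxon.label for lf in node.leaf_iter()
                )
                if ref in side:
                    side = all_names - side
                if 2 <= len(side) <= n - 2:
                    theirs_bips.add(side)
            assert ours.bipartitions() == theirs_bips, f"trial {trial}"

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0, 2], [1.1, 0, 1], [2, 1, 0.0]])
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(list("ABC"), d))


def two_clade_msa():
    return Msa({
        "a1": "AAAAAAAAKLMNPQRS",
        "a2": "AAAAAAAAKLMNPQRS",
        "b1": "CCCCCCCCKLMNPQRS",
        "b2": "CCCCCCCCKLMNPQRS",
    })


class TestBootstrap:
    def test_identical_clades_get_full_support(self):
        tree = bootstrap_support(two_clade_msa(), n_reps=100, seed=1)
        (bp,) = tree.bipartitions()
        node = tree.bipartition_nodes()[bp]
        assert node.support == 100.0

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(two_clade_msa(), n_reps=1, seed=2)
        sups = [n.support for n in tree.postorder() if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_fixed_seed_reproducible(self, toy_msa):
        t1 = bootstrap_support(toy_msa, n_reps=50, seed=9)
        t2 = bootstrap_support(toy_msa, n_reps=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(perm=st.permutations(range(5)))
    def test_support_invariant_to_leaf_order(self, perm):
        base = Msa({
            "a1": "ACDEFGHIKL", "a2": "ACDEFGHIKL", "b1": "ACDEWGHIKV",
            "b2": "ACDEWGHIKV", "c1": "MCDEWGHLKV",
        })
        ids = base.ids
        shuffled = Msa({ids[i]: base.rows[ids[i]] for i in perm})
        t1 = bootstrap_support(base, n_reps=30, seed=4)
        t2 = bootstrap_support(shuffled, n_reps=30, seed=4)
        sup1 = {bp: t1.bipartition_nodes()[bp].support
                for bp in t1.bipartitions()}
        sup2 = {bp: t2.bipartition_nodes()[bp].support
                for bp in t2.bipartitions()}
        assert sup1 == sup2


class TestInformativeSites:
    @pytest.mark.parametrize("col,informative", [
        ("AATT", True),
        ("AAAT", False),
        ("----", False),
        ("AACC", True),
        ("ACGT", False),
    ])
    def test_definition(self, col, informative):
        msa = Msa({f"s{i}": ch for i, ch in enumerate(col)})
        n_col, n_inf = count_informative(msa)
        assert n_col == 1 and n_inf == int(informative)

    def test_all_gap_column_counts_toward_total(self):
        msa = Msa({"a": "AA-", "b": "AA-", "c": "AT-", "d": "AT-"})
        assert count_informative(msa) == (3, 1)


def supported_tree(newick):
    from peroxevol.phylo import Tree

    return Tree.from_newick(newick)


class TestGroupDelineation:
    def test_pure_clade_above_strong_is_a_group(self):
        tree = supported_tree(
            "((m1:1,m2:1,m3:1,m4:1,m5:1)99:1,l1:1,l2:1);"
        )
        calls = {f"m{i}": "MnP" for i in range(1, 6)} | {"l1": "LiP", "l2": "LiP"}
        orders = {k: "Polyporales" for k in calls}
        ga = delineate_groups(tree, calls, orders)
        assert ga.groups == {"MnP": [f"m{i}" for i in range(1, 6)]}
        assert sorted(ga.separate) == ["l1", "l2"]

    def test_low_support_pair_reported_separate(self):
        tree = supported_tree("((a:1,b:1)45:1,c:1,d:1);")
        calls = {k: "MnP" for k in "abcd"}
        orders = {k: "Polyporales" for k in "abcd"}
        ga = delineate_groups(tree, calls, orders)
        assert not ga.groups and set(ga.separate) == set("abcd")

    def test_mixed_order_clade_split_into_pure_subclades(self):
        tree = supported_tree(
            "(((p1:1,p2:1)95:1,(r1:1,r2:1)97:1)99:1,x1:1,x2:1);"
        )
        calls = {k: "MnP" for k in ["p1", "p2", "r1", "r2", "x1", "x2"]}
        orders = {"p1": "Polyporales", "p2": "Polyporales",
                  "r1": "Russulales", "r2": "Russulales",
                  "x1": "Agaricales", "x2": "Agaricales"}
        ga = delineate_groups(tree, calls, orders)
        assert sorted(ga.groups) == ["MnP I", "MnP II"]
        members = sorted(map(tuple, ga.groups.values()))
        assert members == [("p1", "p2"), ("r1", "r2")]

    def test_member_threshold_needs_one_strong_method(self):
        tree = supported_tree("((a:1,b:1,c:1)85:1,d:1,e:1);")
        calls = {k: "VP" for k in "abcde"}
        orders = {k: "Agaricales" for k in "abcde"}
        # 85 alone: above member but no method above strong
        ga = delineate_groups(tree, calls, orders)
        assert not ga.groups
        # an external method calling it 95 makes it a group
        bp = frozenset({"d", "e"})  # canonical side excludes min leaf 'a'
        ga2 = delineate_groups(tree, calls, orders,
                               extra_supports={"ML": {bp: 95.0}})
        assert list(ga2.groups) == ["VP"]

    def test_type_set_naming(self):
        tree = supported_tree("((a:1,b:1)99:1,(c:1,d:1)99:1,e:1);")
        calls = {"a": "MnP", "b": "VP", "c": "LiP", "d": "VP", "e": "CII"}
        orders = {k: "Agaricales" for k in "abcde"}
        ga = delineate_groups(tree, calls, orders)
        assert sorted(ga.groups) == ["LiP and VP", "MnP and VP"]

    def test_outgroup_excluded(self):
        tree = supported_tree("((a:1,b:1)99:1,(o1:1,o2:1)99:1,c:1);")
        calls = {"a": "MnP", "b": "MnP", "c": "CII", "o1": "CcP", "o2": "CcP"}
        orders = {k: "Polyporales" for k in calls}
        ga = delineate_groups(tree, calls, orders, exclude=["o1", "o2"])
        assert list(ga.groups) == ["MnP"]
        assert "o1" not in ga.separate


class TestMonophylyIndex:
    def test_cherries_give_one(self):
        tree = supported_tree("(((s1a:1,s1b:1):1,(s2a:1,s2b:1):1):1,x:1,y:1);")
        species = {"s1a": "S1", "s1b": "S1", "s2a": "S2", "s2b": "S2"}
        group = ["s1a", "s1b", "s2a", "s2b"]
        assert species_monophyly_index(tree, species, group) == 1.0

    def test_interleaved_copies_give_zero(self):
        tree = supported_tree("(((s1a:1,s2a:1):1,(s1b:1,s2b:1):1):1,x:1,y:1);")
        species = {"s1a": "S1", "s1b": "S1", "s2a": "S2", "s2b": "S2"}
        group = ["s1a", "s1b", "s2a", "s2b"]
        assert species_monophyly_index(tree, species, group) == 0.0

    def test_no_multicopy_species_is_na(self):
        tree = supported_tree("((a:1,b:1):1,x:1,y:1);")
        species = {"a": "S1", "b": "S2"}
        assert species_monophyly_index(tree, species, ["a", "b"]) is None


class TestProgressiveAlignment:
    def test_identical_sequences_align_gap_free(self):
        recs = [ProteinRecord("a", "MKWVLE"), ProteinRecord("b", "MKWVLE")]
        msa = align_progressive(recs)
        assert msa.n_col == 6 and "-" not in "".join(msa.rows.values())

    def test_single_deletion_gets_one_gap_column(self):
        msa = align_progressive(
            [ProteinRecord("a", "ACDE"), ProteinRecord("b", "ACE")]
        )
        assert msa.n_col == 4
        assert sum(ch == "-" for ch in msa.rows["b"]) == 1

    def test_pairwise_score_matches_exhaustive_search(self):
        """The aligner attains the optimum over all global alignments of a
        small pair (brute-force affine-gap enumeration oracle)."""
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        gap_open, gap_extend = 10.0, 0.2

        def alignment_score(ra, rb):
            score = 0.0
            for run_seq in (ra, rb):
                in_gap = False
                for ch in run_seq:
                    if ch == "-":
                        score -= gap_extend if in_gap else gap_open
                        in_gap = True
                    else:
                        in_gap = False
            for x, y in zip(ra, rb):
                if x != "-" and y != "-":
                    score += mat[x, y]
            return score

        def all_alignments(a, b):
            if not a and not b:
                yield "", ""
                return
            if a and b:
                for ra, rb in all_alignments(a[1:], b[1:]):
                    yield a[0] + ra, b[0] + rb
            if a:
                for ra, rb in all_alignments(a[1:], b):
                    yield a[0] + ra, "-" + rb
            if b:
                for ra, rb in all_alignments(a, b[1:]):
                    yield "-" + ra, b[0] + rb

        a, b = "WCDE", "WDE"
        best = max(alignment_score(ra, rb) for ra, rb in all_alignments(a, b))
        msa = align_progressive(
            [ProteinRecord("a", a), ProteinRecord("b", b)]
        )
        got = alignment_score(msa.rows["a"], msa.rows["b"])
        assert got == pytest.approx(best)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seqs=st.lists(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=12),
        min_size=2, max_size=4, unique=True,
    ))
    def test_degapping_recovers_inputs(self, seqs):
        recs = [ProteinRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        msa = align_progressive(recs)
        for rec in recs:
            assert msa.ungapped(rec.id) == rec.residues

    def test_empty_sequence_rejected(self):
        with pytest.raises(PhyloError):
            align_progressive([ProteinRecord("a", "MK"), ProteinRecord("b", "")])
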