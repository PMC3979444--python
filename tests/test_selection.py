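"""GY94 codon machinery, pruning likelihoods, LRTs, NEB, decision rule."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from peroxevol.phylo import Msa, Tree
from peroxevol.selection import (
    CODONS,
    N_CODONS,
    CodonAlignment,
    CodonModelSpec,
    SelectionError,
    build_codon_alignment,
    class_matrices,
    class_structure,
    fit_model,
    gy94_Q,
    lrt,
    lrt_from_stat,
    neb_sites,
    positive_selection_decision,
    site_loglik,
    transition_matrix_factory,
)
from peroxevol.syndata import sim_codon_alignment, sim_tree

UNIFORM = np.full(N_CODONS, 1.0 / N_CODONS)


def brute_force_loglik(aln, tree, Qs, probs, pi):
    """Independent oracle: per-site likelihood by explicit summation over
    all internal-node state assignments, transition matrices via expm."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    row = {sid: r for r, sid in enumerate(aln.ids)}
    total = 0.0
    for h in range(aln.L):
        site = 0.0
        for k, Q in enumerate(Qs):
            P = {
                id(n): expm(Q * (n.length or 0.0))
                for n in tree.postorder() if n is not tree.root
            }
            like = 0.0
            for assign in itertools.product(range(N_CODONS),
                                            repeat=len(internals)):
                st = {id(n): a for n, a in zip(internals, assign)}
                for leaf in tree.leaves:
                    st[id(leaf)] = aln.codons[row[leaf.name], h]
                p = pi[st[id(tree.root)]]
                for n in tree.postorder():
                    if n is tree.root:
                        continue
                    p *= P[id(n)][st[id(n.parent)], st[id(n)]]
                like += p
            site += probs[k] * like
        total += np.log(site)
    return total


class TestGeneratorMatrix:
    def test_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(N_CODONS))
        Q = gy94_Q(2.5, 0.7, pi)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        from peroxevol.selection import CODON_AA

        Q = gy94_Q(2.0, 0.0, UNIFORM)
        for i in range(N_CODONS):
            for j in range(N_CODONS):
                if i != j and CODON_AA[i] != CODON_AA[j]:
                    assert Q[i, j] == 0.0

    def test_neutral_symmetric_case_has_equal_offdiagonals(self):
        Q = gy94_Q(1.0, 1.0, UNIFORM)
        off = Q[(Q > 0)]
        assert np.allclose(off, off[0])

    def test_rows_sum_to_zero_and_scaled_rate_one(self):
        Q = gy94_Q(3.0, 0.2, UNIFORM)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert -UNIFORM @ np.diag(Q) == pytest.approx(1.0)

    def test_transition_probabilities_stochastic_and_stationary(self):
        Q = gy94_Q(2.0, 0.5, UNIFORM)
        P = transition_matrix_factory(Q, UNIFORM)
        for t in (0.0, 0.1, 2.0, 50.0):
            M = P(t)
            assert np.allclose(M.sum(axis=1), 1, atol=1e-9)
            assert np.all(M >= 0)
        assert np.allclose(UNIFORM @ P(1.0), UNIFORM, atol=1e-12)

    def test_mixture_scaling_is_joint(self):
        omegas, probs = np.array([0.1, 2.0]), np.array([0.5, 0.5])
        Qs = class_matrices(2.0, omegas, probs, UNIFORM)
        rate = sum(p * -(UNIFORM @ np.diag(Q)) for p, Q in zip(probs, Qs))
        assert rate == pytest.approx(1.0)


class TestCodonAlignment:
    def test_gap_expansion_from_protein_msa(self):
        msa = Msa({"a": "M-A", "b": "MKA"})
        cds = {"a": "ATGGCT", "b": "ATGAAAGCTTAA"}
        aln = build_codon_alignment(msa, cds, drop_gapped=False)
        strings = aln.to_strings()
        assert strings["a"] == "ATG---GCT"
        assert aln.meta["dropped_gapped_sites"] == 0

    def test_cleandata_drops_gapped_codon_columns(self):
        msa = Msa({"a": "M-A", "b": "MKA"})
        cds = {"a": "ATGGCT", "b": "ATGAAAGCT"}
        aln = build_codon_alignment(msa, cds)
        assert aln.L == 2 and aln.meta["dropped_gapped_sites"] == 1

    def test_translation_mismatch_names_id_and_position(self):
        msa = Msa({"a": "MV"})
        with pytest.raises(SelectionError, match="'a'.*residue 2"):
            build_codon_alignment(msa, {"a": "ATGGCT"})

    def test_signal_peptide_prefix_tolerated(self):
        # CDS encodes MKMA; aligned mature row is MA
        msa = Msa({"a": "MA", "b": "MA"})
        cds = {"a": "ATGAAAATGGCT", "b": "ATGGCT"}
        aln = build_codon_alignment(msa, cds)
        assert aln.to_strings()["a"] == "ATGGCT"

    def test_stop_codons_rejected(self):
        with pytest.raises(SelectionError, match="stop"):
            CodonAlignment.from_strings({"a": "ATGTAA", "b": "ATGAAA"})


class TestPruningOracle:
    def test_four_taxon_matches_enumeration(self):
        """Pruning equals brute-force summation over all 61^2 internal
        assignments (expm oracle) on a 4-taxon, 3-site alignment."""
        tree = sim_tree(3, 4, 0.2)
        aln, _ = sim_codon_alignment(
            tree, "M0", {"kappa": 2.0, "omega": 0.5}, L=3, seed=5
        )
        spec = CodonModelSpec("M3")
        params = {"kappa": 2.0, "probs": [0.6, 0.4], "omegas": [0.2, 1.5]}
        lnl, _, omegas, probs = site_loglik(aln, tree, spec, params, pi=UNIFORM)
        Qs = class_matrices(2.0, omegas, probs, UNIFORM)
        oracle = brute_force_loglik(aln, tree, Qs, probs, UNIFORM)
        assert lnl == pytest.approx(oracle, abs=1e-8)

    def test_short_branch_pair_limit_is_pi(self):
        """For two identical one-codon sequences at t -> 0 the site
        likelihood tends to the codon's equilibrium frequency."""
        tree = Tree.from_newick("(a:1e-9,b:1e-9);")
        aln = CodonAlignment.from_strings({"a": "ATG", "b": "ATG"})
        lnl, _, _, _ = site_loglik(
            aln, tree, CodonModelSpec("M0"),
            {"kappa": 2.0, "omega": 0.5}, pi=UNIFORM,
        )
        assert lnl == pytest.approx(np.log(UNIFORM[CODONS.index("ATG")]),
                                    abs=1e-6)

    def test_duplicated_site_doubles_contribution(self):
        tree = sim_tree(4, 5, 0.2)
        aln, _ = sim_codon_alignment(
            tree, "M0", {"kappa": 2.0, "omega": 0.4}, L=1, seed=8
        )
        doubled = CodonAlignment(
            aln.ids, np.concatenate([aln.codons, aln.codons], axis=1)
        )
        args = (CodonModelSpec("M0"), {"kappa": 2.0, "omega": 0.4})
        l1 = site_loglik(aln, tree, *args, pi=UNIFORM)[0]
        l2 = site_loglik(doubled, tree, *args, pi=UNIFORM)[0]
        assert l2 == pytest.approx(2 * l1, abs=1e-9)

    def test_leaf_mismatch_rejected(self):
        tree = Tree.from_newick("(a:0.1,b:0.1,c:0.1);")
        aln = CodonAlignment.from_strings(
            {"a": "ATG", "b": "ATG", "x": "ATG"}
        )
        with pytest.raises(SelectionError):
            site_loglik(aln, tree, CodonModelSpec("M0"),
                        {"kappa": 2, "omega": 1})


class TestModelStructure:
    def test_class_proportions_sum_to_one(self):
        for name, params in [
            ("M1a", {"p0": 0.7, "omega0": 0.2}),
            ("M2a", {"p0": 0.6, "p1": 0.3, "omega0": 0.2, "omega2": 3.0}),
            ("M3", {"probs": [0.5, 0.3, 0.2], "omegas": [0.1, 0.8, 2.0]}),
            ("M7", {"p": 0.5, "q": 1.5}),
            ("M8", {"p0": 0.9, "p": 0.5, "q": 1.5, "omega_s": 2.0}),
        ]:
            omegas, probs = class_structure(CodonModelSpec(name), params)
            assert probs.sum() == pytest.approx(1.0)
            assert np.all(omegas >= 0)

    def test_m8_with_full_beta_weight_equals_m7(self):
        tree = sim_tree(6, 4, 0.2)
        aln, _ = sim_codon_alignment(
            tree, "M7", {"kappa": 2.0, "p": 0.6, "q": 1.2}, L=40, seed=3
        )
        l7 = site_loglik(aln, tree, CodonModelSpec("M7"),
                         {"kappa": 2.0, "p": 0.6, "q": 1.2}, pi=UNIFORM)[0]
        l8 = site_loglik(
            aln, tree, CodonModelSpec("M8"),
            {"kappa": 2.0, "p0": 1 - 1e-12, "p": 0.6, "q": 1.2,
             "omega_s": 1.0}, pi=UNIFORM,
        )[0]
        assert l8 == pytest.approx(l7, abs=1e-6)

    def test_m3_fit_dominates_m0_fit(self):
        from peroxevol.selection import fit_all_models

        tree = sim_tree(9, 5, 0.15)
        aln, _ = sim_codon_alignment(
            tree, "M0", {"kappa": 2.0, "omega": 0.5}, L=60, seed=9
        )
        fits, lrts = fit_all_models(aln, tree, models=["M0", "M3"])
        assert fits["M3"].lnl >= fits["M0"].lnl - 1e-4
        assert lrts["M0 vs M3"].stat >= 0


class TestLrt:
    def test_published_mnp1_statistic_significant_at_001(self):
        res = lrt_from_stat("M0 vs M3", 24.743772)
        assert res.df == 4 and res.p < 0.01

    def test_zero_statistic_p_one(self):
        res = lrt_from_stat("M7 vs M8", 0.0)
        assert res.p == 1.0

    def test_critical_value_two_df(self):
        # chi-square 0.05 critical value for 2 df
        res = lrt_from_stat("M1a vs M2a", 5.991465)
        assert res.p == pytest.approx(0.05, abs=1e-4)

    def test_raw_logliks_with_pair_name(self):
        res = lrt(-1000.0, -990.0, pair="M7 vs M8")
        assert res.stat == pytest.approx(20.0)
        assert res.p == pytest.approx(chi2.sf(20.0, 2))

    def test_negative_difference_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floor"):
            res = lrt(-990.0, -991.0, pair="M7 vs M8")
        assert res.stat == 0.0 and res.p == 1.0

    def test_unknown_pair_rejected(self):
        with pytest.raises(SelectionError):
            lrt(-10.0, -9.0, pair="M1a vs M8")


class TestNeb:
    def _planted_fit(self):
        """Fit-free NEB check: likelihoods at the true generating values of
        an M2a-style mixture with one strongly positive site class."""
        tree = sim_tree(2, 6, 0.3)
        spec = CodonModelSpec("M3")
        params = {"kappa": 2.0, "probs": [0.9, 0.1],
                  "omegas": [0.1, 5.0]}
        aln, classes = sim_codon_alignment(tree, spec, params, L=50, seed=21)
        lnl, site_cls, omegas, probs = site_loglik(
            aln, tree, spec, params, pi=UNIFORM
        )
        from peroxevol.selection import SiteModelFit

        fit = SiteModelFit(
            model="M3", lnl=lnl, kappa=2.0, params=params,
            class_omegas=omegas, class_probs=probs,
            site_class_loglik=site_cls, tree=tree, pi=UNIFORM, spec=spec,
        )
        return fit, classes

    def test_posteriors_sum_to_one(self):
        fit, _ = self._planted_fit()
        assert np.allclose(fit.site_posteriors().sum(axis=1), 1.0)

    def test_planted_positive_site_ranks_highest(self):
        fit, classes = self._planted_fit()
        table = neb_sites(fit)
        top = int(table.loc[table["posterior"].idxmax(), "site"])
        assert classes[top - 1] == 1  # the omega = 5 class

    def test_flags_nested_across_levels(self):
        fit, _ = self._planted_fit()
        table = neb_sites(fit)
        at99 = set(table.loc[table["level"] == 0.99, "site"])
        at95 = set(table.loc[table["level"].notna(), "site"])
        assert at99 <= at95

    def test_no_positive_class_returns_reasoned_empty(self):
        fit, _ = self._planted_fit()
        fit.class_omegas = np.array([0.1, 0.9])
        table = neb_sites(fit)
        assert table.empty and "omega" in table.attrs["reason"]


class TestDecisionRule:
    def test_significant_m3_with_high_omega_is_positive(self):
        verdict = positive_selection_decision(
            {"M3": 19.89},
            {"M0 vs M3": lrt_from_stat("M0 vs M3", 56.385656)},
        )
        assert verdict.positive and verdict.ensured_by == ["M0 vs M3"]

    def test_high_omega_with_nonsignificant_lrt_rejected(self):
        verdict = positive_selection_decision(
            {"M8": 2.38},
            {"M7 vs M8": lrt_from_stat("M7 vs M8", 2.0)},
        )
        assert not verdict.positive

    def test_all_omegas_at_most_one_rejected_without_lrt(self):
        verdict = positive_selection_decision({"M3": 0.8, "M8": 1.0}, {})
        assert not verdict.positive and verdict.ensured_by == []

    def test_published_group_summaries_reproduce_all_verdicts(self):
        """The decision rule reproduces the published verdict for the whole
        family and each of the eight groups."""
        from peroxevol.reference_data import LP_GROUP_SUMMARIES

        assert len(LP_GROUP_SUMMARIES) == 9
        for summary in LP_GROUP_SUMMARIES:
            verdict = summary.verdict()
            assert verdict.positive == summary.expected_positive, summary.name
        positives = {s.name for s in LP_GROUP_SUMMARIES
                     if s.verdict().positive}
        assert positives == {"MnP I", "MnP III", "CII"}
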