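"""Likelihood engine: pruning, branch optimisation, mixtures, partitions."""

import math

import numpy as np
import pytest

from conftest import brute_force_log_likelihood
from rsaevol.engine import (
    BRANCH_MAX,
    BRANCH_MIN,
    AlignmentLikelihood,
    categorize_sites,
    effective_categories,
    fit_heterotachy,
    fit_partitioned,
    optimize_branch_lengths,
    tree_log_likelihood,
)
from rsaevol.io import LabeledTree, ResidueAlignment
from rsaevol.revmodel import RevModel
from rsaevol.simulate import simulate_alignment, simulate_heterotachy


class TestTransitionProbabilities:
    def test_rows_sum_to_one_and_p0_identity(self, aa_model):
        for t in (0.0, 0.1, 2.0):
            P = aa_model.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1, atol=1e-12)
        assert np.allclose(aa_model.transition_matrix(0.0), np.eye(20),
                           atol=1e-12)

    def test_chapman_kolmogorov(self, dna_model):
        Pa = dna_model.transition_matrix(0.3)
        Pb = dna_model.transition_matrix(0.7)
        Pab = dna_model.transition_matrix(1.0)
        assert np.allclose(Pa @ Pb, Pab, atol=1e-10)

    @pytest.mark.parametrize("K", [4, 20])
    def test_equal_rates_closed_form(self, K):
        model = RevModel.equal_rates("ACGT" if K == 4 else
                                     "ARNDCEQGHILKMFPSTWYV")
        for t in np.linspace(0.0, 5.0, 21):
            P = model.transition_matrix(t)
            expected = 1 / K + (K - 1) / K * math.exp(-K / (K - 1) * t)
            assert np.allclose(np.diag(P), expected, atol=1e-10)


class TestTreeLogLikelihood:
    def test_two_leaf_zero_length_gives_pi(self, dna_model):
        tree = LabeledTree.from_newick("(a,b);")
        aln = ResidueAlignment(["a", "b"], ["C", "C"], alphabet="ACGT")
        ll = tree_log_likelihood(aln, tree, dna_model,
                                 {"a": 1e-6, "b": 1e-6})
        assert ll == pytest.approx(math.log(dna_model.frequencies[1]),
                                   abs=1e-3)

    def test_matches_brute_force_enumeration(self, quartet_tree, aa_model):
        rng = np.random.default_rng(1)
        lengths = {lab: float(v) for lab, v in
                   zip(quartet_tree.branch_labels, rng.uniform(0.05, 0.8, 6))}
        aln = simulate_alignment(quartet_tree, aa_model, lengths, 10, seed=2)
        ll = tree_log_likelihood(aln, quartet_tree, aa_model, lengths)
        oracle = brute_force_log_likelihood(aln, quartet_tree, aa_model,
                                            lengths)
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_missing_data_all_ones_partial(self, quartet_tree, dna_model):
        full = ResidueAlignment(["a", "b", "c", "d"],
                                ["ACGT", "ACGT", "AAAA", "CCCC"],
                                alphabet="ACGT")
        gapped = ResidueAlignment(["a", "b", "c", "d"],
                                  ["ACGT", "ACGT", "AAAA", "-CCC"],
                                  alphabet="ACGT")
        lengths = {lab: 0.2 for lab in quartet_tree.branch_labels}
        oracle = brute_force_log_likelihood(gapped, quartet_tree, dna_model,
                                            lengths)
        ll = tree_log_likelihood(gapped, quartet_tree, dna_model, lengths)
        assert ll == pytest.approx(oracle, rel=1e-10)
        assert ll != pytest.approx(
            tree_log_likelihood(full, quartet_tree, dna_model, lengths)
        )

    def test_reroot_invariance(self, dna_model):
        """The same weighted unrooted tree written with different roots."""
        rng = np.random.default_rng(7)
        la, lb, lc, ld, lx, ly = rng.uniform(0.05, 0.6, 6)
        t1 = LabeledTree.from_newick(
            f"((a:{la},b:{lb})X:{lx},(c:{lc},d:{ld})Y:{ly});"
        )
        aln = simulate_alignment(
            t1, dna_model, t1.input_lengths, 50, seed=8
        )
        ll1 = tree_log_likelihood(aln, t1, dna_model)
        # root collapsed onto node X
        t2 = LabeledTree.from_newick(
            f"(a:{la},b:{lb},(c:{lc},d:{ld})Y:{lx + ly});"
        )
        ll2 = tree_log_likelihood(aln, t2, dna_model)
        # root placed elsewhere on the central edge
        q = 0.3 * (lx + ly)
        t3 = LabeledTree.from_newick(
            f"((a:{la},b:{lb})X:{q},(c:{lc},d:{ld})Y:{lx + ly - q});"
        )
        ll3 = tree_log_likelihood(aln, t3, dna_model)
        assert ll2 == pytest.approx(ll1, rel=1e-10)
        assert ll3 == pytest.approx(ll1, rel=1e-10)

    def test_kernel_and_reference_paths_agree(self, six_taxon_tree, aa_model):
        aln = simulate_alignment(six_taxon_tree, aa_model, 0.2, 300, seed=3)
        lik = AlignmentLikelihood(aln, six_taxon_tree)
        lik.set_models([aa_model])
        vec = lik.lengths_vector(0.17)
        a = lik.class_site_log_likelihood(vec).copy()
        lik._use_kernels = False
        b = lik.class_site_log_likelihood(vec)
        assert np.allclose(a, b, atol=1e-10)


class TestOptimizeBranchLengths:
    def test_logl_not_below_start(self, six_taxon_tree, dna_model):
        aln = simulate_alignment(six_taxon_tree, dna_model, 0.3, 400, seed=4)
        start = tree_log_likelihood(aln, six_taxon_tree, dna_model, 0.1)
        fit = optimize_branch_lengths(aln, six_taxon_tree, dna_model)
        assert fit.log_likelihood >= start

    def test_constant_alignment_drives_lengths_to_floor(self, six_taxon_tree,
                                                        dna_model):
        aln = ResidueAlignment(["a", "b", "c", "d", "e", "f"],
                               ["AAAA"] * 6, alphabet="ACGT")
        fit = optimize_branch_lengths(aln, six_taxon_tree, dna_model)
        assert all(v == pytest.approx(BRANCH_MIN, abs=1e-8)
                   for v in fit.lengths.values())

    def test_length_recovery(self, six_taxon_tree, aa_model):
        rng = np.random.default_rng(11)
        truth = {lab: float(v) for lab, v in
                 zip(six_taxon_tree.branch_labels,
                     rng.uniform(0.2, 0.4, 9))}
        aln = simulate_alignment(six_taxon_tree, aa_model, truth, 5000,
                                 seed=12)
        fit = optimize_branch_lengths(aln, six_taxon_tree, aa_model)
        for lab in six_taxon_tree.inner_branch_labels:
            assert fit.lengths[lab] == pytest.approx(truth[lab], rel=0.10)


class TestHeterotachy:
    def test_h1_reduces_to_single_set(self, six_taxon_tree, dna_model):
        aln = simulate_alignment(six_taxon_tree, dna_model, 0.2, 500, seed=5)
        single = optimize_branch_lengths(aln, six_taxon_tree, dna_model)
        fit = fit_heterotachy(aln, six_taxon_tree, dna_model, H=1)
        assert fit.log_likelihood == pytest.approx(single.log_likelihood,
                                                   abs=1e-6)
        assert fit.n_classes == 1

    def test_weights_on_simplex_and_nesting(self, six_taxon_tree, aa_model):
        aln = simulate_alignment(six_taxon_tree, aa_model, 0.25, 600, seed=6)
        single = optimize_branch_lengths(aln, six_taxon_tree, aa_model)
        fit = fit_heterotachy(aln, six_taxon_tree, aa_model, H=3)
        assert fit.weights.sum() == pytest.approx(1.0)
        assert (fit.weights >= 0).all()
        assert fit.log_likelihood >= single.log_likelihood - 1e-9

    def test_classes_sorted_by_tree_length(self, six_taxon_tree, aa_model):
        aln = simulate_alignment(six_taxon_tree, aa_model, 0.25, 600, seed=6)
        fit = fit_heterotachy(aln, six_taxon_tree, aa_model, H=3)
        totals = fit.class_tree_lengths()
        assert np.all(np.diff(totals) >= -1e-12)

    def test_two_class_mixture_recovery(self, six_taxon_tree, aa_model):
        base = {lab: 0.12 for lab in six_taxon_tree.branch_labels}
        fast = {lab: 3 * v for lab, v in base.items()}
        aln, _ = simulate_heterotachy(six_taxon_tree, aa_model, [base, fast],
                                      [0.5, 0.5], 5000, seed=13)
        fit = fit_heterotachy(aln, six_taxon_tree, aa_model, H=2)
        assert abs(fit.weights[0] - 0.5) < 0.1
        totals = fit.class_tree_lengths()
        assert totals[1] / totals[0] == pytest.approx(3.0, rel=0.3)

    def test_combined_length_is_weighted_average(self, six_taxon_tree,
                                                 dna_model):
        aln = simulate_alignment(six_taxon_tree, dna_model, 0.2, 400, seed=14)
        fit = fit_heterotachy(aln, six_taxon_tree, dna_model, H=2)
        for lab in six_taxon_tree.branch_labels:
            expected = sum(
                w * d[lab] for w, d in zip(fit.weights, fit.class_lengths)
            )
            assert fit.combined_lengths[lab] == pytest.approx(expected,
                                                              abs=1e-9)


class TestSiteCategories:
    def test_invariant_site_lowest_category(self):
        aln = ResidueAlignment(["a", "b", "c", "d"],
                               ["AA", "AC", "AG", "AT"], alphabet="ACGT")
        cats = categorize_sites(aln, 4)
        assert cats[0] == 1
        assert cats[1] == 4      # all distinct, n_taxa = K reach the top

    def test_taxon_order_invariance(self):
        rows = ["ACGGT", "CCGAT", "ACGAT", "TCGAA"]
        names = ["a", "b", "c", "d"]
        aln1 = ResidueAlignment(names, rows, alphabet="ACGT")
        aln2 = ResidueAlignment(names[::-1], rows[::-1], alphabet="ACGT")
        assert np.array_equal(categorize_sites(aln1, 8),
                              categorize_sites(aln2, 8))

    def test_quantile_scheme_available(self):
        aln = ResidueAlignment(["a", "b", "c", "d"],
                               ["AAAC", "ACAC", "AGGC", "ATGC"],
                               alphabet="ACGT")
        cats = categorize_sites(aln, 2, scheme="quantile")
        assert set(cats) <= {1, 2}

    def test_effective_categories_examples(self):
        assert effective_categories(np.ones(50, dtype=int)) == (1, 1.0)
        half = np.array([1] * 25 + [2] * 25)
        assert effective_categories(half) == (2, 1.0)
        mix = np.array([1] * 90 + [2] * 6 + [3] * 4)
        count, frac = effective_categories(mix)
        assert count == 2
        assert frac == pytest.approx(0.96)


class TestPartitionFit:
    def test_single_category_reduces_to_plain_fit(self, six_taxon_tree,
                                                  dna_model):
        aln = simulate_alignment(six_taxon_tree, dna_model, 0.2, 400, seed=15)
        cats = np.ones(aln.n_sites, dtype=int)
        part = fit_partitioned(aln, six_taxon_tree, dna_model, cats)
        from rsaevol.revmodel import empirical_frequencies
        ref_model = RevModel(dna_model.exchangeabilities,
                             empirical_frequencies(aln), "ACGT")
        plain = optimize_branch_lengths(aln, six_taxon_tree, ref_model)
        assert part.log_likelihood == pytest.approx(plain.log_likelihood,
                                                    abs=1e-6)

    def test_total_logl_is_sum_of_categories(self, six_taxon_tree, dna_model):
        aln = simulate_alignment(six_taxon_tree, dna_model, 0.2, 400, seed=16)
        cats = categorize_sites(aln, 4)
        part = fit_partitioned(aln, six_taxon_tree, dna_model, cats)
        assert part.log_likelihood == pytest.approx(
            sum(part.category_log_likelihoods.values())
        )
        assert sum(part.site_fractions.values()) == pytest.approx(1.0)

    def test_tiny_categories_merged(self, six_taxon_tree, dna_model):
        aln = simulate_alignment(six_taxon_tree, dna_model, 0.2, 100, seed=17)
        cats = np.ones(100, dtype=int)
        cats[:3] = 5
        with pytest.warns(UserWarning, match="merged"):
            part = fit_partitioned(aln, six_taxon_tree, dna_model, cats)
        assert part.merged == {5: 1}
        assert list(part.category_lengths) == [1]

    def test_saturated_category_hits_length_cap(self, six_taxon_tree):
        """Random iid columns carry no tree signal: lengths run to the cap."""
        rng = np.random.default_rng(18)
        rows = ["".join(rng.choice(list("ACGT"), 400)) for _ in range(6)]
        aln = ResidueAlignment(["a", "b", "c", "d", "e", "f"], rows,
                               alphabet="ACGT")
        model = RevModel.equal_rates("ACGT")
        fit = optimize_branch_lengths(aln, six_taxon_tree, model)
        assert max(fit.lengths.values()) == pytest.approx(BRANCH_MAX)
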