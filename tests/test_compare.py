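"""Jackknife statistics, effect sizes, filters, classification."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import rsaevol.compare as cmp
from rsaevol.compare import (
    BranchComparison,
    BranchTable,
    ChannelMoments,
    build_branch_table,
    channel_moments,
    classify_branches,
    cliffs_delta,
    compare_branch,
    compare_branches,
    comparisons_to_frame,
    family_sensitivity,
    filter_branches,
    heterotachy_weight_ratio,
    holm_adjust,
    iqr_filter,
    jackknife_replicates,
    ln_ratio,
    summarize_clades,
    tree_summary,
)
from rsaevol.engine import HeterotachyFit
from rsaevol.io import AMINO_ACIDS
from rsaevol.revmodel import RevModel
from rsaevol.simulate import SimulationSpec, simulate_paired


class TestJackknife:
    def test_delete_half_sizes(self):
        reps = jackknife_replicates(100, n=10, seed=1)
        assert len(reps) == 10
        assert all(len(r) == 50 for r in reps)

    def test_indices_distinct_within_replicate(self):
        for r in jackknife_replicates(31, n=20, seed=2):
            assert len(np.unique(r)) == len(r) == 15

    def test_seed_reproducibility(self):
        a = jackknife_replicates(60, n=5, seed=3)
        b = jackknife_replicates(60, n=5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            jackknife_replicates(100, fraction=0.0)


class TestLnRatio:
    def test_equal_lengths_zero(self):
        assert ln_ratio(0.1, 0.1) == 0.0

    def test_doubling_gives_ln2(self):
        assert ln_ratio(0.2, 0.1) == pytest.approx(np.log(2))

    def test_zero_floored(self):
        assert ln_ratio(0.0, 5e-5) == 0.0
        assert ln_ratio(5e-3, 0.0) == pytest.approx(np.log(5e-3 / 5e-5))


class TestFilters:
    def _table(self, l_rsa_rows):
        idx = pd.Index([f"N{i+1}" for i in range(len(l_rsa_rows))],
                       name="branch")
        cols = pd.RangeIndex(len(l_rsa_rows[0]), name="replicate")
        l_aa = pd.DataFrame(0.1, index=idx, columns=cols)
        l_rsa = pd.DataFrame(l_rsa_rows, index=idx, columns=cols)
        return BranchTable(l_aa, l_rsa, "heterotachy")

    def test_all_zero_branch_filtered(self):
        table = self._table([[0.0] * 6, [1e-3] * 6])
        _, filtered = filter_branches(table)
        assert filtered == ("N1",)

    def test_zero_threshold_retains_all(self):
        table = self._table([[0.0] * 6])
        _, filtered = filter_branches(table, min_len=0)
        assert filtered == ()

    def test_iqr_examples(self):
        kept, dropped, iqrs = iqr_filter({
            "flat": np.zeros(8),
            "wild": np.array([10.0, -10.0] * 4),
        })
        assert kept == ["flat"] and dropped == ["wild"]
        assert iqrs["wild"] == pytest.approx(20.0)

    def test_iqr_threshold_configurable(self):
        samples = {"b": np.array([0, 0, 5, 5.0])}
        kept6, _, _ = iqr_filter(samples, threshold=6)
        kept4, _, _ = iqr_filter(samples, threshold=4)
        assert kept6 == ["b"] and kept4 == []

    def test_short_samples_unestimable(self):
        kept, dropped, _ = iqr_filter({"b": np.array([1.0, 2.0, 3.0])})
        assert dropped == ["b"]


class TestCliffsDelta:
    def test_complete_separation(self):
        assert cliffs_delta([2, 2], [1, 1]) == 1.0
        assert cliffs_delta([1, 1], [2, 2]) == -1.0

    def test_identical_samples_zero(self):
        assert cliffs_delta([1, 2, 3], [1, 2, 3]) == 0.0

    def test_interleaved_example(self):
        assert cliffs_delta([1, 3], [2]) == 0.0

    def test_matches_explicit_double_loop(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            x = rng.normal(size=rng.integers(1, 15))
            y = rng.normal(size=rng.integers(1, 15))
            wins = sum(1 for a in x for b in y if a > b)
            losses = sum(1 for a in x for b in y if a < b)
            oracle = (wins - losses) / (len(x) * len(y))
            assert cliffs_delta(x, y) == pytest.approx(oracle, abs=1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])


class TestCompareBranch:
    def test_fully_shifted_sample(self):
        p, delta = compare_branch([5.0, 6, 7, 8], [0.0, 1, 2, 3], seed=0)
        assert delta == 1.0
        assert p < 0.05

    def test_pool_subsampled_to_ten_times(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        y = np.concatenate([rng.normal(size=1900), np.full(100, 50.0)])
        # with subsampling to <= 1000 the pool keeps its distribution shape
        p, delta = compare_branch(x, y, seed=6)
        frac_big = 100 / 2000
        assert abs(delta) <= 1
        # direct check on the subsample mechanics
        cap = 10 * x.size
        rng2 = np.random.default_rng(6)
        sub = y[rng2.choice(y.size, size=cap, replace=False)]
        assert sub.size == 1000
        assert cliffs_delta(x, sub) == pytest.approx(delta)

    def test_all_tied_degenerate(self):
        p, delta = compare_branch([1.0, 1.0], [1.0, 1.0, 1.0])
        assert (p, delta) == (1.0, 0.0)

    def test_null_delta_concentrates_near_zero(self):
        rng = np.random.default_rng(7)
        deltas = []
        for seed in range(60):
            x = rng.normal(size=20)
            y = rng.normal(size=200)
            _, d = compare_branch(x, y, seed=seed)
            deltas.append(d)
        assert abs(np.mean(deltas)) < 0.08
        assert np.quantile(np.abs(deltas), 0.9) < 0.45


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_adjusted_never_below_raw_and_capped(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 12))
            adj = holm_adjust(p)
            assert (adj >= p - 1e-15).all()
            assert (adj <= 1.0).all()

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 20))
            ours = holm_adjust(p)
            ref = multipletests(p, method="holm")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


def _comparison(branch, delta, p_holm, call="neutral"):
    return BranchComparison(
        branch=branch, lnL=np.zeros(4), median_lnL=0.0, iqr=0.1,
        p_value=p_holm, p_holm=p_holm, delta=delta, call=call,
    )


class TestClassification:
    def test_threshold_gates(self):
        comps = [
            _comparison("acc", 0.8, 1e-6),
            _comparison("dec", -0.9, 1e-6),
            _comparison("weak_p", 0.8, 0.01),
            _comparison("weak_d", 0.5, 1e-6),
        ]
        calls = classify_branches(comps)
        assert calls == {
            "acc": "accelerated", "dec": "decelerated",
            "weak_p": "neutral", "weak_d": "neutral",
        }

    def test_filtered_flag_kept(self):
        comp = _comparison("f", np.nan, np.nan, call="filtered")
        assert classify_branches([comp]) == {"f": "filtered"}

    def test_consensus_requires_partition_agreement(self):
        het = [_comparison("b", 0.8, 1e-6)]
        part_ok = [_comparison("b", 0.65, 1e-6)]
        part_no = [_comparison("b", 0.4, 1e-6)]
        assert classify_branches(het, partition_comparisons=part_ok) == \
            {"b": "accelerated"}
        assert classify_branches(het, partition_comparisons=part_no) == \
            {"b": "neutral"}

    def test_antisymmetry_under_channel_swap(self, rooted_six_taxon_tree):
        """Swapping the channels negates ln(L) and swaps the calls."""
        rng = np.random.default_rng(10)
        idx = pd.Index(["N1", "N2", "N3", "N4"], name="branch")
        cols = pd.RangeIndex(20, name="replicate")
        l_aa = pd.DataFrame(rng.uniform(0.05, 0.2, (4, 20)), idx, cols)
        l_rsa = pd.DataFrame(rng.uniform(0.05, 0.2, (4, 20)), idx, cols)
        l_rsa.loc["N1"] *= 8.0
        fwd = compare_branches(BranchTable(l_aa, l_rsa, "h"), seed=3)
        rev = compare_branches(BranchTable(l_rsa, l_aa, "h"), seed=3)
        calls_f = classify_branches(fwd)
        calls_r = classify_branches(rev)
        swap = {"accelerated": "decelerated", "decelerated": "accelerated",
                "neutral": "neutral", "filtered": "filtered"}
        assert calls_r == {b: swap[c] for b, c in calls_f.items()}
        for cf, cr in zip(fwd, rev):
            if np.isfinite(cf.delta):
                assert cr.delta == pytest.approx(-cf.delta, abs=1e-12)
                assert cr.p_holm == pytest.approx(cf.p_holm, rel=1e-9)


class TestSummaries:
    def test_tree_summary_counts(self):
        comps = [
            _comparison("a", 0.75, 1e-6), _comparison("b", 0.45, 1e-6),
            _comparison("c", -0.55, 1e-6),
        ]
        summary = tree_summary(comps)
        assert summary[0.3] == 1        # +2 positive, -1 negative
        assert summary[0.5] == 0
        assert summary[0.7] == 1
        counts = [abs(summary[t]) for t in (0.3, 0.4, 0.5, 0.6, 0.7)]
        pos_counts = [
            sum(1 for c in comps if c.delta >= t)
            for t in (0.3, 0.4, 0.5, 0.6, 0.7)
        ]
        assert pos_counts == sorted(pos_counts, reverse=True)

    def test_family_sensitivity(self):
        med, shift = family_sensitivity([1.0, 1.0, 1.0, 9.0])
        assert med == 1.0
        assert shift == pytest.approx(2.0)

    def test_family_sensitivity_zero_median_undefined(self):
        med, shift = family_sensitivity([-1.0, 0.0, 1.0])
        assert med == 0.0
        assert shift is None

    def test_channel_moments_hand_variance(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        m = channel_moments(a, a)
        assert m.variance_aa == pytest.approx(2.5)
        assert m.welch_p == pytest.approx(1.0)

    def test_channel_moments_normal_sample(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=10000)
        b = rng.normal(size=10000)
        m = channel_moments(a, b)
        assert abs(m.skewness_aa) < 0.05
        assert abs(m.kurtosis_aa) < 0.1

    def test_heterotachy_weight_ratio(self):
        def fit(weights, scale):
            H = len(weights)
            return HeterotachyFit(
                n_classes=H, weights=np.array(weights),
                class_lengths=[{"x": scale * (i + 1)} for i in range(H)],
                class_frequencies=[np.ones(4) / 4] * H,
                log_likelihood=0.0, combined_lengths={"x": 1.0},
            )
        ratios = heterotachy_weight_ratio(fit([0.5, 0.5], 1),
                                          fit([0.25, 0.75], 1))
        assert np.allclose(ratios, [2.0, 2 / 3])
        same = heterotachy_weight_ratio(fit([0.3, 0.7], 1), fit([0.3, 0.7], 2))
        assert np.allclose(same, 1.0)

    def test_zero_weight_gives_inf(self):
        f1 = HeterotachyFit(1, np.array([1.0]), [{"x": 1.0}],
                            [np.ones(2) / 2], 0.0, {"x": 1.0})
        f0 = HeterotachyFit(1, np.array([0.0]), [{"x": 1.0}],
                            [np.ones(2) / 2], 0.0, {"x": 1.0})
        assert heterotachy_weight_ratio(f1, f0)[0] == np.inf

    def test_summarize_clades(self):
        calls = {
            "famA": {"N1": "accelerated", "N2": "neutral"},
            "famB": {"N1": "decelerated", "N2": "accelerated"},
        }
        out = summarize_clades(calls, {"cladeX": ["N1"], "cladeY": ["N2"]})
        by_name = {c.clade: c for c in out}
        assert by_name["cladeX"].n_accelerated == 1
        assert by_name["cladeX"].n_decelerated == 1
        assert by_name["cladeY"].accelerated == {"famB": ["N2"]}


class TestBranchTable:
    def test_tsv_round_trip(self, tmp_path):
        idx = pd.Index(["N1", "N2"], name="branch")
        cols = pd.RangeIndex(3, name="replicate")
        table = BranchTable(
            pd.DataFrame([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]], idx, cols),
            pd.DataFrame([[0.2, 0.1, 0.3], [0.1, 0.5, 0.9]], idx, cols),
            "heterotachy",
        )
        p = tmp_path / "table.tsv"
        table.to_tsv(p)
        back = BranchTable.from_tsv(p)
        pd.testing.assert_frame_equal(back.l_aa, table.l_aa,
                                      check_names=False)
        assert back.mode == "heterotachy"

    def test_negative_lengths_rejected(self):
        idx = pd.Index(["N1"], name="branch")
        cols = pd.RangeIndex(2, name="replicate")
        with pytest.raises(ValueError, match="nonnegative"):
            BranchTable(pd.DataFrame([[0.1, -0.2]], idx, cols),
                        pd.DataFrame([[0.1, 0.2]], idx, cols), "h")

    def test_dimensions_and_recovery(self, rooted_six_taxon_tree):
        """Small end-to-end table: shape, null median, and 3x recovery."""
        aa_m = RevModel.random(AMINO_ACIDS, seed=20)
        paa_m = RevModel.random(AMINO_ACIDS, seed=21)
        spec = SimulationSpec(
            tree=rooted_six_taxon_tree, n_sites=2000, aa_model=aa_m,
            paa_model=paa_m, focal_branches=["N1"], rsa_multiplier=3.0,
            seed=22, base_lengths=0.1,
        )
        sim = simulate_paired(spec)
        reps = jackknife_replicates(sim.aa_alignment, n=20, seed=23)
        table = build_branch_table(
            sim.aa_alignment, sim.paa_alignment, rooted_six_taxon_tree,
            aa_m, paa_m, reps,
        )
        assert table.l_aa.shape == (4, 20)
        part = build_branch_table(
            sim.aa_alignment, sim.paa_alignment, rooted_six_taxon_tree,
            aa_m, paa_m, reps[:4], mode="partition", n_categories=8,
        )
        assert part.l_aa.shape == (4, 4)
        assert part.mode == "partition"
        assert (part.l_rsa.to_numpy() >= 0).all()
        lnL = ln_ratio(table.l_rsa.loc["N1"], table.l_aa.loc["N1"])
        assert np.median(lnL) == pytest.approx(np.log(3), abs=0.35)
        for other in ("N2", "N3", "N4"):
            lnL_o = ln_ratio(table.l_rsa.loc[other], table.l_aa.loc[other])
            assert abs(np.median(lnL_o)) < np.log(3) / 2
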