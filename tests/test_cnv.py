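"""Per-window chi-squared tests, BH correction, call merging, ploidy, mtDNA."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from g4stability import CNVModel, chromosome_ploidy, merge_calls, mtdna_copy_number
from g4stability.cnv import quantile_normalize
from g4stability.cnv import test_windows as window_tests  # alias: not a pytest case
from g4stability.windows import WindowedCoverage, make_windows


def _cov(counts, sample="s", chrom_len=None, gc=None):
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    chrom_len = chrom_len or (n + 1) * 100
    windows = make_windows({"c": chrom_len}, 200, 100).iloc[:n].reset_index(drop=True)
    return WindowedCoverage(windows, counts, sample_id=sample, gc=gc)


def _pearson_chi2_oracle(a, b, c, d):
    """Sum (O-E)^2/E over the four cells, the textbook formula."""
    import scipy.stats

    obs = np.array([[a, b], [c, d]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / obs.sum()
    stat = ((obs - exp) ** 2 / exp).sum()
    return stat, scipy.stats.chi2.sf(stat, 1)


class TestWindowTests:
    def test_identical_profiles_give_p_one_no_significance(self):
        counts = np.full(50, 100.0)
        tests = window_tests(_cov(counts, "wt"), _cov(counts, "mut"))
        assert np.allclose(tests["p"].dropna(), 1.0)
        assert not tests["significant"].any()

    def test_statistic_matches_hand_evaluated_pearson_formula(self):
        # window with wt=100 of 10000 total vs mut=200 of 10000 total
        wt = np.concatenate([[100.0], np.full(99, 100.0)])
        mut = np.concatenate([[200.0], np.full(99, (10_000 - 200) / 99)])
        tests = window_tests(_cov(wt, "wt"), _cov(mut, "mut"))
        _, p_oracle = _pearson_chi2_oracle(100, 9900, 200, 9800)
        assert tests["p"].iloc[0] == pytest.approx(p_oracle, rel=1e-12)

    def test_zero_zero_windows_excluded(self):
        wt = np.array([0.0, 100.0, 100.0, 100.0])
        mut = np.array([0.0, 100.0, 100.0, 100.0])
        tests = window_tests(_cov(wt, "wt"), _cov(mut, "mut"))
        assert np.isnan(tests["p"].iloc[0]) and not tests["significant"].iloc[0]

    def test_random_windows_match_brute_force_chi2_and_bh(self, rng):
        wt = rng.poisson(100.0, 1000).astype(float)
        mut = rng.poisson(100.0, 1000).astype(float)
        mut[:20] = rng.poisson(220.0, 20)
        tests = window_tests(_cov(wt, "wt"), _cov(mut, "mut"))
        wt_tot, mut_tot = wt.sum(), mut.sum()
        p_oracle = np.array([
            _pearson_chi2_oracle(a, wt_tot - a, c, mut_tot - c)[1] for a, c in zip(wt, mut)
        ])
        assert np.allclose(tests["p"].to_numpy(), p_oracle, atol=1e-10)
        # textbook BH step-up oracle
        p = p_oracle
        order = np.argsort(p)
        ranked = p[order] * len(p) / np.arange(1, len(p) + 1)
        q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        q_oracle = np.empty_like(p)
        q_oracle[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(tests["q"].to_numpy(), q_oracle, atol=1e-12)

    def test_bh_textbook_example(self):
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            window_tests(_cov(np.zeros(5), "wt"), _cov(np.ones(5), "mut"))


class TestMergeCalls:
    def _tests_df(self, rows):
        # rows: (start, significant, ratio)
        df = pd.DataFrame(rows, columns=["start", "significant", "ratio"])
        df["chrom"] = "c"
        df["end"] = df["start"] + 200
        df["q"] = np.where(df["significant"], 1e-4, 0.5)
        df["wt"] = 100.0
        df["mut"] = 100.0 * df["ratio"]
        df["p"] = df["q"]
        return df

    def test_three_windows_span_400_rejected_by_strict_threshold(self):
        df = self._tests_df([(0, True, 2.0), (100, True, 2.0), (200, True, 2.0)])
        assert len(merge_calls(df)) == 0  # span 400 <= 500

    def test_five_windows_span_600_accepted(self):
        df = self._tests_df([(s, True, 2.0) for s in range(0, 500, 100)])
        calls = merge_calls(df)
        assert len(calls) == 1
        call = calls.iloc[0]
        assert (call["start"], call["end"], call["n_windows"], call["direction"]) == (0, 600, 5, "gain")

    def test_direction_change_splits_runs(self):
        rows = [(s, True, 2.0) for s in range(0, 600, 100)]
        rows += [(s, True, 0.4) for s in range(600, 1200, 100)]
        calls = merge_calls(self._tests_df(rows))
        assert list(calls["direction"]) == ["gain", "loss"]
        assert len(calls) == 2

    def test_gap_of_two_nonsig_windows_splits(self):
        rows = [(s, True, 2.0) for s in range(0, 600, 100)]
        rows += [(600, False, 1.0), (700, False, 1.0)]
        rows += [(s, True, 2.0) for s in range(800, 1400, 100)]
        calls = merge_calls(self._tests_df(rows))
        assert len(calls) == 2

    def test_single_nonsig_window_is_bridged_by_adjoining_spans(self):
        # significant windows at 0 and 200 touch ([0,200) + [200,400))
        rows = [(0, True, 2.0), (100, False, 1.0)] + [(s, True, 2.0) for s in range(200, 700, 100)]
        calls = merge_calls(self._tests_df(rows))
        assert len(calls) == 1
        assert calls.iloc[0]["end"] - calls.iloc[0]["start"] == 800


class TestChromosomePloidy:
    def _pair(self, wt_depths, mut_depths, n=50):
        frames_wt, frames_mut, windows = [], [], []
        sizes = {f"chr{i}": (n + 1) * 100 for i in range(len(wt_depths))}
        grid = make_windows(sizes, 200, 100)
        rngs = np.random.default_rng(0)
        wt = np.concatenate([np.full(n, d, dtype=float) for d in wt_depths])
        mut = np.concatenate([np.full(n, d, dtype=float) for d in mut_depths])
        return (WindowedCoverage(grid, wt, "wt"), WindowedCoverage(grid, mut, "mut"))

    def test_identical_samples_no_flags(self):
        wt, mut = self._pair([100, 100, 100], [100, 100, 100])
        res = chromosome_ploidy(wt, mut)
        assert np.allclose(res["ratio"], 1.0)
        assert not res["duplicated"].any()

    def test_whole_chromosome_duplication_flagged(self, small_genome, small_grid):
        # median rescaling assumes most of the genome is unchanged, so the
        # duplicated chromosome must be a minority of the windows (as in a
        # single-chromosome aneuploidy of a 16-chromosome genome)
        from g4stability import CnvTruth, simulate_coverage
        from g4stability.intervals import IntervalSet

        windows, gc = small_grid
        truth = CnvTruth(IntervalSet(), np.array([]), whole_chrom_dups=["chrI"])
        wt = simulate_coverage(small_genome, gc_bias=None, seed=21, windows=windows, gc=gc)
        mut = simulate_coverage(small_genome, truth, gc_bias=None, seed=22, windows=windows, gc=gc)
        res = chromosome_ploidy(wt, mut)
        dup = res.set_index("chrom")["duplicated"]
        assert dup["chrI"] and not dup["chrII"] and not dup["chrIII"]
        ratio = res.set_index("chrom")["ratio"]
        assert 1.8 <= ratio["chrI"] <= 2.2

    def test_global_depth_difference_cancels(self):
        wt, mut = self._pair([100, 100, 100], [200, 200, 200])
        res = chromosome_ploidy(wt, mut)
        assert np.allclose(res["ratio"], 1.0)
        assert not res["duplicated"].any()

    def test_small_chromosome_flag_suppressed(self):
        sizes = {"big": 10_000, "tiny": 600}
        grid = make_windows(sizes, 200, 100)
        wt = WindowedCoverage(grid, np.full(len(grid), 100.0), "wt")
        mut_counts = np.full(len(grid), 100.0)
        mut_counts[(grid["chrom"] == "tiny").to_numpy()] = 300.0
        mut = WindowedCoverage(grid, mut_counts, "mut")
        with pytest.warns(UserWarning, match="tiny"):
            res = chromosome_ploidy(wt, mut)
        assert not res.set_index("chrom").loc["tiny", "duplicated"]


class TestMtCopyNumber:
    def _features(self, mt_count, nuc_counts, length=1000):
        rows = [("mt", length, mt_count, True, False)]
        rows += [(f"g{i}", length, c, False, True) for i, c in enumerate(nuc_counts)]
        return pd.DataFrame(rows, columns=["feature", "length", "count", "is_mt", "is_single_copy"])

    def test_uniform_depth_gives_copy_number_one(self):
        fc = self._features(100, [100, 100, 100])
        assert mtdna_copy_number(fc, total_mapped=1e6).copy_number == pytest.approx(1.0)

    def test_twenty_fold_mt_depth(self):
        fc = self._features(2000, [100, 100, 100])
        assert mtdna_copy_number(fc, total_mapped=1e6).copy_number == pytest.approx(20.0)

    def test_relative_copy_number_across_samples(self):
        sample = mtdna_copy_number(self._features(500, [100, 100]), 1e6).copy_number
        control = mtdna_copy_number(self._features(2000, [100, 100]), 1e6).copy_number
        assert sample / control == pytest.approx(0.25)

    def test_invert_flag(self):
        fc = self._features(2000, [100])
        res = mtdna_copy_number(fc, 1e6, invert=True)
        assert res.copy_number == pytest.approx(1 / 20)

    def test_errors(self):
        fc = self._features(100, [100])
        with pytest.raises(ValueError):
            mtdna_copy_number(fc, total_mapped=0)
        with pytest.raises(ValueError):
            mtdna_copy_number(fc[fc["is_mt"]], total_mapped=1e6)  # empty nuclear set


def test_quantile_normalize_makes_column_distributions_identical():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"a": rng.gamma(2, 10, 100), "b": rng.gamma(5, 3, 100)})
    qn = quantile_normalize(df)
    assert np.allclose(np.sort(qn["a"]), np.sort(qn["b"]))


def test_cnv_model_end_to_end_summary(small_genome, small_grid):
    from g4stability import simulate_cnv_truth, simulate_coverage

    windows, gc = small_grid
    truth = simulate_cnv_truth(small_genome, n_cnvs=4, seed=3)
    wt = simulate_coverage(small_genome, seed=30, windows=windows, gc=gc, sample_id="wt")
    mut = simulate_coverage(small_genome, truth, seed=31, windows=windows, gc=gc, sample_id="m1")
    res = CNVModel(wt, mut).fit()
    assert len(res.calls) >= 3  # most of the 4 planted events
    assert set(res.calls["direction"]).issubset({"gain", "loss"})
    text = res.summary()
    assert "CNV calls" in text and "wt" in text
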