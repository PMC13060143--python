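import math

import numpy as np
import pandas as pd
import pytest

from regscreen.core import CountMatrix, FragmentSet, GenomicInterval, overlap_width
from regscreen.starr import (
    StarrParams,
    classify_regions,
    combine_region_pvalues,
    count_in_windows,
    filter_fragments,
    make_windows,
    merge_windows,
    run_starr_pipeline,
)
from regscreen.starr import test_windows as window_test


def _frags(rows):
    return FragmentSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "replicate"])
    )


class TestFilterFragments:
    def test_inclusive_bounds(self):
        fs = _frags(
            [("chr1", 0, L, "a", "rep1") for L in (100, 150, 500, 800, 900)]
        )
        kept = filter_fragments(fs, 150, 800)
        assert sorted(kept.lengths.tolist()) == [150, 500, 800]

    def test_empty_input(self):
        fs = _frags([])
        assert len(filter_fragments(fs)) == 0

    def test_all_in_range_identity(self):
        fs = _frags([("chr1", 0, 300, "a", "rep1"), ("chr1", 10, 500, "a", "rep1")])
        assert len(filter_fragments(fs)) == 2

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            filter_fragments(_frags([]), 800, 150)


class TestMakeWindows:
    def test_phase_anchored_enumeration(self):
        peaks = [GenomicInterval("chr1", 1000, 1100)]
        wins = make_windows(peaks, width=50, step=25)
        assert [w.start for w in wins] == [975, 1000, 1025, 1050, 1075]
        assert all(w.length == 50 for w in wins)

    def test_no_peaks(self):
        assert make_windows([], 50, 25) == []

    def test_narrow_peak_still_covered(self):
        peaks = [GenomicInterval("chr1", 1003, 1010)]
        wins = make_windows(peaks, width=50, step=25)
        assert len(wins) >= 1
        assert all(overlap_width(w, peaks[0]) >= 1 for w in wins)

    def test_all_windows_overlap_some_peak(self):
        peaks = [GenomicInterval("chr1", 130, 420), GenomicInterval("chr2", 77, 91)]
        wins = make_windows(peaks, 50, 25)
        for w in wins:
            assert any(overlap_width(w, p) >= 1 for p in peaks)

    def test_clipped_at_zero(self):
        wins = make_windows([GenomicInterval("chr1", 0, 30)], 50, 25)
        assert all(w.start >= 0 for w in wins)


class TestCountInWindows:
    def test_fragment_counted_in_every_overlapping_window(self):
        fs = _frags([("chr1", 0, 300, "a", "rep1")])
        wins = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 25, 75)]
        cm = count_in_windows(fs, wins)
        assert cm.values["a"].tolist() == [1, 1]

    def test_no_overlap_zero(self):
        fs = _frags([("chr1", 1000, 1200, "a", "rep1")])
        wins = [GenomicInterval("chr1", 0, 50)]
        cm = count_in_windows(fs, wins)
        assert cm.values["a"].tolist() == [0]

    def test_quadratic_oracle(self, rng):
        # 100 fragments x 50 windows vs brute-force all-pairs overlap
        frows = []
        for i in range(100):
            s = int(rng.integers(0, 2000))
            frows.append(("chr1", s, s + int(rng.integers(50, 400)),
                          "a" if i % 2 else "b", "rep1"))
        fs = _frags(frows)
        wins = [GenomicInterval("chr1", int(x), int(x) + 50)
                for x in rng.choice(np.arange(0, 2400, 25), size=50, replace=False)]
        cm = count_in_windows(fs, wins)
        for wi, w in enumerate(wins):
            for sample in ("a", "b"):
                sub = fs.frame[fs.frame["sample"] == sample]
                expected = sum(
                    1 for r in sub.itertuples()
                    if min(r.end, w.end) - max(r.start, w.start) > 0
                )
                assert cm.values.iloc[wi][sample] == expected

    def test_library_sizes_from_fragment_set(self):
        fs = _frags([("chr1", 0, 300, "a", "rep1"), ("chr5", 0, 300, "a", "rep1")])
        cm = count_in_windows(fs, [GenomicInterval("chr1", 0, 50)])
        assert cm.library_sizes["a"] == 2


def _null_counts(seed, n_windows=2000, depth=200, dispersion=0.05):
    rng = np.random.default_rng(seed)
    samples = ["input_rep1", "input_rep2", "rna_rep1", "rna_rep2", "rna_rep3"]
    mu = rng.gamma(5.0, depth / 5.0, size=n_windows)
    y = np.empty((n_windows, len(samples)), dtype=int)
    for j in range(len(samples)):
        lam = mu if dispersion == 0 else mu * rng.gamma(
            1 / dispersion, dispersion, size=n_windows
        )
        y[:, j] = rng.poisson(lam)
    ivs = [GenomicInterval("chr1", i * 50, i * 50 + 50) for i in range(n_windows)]
    cm = CountMatrix(
        ivs, pd.DataFrame(y, columns=samples),
        library_sizes=pd.Series(1e6, index=samples),
    )
    design = {s: ("input" if s.startswith("input") else "rna") for s in samples}
    return cm, design


class TestTestWindows:
    def test_identical_counts_give_zero_log2fc(self):
        samples = ["input_rep1", "input_rep2", "rna_rep1", "rna_rep2"]
        y = np.tile(np.array([[7], [13], [50]]), (1, 4))
        ivs = [GenomicInterval("chr1", i * 50, i * 50 + 50) for i in range(3)]
        cm = CountMatrix(ivs, pd.DataFrame(y, columns=samples),
                         library_sizes=pd.Series(100.0, index=samples))
        design = {s: ("input" if "input" in s else "rna") for s in samples}
        res = window_test(cm, design)["rna"]
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-6)
        np.testing.assert_allclose(res["pvalue"], 1.0, atol=1e-6)

    def test_null_type_i_calibration(self):
        cm, design = _null_counts(seed=11)
        res = window_test(cm, design)["rna"]
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.08

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(3)
        n = 2000
        samples = ["input_rep1", "input_rep2", "rna_rep1", "rna_rep2", "rna_rep3"]
        mu = np.full(n, 200.0)
        active = np.arange(n) < 300
        y = np.empty((n, len(samples)), dtype=int)
        for j, s in enumerate(samples):
            m = mu * np.where(active & s.startswith("rna"), 4.0, 1.0)
            y[:, j] = rng.poisson(m * rng.gamma(20, 0.05, size=n))
        ivs = [GenomicInterval("chr1", i * 50, i * 50 + 50) for i in range(n)]
        cm = CountMatrix(ivs, pd.DataFrame(y, columns=samples),
                         library_sizes=pd.Series(1e6, index=samples))
        design = {s: ("input" if "input" in s else "rna") for s in samples}
        res = window_test(cm, design)["rna"]
        assert abs(res["log2fc"].to_numpy()[active].mean() - 2.0) < 0.15

    def test_all_zero_windows_excluded(self):
        samples = ["input_rep1", "input_rep2", "rna_rep1"]
        y = np.array([[5, 6, 7], [0, 0, 0], [3, 2, 4]])
        ivs = [GenomicInterval("chr1", i * 50, i * 50 + 50) for i in range(3)]
        cm = CountMatrix(ivs, pd.DataFrame(y, columns=samples))
        design = {s: ("input" if "input" in s else "rna") for s in samples}
        res = window_test(cm, design)["rna"]
        assert res["window_index"].tolist() == [0, 2]

    def test_column_order_invariance(self):
        cm, design = _null_counts(seed=5, n_windows=200)
        res1 = window_test(cm, design)["rna"]
        perm = list(cm.values.columns)[::-1]
        cm2 = CountMatrix(cm.intervals, cm.values[perm],
                          library_sizes=cm.library_sizes[perm])
        res2 = window_test(cm2, design)["rna"]
        np.testing.assert_allclose(res1["pvalue"], res2["pvalue"], rtol=1e-8)
        np.testing.assert_allclose(res1["log2fc"], res2["log2fc"], rtol=1e-8)

    def test_global_depth_rescale_invariance(self):
        cm, design = _null_counts(seed=6, n_windows=200)
        res1 = window_test(cm, design)["rna"]
        cm2 = CountMatrix(cm.intervals, cm.values,
                          library_sizes=cm.library_sizes * 10)
        res2 = window_test(cm2, design)["rna"]
        # the abundance pseudocount makes this approximate, like aveLogCPM
        np.testing.assert_allclose(res1["log2fc"], res2["log2fc"], atol=1e-6)
        np.testing.assert_allclose(res1["pvalue"], res2["pvalue"], atol=0.01)

    def test_requires_two_input_reps(self):
        samples = ["input_rep1", "rna_rep1"]
        ivs = [GenomicInterval("chr1", 0, 50)]
        cm = CountMatrix(ivs, pd.DataFrame([[1, 2]], columns=samples))
        with pytest.raises(ValueError, match="input"):
            window_test(cm, {"input_rep1": "input", "rna_rep1": "rna"})


def _win(start, end=None, chrom="chr1"):
    return GenomicInterval(chrom, start, end if end is not None else start + 50)


class TestMergeWindows:
    def test_overlapping_merge(self):
        wins = [_win(100, 150), _win(125, 175)]
        assert merge_windows(wins) == [[0, 1]]

    def test_gap_one_splits_at_tolerance_zero(self):
        wins = [_win(100, 150), _win(151, 201)]
        assert merge_windows(wins, tolerance=0) == [[0], [1]]

    def test_abutting_merge_at_tolerance_zero(self):
        wins = [_win(100, 150), _win(150, 200)]
        assert merge_windows(wins, tolerance=0) == [[0, 1]]

    def test_max_width_split(self):
        # 200 abutting 50 bp windows at 25 bp step span 5,025 bp -> 2 clusters
        wins = [_win(i * 25) for i in range(200)]
        clusters = merge_windows(wins, tolerance=0, max_width=3000)
        assert len(clusters) == 2
        for c in clusters:
            span = wins[c[-1]].end - wins[c[0]].start
            assert span <= 3000
        assert sorted(i for c in clusters for i in c) == list(range(200))

    def test_chromosomes_not_merged(self):
        wins = [_win(0, 50, "chr1"), _win(0, 50, "chr2")]
        assert len(merge_windows(wins)) == 2


def _holm_oracle(p, w):
    """Independent weighted-Holm: for each hypothesis, direct definition."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i] / w[i])
    adj = {}
    running = 0.0
    for pos, i in enumerate(order):
        rem = sum(w[j] for j in order[pos:])
        val = min(1.0, p[i] * rem / w[i])
        running = max(running, val)
        adj[i] = running
    return [adj[i] for i in range(n)]


class TestCombineRegionPvalues:
    def test_hand_computed_unweighted_holm(self):
        p = np.array([0.001, 0.01, 0.2])
        fc = np.array([1.0, 2.0, 3.0])
        combined, _, _ = combine_region_pvalues(p, fc, min_sig_n=3)
        # Holm-adjusted: 0.003, 0.02, 0.2; k = 3 -> 0.2
        assert combined == pytest.approx(0.2)

    def test_single_window(self):
        combined, fc, _ = combine_region_pvalues(
            np.array([0.07]), np.array([1.5]), min_sig_n=3
        )
        assert combined == pytest.approx(0.07)
        assert fc == 1.5

    def test_brute_force_oracle_random_clusters(self, rng):
        for _ in range(500):
            n = 5
            p = rng.uniform(1e-6, 1, size=n)
            w = rng.uniform(0.5, 5, size=n)
            fc = rng.normal(size=n)
            min_sig_n = int(rng.integers(1, 5))
            combined, rep_fc, best = combine_region_pvalues(p, fc, w, min_sig_n)
            adj = _holm_oracle(list(p), list(w))
            k = min(n, max(min_sig_n, math.ceil(0.4 * n)))
            assert combined == pytest.approx(sorted(adj)[k - 1], rel=1e-12)
            best_oracle = min(range(n), key=lambda i: (adj[i], -abs(fc[i])))
            assert rep_fc == fc[best_oracle]

    def test_combined_never_below_min_member(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 9))
            p = rng.uniform(0, 1, size=n)
            fc = rng.normal(size=n)
            combined, _, _ = combine_region_pvalues(p, fc, min_sig_n=3)
            assert combined >= p.min() - 1e-15

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError):
            combine_region_pvalues(np.array([]), np.array([]))


class TestClassifyRegions:
    def test_bh_step_up_by_hand(self):
        df = pd.DataFrame(
            {"combined_p": [0.01, 0.02, 0.03, 0.04], "rep_log2fc": [1, 1, 1, 1]}
        )
        out = classify_regions(df)
        np.testing.assert_allclose(out["fdr"], 0.04)
        assert (out["class"] == "active").all()

    def test_all_p_one_no_actives(self):
        df = pd.DataFrame({"combined_p": [1.0] * 5, "rep_log2fc": [2.0] * 5})
        out = classify_regions(df)
        assert (out["class"] == "not-significant").all()

    def test_repressive_class(self):
        df = pd.DataFrame({"combined_p": [1e-8], "rep_log2fc": [-1.5]})
        out = classify_regions(df)
        assert out["class"].iloc[0] == "repressive"


class TestPipelineRecovery:
    def test_null_active_fraction_bounded(self):
        # no planted activity: active regions at FDR 0.05 stay rare
        from regscreen.simulate import (SimulationConfig, simulate_activity_truth,
                                        simulate_peaks, simulate_starr_experiment)

        total_active = 0
        total_regions = 0
        for seed in (0, 1, 2):
            peaks = simulate_peaks(600_000, n_peaks=30, width=500, seed=seed)
            truth = simulate_activity_truth(
                peaks, subsets=("rna",), proportions={"inactive": 1.0}, seed=seed
            )
            cfg = SimulationConfig(
                seed=seed, subsets=("rna",), depth=30_000,
                n_input_reps=2, n_output_reps=2,
            )
            frags = simulate_starr_experiment(peaks, truth, cfg)
            design = {s: ("input" if s.startswith("input") else "rna")
                      for s in frags.samples}
            out = run_starr_pipeline(frags, peaks, design)
            reg = out["regions"]["rna"]
            total_active += (reg["class"] != "not-significant").sum()
            total_regions += len(reg)
        assert total_active / total_regions <= 0.10

    def test_planted_recovery_and_fdr(self):
        from regscreen.simulate import (SimulationConfig, simulate_activity_truth,
                                        simulate_peaks, simulate_starr_experiment)

        peaks = simulate_peaks(2_000_000, n_peaks=100, width=500, seed=4)
        truth = simulate_activity_truth(
            peaks, subsets=("rna",),
            proportions={"inactive": 0.9, "subset-specific": 0.1}, seed=4
        )
        cfg = SimulationConfig(seed=4, subsets=("rna",), depth=50_000,
                               n_input_reps=2, n_output_reps=3, dispersion=0.0)
        frags = simulate_starr_experiment(peaks, truth, cfg)
        design = {s: ("input" if s.startswith("input") else "rna")
                  for s in frags.samples}
        out = run_starr_pipeline(frags, peaks, design)
        called = out["regions"]["rna"]
        called_active = called[called["class"] == "active"]
        active_truth = truth[truth["class"] == "subset-specific"]

        def hit(t):
            return ((called_active["start"] < t.end)
                    & (called_active["end"] > t.start)).any()

        sens = np.mean([hit(t) for t in active_truth.itertuples()])
        assert sens >= 0.8
        # empirical FDR among called actives
        false_calls = 0
        for r in called_active.itertuples():
            ov = (active_truth["start"] < r.end) & (active_truth["end"] > r.start)
            if not ov.any():
                false_calls += 1
        assert false_calls / max(len(called_active), 1) <= 0.10
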