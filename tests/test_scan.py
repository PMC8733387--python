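"""Tests of SNP indices, filtering, windows, thresholds and region calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bsamap as b
from bsamap.scan import ZeroDepthError, attach_thresholds, call_regions


class TestSnpIndex:
    @pytest.mark.parametrize(
        "alt, depth, expected",
        [(12, 12, 1.0), (0, 15, 0.0), (7, 20, 0.35)],
    )
    def test_boundary_and_interior_values(self, alt, depth, expected):
        assert b.compute_snp_index(alt, depth) == expected

    def test_zero_depth_is_an_error_not_zero(self):
        with pytest.raises(ZeroDepthError):
            b.compute_snp_index(0, 0)
        with pytest.raises(ZeroDepthError):
            b.compute_snp_index(np.array([3, 0]), np.array([10, 0]))

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            b.compute_snp_index(5, 3)

    @given(alt=st.integers(0, 60), depth=st.integers(1, 60))
    def test_index_in_unit_interval(self, alt, depth):
        if alt > depth:
            alt = depth
        assert 0.0 <= b.compute_snp_index(alt, depth) <= 1.0

    def test_delta_examples(self):
        assert b.delta_index(0.5, 0.5) == (0.0, 0.0)
        assert b.delta_index(1.0, 0.5) == (0.5, 0.5)
        assert b.delta_index(0.2, 0.9) == pytest.approx((-0.7, 0.7))

    def test_add_snp_indices_drops_zero_depth_rows(self):
        counts = pd.DataFrame(
            {
                "chrom": ["chr1"] * 2,
                "pos": [100, 200],
                "ref": "A",
                "alt": "T",
                "variant_type": "SNP",
                "refF": [10, 0],
                "altF": [5, 0],
                "refM": [8, 10],
                "altM": [2, 5],
            }
        )
        df = b.add_snp_indices(counts)
        assert len(df) == 1 and df.loc[0, "pos"] == 100
        assert df.loc[0, "abs_delta"] == pytest.approx(abs(5 / 15 - 2 / 10))


def index_record(indexF, indexM, depthF=30, depthM=30):
    return {
        "chrom": "chr1",
        "pos": 1000,
        "indexF": indexF,
        "indexM": indexM,
        "depthF": depthF,
        "depthM": depthM,
    }


class TestFilter:
    @pytest.mark.parametrize(
        "rec, kept",
        [
            (index_record(0.2, 0.25), False),  # both indices below 0.3
            (index_record(0.2, 0.9), True),  # only one bulk below 0.3
            (index_record(0.5, 0.5, depthF=6), False),  # one shallow bulk
            (index_record(0.5, 0.5, depthM=6), False),
            (index_record(0.3, 0.0), True),  # boundary: 0.3 is not < 0.3
            (index_record(0.5, 0.5, depthF=7, depthM=7), True),
        ],
    )
    def test_default_rule(self, rec, kept):
        out = b.filter_variants(pd.DataFrame([rec]), b.ScanConfig())
        assert (len(out) == 1) is kept

    def test_both_bulks_depth_rule(self):
        cfg = b.ScanConfig(depth_rule="both")
        one_shallow = pd.DataFrame([index_record(0.5, 0.5, depthF=6)])
        both_shallow = pd.DataFrame([index_record(0.5, 0.5, depthF=6, depthM=6)])
        assert len(b.filter_variants(one_shallow, cfg)) == 1
        assert len(b.filter_variants(both_shallow, cfg)) == 0


class TestScanConfig:
    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            b.ScanConfig(window_bp=100, step_bp=200)

    def test_bad_levels_rejected(self):
        with pytest.raises(ValueError):
            b.ScanConfig(conf_levels=(0.95, 1.0))


def records_at(positions, abs_deltas, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "abs_delta": abs_deltas,
            "depthF": 30,
            "depthM": 30,
        }
    )


class TestSlidingWindows:
    def test_window_mean_of_two_variants(self):
        recs = records_at([500_000, 1_500_000], [0.2, 0.6])
        w = b.sliding_windows(recs, {"chr1": 4_000_000}, b.ScanConfig())
        first = w.iloc[0]
        assert (first["start"], first["end"]) == (1, 2_000_001)
        assert first["n_variants"] == 2
        assert first["mean_abs_delta"] == pytest.approx(0.4)

    def test_empty_windows_have_no_statistic(self):
        recs = records_at([500_000], [0.3])
        w = b.sliding_windows(recs, {"chr1": 10_000_000}, b.ScanConfig())
        empty = w[w["n_variants"] == 0]
        assert len(empty) > 0 and empty["mean_abs_delta"].isna().all()

    def test_single_variant_window_reproduces_its_value(self):
        recs = records_at([500_000], [0.37])
        w = b.sliding_windows(recs, {"chr1": 2_000_000}, b.ScanConfig())
        hit = w[w["n_variants"] == 1]
        assert (hit["mean_abs_delta"] == 0.37).all()

    def test_windows_tile_every_chromosome(self):
        cfg = b.ScanConfig(window_bp=2_000_000, step_bp=100_000)
        w = b.sliding_windows(records_at([1], [0.1]), {"chr1": 5_000_000}, cfg)
        assert list(w["start"]) == list(range(1, 5_000_001, 100_000))
        assert (w["end"] <= 5_000_001).all()  # terminal windows truncated

    def test_unsorted_records_rejected(self):
        recs = records_at([2000, 1000], [0.1, 0.2])
        with pytest.raises(ValueError):
            b.sliding_windows(recs, {"chr1": 10_000}, b.ScanConfig())


class TestBootstrapThresholds:
    def test_degenerate_null_gives_zero_thresholds(self):
        """With the read probability forced to 0 both bulks always return
        identical (all-reference) counts, so the null |Δ| is exactly 0."""
        cfg = b.ScanConfig(null_model="read_only", null_p=0.0, n_bootstrap=200, seed=1)
        t = b.bootstrap_thresholds([10, 30], cfg)
        assert all(qs == (0.0, 0.0) for qs in t.table.values())

    def test_depth_one_symmetric_read_null(self):
        """At depth 1 with read probability 1/2, |Δ| is Bernoulli(1/2)
        (enumerating the four read outcomes), so the 99% quantile is 1."""
        cfg = b.ScanConfig(null_model="read_only", null_p=0.5, n_bootstrap=1000, seed=3)
        t = b.bootstrap_thresholds([1], cfg)
        assert t.quantile(1, 0.99) == 1.0

    def test_thresholds_shrink_with_depth(self):
        """Binomial proportions concentrate with depth, so deep thresholds
        sit below shallow ones (averaged over 20 table rebuilds)."""
        q5, q50 = [], []
        for seed in range(20):
            t = b.bootstrap_thresholds([5, 50], b.ScanConfig(n_bootstrap=500, seed=seed))
            q5.append(t.quantile(5, 0.99))
            q50.append(t.quantile(50, 0.99))
        assert np.mean(q50) < np.mean(q5)

    def test_quantiles_ordered_and_in_unit_interval(self):
        t = b.bootstrap_thresholds(range(7, 60), b.ScanConfig(n_bootstrap=300, seed=0))
        for q95, q99 in t.table.values():
            assert 0.0 <= q95 <= q99 <= 1.0

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            b.bootstrap_thresholds([0], b.ScanConfig())


def window_frame(stats, thr=0.3):
    n = len(stats)
    starts = np.arange(1, n * 100_000 + 1, 100_000)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + 100_000,
            "n_variants": 1,
            "mean_abs_delta": stats,
            "thr95": thr,
            "thr99": thr,
        }
    )


class TestCallRegions:
    def test_run_of_marked_windows_merges(self):
        w = window_frame([0.1, 0.5, 0.6, 0.1])
        regions = call_regions(w, 0.99)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert (r["start"], r["end"]) == (100_001, 300_001)
        assert r["peak_value"] == pytest.approx(0.6)

    def test_no_window_above_threshold(self):
        assert call_regions(window_frame([0.1, 0.2]), 0.99).empty

    def test_single_marked_window_is_a_region(self):
        regions = call_regions(window_frame([0.1, 0.9, 0.1]), 0.95)
        assert len(regions) == 1 and regions.iloc[0]["n_windows"] == 1

    def test_separate_runs_stay_separate(self):
        regions = call_regions(window_frame([0.9, 0.1, 0.1, 0.9]), 0.99)
        assert len(regions) == 2

    def test_empty_windows_never_contribute(self):
        w = window_frame([0.9, np.nan, 0.9])
        w.loc[1, "n_variants"] = 0
        regions = call_regions(w, 0.99)
        assert len(regions) == 2

    def test_unknown_level_rejected(self):
        with pytest.raises(KeyError):
            call_regions(window_frame([0.1]), 0.5)


class TestScanEndToEnd:
    def test_region_calls_invariant_under_pseudoexchange(self, demo_experiment):
        """Bit-identical candidate regions before and after arbitrary
        ref/alt relabelling: the scan statistic is |Δ|.  The low-index
        variant filter is disabled here because it keys on the labelling
        (an index of 0.9 in both bulks becomes 0.1 after a flip), so exact
        invariance holds for the scan statistic, not for that filter."""
        e = demo_experiment
        cfg = b.ScanConfig(n_bootstrap=300, seed=5, min_index=0.0)
        flipped = b.apply_pseudoexchange(e.counts, 0.37, seed=21)
        r1 = b.scan(e.counts, e.genome.chrom_lengths, cfg)
        r2 = b.scan(flipped, e.genome.chrom_lengths, cfg)
        for level in cfg.conf_levels:
            pd.testing.assert_frame_equal(r1.regions[level], r2.regions[level])
        pd.testing.assert_frame_equal(r1.windows, r2.windows)

    def test_record_invariants(self, demo_experiment):
        e = demo_experiment
        cfg = b.ScanConfig(n_bootstrap=200, seed=2)
        res = b.scan(e.counts, e.genome.chrom_lengths, cfg)
        rec = res.records
        assert rec["indexF"].between(0, 1).all() and rec["indexM"].between(0, 1).all()
        assert rec["delta"].between(-1, 1).all()
        np.testing.assert_array_equal(rec["abs_delta"], rec["delta"].abs())

    def test_planted_locus_recovered(self, demo_experiment):
        e = demo_experiment
        res = b.scan(e.counts, e.genome.chrom_lengths, b.ScanConfig(seed=4))
        regions = res.regions[0.99]
        chrom, pos = e.genome.sex_locus
        assert (
            (regions["chrom"] == chrom) & (regions["start"] <= pos) & (regions["end"] > pos)
        ).any()

    def test_variant_thresholds_keyed_by_shallower_depth(self, demo_experiment):
        e = demo_experiment
        cfg = b.ScanConfig(n_bootstrap=100, seed=0)
        df = b.filter_variants(b.add_snp_indices(e.counts), cfg)
        out, table = attach_thresholds(df, cfg)
        eff = np.minimum(out["depthF"], out["depthM"])
        expected = [table.quantile(d, 0.99) for d in eff]
        np.testing.assert_array_equal(out["thr99"], expected)
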