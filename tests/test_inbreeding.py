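import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sbg
from sbg.config import MISSING

from conftest import make_dataset
from _oracles import roh_segments_bruteforce


class TestFis:
    def test_fully_homozygous_individual_is_one(self):
        # S4 is homozygous everywhere; others carry hets so L > E_hom
        ds = make_dataset(
            [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 0, 2]]
        )
        recs = {r.sample: r for r in sbg.f_is(ds)}
        assert recs["S4"].fis == pytest.approx(1.0)

    def test_hand_computed_three_snp_example(self):
        # literal arithmetic oracle, written out step by step
        calls = np.array(
            [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 0, 2], [1, 2, MISSING]],
            dtype=np.int8,
        )
        ds = make_dataset(calls)
        p = []
        n = []
        for j in range(3):
            col = [c for c in calls[:, j] if c != MISSING]
            n.append(len(col))
            p.append(sum(col) / (2 * len(col)))
        e_term = [
            1 - 2 * pj * (1 - pj) * nj / (nj - 1) for pj, nj in zip(p, n)
        ]
        for i, rec in enumerate(sbg.f_is(ds)):
            nonmiss = [j for j in range(3) if calls[i, j] != MISSING]
            o_hom = sum(1 for j in nonmiss if calls[i, j] in (0, 2))
            e_hom = sum(e_term[j] for j in nonmiss)
            L = len(nonmiss)
            expected = np.clip((o_hom - e_hom) / (L - e_hom), -1, 1)
            assert rec.fis == pytest.approx(float(expected))
            assert rec.o_hom == o_hom and rec.n_snps == L

    def test_low_count_snps_skipped_with_warning(self):
        calls = np.array([[0, 1], [1, MISSING]], dtype=np.int8)
        with pytest.warns(UserWarning, match="n < 2"):
            recs = sbg.f_is(make_dataset(calls))
        assert all(r.n_snps <= 1 for r in recs)


def _roh_args(rng, n_snps, n_ind):
    """Random genotype panel with planted homozygous stretches and gaps."""
    n_chrom = int(rng.integers(1, 4))
    chrom, pos = [], []
    counters = {}
    for j in range(n_snps):
        c = str(1 + j % n_chrom)
        gap = int(rng.choice([20_000, 40_000, 1_500_000], p=[0.6, 0.35, 0.05]))
        counters[c] = counters.get(c, 0) + gap
        chrom.append(c)
        pos.append(counters[c])
    calls = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8),
        size=(n_ind, n_snps),
        p=[0.25, 0.4, 0.25, 0.1],
    )
    # plant homozygous stretches (with rare isolated hets/missing)
    for i in range(n_ind):
        for _ in range(int(rng.integers(0, 4))):
            a = int(rng.integers(0, n_snps))
            b = min(n_snps, a + int(rng.integers(20, 120)))
            calls[i, a:b] = rng.choice(np.array([0, 2], dtype=np.int8))
            for k in rng.integers(a, max(a + 1, b), size=int(rng.integers(0, 3))):
                calls[i, int(k)] = rng.choice(
                    np.array([1, MISSING], dtype=np.int8)
                )
    return calls, np.array(chrom, dtype=object), np.array(pos)


class TestDetectRoh:
    def test_all_heterozygous_no_segments(self):
        ds = make_dataset(np.ones((1, 200), dtype=np.int8))
        assert sbg.detect_roh(ds) == []

    def test_fully_homozygous_single_segment_first_to_last(self):
        pos = list(np.linspace(25_000, 3_000_000, 120).astype(int))
        ds = make_dataset(np.zeros((1, 120), dtype=np.int8), pos=pos)
        segs = sbg.detect_roh(ds)
        assert len(segs) == 1
        assert (segs[0].start_bp, segs[0].end_bp) == (pos[0], pos[-1])
        assert segs[0].n_snps == 120

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_bruteforce_oracle_on_fuzzed_panels(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_snps = int(rng.integers(30, 900))
        n_ind = int(rng.integers(1, 6))
        calls, chrom, pos = _roh_args(rng, n_snps, n_ind)
        ds = make_dataset(calls, chrom=list(chrom), pos=list(pos))
        got = sorted(
            (s.sample, s.chrom, s.start_bp, s.end_bp, s.n_snps)
            for s in sbg.detect_roh(ds)
        )
        want = sorted(
            (ds.samples[i],) + seg
            for i in range(n_ind)
            for seg in roh_segments_bruteforce(calls[i], chrom, pos)
        )
        assert got == want

    def test_short_chromosome_single_truncated_window(self):
        # 10 SNPs < window 30: one verdict for the whole chromosome
        pos = list(np.linspace(10_000, 4_000_000, 10).astype(int))
        ds = make_dataset(np.zeros((1, 10), dtype=np.int8), pos=pos)
        segs = sbg.detect_roh(ds, min_snps=5)
        assert len(segs) == 1 and segs[0].n_snps == 10


class TestFroh:
    def test_examples(self):
        assert sbg.f_roh([], samples=["A"]).loc["A"] == 0.0
        seg = sbg.RohSegment("A", "1", 1000, 2_242_960_000 + 1000, 99)
        assert sbg.f_roh([seg]).loc["A"] == pytest.approx(1.0)
        seg = sbg.RohSegment("A", "1", 1000, int(44_859.2 * 1000) + 1000, 99)
        assert sbg.f_roh([seg]).loc["A"] == pytest.approx(0.02)

    def test_overlength_raises(self):
        seg = sbg.RohSegment("A", "1", 0, 3_000_000_000, 99)
        with pytest.raises(ValueError):
            sbg.f_roh([seg])

    def test_long_roh_subset_of_short(self, rng):
        cfg = sbg.SimulationConfig(
            seed=31, n_chromosomes=2, total_kb=80_000, n_snps=2400,
            cohort_years=8, cohort_size=40, skew_start=0.3, skew_end=0.9,
        )
        res = sbg.simulate_temporal_cohorts(cfg)
        short = sbg.detect_roh(res.dataset, min_kb=1000)
        long = sbg.detect_roh(res.dataset, min_kb=5000)
        f_short = sbg.f_roh(short, samples=res.dataset.samples, l_auto_kb=cfg.total_kb)
        f_long = sbg.f_roh(long, samples=res.dataset.samples, l_auto_kb=cfg.total_kb)
        assert (f_long <= f_short + 1e-12).all()


class TestRohPrevalence:
    def test_no_segments_all_zero(self):
        ds = make_dataset(np.ones((3, 5), dtype=np.int8))
        pct, table = sbg.roh_prevalence([], ds)
        assert np.all(pct == 0)

    def test_full_coverage_hundred_percent(self):
        ds = make_dataset(np.zeros((4, 5), dtype=np.int8))
        segs = [sbg.RohSegment(s, "1", 1000, 5000, 5) for s in ds.samples]
        pct, table = sbg.roh_prevalence(segs, ds)
        assert np.all(pct == 100.0)

    def test_partial_coverage_counted(self):
        ds = make_dataset(np.zeros((10, 3), dtype=np.int8))
        segs = [sbg.RohSegment(s, "1", 900, 1100, 1) for s in ds.samples[:3]]
        pct, table = sbg.roh_prevalence(segs, ds, top_n=2)
        assert pct[0] == pytest.approx(30.0)
        assert pct[1] == 0.0
        assert table.iloc[0]["pct_in_roh"] == pytest.approx(30.0)
        assert len(table) == 2


def _records(values, samples=None):
    samples = samples or [f"S{i}" for i in range(len(values))]
    return pd.Series(values, index=samples, dtype=float)


def _meta(samples, yob=None, region=None):
    meta = sbg.GenotypeDataset.empty_meta(samples)
    if yob is not None:
        meta["yob"] = yob
    if region is not None:
        meta["region"] = region
    return meta


class TestAnnualTrend:
    def test_constant_measure_zero_slope_guard(self):
        vals = _records([0.1] * 6)
        meta = _meta(vals.index, yob=[2000, 2000, 2001, 2001, 2002, 2002])
        res = sbg.annual_trend(vals, meta)
        assert res.slope == 0 and res.r2 == 0 and res.p_value == 1

    def test_exactly_linear_annual_means_r2_one(self):
        vals = _records([0.1, 0.2, 0.3, 0.4])
        meta = _meta(vals.index, yob=[2000, 2001, 2002, 2003])
        res = sbg.annual_trend(vals, meta)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.1)

    def test_ci_contains_mean_and_year_filter(self):
        rng = np.random.default_rng(0)
        vals = _records(rng.normal(0.2, 0.01, 40))
        meta = _meta(vals.index, yob=[2000 + i % 5 for i in range(40)])
        res = sbg.annual_trend(vals, meta, min_year=2001, max_year=2004)
        assert list(res.annual["year"]) == [2001, 2002, 2003, 2004]
        assert (res.annual["ci_low"] <= res.annual["mean"]).all()
        assert (res.annual["ci_high"] >= res.annual["mean"]).all()

    def test_fewer_than_three_years_raises(self):
        vals = _records([0.1, 0.2])
        meta = _meta(vals.index, yob=[2000, 2001])
        with pytest.raises(ValueError):
            sbg.annual_trend(vals, meta)


class TestRegionTtest:
    def test_identical_distributions_t_zero(self):
        vals = _records([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        meta = _meta(vals.index, region=["A"] * 3 + ["B"] * 3)
        row = sbg.region_ttest(vals, meta).iloc[0]
        assert row["t"] == pytest.approx(0.0) and row["p_value"] == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        a, b = [0.1, 0.2, 0.3], [0.3, 0.4, 0.5]
        vals = _records(a + b)
        meta = _meta(vals.index, region=["A"] * 3 + ["B"] * 3)
        row = sbg.region_ttest(vals, meta).iloc[0]
        # textbook pooled t on 3+3 values
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_hand = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        assert row["t"] == pytest.approx(t_hand)
        assert row["df"] == 4
        assert row["p_value"] == pytest.approx(p_hand)

    def test_swapping_groups_flips_sign(self):
        vals = _records([0.1, 0.2, 0.3, 0.5, 0.6, 0.7])
        meta1 = _meta(vals.index, region=["A"] * 3 + ["B"] * 3)
        meta2 = _meta(vals.index, region=["B"] * 3 + ["A"] * 3)
        r1 = sbg.region_ttest(vals, meta1).iloc[0]
        r2 = sbg.region_ttest(vals, meta2).iloc[0]
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p_value"] == pytest.approx(r2["p_value"])

    def test_small_region_skipped(self):
        vals = _records([0.1, 0.2, 0.3, 0.4, 0.9])
        meta = _meta(vals.index, region=["A", "A", "B", "B", "C"])
        with pytest.warns(UserWarning, match="skipped"):
            table = sbg.region_ttest(vals, meta)
        assert set(table["region_a"]) | set(table["region_b"]) == {"A", "B"}


class TestPerformanceCorrelation:
    def test_affine_transform_r_one(self):
        f = _records([0.1, 0.2, 0.3, 0.4])
        res = sbg.performance_correlation(f, 5 + 2 * f)
        assert res.r == pytest.approx(1.0)

    def test_sign_flip_negates_r(self):
        rng = np.random.default_rng(1)
        f = _records(rng.random(20))
        ratings = pd.Series(rng.random(20), index=f.index)
        r1 = sbg.performance_correlation(f, ratings)
        r2 = sbg.performance_correlation(f, -ratings)
        assert r1.r == pytest.approx(-r2.r)

    def test_missing_ratings_dropped_and_counted(self):
        f = _records([0.1, 0.2, 0.3, 0.4, 0.5])
        ratings = pd.Series([1.0, np.nan, 3.0, 4.0, 5.0], index=f.index)
        res = sbg.performance_correlation(f, ratings)
        assert res.n_used == 4 and res.n_dropped == 1

    def test_null_simulation_small_r(self):
        rng = np.random.default_rng(2)
        f = _records(rng.random(1000))
        res = sbg.performance_correlation(f, pd.Series(rng.random(1000), index=f.index))
        assert abs(res.r) < 0.1

    def test_zero_variance_raises(self):
        f = _records([0.1, 0.1, 0.1])
        with pytest.raises(ValueError):
            sbg.performance_correlation(f, pd.Series([1.0, 2.0, 3.0], index=f.index))
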