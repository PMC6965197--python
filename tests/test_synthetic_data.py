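import dataclasses

import numpy as np
import pytest
from scipy import stats

import sbg
from sbg.config import MISSING

WF_SMALL = dict(
    n_chromosomes=3, total_kb=60_000, n_snps=600, pop_size=80, sample_size=None,
    generations=5, burn_in_generations=3,
)


class TestDeterminism:
    def test_wright_fisher_seed_reproducible(self):
        cfg = sbg.SimulationConfig(seed=7, **WF_SMALL)
        a = sbg.simulate_wright_fisher(cfg)
        b = sbg.simulate_wright_fisher(cfg)
        assert np.array_equal(a.selected.calls, b.selected.calls)
        assert np.array_equal(a.haplotypes_reference, b.haplotypes_reference)

    def test_cohorts_seed_reproducible(self):
        cfg = sbg.SimulationConfig(
            seed=7, n_chromosomes=2, total_kb=40_000, n_snps=800,
            cohort_years=4, cohort_size=30, burn_in_years=2,
        )
        a = sbg.simulate_temporal_cohorts(cfg)
        b = sbg.simulate_temporal_cohorts(cfg)
        assert np.array_equal(a.dataset.calls, b.dataset.calls)
        assert a.pedigree.equals(b.pedigree)


class TestWrightFisher:
    def test_output_dimensions_match_config(self):
        cfg = sbg.SimulationConfig(seed=1, **{**WF_SMALL, "sample_size": 40})
        res = sbg.simulate_wright_fisher(cfg)
        assert res.selected.n_samples == 40
        assert res.reference.n_samples == 40
        assert res.selected.n_snps == cfg.n_snps
        assert res.haplotypes_selected.shape == (80, cfg.n_snps)

    def test_drift_only_frequency_change_is_small(self):
        # Var(dp) ~ p(1-p) t/(2N): with N=1000, t=5 the mean |dp| stays tiny
        cfg = sbg.SimulationConfig(
            seed=2, n_chromosomes=3, total_kb=60_000, n_snps=400,
            pop_size=1000, sample_size=None, generations=5, burn_in_generations=2,
        )
        res = sbg.simulate_wright_fisher(cfg)
        p_sel = res.haplotypes_selected.mean(axis=0)
        p_ref = res.haplotypes_reference.mean(axis=0)
        assert np.abs(p_sel - p_ref).mean() < 0.05

    def test_selection_raises_favoured_allele_frequency(self):
        wins = 0
        for seed in range(10):
            cfg = sbg.SimulationConfig(
                seed=seed, n_chromosomes=2, total_kb=50_000, n_snps=300,
                pop_size=150, sample_size=None, generations=40,
                burn_in_generations=3, s=0.1, selected_loci=(150,),
            )
            res = sbg.simulate_wright_fisher(cfg)
            if (
                res.haplotypes_selected[:, 150].mean()
                > res.haplotypes_reference[:, 150].mean()
            ):
                wins += 1
        assert wins >= 9

    def test_maf_floor_respected_after_thinning(self):
        cfg = sbg.SimulationConfig(seed=3, **WF_SMALL, maf_floor=0.1)
        res = sbg.simulate_wright_fisher(cfg)
        # the floor is enforced on the ancestral pool; post-split drift in 5
        # generations cannot push far below it
        p = np.concatenate(
            [res.haplotypes_selected, res.haplotypes_reference]
        ).mean(axis=0)
        assert np.minimum(p, 1 - p).min() > 0.02

    def test_generated_dataset_round_trips_through_ped(self, tmp_path):
        cfg = sbg.SimulationConfig(seed=4, **WF_SMALL)
        res = sbg.simulate_wright_fisher(cfg)
        sbg.write_plink_text(res.selected, tmp_path / "s.ped", tmp_path / "s.map")
        back = sbg.read_plink_text(tmp_path / "s.ped", tmp_path / "s.map")
        assert back.equals(res.selected)

    def test_selected_locus_out_of_range_raises(self):
        cfg = sbg.SimulationConfig(seed=1, **WF_SMALL, s=0.1, selected_loci=(10**6,))
        with pytest.raises(ValueError):
            sbg.simulate_wright_fisher(cfg)


class TestHalfSibFamily:
    def test_homozygous_sire_fixed_dam_pool_all_bb(self):
        fam = sbg.simulate_half_sib_family(
            np.full(50, 2, dtype=np.int8), np.ones(50), n_offspring=12, seed=0
        )
        assert np.all(fam.offspring.calls == 2)

    def test_error_free_offspring_share_a_sire_allele(self, rng):
        L = 400
        sire = rng.integers(0, 3, L).astype(np.int8)
        p = rng.uniform(0.1, 0.9, L)
        fam = sbg.simulate_half_sib_family(sire, p, n_offspring=30, seed=1)
        calls = fam.offspring.calls
        # a sire AA cannot produce BB offspring and vice versa
        assert not np.any(calls[:, sire == 0] == 2)
        assert not np.any(calls[:, sire == 2] == 0)

    def test_het_sire_offspring_distribution_matches_model(self):
        # sire AB, p = 0.5 -> offspring (AA, AB, BB) ~ (0.25, 0.5, 0.25)
        fam = sbg.simulate_half_sib_family(
            np.ones(1, dtype=np.int8), np.array([0.5]), n_offspring=10_000, seed=2
        )
        counts = np.bincount(fam.offspring.calls[:, 0], minlength=3)
        res = stats.chisquare(counts, f_exp=[2500, 5000, 2500])
        assert res.pvalue > 0.01

    def test_error_and_missing_rates_applied(self):
        L = 2000
        sire = np.zeros(L, dtype=np.int8)
        fam = sbg.simulate_half_sib_family(
            sire, np.zeros(L), n_offspring=10, error_rate=0.1, missing_rate=0.2, seed=3
        )
        calls = fam.offspring.calls
        assert np.isclose((calls == MISSING).mean(), 0.2, atol=0.02)
        observed = calls[calls != MISSING]
        assert np.isclose((observed != 0).mean(), 0.1, atol=0.02)


class TestTemporalCohorts:
    def test_metadata_year_range_equals_span(self):
        cfg = sbg.SimulationConfig(
            seed=5, n_chromosomes=2, total_kb=40_000, n_snps=600,
            cohort_years=6, cohort_size=25, burn_in_years=2, start_year=2000,
        )
        res = sbg.simulate_temporal_cohorts(cfg)
        years = res.dataset.meta["yob"].astype(int)
        assert years.min() == 2000 and years.max() == 2005
        assert res.dataset.n_samples == 6 * 25

    def test_pedigree_truth_recorded(self):
        cfg = sbg.SimulationConfig(
            seed=5, n_chromosomes=2, total_kb=40_000, n_snps=400,
            cohort_years=3, cohort_size=20, burn_in_years=1,
        )
        res = sbg.simulate_temporal_cohorts(cfg)
        assert set(res.pedigree.columns) >= {"sample", "sire", "dam", "yob", "sex"}
        assert len(res.true_froh) == res.dataset.n_samples
        assert ((res.true_froh >= 0) & (res.true_froh <= 1)).all()

    def test_zero_skew_null_slope_within_two_se(self):
        cfg = sbg.SimulationConfig(
            seed=11, n_chromosomes=2, total_kb=80_000, n_snps=2400,
            cohort_years=10, cohort_size=80, skew_start=0.0, skew_end=0.0,
        )
        res = sbg.simulate_temporal_cohorts(cfg)
        trend = sbg.annual_trend(sbg.f_is(res.dataset), res.dataset.meta, "fis")
        assert abs(trend.slope) <= 2 * trend.slope_se

    def test_rising_skew_raises_froh(self):
        positives = 0
        for seed in range(5):
            cfg = sbg.SimulationConfig(
                seed=seed, n_chromosomes=2, total_kb=80_000, n_snps=2400,
                cohort_years=10, cohort_size=80, skew_start=0.0, skew_end=0.9,
            )
            res = sbg.simulate_temporal_cohorts(cfg)
            segs = sbg.detect_roh(res.dataset)
            froh = sbg.f_roh(segs, samples=res.dataset.samples, l_auto_kb=cfg.total_kb)
            if sbg.annual_trend(froh, res.dataset.meta, "froh").slope > 0:
                positives += 1
        assert positives >= 4

    def test_heterozygosity_declines_when_skew_rises(self):
        def late_het(skew_end, seed):
            cfg = sbg.SimulationConfig(
                seed=seed, n_chromosomes=2, total_kb=60_000, n_snps=1500,
                cohort_years=10, cohort_size=60, skew_start=0.0, skew_end=skew_end,
            )
            res = sbg.simulate_temporal_cohorts(cfg)
            late = res.dataset.meta["yob"] >= res.dataset.meta["yob"].max() - 2
            return (res.dataset.calls[late.to_numpy()] == 1).mean()

        seeds = range(3)
        het_skew = np.mean([late_het(0.9, s) for s in seeds])
        het_null = np.mean([late_het(0.0, s) for s in seeds])
        assert het_skew < het_null

    def test_requires_two_years(self):
        with pytest.raises(ValueError):
            sbg.simulate_temporal_cohorts(sbg.SimulationConfig(cohort_years=1))


class TestImplantRoh:
    def _flat_dataset(self, rng, L=300, spacing_bp=20_000):
        # ~50 SNP/Mb map on one chromosome, all-het individual
        calls = np.ones((1, L), dtype=np.int8)
        pos = np.arange(1, L + 1) * spacing_bp
        from conftest import make_dataset

        return make_dataset(calls, chrom=["1"] * L, pos=list(pos))

    def test_implanted_region_has_no_hets(self, rng):
        ds = self._flat_dataset(rng)
        out, record = sbg.implant_roh(ds, "S1", "1", 1000, 3000)
        pos = out.snp_map["pos"].to_numpy()
        inside = (pos >= 1_000_000) & (pos <= 3_000_000)
        assert not np.any(out.calls[0, inside] == 1)
        assert record["n_snps"] == inside.sum()

    def test_detector_recovers_implanted_boundaries(self, rng):
        # 2 Mb implant on a 50 SNP/Mb map: boundary error < one spacing
        ds = self._flat_dataset(rng, L=500)
        out, _ = sbg.implant_roh(ds, "S1", "1", 3000, 5000)
        segs = sbg.detect_roh(out)
        assert len(segs) == 1
        seg = segs[0]
        assert abs(seg.start_bp - 3_000_000) <= 20_000
        assert abs(seg.end_bp - 5_000_000) <= 20_000

    def test_froh_monotone_in_implanted_length(self, rng):
        ds = self._flat_dataset(rng, L=500)
        frohs = []
        for end in (3000, 5000, 8000):
            out, _ = sbg.implant_roh(ds, "S1", "1", 1000, end)
            segs = sbg.detect_roh(out)
            froh = sbg.f_roh(segs, samples=["S1"], l_auto_kb=10_000)
            frohs.append(float(froh["S1"]))
        assert frohs[0] < frohs[1] < frohs[2]

    def test_empty_interval_raises(self, rng):
        ds = self._flat_dataset(rng, L=10)
        with pytest.raises(ValueError):
            sbg.implant_roh(ds, "S1", "1", 50_000, 60_000)
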