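"""Synthetic genotype generators with full ground truth.

Every downstream stage of the pipeline is exercised on data from this
module: two-population Wright-Fisher drift with optional selective sweeps
(for the selection scan and Ne estimation), half-sib families (for sire
reconstruction), temporal cohorts with a programmable sire-popularity skew
(for the inbreeding-trend machinery) and direct implantation of autozygous
segments (for ROH detection).

Model notes
-----------
* Haplotypes are simulated explicitly; genotype datasets are built by
  pairing haplotypes, so phased output is always available.
* Recombination: uniform 1 Morgan per 100 Mb (Haldane map function);
  chromosomes assort independently.
* Chromosome lengths follow a fixed declining profile summing to the
  configured total; SNP positions are uniform per chromosome, then sorted.
* Genotyping error is a symmetric code flip - adequate for concordance
  testing, not an array-specific intensity model.
* All randomness flows through one integer-seeded ``numpy`` Generator, so a
  fixed seed reproduces outputs exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .config import MISSING
from .io_core import AlleleFrequencyTable, GenotypeDataset

__all__ = [
    "SimulationConfig",
    "WrightFisherResult",
    "CohortResult",
    "FamilyResult",
    "genome_map",
    "simulate_wright_fisher",
    "simulate_half_sib_family",
    "simulate_temporal_cohorts",
    "implant_roh",
]

#: Morgans per Mb (1 Morgan / 100 Mb, horse-scale uniform approximation).
MORGAN_PER_MB = 0.01


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of every generator.  Defaults are the study-scale conditions
    (31 horse autosomes totalling 2,242,960 kb, MAF floor 0.05, selection
    over 40 generations in populations of 100 diploids); tests and examples
    pass scaled-down genomes through the same fields."""

    seed: int = 0
    # genome
    n_chromosomes: int = 31
    total_kb: float = 2_242_960.0
    n_snps: int = 9000
    maf_floor: float = 0.05
    # Wright-Fisher two-population scenario
    pop_size: int = 300                # diploids per population
    sample_size: int | None = 100      # diploids sampled per population (None: all)
    generations: int = 40              # post-split generations
    burn_in_generations: int = 10      # ancestral-pool generations before thinning
    s: float = 0.0                     # genic selection coefficient (1+s per copy)
    selected_loci: tuple[int, ...] = ()  # indices into the final SNP panel
    #: when set, each selected locus is snapped to the nearest panel SNP
    #: whose pool minor-allele frequency lies in this band, so the sweep
    #: starts from rare standing variation (the classic implanted-sweep
    #: scenario) instead of an arbitrary-frequency allele
    sweep_maf_band: tuple[float, float] | None = None
    max_sweep_retries: int = 20
    # half-sib family
    n_offspring: int = 20
    error_rate: float = 0.0
    missing_rate: float = 0.0
    # temporal cohorts
    cohort_years: int = 12
    cohort_size: int = 100
    start_year: int = 1996
    burn_in_years: int = 8
    skew_start: float = 0.0            # fraction of matings routed to top sires
    skew_end: float = 0.0
    top_sires: int = 2
    dam_recruit: float = 0.75          # P(dam from previous cohort vs outside base)
    regions: tuple[str, ...] = ("EUR", "ANZ", "NAM")


@dataclasses.dataclass
class WrightFisherResult:
    selected: GenotypeDataset
    reference: GenotypeDataset
    haplotypes_selected: np.ndarray     # (2N, L) uint8, B-allele indicators
    haplotypes_reference: np.ndarray
    chrom: np.ndarray                   # per-SNP chromosome label (str)
    pos: np.ndarray                     # per-SNP bp
    selected_loci: tuple[int, ...]
    selected_positions: tuple[tuple[str, int], ...]
    retries: int = 0


@dataclasses.dataclass
class FamilyResult:
    offspring: GenotypeDataset
    sire_truth: np.ndarray              # the sire genotype vector used
    clean_calls: np.ndarray             # offspring codes before error/missingness


@dataclasses.dataclass
class CohortResult:
    dataset: GenotypeDataset
    pedigree: pd.DataFrame              # sample, sire, dam, yob, sex, region
    true_froh: pd.Series                # per-sample autozygous genome fraction
    total_kb: float


# ---------------------------------------------------------------------------
# Genome map and recombination machinery
# ---------------------------------------------------------------------------


def genome_map(
    n_chromosomes: int,
    total_kb: float,
    n_snps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Chromosome labels and sorted bp positions for ``n_snps`` SNPs.

    Chromosome lengths follow the declining profile w_i = n - i + 3
    (normalised to ``total_kb``); SNP counts are allocated proportionally
    (largest-remainder) and positions drawn uniformly without duplicates.
    """
    w = np.array([n_chromosomes - i + 3.0 for i in range(1, n_chromosomes + 1)])
    lengths_kb = total_kb * w / w.sum()
    exact = n_snps * w / w.sum()
    counts = np.floor(exact).astype(int)
    rem = n_snps - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:rem]] += 1

    chroms: list[str] = []
    positions: list[np.ndarray] = []
    lengths: dict[str, float] = {}
    for i in range(n_chromosomes):
        label = str(i + 1)
        lengths[label] = float(lengths_kb[i])
        k = int(counts[i])
        len_bp = max(int(lengths_kb[i] * 1000), k + 1)
        pos = np.unique(rng.integers(1, len_bp + 1, size=2 * k + 8))
        while len(pos) < k:  # pragma: no cover - astronomically rare top-up
            pos = np.unique(
                np.concatenate([pos, rng.integers(1, len_bp + 1, size=2 * k)])
            )
        pos = np.sort(rng.choice(pos, size=k, replace=False))
        chroms.extend([label] * k)
        positions.append(pos)
    return np.array(chroms, dtype=object), np.concatenate(positions) if positions else np.array([], dtype=np.int64), lengths


def _recomb_probs(chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Per-gap recombination fraction (Haldane), 0.5 across chromosome
    boundaries; entry 0 is the random-start probability 0.5."""
    L = len(pos)
    r = np.empty(L)
    r[0] = 0.5
    if L > 1:
        d_morgan = np.diff(pos) / 1e6 * MORGAN_PER_MB
        r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
        r[1:][chrom[1:] != chrom[:-1]] = 0.5
    return r


def _gametes(
    haps: np.ndarray,
    parents: np.ndarray,
    rec: np.ndarray,
    rng: np.random.Generator,
    ancestry: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """One recombinant gamete per parent index.  ``haps`` holds individual
    ``i``'s haplotypes at rows ``2i`` and ``2i+1``.  If ``ancestry`` is
    given the same crossover masks are applied to it (founder-segment
    tracking)."""
    hap_a = haps[2 * parents]
    hap_b = haps[2 * parents + 1]
    cross = rng.random((len(parents), len(rec)), dtype=np.float32) < rec[None, :].astype(np.float32)
    phase = np.cumsum(cross, axis=1, dtype=np.int32) & 1
    out = np.where(phase == 0, hap_a, hap_b)
    anc_out = None
    if ancestry is not None:
        anc_out = np.where(phase == 0, ancestry[2 * parents], ancestry[2 * parents + 1])
    return out, anc_out


def _evolve(
    haps: np.ndarray,
    n_generations: int,
    rec: np.ndarray,
    rng: np.random.Generator,
    sel_idx: np.ndarray | None = None,
    s: float = 0.0,
) -> np.ndarray:
    """Wright-Fisher evolution of a diploid population (constant size).
    With selection, parents are drawn with weight (1+s) per copy of the
    selected (B) allele across ``sel_idx`` loci."""
    n = haps.shape[0] // 2
    for _ in range(n_generations):
        if sel_idx is not None and len(sel_idx) and s != 0.0:
            dosage = (haps[0::2][:, sel_idx] + haps[1::2][:, sel_idx]).sum(axis=1)
            w = (1.0 + s) ** dosage.astype(float)
            prob = w / w.sum()
            parents = rng.choice(n, size=2 * n, p=prob)
        else:
            parents = rng.integers(0, n, size=2 * n)
        haps, _ = _gametes(haps, parents, rec, rng)
    return haps


def _dataset_from_haps(
    haps: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    prefix: str,
    region: str | None = None,
) -> GenotypeDataset:
    n = haps.shape[0] // 2
    calls = (haps[0::2] + haps[1::2]).astype(np.int8)
    samples = [f"{prefix}{i + 1:04d}" for i in range(n)]
    snps = [f"snp_{c}_{p}" for c, p in zip(chrom, pos)]
    meta = GenotypeDataset.empty_meta(samples)
    if region is not None:
        meta["region"] = region
    return GenotypeDataset.from_arrays(
        samples, snps, calls, chrom=chrom, pos=pos,
        allele_a=["A"] * len(snps), allele_b=["B"] * len(snps), meta=meta,
    )


# ---------------------------------------------------------------------------
# Two-population Wright-Fisher with optional sweeps
# ---------------------------------------------------------------------------


def simulate_wright_fisher(config: SimulationConfig) -> WrightFisherResult:
    """A common ancestral haplotype pool drifts into two descendant
    populations; loci in ``config.selected_loci`` evolve under genic
    selection (weight 1+s per copy) in the *selected* population only.

    The ancestral pool is evolved for ``burn_in_generations`` and then
    thinned to SNPs with pool MAF >= ``maf_floor`` (evenly subsampled down
    to ``n_snps``).  At each selected locus the allele coding is oriented
    so the favoured B allele is the pool-minor allele - a sweep from low
    frequency, the classic design.  If a selected allele is lost before
    the final generation the selected population is re-drawn up to
    ``max_sweep_retries`` times, then an error is raised.

    The output datasets (and the returned phased haplotypes) hold a random
    sample of ``sample_size`` diploids per population, so sampling noise
    and drift scale can be controlled separately.
    """
    rng = np.random.default_rng(config.seed)
    n_init = int(np.ceil(config.n_snps * 1.6)) + 32
    chrom0, pos0, _ = genome_map(config.n_chromosomes, config.total_kb, n_init, rng)
    rec0 = _recomb_probs(chrom0, pos0)

    p0 = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=n_init)
    pool = (rng.random((2 * config.pop_size, n_init)) < p0[None, :]).astype(np.uint8)
    pool = _evolve(pool, config.burn_in_generations, rec0, rng)

    freq = pool.mean(axis=0)
    ok = np.flatnonzero(
        (np.minimum(freq, 1 - freq) >= config.maf_floor)
    )
    if len(ok) < config.n_snps:
        raise RuntimeError(
            f"only {len(ok)} SNPs survive the MAF floor; increase the panel margin"
        )
    keep = ok[np.round(np.linspace(0, len(ok) - 1, config.n_snps)).astype(int)]
    pool = pool[:, keep]
    chrom, pos = chrom0[keep], pos0[keep]
    rec = _recomb_probs(chrom, pos)

    sel_idx = np.asarray(config.selected_loci, dtype=np.intp)
    if len(sel_idx) and (sel_idx.min() < 0 or sel_idx.max() >= config.n_snps):
        raise ValueError("selected locus index outside the SNP panel")
    if len(sel_idx) and config.sweep_maf_band is not None:
        lo, hi = config.sweep_maf_band
        freq_kept = pool.mean(axis=0)
        maf_kept = np.minimum(freq_kept, 1 - freq_kept)
        eligible = np.flatnonzero((maf_kept >= lo) & (maf_kept <= hi))
        if len(eligible) == 0:
            raise ValueError("no panel SNP has pool MAF in sweep_maf_band")
        sel_idx = np.array(
            [eligible[np.argmin(np.abs(eligible - i))] for i in sel_idx],
            dtype=np.intp,
        )
    # favoured allele starts as the pool-minor allele (coding flip only)
    for i in sel_idx:
        if pool[:, i].mean() > 0.5:
            pool[:, i] = 1 - pool[:, i]

    reference = _evolve(pool.copy(), config.generations, rec, rng)

    retries = 0
    while True:
        selected = _evolve(
            pool.copy(), config.generations, rec, rng, sel_idx=sel_idx, s=config.s
        )
        if not len(sel_idx) or np.all(selected[:, sel_idx].mean(axis=0) > 0):
            break
        retries += 1
        if retries > config.max_sweep_retries:
            raise RuntimeError("selected allele lost in every retry")

    k = config.sample_size
    if k is not None and k < config.pop_size:
        sub_sel = np.sort(rng.choice(config.pop_size, size=k, replace=False))
        sub_ref = np.sort(rng.choice(config.pop_size, size=k, replace=False))
        hap_rows = lambda sub: np.stack([2 * sub, 2 * sub + 1], axis=1).ravel()
        selected_out = selected[hap_rows(sub_sel)]
        reference_out = reference[hap_rows(sub_ref)]
    else:
        selected_out, reference_out = selected, reference

    return WrightFisherResult(
        selected=_dataset_from_haps(selected_out, chrom, pos, "SEL", region="selected"),
        reference=_dataset_from_haps(reference_out, chrom, pos, "REF", region="reference"),
        haplotypes_selected=selected_out,
        haplotypes_reference=reference_out,
        chrom=chrom,
        pos=pos,
        selected_loci=tuple(int(i) for i in sel_idx),
        selected_positions=tuple((str(chrom[i]), int(pos[i])) for i in sel_idx),
        retries=retries,
    )


# ---------------------------------------------------------------------------
# Half-sib families
# ---------------------------------------------------------------------------


def simulate_half_sib_family(
    sire_genotype: np.ndarray,
    freqs: AlleleFrequencyTable | np.ndarray,
    n_offspring: int = 20,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    chrom: Sequence[str] | None = None,
    pos: Sequence[int] | None = None,
) -> FamilyResult:
    """Mendelian half-sib offspring of one sire: each offspring receives one
    fair draw from the sire's two alleles and one dam allele Bernoulli(p)
    per SNP (dams random under HWE at the population frequencies).
    Genotyping error flips a call to a uniformly chosen different code with
    probability ``error_rate``; missingness is applied last."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = freqs.p if isinstance(freqs, AlleleFrequencyTable) else np.asarray(freqs, float)
    sire = np.asarray(sire_genotype, dtype=np.int8)
    L = len(sire)
    if len(p) != L:
        raise ValueError("freqs must cover all SNPs")

    # sire allele: 0 for code 0, 1 for code 2, fair coin for hets
    coin = rng.random((n_offspring, L)) < 0.5
    sire_allele = np.where(
        sire[None, :] == 1, coin.astype(np.int8), (sire[None, :] // 2).astype(np.int8)
    )
    dam_allele = (rng.random((n_offspring, L)) < p[None, :]).astype(np.int8)
    clean = (sire_allele + dam_allele).astype(np.int8)

    calls = clean.copy()
    if error_rate > 0:
        err = rng.random(calls.shape) < error_rate
        # flip to one of the two other codes, uniformly
        shift = rng.integers(1, 3, size=calls.shape).astype(np.int8)
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate, MISSING, calls)

    if chrom is None or pos is None:
        chrom = np.array(["1"] * L, dtype=object)
        pos = np.arange(1, L + 1, dtype=np.int64) * 1000
    samples = [f"OFF{i + 1:04d}" for i in range(n_offspring)]
    snps = [f"snp_{c}_{q}" for c, q in zip(chrom, pos)]
    ds = GenotypeDataset.from_arrays(
        samples, snps, calls, chrom=chrom, pos=pos,
        allele_a=["A"] * L, allele_b=["B"] * L,
    )
    return FamilyResult(offspring=ds, sire_truth=sire, clean_calls=clean)


# ---------------------------------------------------------------------------
# Temporal cohorts with sire-popularity skew
# ---------------------------------------------------------------------------


def simulate_temporal_cohorts(config: SimulationConfig) -> CohortResult:
    """Yearly cohorts whose sires come from the previous cohort with a
    programmable popularity skew.

    Each year a fraction ``skew(t)`` of matings (rising linearly from
    ``skew_start`` to ``skew_end`` over the recorded span) is routed to a
    small set of ``top_sires`` popular males of the previous cohort; the
    remainder are sired uniformly.  Dams are recruited from the previous
    cohort with probability ``dam_recruit`` and otherwise drawn from an
    effectively unlimited outside base population at the founder allele
    frequencies (the broad mare population surrounding the genotyped
    slice).  The outside gene inflow makes the zero-skew process stationary
    - cohorts are exchangeable, so no inbreeding trend - while rising skew
    concentrates paternal ancestry, producing consanguineous matings,
    autozygous segments and a genuine upward F_IS / F_ROH trend.

    Founder-segment ancestry is propagated through the same crossovers, so
    the result carries each individual's *true* autozygous genome fraction.
    """
    if config.cohort_years < 2:
        raise ValueError("need at least 2 cohort years")
    rng = np.random.default_rng(config.seed)
    chrom, pos, _ = genome_map(
        config.n_chromosomes, config.total_kb, config.n_snps, rng
    )
    rec = _recomb_probs(chrom, pos)
    L = config.n_snps
    N = config.cohort_size
    p0 = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=L)

    anc_counter = [0]

    def base_haps(k: int) -> tuple[np.ndarray, np.ndarray]:
        h = (rng.random((k, L)) < p0[None, :]).astype(np.uint8)
        a = np.arange(anc_counter[0], anc_counter[0] + k, dtype=np.int64)
        anc_counter[0] += k
        return h, np.repeat(a[:, None], L, axis=1)

    total_years = config.burn_in_years + config.cohort_years
    haps, anc = base_haps(2 * N)
    sex = np.where(rng.random(N) < 0.5, "M", "F")
    ids = [f"Y00_{i + 1:04d}" for i in range(N)]

    rows: list[dict] = []
    all_calls: list[np.ndarray] = []
    all_ids: list[str] = []
    froh_true: list[float] = []

    for t in range(1, total_years):
        males = np.flatnonzero(sex == "M")
        females = np.flatnonzero(sex == "F")
        if len(males) == 0:
            males = np.arange(N)
        if len(females) == 0:
            females = np.arange(N)
        rec_t = t - config.burn_in_years  # recorded-year index (may be <0)
        if config.cohort_years > 1:
            frac = min(max(rec_t, 0), config.cohort_years - 1) / (config.cohort_years - 1)
        else:
            frac = 0.0
        skew = config.skew_start + (config.skew_end - config.skew_start) * frac

        popular = rng.choice(males, size=min(config.top_sires, len(males)), replace=False)
        to_top = rng.random(N) < skew
        sires = np.where(
            to_top,
            rng.choice(popular, size=N),
            rng.choice(males, size=N),
        )
        dam_from_cohort = rng.random(N) < config.dam_recruit
        dams = rng.choice(females, size=N)

        pat_h, pat_a = _gametes(haps, sires, rec, rng, ancestry=anc)
        mat_h, mat_a = _gametes(haps, dams, rec, rng, ancestry=anc)
        base_h, base_a = base_haps(N)
        mat_h = np.where(dam_from_cohort[:, None], mat_h, base_h)
        mat_a = np.where(dam_from_cohort[:, None], mat_a, base_a)

        new_ids = [f"Y{t:02d}_{i + 1:04d}" for i in range(N)]
        new_sex = np.where(rng.random(N) < 0.5, "M", "F")
        if rec_t >= 0:
            calls = (pat_h + mat_h).astype(np.int8)
            auto = (pat_a == mat_a).mean(axis=1)
            yob = config.start_year + rec_t
            regions = rng.choice(np.array(config.regions, dtype=object), size=N)
            for i in range(N):
                rows.append(
                    {
                        "sample": new_ids[i],
                        "sire": ids[sires[i]],
                        "dam": ids[dams[i]] if dam_from_cohort[i] else f"BASE_{t:02d}_{i}",
                        "yob": yob,
                        "sex": str(new_sex[i]),
                        "region": str(regions[i]),
                    }
                )
            all_calls.append(calls)
            all_ids.extend(new_ids)
            froh_true.extend(float(a) for a in auto)

        new_haps = np.empty_like(haps)
        new_anc = np.empty_like(anc)
        new_haps[0::2], new_haps[1::2] = pat_h, mat_h
        new_anc[0::2], new_anc[1::2] = pat_a, mat_a
        haps, anc, sex, ids = new_haps, new_anc, new_sex, new_ids

    ped = pd.DataFrame(rows)
    snps = [f"snp_{c}_{q}" for c, q in zip(chrom, pos)]
    meta = pd.DataFrame(
        {
            "sire": ped["sire"].to_numpy(),
            "dam": ped["dam"].to_numpy(),
            "sex": ped["sex"].to_numpy(),
            "yob": ped["yob"].to_numpy(float),
            "region": ped["region"].to_numpy(),
        },
        index=pd.Index(all_ids, name="sample"),
    )
    ds = GenotypeDataset.from_arrays(
        all_ids, snps, np.vstack(all_calls), chrom=chrom, pos=pos,
        allele_a=["A"] * L, allele_b=["B"] * L, meta=meta,
    )
    return CohortResult(
        dataset=ds,
        pedigree=ped,
        true_froh=pd.Series(froh_true, index=all_ids, name="true_froh"),
        total_kb=config.total_kb,
    )


# ---------------------------------------------------------------------------
# ROH implantation
# ---------------------------------------------------------------------------


def implant_roh(
    dataset: GenotypeDataset,
    individual: str,
    chromosome: str,
    start_kb: float,
    end_kb: float,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeDataset, dict]:
    """Force one individual homozygous over [start_kb, end_kb] on a
    chromosome by copying one haplotype over the other: each heterozygous
    call in the interval becomes a homozygote, the side chosen by a fair
    coin per SNP (the phase is unobserved).  Missing calls stay missing.
    Raises if the interval contains no SNPs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i = dataset.sample_indices([individual])[0]
    m = dataset.snp_map
    in_ival = (
        (m["chrom"].to_numpy(dtype=object) == str(chromosome))
        & (m["pos"].to_numpy() >= start_kb * 1000)
        & (m["pos"].to_numpy() <= end_kb * 1000)
    )
    if not in_ival.any():
        raise ValueError(
            f"no SNPs on chromosome {chromosome} in [{start_kb}, {end_kb}] kb"
        )
    calls = dataset.calls.copy()
    row = calls[i]
    het = in_ival & (row == 1)
    row[het] = 2 * (rng.random(int(het.sum())) < 0.5).astype(np.int8)
    calls[i] = row
    new = GenotypeDataset(
        samples=list(dataset.samples),
        snps=list(dataset.snps),
        calls=calls,
        snp_map=dataset.snp_map.copy(),
        meta=dataset.meta.copy(),
    )
    record = {
        "individual": individual,
        "chrom": str(chromosome),
        "start_kb": float(start_kb),
        "end_kb": float(end_kb),
        "n_snps": int(in_ival.sum()),
    }
    return new, record
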