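"""Per-individual genomic inbreeding and its temporal/contrast statistics.

Two measures are computed: F_IS, the deficit of observed heterozygosity
relative to Hardy-Weinberg expectation at the *pooled* sample allele
frequencies (the ``--het`` convention: expected homozygosity carries the
n/(n-1) small-sample factor), and F_ROH, the fraction of the autosomal
genome covered by runs of homozygosity (ROH) found by a PLINK
``--homozyg``-style sliding-window scan.  Trend machinery regresses annual
means on year of birth; region contrasts use Student's t; performance
correlation is a plain Pearson test.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import config
from .config import MISSING
from .io_core import GenotypeDataset, allele_frequencies

__all__ = [
    "InbreedingRecord",
    "RohSegment",
    "TrendResult",
    "CorrelationResult",
    "f_is",
    "detect_roh",
    "f_roh",
    "roh_prevalence",
    "annual_trend",
    "region_ttest",
    "performance_correlation",
    "records_frame",
]


@dataclasses.dataclass
class InbreedingRecord:
    """Per-individual inbreeding summary.

    ``fis`` = (O_hom - E_hom) / (L - E_hom) over the individual's L
    non-missing usable SNPs; ``froh`` = L_ROH / L_AUTO when ROH results have
    been attached (NaN otherwise)."""

    sample: str
    n_snps: int
    o_hom: float
    e_hom: float
    fis: float
    l_roh_kb: float = np.nan
    froh: float = np.nan


@dataclasses.dataclass(frozen=True)
class RohSegment:
    """One homozygous run: bp interval of the first/last SNP (inclusive)."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


@dataclasses.dataclass
class TrendResult:
    """Annual means of an inbreeding measure and the OLS fit on year."""

    annual: pd.DataFrame  # year, n, mean, sd, se, ci_low, ci_high
    slope: float
    intercept: float
    r2: float
    p_value: float
    slope_se: float


@dataclasses.dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_used: int
    n_dropped: int


def records_frame(records: Iterable[InbreedingRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------


def f_is(dataset: GenotypeDataset) -> list[InbreedingRecord]:
    """Method-of-moments individual inbreeding coefficient against the
    pooled sample frequencies.

    Per SNP j with frequency p_j and non-missing count n_j, the expected
    homozygosity contribution is 1 - 2 p_j q_j n_j/(n_j - 1); SNPs with
    n_j < 2 are skipped (counted in a warning).  F = (O - E)/(L - E),
    clamped to [-1, 1].
    """
    freq = allele_frequencies(dataset)
    usable = freq.n >= 2
    n_skipped = int((~usable).sum())
    if n_skipped:
        warnings.warn(f"skipping {n_skipped} SNPs with n < 2", stacklevel=2)
    p = freq.p[usable]
    n = freq.n[usable]
    e_term = 1.0 - 2.0 * p * (1.0 - p) * n / (n - 1.0)
    calls = dataset.calls[:, usable]
    present = calls != MISSING
    hom = present & (calls != 1)

    records = []
    o_hom = hom.sum(axis=1).astype(float)
    e_hom = (present * e_term[None, :]).sum(axis=1)
    L = present.sum(axis=1).astype(float)
    denom = L - e_hom
    for i, sample in enumerate(dataset.samples):
        if denom[i] == 0:
            raise ZeroDivisionError(
                f"L equals E_hom for sample {sample!r}; F_IS undefined"
            )
        f = float(np.clip((o_hom[i] - e_hom[i]) / denom[i], -1.0, 1.0))
        records.append(
            InbreedingRecord(sample, int(L[i]), float(o_hom[i]), float(e_hom[i]), f)
        )
    return records


# ---------------------------------------------------------------------------
# ROH detection (PLINK --homozyg style)
# ---------------------------------------------------------------------------


def detect_roh(
    dataset: GenotypeDataset,
    min_kb: float = config.ROH_MIN_KB,
    min_snps: int = config.ROH_MIN_SNPS,
    max_gap_kb: float = config.ROH_MAX_GAP_KB,
    max_density_kb_per_snp: float = config.ROH_MAX_DENSITY_KB_PER_SNP,
    window_snps: int = config.ROH_WINDOW_SNPS,
    window_het: int = config.ROH_WINDOW_HET,
    window_missing: int = config.ROH_WINDOW_MISSING,
    hit_fraction: float = config.ROH_HIT_FRACTION,
) -> list[RohSegment]:
    """Sliding-window homozygosity scan per individual per chromosome.

    A window of ``window_snps`` is homozygous if it has <= ``window_het``
    heterozygous and <= ``window_missing`` missing calls.  A SNP is a *hit*
    if >= ``hit_fraction`` of the windows containing it are homozygous.
    Maximal runs of consecutive hit SNPs are split at inter-SNP gaps
    > ``max_gap_kb`` and kept when length > ``min_kb``, SNP count >=
    ``min_snps`` and mean spacing <= ``max_density_kb_per_snp``.  A
    chromosome with fewer than ``window_snps`` SNPs is scanned with a
    single truncated window covering it.
    """
    segments: list[RohSegment] = []
    gap_bp = max_gap_kb * 1000.0
    for chrom, grp in dataset.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        M = len(idx)
        calls = dataset.calls[:, idx]
        het = calls == 1
        mis = calls == MISSING
        if M <= window_snps:
            hom = (het.sum(axis=1) <= window_het) & (mis.sum(axis=1) <= window_missing)
            hit = np.repeat(hom[:, None], M, axis=1)
        else:
            W = M - window_snps + 1
            cs_het = np.zeros((het.shape[0], M + 1), dtype=np.int32)
            cs_mis = np.zeros_like(cs_het)
            np.cumsum(het, axis=1, out=cs_het[:, 1:])
            np.cumsum(mis, axis=1, out=cs_mis[:, 1:])
            het_win = cs_het[:, window_snps:] - cs_het[:, :W]
            mis_win = cs_mis[:, window_snps:] - cs_mis[:, :W]
            hom = (het_win <= window_het) & (mis_win <= window_missing)
            cs_hom = np.zeros((hom.shape[0], W + 1), dtype=np.int32)
            np.cumsum(hom, axis=1, out=cs_hom[:, 1:])
            j = np.arange(M)
            lo = np.maximum(0, j - window_snps + 1)
            hi = np.minimum(j, W - 1) + 1
            n_win = (hi - lo).astype(float)
            n_hom = cs_hom[:, hi] - cs_hom[:, lo]
            hit = n_hom / n_win[None, :] >= hit_fraction

        for i, sample in enumerate(dataset.samples):
            h = hit[i]
            if not h.any():
                continue
            bounds = np.flatnonzero(np.diff(np.concatenate(([0], h.view(np.int8), [0]))))
            for a, b in zip(bounds[0::2], bounds[1::2]):  # [a, b) hit run
                run = np.arange(a, b)
                gaps = np.diff(pos[run])
                cut = np.flatnonzero(gaps > gap_bp) + 1
                for piece in np.split(run, cut):
                    length_kb = (pos[piece[-1]] - pos[piece[0]]) / 1000.0
                    k = len(piece)
                    if (
                        length_kb > min_kb
                        and k >= min_snps
                        and length_kb / k <= max_density_kb_per_snp
                    ):
                        segments.append(
                            RohSegment(
                                sample,
                                str(chrom),
                                int(pos[piece[0]]),
                                int(pos[piece[-1]]),
                                k,
                            )
                        )
    return segments


def f_roh(
    segments: Sequence[RohSegment],
    samples: Sequence[str] | None = None,
    l_auto_kb: float = config.L_AUTO_KB,
) -> pd.Series:
    """F_ROH = L_ROH / L_AUTO per sample: summed ROH length over the
    autosomal genome length.  ``samples`` lists individuals that should
    appear with F_ROH = 0 when they have no segment."""
    totals: dict[str, float] = {s: 0.0 for s in (samples or [])}
    for seg in segments:
        totals[seg.sample] = totals.get(seg.sample, 0.0) + seg.length_kb
    out = pd.Series(totals, dtype=float, name="froh") / l_auto_kb
    if (out > 1.0).any():
        bad = out.idxmax()
        raise ValueError(
            f"L_ROH exceeds the autosomal length for {bad!r}: overlapping segments?"
        )
    return out.sort_index()


def roh_prevalence(
    segments: Sequence[RohSegment],
    dataset: GenotypeDataset,
    top_n: int = 1000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Percentage of individuals with each SNP inside a ROH, plus the
    ``top_n`` SNPs ranked by that percentage (ties broken by map order)."""
    chrom = dataset.snp_map["chrom"].to_numpy(dtype=object)
    pos = dataset.snp_map["pos"].to_numpy()
    covered = np.zeros((dataset.n_samples, dataset.n_snps), dtype=bool)
    sample_row = {s: i for i, s in enumerate(dataset.samples)}
    for seg in segments:
        i = sample_row[seg.sample]
        mask = (chrom == seg.chrom) & (pos >= seg.start_bp) & (pos <= seg.end_bp)
        covered[i] |= mask
    pct = 100.0 * covered.sum(axis=0) / max(dataset.n_samples, 1)
    order = np.lexsort((np.arange(dataset.n_snps), -pct))[:top_n]
    table = pd.DataFrame(
        {
            "snp": [dataset.snps[i] for i in order],
            "chrom": chrom[order],
            "pos": pos[order],
            "pct_in_roh": pct[order],
        }
    )
    return pct, table


# ---------------------------------------------------------------------------
# Trend and contrast statistics
# ---------------------------------------------------------------------------


def _measure_series(
    records: Sequence[InbreedingRecord] | pd.DataFrame | pd.Series,
    measure: str,
) -> pd.Series:
    if isinstance(records, pd.Series):
        return records
    frame = records if isinstance(records, pd.DataFrame) else records_frame(records)
    return frame.set_index("sample")[measure]


def annual_trend(
    records: Sequence[InbreedingRecord] | pd.DataFrame | pd.Series,
    meta: pd.DataFrame,
    measure: str = "fis",
    min_year: int | None = None,
    max_year: int | None = None,
) -> TrendResult:
    """Annual mean/SD/SE/95% CI of an inbreeding measure by year of birth,
    and the unweighted OLS regression of annual means on year.

    The CI is mean +/- 1.96 SE (normal multiplier).  Slope P is two-sided
    from t with (n_years - 2) df; a zero-variance response returns slope 0,
    R^2 = 0, P = 1.  Requires >= 3 distinct years in range.
    """
    values = _measure_series(records, measure)
    yob = meta.loc[values.index, "yob"].astype(float)
    keep = yob.notna()
    if min_year is not None:
        keep &= yob >= min_year
    if max_year is not None:
        keep &= yob <= max_year
    values, yob = values[keep], yob[keep]
    grouped = values.groupby(yob.astype(int))
    annual = grouped.agg(["size", "mean", "std"]).rename(
        columns={"size": "n", "std": "sd"}
    )
    if len(annual) < 3:
        raise ValueError(f"need >= 3 distinct years, got {len(annual)}")
    annual["se"] = annual["sd"] / np.sqrt(annual["n"])
    annual["ci_low"] = annual["mean"] - 1.96 * annual["se"]
    annual["ci_high"] = annual["mean"] + 1.96 * annual["se"]
    annual = annual.reset_index(names="year")

    x = annual["year"].to_numpy(float)
    y = annual["mean"].to_numpy(float)
    if np.ptp(y) == 0 or np.allclose(np.var(y), 0):
        return TrendResult(annual, 0.0, float(y[0]), 0.0, 1.0, np.nan)
    fit = stats.linregress(x, y)
    return TrendResult(
        annual,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        slope_se=float(fit.stderr),
    )


def region_ttest(
    records: Sequence[InbreedingRecord] | pd.DataFrame | pd.Series,
    meta: pd.DataFrame,
    measure: str = "fis",
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sided Student's t-test of an inbreeding measure between
    geographic regions, on individual-level values (pooled variance by
    default, Welch by flag).  Regions with < 2 records are skipped."""
    values = _measure_series(records, measure)
    region = meta.loc[values.index, "region"]
    groups: dict[str, np.ndarray] = {}
    for name, vals in values.groupby(region):
        if len(vals) < 2:
            warnings.warn(f"region {name!r} has <2 records; skipped", stacklevel=2)
            continue
        groups[str(name)] = vals.to_numpy(float)
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 regions with >= 2 records each")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = stats.ttest_ind(groups[a], groups[b], equal_var=not welch)
            if welch:
                va, vb = groups[a].var(ddof=1), groups[b].var(ddof=1)
                na, nb = len(groups[a]), len(groups[b])
                df = (va / na + vb / nb) ** 2 / (
                    (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
                )
            else:
                df = len(groups[a]) + len(groups[b]) - 2
            rows.append(
                {
                    "region_a": a,
                    "region_b": b,
                    "t": float(res.statistic),
                    "df": float(df),
                    "p_value": float(res.pvalue),
                }
            )
    return pd.DataFrame(rows)


def performance_correlation(
    f_values: pd.Series | Sequence[float],
    ratings: pd.Series | Sequence[float],
) -> CorrelationResult:
    """Pearson correlation of inbreeding against a performance rating,
    two-sided P via the t transform on n - 2 df.  Pairs with a missing
    value on either side are dropped (and counted)."""
    f = pd.Series(f_values, dtype=float)
    r = pd.Series(ratings, dtype=float)
    if isinstance(f_values, pd.Series) and isinstance(ratings, pd.Series):
        r = r.reindex(f.index)
    if len(f) != len(r):
        raise ValueError("unpaired inputs")
    ok = f.notna().to_numpy() & r.notna().to_numpy()
    n_dropped = int((~ok).sum())
    x, y = f.to_numpy(float)[ok], r.to_numpy(float)[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        float(res.statistic), float(res.pvalue), int(len(x)), n_dropped
    )
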