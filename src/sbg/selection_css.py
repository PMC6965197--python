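"""Composite selection signal (CSS) scan.

Three constituent contrasts between a selected and a reference population -
Wright's two-group FST, the change in selected allele frequency (dSAF) and
cross-population extended haplotype homozygosity (XP-EHH) - are combined
per SNP through fractional ranks: each statistic is ranked genome-wide,
ranks map to (0,1) fractional ranks r' = rank/(n+1), to z = Phi^-1(r'),
and the mean z across the m tests gets a one-sided upper-tail P from
N(0, 1/m); CSS = -log10 P.  CSS is then averaged over 1 Mb windows, the
top 1% of the smoothed statistic is clustered into candidate selected
regions, and genes within +/-0.5 Mb are attached.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import config
from .io_core import GeneTable, GenotypeDataset, allele_frequencies, _chrom_sort_key

__all__ = [
    "SelectionRegion",
    "fst_per_snp",
    "delta_saf",
    "xp_ehh",
    "composite_score",
    "smooth_css",
    "top_tier",
    "call_regions",
    "map_genes",
    "css_scan",
]


@dataclasses.dataclass
class SelectionRegion:
    """A called cluster of top-ranked SNPs."""

    chrom: str
    start_bp: int
    end_bp: int
    n_top_snps: int
    top_css: float
    genes: list[str] = dataclasses.field(default_factory=list)


def _paired_freqs(
    selected: GenotypeDataset, reference: GenotypeDataset
) -> tuple[np.ndarray, np.ndarray]:
    if selected.snps != reference.snps:
        raise ValueError("selected and reference datasets must share the SNP panel")
    p1 = allele_frequencies(selected).p
    p2 = allele_frequencies(reference).p
    return p1, p2


def fst_per_snp(
    selected: GenotypeDataset, reference: GenotypeDataset
) -> np.ndarray:
    """Two-group Wright FST per SNP: Var(p; divisor 2) / (p_bar q_bar) with
    p_bar the unweighted mean of the two sample frequencies.  SNPs that are
    monomorphic overall get 0; SNPs missing in one group get NaN (flagged,
    excluded from ranking)."""
    p1, p2 = _paired_freqs(selected, reference)
    pbar = 0.5 * (p1 + p2)
    var = 0.25 * (p1 - p2) ** 2  # two-value variance with divisor 2
    denom = pbar * (1.0 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom > 0, var / np.where(denom > 0, denom, 1.0), 0.0)
    fst = np.where(np.isnan(p1) | np.isnan(p2), np.nan, fst)
    return fst


def delta_saf(
    selected: GenotypeDataset, reference: GenotypeDataset
) -> np.ndarray:
    """Change in selected allele frequency.  Per SNP, the tracked allele is
    the one at higher frequency in the selected than in the reference
    population; dSAF = p_sel - p_ref of that allele (>= 0; exact ties give
    0).  SNPs missing in one group get NaN."""
    p1, p2 = _paired_freqs(selected, reference)
    return np.abs(p1 - p2)


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------


def _ehh_integrals_chrom(
    haps: np.ndarray, pos: np.ndarray, floor: float
) -> np.ndarray:
    """EHH integral for every core SNP of one chromosome.

    EHH(core -> x) is the probability that two distinct random haplotypes
    are identical over every SNP in [core, x]; per core the trapezoidal
    integral of EHH over bp distance is accumulated outward in both
    directions until EHH < floor or the chromosome end, and the two
    directions are summed.

    Implementation: per haplotype pair, the *reach* at core c is the index
    of the first mismatch at/after c (direction +1; at/before c for -1).
    The EHH survival curve of a core is the prefix sum of the histogram of
    reaches, and moving the core by one SNP only re-bins the pairs that
    mismatch at the new core, so the whole chromosome is scanned with one
    incrementally-updated histogram per direction.  Memory scales as
    n_pairs (= n(n-1)/2) plus the mismatch matrix n_pairs x n_snps.
    """
    n, M = haps.shape
    denom = float(n * (n - 1))
    # pairwise mismatch matrix, stored core-major (M x pairs) so each scan
    # step touches contiguous memory
    rows = []
    for i in range(n - 1):
        rows.append(haps[i][None, :] != haps[i + 1 :])
    mism = np.ascontiguousarray(np.concatenate(rows, axis=0).T)  # (M, P)
    P = mism.shape[1]
    total = np.zeros(M)
    pos_f = pos.astype(float)

    for direction in (+1, -1):
        # histogram bins hold reach (direction +1) or reach+1 (direction -1,
        # so the sentinel -1 lands in bin 0); cores are visited so that the
        # current core's reaches are always in the histogram
        hist = np.zeros(M + 1, dtype=np.int64)
        cur = np.empty(P, dtype=np.int64)
        if direction == +1:
            order = range(M - 1, -1, -1)
            cur[:] = M
            hist[M] = P
        else:
            order = range(M)
            cur[:] = 0
            hist[0] = P
        for c in order:
            mm = mism[c]
            moved = cur[mm]
            if moved.size:
                hist -= np.bincount(moved, minlength=M + 1)
                newbin = c if direction == +1 else c + 1
                hist[newbin] += moved.size
                cur[mm] = newbin
            cum = np.cumsum(hist)
            if direction == +1:
                # identical on [c, c+k] iff reach > c+k: e[k] = P - cum[c+k]
                e = 2.0 * (P - cum[c:M]) / denom
                p_here = pos_f[c:M]
            else:
                # identical on [c-k, c] iff reach < c-k, i.e. bin <= c-k
                e = 2.0 * cum[c::-1] / denom
                p_here = pos_f[c::-1]
            if e[0] < floor:
                continue
            below = np.flatnonzero(e < floor)
            stop = below[0] if len(below) else len(e)  # points [0, stop) >= floor
            if stop < 2:
                continue
            seg = 0.5 * (e[: stop - 1] + e[1:stop]) * np.abs(np.diff(p_here[:stop]))
            total[c] += float(seg.sum())
    return total


def xp_ehh(
    haps_selected: np.ndarray,
    haps_reference: np.ndarray,
    chrom: Sequence[str],
    pos: Sequence[int],
    ehh_floor: float = config.XPEHH_EHH_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-population extended haplotype homozygosity per core SNP.

    ``haps_*`` are phased haplotype matrices (haplotypes x SNPs, 0/1) on a
    shared map.  raw = ln(I_sel / I_ref) of the per-population EHH
    integrals; SNPs with a zero reference integral are flagged NaN and
    excluded.  The standardized vector is (raw - mean)/SD over finite
    entries.
    """
    haps_selected = np.ascontiguousarray(haps_selected, dtype=np.int64)
    haps_reference = np.ascontiguousarray(haps_reference, dtype=np.int64)
    if haps_selected.shape[0] < 2 or haps_reference.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes per population")
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    L = len(pos)
    raw = np.full(L, np.nan)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        i_sel = _ehh_integrals_chrom(haps_selected[:, idx], p, ehh_floor)
        i_ref = _ehh_integrals_chrom(haps_reference[:, idx], p, ehh_floor)
        ok = (i_sel > 0) & (i_ref > 0)
        raw[idx[ok]] = np.log(i_sel[ok] / i_ref[ok])
    finite = np.isfinite(raw)
    if finite.sum() >= 2 and np.nanstd(raw) > 0:
        std = (raw - np.nanmean(raw)) / np.nanstd(raw)
    else:
        std = np.where(finite, 0.0, np.nan)
    return raw, std


# ---------------------------------------------------------------------------
# Rank composite
# ---------------------------------------------------------------------------


def composite_score(
    stat_vectors: Mapping[str, np.ndarray],
    snp_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Combine constituent selection statistics into the CSS.

    Per test: ascending average ranks over the SNPs where every test is
    finite; fractional ranks r' = rank/(n+1); z = Phi^-1(r').  The mean
    z-bar over the m tests gets a one-sided upper-tail P from N(0, 1/m)
    and CSS = -log10 P.  A test with all-identical values contributes
    z = 0 everywhere (with a warning).  Returns a frame with per-test
    ranks/z plus ``zbar``, ``p``, ``css`` (NaN on excluded SNPs); map
    columns are prepended when ``snp_map`` is given.
    """
    names = list(stat_vectors)
    if not names:
        raise ValueError("no statistic vectors")
    mat = np.vstack([np.asarray(stat_vectors[k], float) for k in names])
    m, L = mat.shape
    if L < 2:
        raise ValueError("need at least 2 SNPs")
    valid = np.isfinite(mat).all(axis=0)
    n = int(valid.sum())
    out: dict[str, np.ndarray] = {}
    zsum = np.zeros(L)
    for t, name in enumerate(names):
        v = mat[t, valid]
        if np.ptp(v) == 0:
            warnings.warn(f"test {name!r} has all-identical values; z=0", stacklevel=2)
        ranks = stats.rankdata(v, method="average")
        rprime = ranks / (n + 1.0)
        z = stats.norm.ppf(rprime)
        col_r = np.full(L, np.nan)
        col_z = np.full(L, np.nan)
        col_r[valid] = rprime
        col_z[valid] = z
        out[name] = mat[t]
        out[f"r_{name}"] = col_r
        out[f"z_{name}"] = col_z
        zsum[valid] += z
    zbar = np.where(valid, zsum / m, np.nan)
    p = np.where(valid, stats.norm.sf(zbar * math.sqrt(m)), np.nan)
    css = -np.log10(p)
    frame = pd.DataFrame(out)
    frame["zbar"] = zbar
    frame["p"] = p
    frame["css"] = css
    frame.attrs["m"] = m
    if snp_map is not None:
        frame.insert(0, "snp", snp_map["snp"].to_numpy())
        frame.insert(1, "chrom", snp_map["chrom"].to_numpy())
        frame.insert(2, "pos", snp_map["pos"].to_numpy())
    return frame


def smooth_css(
    css: np.ndarray,
    chrom: Sequence[str],
    pos: Sequence[int],
    window_kb: float = config.CSS_SMOOTH_WINDOW_KB,
) -> np.ndarray:
    """Average CSS over SNPs on the same chromosome within +/- window_kb/2
    of each SNP (window centred on the SNP, inclusive bounds).  NaN CSS
    entries are ignored in the averages and stay NaN in the output."""
    css = np.asarray(css, float)
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, float)
    half = window_kb * 1000.0 / 2.0
    out = np.full(len(css), np.nan)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        v = css[idx]
        fin = np.isfinite(v)
        cs = np.concatenate(([0.0], np.cumsum(np.where(fin, v, 0.0))))
        cn = np.concatenate(([0], np.cumsum(fin.astype(int))))
        lo = np.searchsorted(p, p - half, side="left")
        hi = np.searchsorted(p, p + half, side="right")
        sums = cs[hi] - cs[lo]
        cnts = cn[hi] - cn[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        sm[~fin] = np.nan
        out[idx] = sm
    return out


def top_tier(values: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the top ``floor(n * fraction)`` SNPs of a significance
    tier (n = finite values), ranked descending with ties broken by map
    order.  The 0.1% tier of a 48,896-SNP panel has 48 members."""
    values = np.asarray(values, float)
    finite = np.flatnonzero(np.isfinite(values))
    k = int(len(finite) * fraction)
    order = finite[np.lexsort((finite, -values[finite]))]
    return np.sort(order[:k])


def call_regions(
    smoothed: np.ndarray,
    chrom: Sequence[str],
    pos: Sequence[int],
    css: np.ndarray | None = None,
    top_fraction: float = config.CSS_TOP_FRACTION,
    min_snps: int = config.CSS_REGION_MIN_SNPS,
    max_gap_kb: float = config.CSS_REGION_MAX_GAP_KB,
) -> list[SelectionRegion]:
    """Cluster the top ``top_fraction`` of smoothed CSS into candidate
    selected regions.

    The top set holds ceil(top_fraction * n) SNPs with ties at the cutoff
    included; a cluster is a maximal chain of top-set SNPs on one
    chromosome with consecutive gaps <= max_gap_kb; clusters with >=
    ``min_snps`` members are reported with member min/max positions and
    the top *raw* CSS among members (the smoothed maximum when ``css`` is
    not given)."""
    smoothed = np.asarray(smoothed, float)
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    peak = smoothed if css is None else np.asarray(css, float)
    finite = np.isfinite(smoothed)
    n = int(finite.sum())
    if n == 0:
        return []
    k = int(np.ceil(top_fraction * n))
    cutoff = np.sort(smoothed[finite])[::-1][min(k, n) - 1]
    in_top = finite & (smoothed >= cutoff)
    gap_bp = max_gap_kb * 1000.0
    regions: list[SelectionRegion] = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero((chrom == c) & in_top)
        if len(idx) == 0:
            continue
        p = pos[idx].astype(float)
        cut = np.flatnonzero(np.diff(p) > gap_bp) + 1
        for cluster in np.split(idx, cut):
            if len(cluster) >= min_snps:
                regions.append(
                    SelectionRegion(
                        chrom=str(c),
                        start_bp=int(pos[cluster].min()),
                        end_bp=int(pos[cluster].max()),
                        n_top_snps=int(len(cluster)),
                        top_css=float(np.nanmax(peak[cluster])),
                    )
                )
    regions.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.start_bp))
    return regions


def map_genes(
    regions: Sequence[SelectionRegion],
    gene_table: GeneTable,
    flank_kb: float = config.CSS_GENE_FLANK_KB,
) -> pd.DataFrame:
    """Attach genes overlapping each region extended by +/- flank_kb
    (closed-interval overlap: touching counts).  Fills ``region.genes``
    in place and returns a (region, gene) table."""
    flank = flank_kb * 1000.0
    g = gene_table.genes
    rows = []
    for r in regions:
        lo, hi = r.start_bp - flank, r.end_bp + flank
        hit = g[(g["chrom"] == r.chrom) & (g["end"] >= lo) & (g["start"] <= hi)]
        r.genes = list(hit["name"])
        for name in r.genes:
            rows.append(
                {"chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp, "gene": name}
            )
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "gene"])


def css_scan(
    selected: GenotypeDataset,
    reference: GenotypeDataset,
    haps_selected: np.ndarray | None = None,
    haps_reference: np.ndarray | None = None,
    window_kb: float = config.CSS_SMOOTH_WINDOW_KB,
    top_fraction: float = config.CSS_TOP_FRACTION,
    min_snps: int = config.CSS_REGION_MIN_SNPS,
    max_gap_kb: float = config.CSS_REGION_MAX_GAP_KB,
    gene_table: GeneTable | None = None,
    flank_kb: float = config.CSS_GENE_FLANK_KB,
    ehh_floor: float = config.XPEHH_EHH_FLOOR,
) -> tuple[pd.DataFrame, list[SelectionRegion]]:
    """End-to-end CSS scan: constituent statistics, composite, smoothing,
    region calling and (optionally) gene mapping.  XP-EHH is included when
    phased haplotypes are supplied (m = 3), otherwise the composite uses
    FST and dSAF (m = 2)."""
    vectors: dict[str, np.ndarray] = {
        "fst": fst_per_snp(selected, reference),
        "dsaf": delta_saf(selected, reference),
    }
    chrom = selected.snp_map["chrom"].to_numpy(dtype=object)
    pos = selected.snp_map["pos"].to_numpy()
    if haps_selected is not None and haps_reference is not None:
        _, vectors["xpehh"] = xp_ehh(
            haps_selected, haps_reference, chrom, pos, ehh_floor=ehh_floor
        )
    frame = composite_score(vectors, snp_map=selected.snp_map)
    frame["css_smoothed"] = smooth_css(
        frame["css"].to_numpy(), chrom, pos, window_kb=window_kb
    )
    regions = call_regions(
        frame["css_smoothed"].to_numpy(),
        chrom,
        pos,
        css=frame["css"].to_numpy(),
        top_fraction=top_fraction,
        min_snps=min_snps,
        max_gap_kb=max_gap_kb,
    )
    if gene_table is not None:
        map_genes(regions, gene_table, flank_kb=flank_kb)
    return frame, regions
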