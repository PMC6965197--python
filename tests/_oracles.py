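"""Independent brute-force reference implementations used by the tests.

These are written as literal, loop-by-loop transcriptions of the
definitions (windows and runs enumerated one by one, haplotype pairs
enumerated explicitly, the rank composite step by step) and stay
independent of the vectorised library code paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

MISSING = -1


def roh_segments_bruteforce(
    calls_row: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    min_kb: float = 1000.0,
    min_snps: int = 30,
    max_gap_kb: float = 1000.0,
    max_density_kb_per_snp: float = 1000.0,
    window_snps: int = 30,
    window_het: int = 1,
    window_missing: int = 2,
    hit_fraction: float = 0.05,
) -> list[tuple[str, int, int, int]]:
    """All ROH of one individual as (chrom, start_bp, end_bp, n_snps),
    by explicit enumeration of every window and every run."""
    out = []
    for c in dict.fromkeys(chrom):  # preserve order
        sel = [j for j in range(len(chrom)) if chrom[j] == c]
        g = [int(calls_row[j]) for j in sel]
        p = [int(pos[j]) for j in sel]
        m = len(sel)
        # window verdicts
        if m <= window_snps:
            starts = [0]
            width = m
        else:
            starts = list(range(m - window_snps + 1))
            width = window_snps
        homwin = []
        for s in starts:
            w = g[s : s + width]
            homwin.append(
                sum(1 for x in w if x == 1) <= window_het
                and sum(1 for x in w if x == MISSING) <= window_missing
            )
        # per-SNP hit verdicts
        hit = []
        for j in range(m):
            wins = [s for s in starts if s <= j < s + width]
            frac = sum(homwin[s] for s in wins) / len(wins)
            hit.append(frac >= hit_fraction)
        # maximal hit runs, split at large gaps
        runs = []
        j = 0
        while j < m:
            if hit[j]:
                k = j
                while k + 1 < m and hit[k + 1]:
                    k += 1
                runs.append((j, k))
                j = k + 1
            else:
                j += 1
        pieces = []
        for a, b in runs:
            start = a
            for j in range(a + 1, b + 1):
                if (p[j] - p[j - 1]) / 1000.0 > max_gap_kb:
                    pieces.append((start, j - 1))
                    start = j
            pieces.append((start, b))
        for a, b in pieces:
            n = b - a + 1
            length_kb = (p[b] - p[a]) / 1000.0
            if length_kb > min_kb and n >= min_snps and length_kb / n <= max_density_kb_per_snp:
                out.append((str(c), p[a], p[b], n))
    return out


def ehh_integral_bruteforce(
    haps: np.ndarray, pos: np.ndarray, core: int, floor: float
) -> float:
    """EHH integral at one core SNP by enumerating every ordered haplotype
    pair's shared interval, step by step in each direction."""
    n, M = haps.shape
    denom = n * (n - 1)
    total = 0.0
    for step in (1, -1):
        shared = [
            (i, j)
            for i in range(n)
            for j in range(n)
            if i != j and haps[i, core] == haps[j, core]
        ]
        ehh = len(shared) / denom
        if ehh < floor:
            continue
        prev_pos, prev_ehh = pos[core], ehh
        x = core + step
        while 0 <= x < M:
            shared = [(i, j) for (i, j) in shared if haps[i, x] == haps[j, x]]
            ehh = len(shared) / denom
            if ehh < floor:
                break
            total += 0.5 * (prev_ehh + ehh) * abs(int(pos[x]) - int(prev_pos))
            prev_pos, prev_ehh = pos[x], ehh
            x += step
    return total


def composite_css_bruteforce(vectors: dict[str, np.ndarray]) -> np.ndarray:
    """Step-literal CSS: ranks -> fractional ranks -> inverse-normal ->
    mean -> N(0, 1/m) upper tail -> -log10."""
    names = list(vectors)
    m = len(names)
    L = len(next(iter(vectors.values())))
    zs = np.zeros((m, L))
    for t, name in enumerate(names):
        v = np.asarray(vectors[name], float)
        ranks = stats.rankdata(v, method="average")
        rprime = ranks / (L + 1.0)
        zs[t] = stats.norm.ppf(rprime)
    zbar = zs.mean(axis=0)
    p = 1.0 - stats.norm.cdf(zbar * np.sqrt(m))
    return -np.log10(p)
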