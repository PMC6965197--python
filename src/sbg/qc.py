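"""Sample/SNP quality control, VIF-based LD pruning and relatedness exclusion.

The filters mirror the standard SNP-array recipe: strictly-greater call-rate
thresholds (SNPs filtered before samples), a strict MAF cut, PLINK
``--indep``-style variance-inflation-factor pruning with deterministic
tie-breaking, and method-of-moments identity-by-descent (pi-hat) estimation
with greedy removal of related individuals.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from . import config
from .config import MISSING
from .io_core import GenotypeDataset, allele_frequencies

__all__ = [
    "PruneReport",
    "RelatednessPair",
    "filter_call_rate",
    "filter_maf",
    "vif_prune",
    "ibd_pihat",
    "remove_related",
]


@dataclasses.dataclass
class PruneReport:
    """Outcome of VIF pruning: the kept SNP ids plus, for each removed SNP,
    the (window index, VIF at removal) that triggered it."""

    kept: list[str]
    removed: list[tuple[str, int, float]]  # (snp, window index, VIF)

    @property
    def removed_ids(self) -> list[str]:
        return [r[0] for r in self.removed]


@dataclasses.dataclass
class RelatednessPair:
    """A sample pair with estimated IBD-state probabilities and
    pi-hat = P(IBD=2) + P(IBD=1)/2, clamped to [0, 1]."""

    sample_a: str
    sample_b: str
    pihat: float
    p_ibd: tuple[float, float, float] = (np.nan, np.nan, np.nan)


# ---------------------------------------------------------------------------
# Call rate and MAF
# ---------------------------------------------------------------------------


def filter_call_rate(
    dataset: GenotypeDataset,
    sample_min: float = config.CALL_RATE_MIN,
    snp_min: float = config.CALL_RATE_MIN,
) -> GenotypeDataset:
    """Keep SNPs with call rate > snp_min, then samples with call rate >
    sample_min on the surviving SNPs (strictly-greater comparisons, SNP pass
    first).  Raises if either pass empties the dataset."""
    if not (0 < sample_min <= 1 and 0 < snp_min <= 1):
        raise ValueError("call-rate thresholds must be in (0, 1]")
    present = dataset.calls != MISSING
    n_samp = dataset.n_samples
    if n_samp == 0:
        raise ValueError("empty dataset")
    snp_rate = present.sum(axis=0) / n_samp
    snp_keep = snp_rate > snp_min
    if not snp_keep.any():
        raise ValueError(f"call-rate filter removed all {dataset.n_snps} SNPs")
    ds = dataset.subset_snps(snp_keep)
    present = ds.calls != MISSING
    sample_rate = present.sum(axis=1) / max(ds.n_snps, 1)
    sample_keep = sample_rate > sample_min
    if not sample_keep.any():
        raise ValueError(
            f"call-rate filter kept {int(snp_keep.sum())}/{dataset.n_snps} SNPs "
            f"but removed all {n_samp} samples"
        )
    return ds.subset_samples([s for s, k in zip(ds.samples, sample_keep) if k])


def filter_maf(dataset: GenotypeDataset, maf_min: float = config.MAF_MIN) -> GenotypeDataset:
    """Keep SNPs with minor allele frequency strictly greater than maf_min."""
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    freq = allele_frequencies(dataset)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq.p, 1.0 - freq.p)
    keep = maf > maf_min  # NaN (all-missing SNP) compares False -> removed
    if not keep.any():
        warnings.warn("MAF filter removed every SNP", stacklevel=2)
    return dataset.subset_snps(keep)


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------


def _window_vifs(dos: np.ndarray) -> np.ndarray:
    """VIF = 1/(1 - R^2) for each column of a (samples x k) mean-imputed
    dosage window, R^2 from regressing that column on the others.

    Singularities go through the pseudo-inverse; R^2 is capped at
    1 - 1e-12 so a perfectly collinear SNP gets a finite, huge VIF.
    """
    k = dos.shape[1]
    x = dos - dos.mean(axis=0)
    cov = x.T @ x
    vifs = np.empty(k)
    for j in range(k):
        sjj = cov[j, j]
        if sjj <= 0:  # constant column: define VIF = 1 (nothing to inflate)
            vifs[j] = 1.0
            continue
        others = [i for i in range(k) if i != j]
        if not others:
            vifs[j] = 1.0
            continue
        a = cov[np.ix_(others, others)]
        b = cov[np.ix_(others, [j])]
        beta = np.linalg.pinv(a) @ b
        r2 = float((b.T @ beta).item() / sjj)
        r2 = min(max(r2, 0.0), 1.0 - 1e-12)
        vifs[j] = 1.0 / (1.0 - r2)
    return vifs


def vif_prune(
    dataset: GenotypeDataset,
    window_snps: int = config.PRUNE_WINDOW_SNPS,
    step_snps: int = config.PRUNE_STEP_SNPS,
    vif_max: float = config.PRUNE_VIF_MAX,
) -> PruneReport:
    """PLINK ``--indep``-style pruning: per chromosome, slide a window of
    ``window_snps`` map-consecutive kept SNPs advancing by ``step_snps``;
    within a window repeatedly remove the highest-VIF SNP until every VIF
    <= vif_max.  Removals are global.  Ties are broken by lower MAF first,
    then by map order (PLINK's own tie-breaking is unspecified; SNP-level
    parity with PLINK is not guaranteed, only the VIF contract).
    """
    if not (window_snps > step_snps >= 1):
        raise ValueError("need window_snps > step_snps >= 1")
    freq = allele_frequencies(dataset)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq.p, 1.0 - freq.p)
    maf = np.where(np.isnan(maf), 0.0, maf)

    present = dataset.calls != MISSING
    colmean = np.where(
        present.any(axis=0),
        np.where(present, dataset.calls, 0).sum(axis=0) / np.maximum(present.sum(axis=0), 1),
        0.0,
    )
    dos = np.where(present, dataset.calls, colmean[None, :]).astype(float)

    kept = np.ones(dataset.n_snps, dtype=bool)
    removed: list[tuple[str, int, float]] = []
    window_counter = 0
    for _, grp in dataset.snp_map.groupby("chrom", sort=False):
        idx_chrom = grp.index.to_numpy()
        start = 0
        while start < len(idx_chrom):
            win = idx_chrom[start : start + window_snps]
            win = win[kept[win]]
            while len(win) >= 2:
                vifs = _window_vifs(dos[:, win])
                worst = vifs.max()
                if worst <= vif_max:
                    break
                cand = np.flatnonzero(vifs >= worst)
                # ties: lower MAF first, then map order
                drop_local = cand[np.lexsort((win[cand], maf[win[cand]]))][0]
                drop = win[drop_local]
                kept[drop] = False
                removed.append((dataset.snps[drop], window_counter, float(vifs[drop_local])))
                win = np.delete(win, drop_local)
            window_counter += 1
            if start + window_snps >= len(idx_chrom):
                break
            start += step_snps
    return PruneReport(
        kept=[s for s, k in zip(dataset.snps, kept) if k],
        removed=removed,
    )


# ---------------------------------------------------------------------------
# IBD (pi-hat)
# ---------------------------------------------------------------------------


def _ibs_expectations(p: np.ndarray, n_alleles: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP expected IBS-state probabilities conditional on IBD state,
    with the small-sample correction: allele products are estimated without
    replacement from the 2N sampled alleles (the method-of-moments
    correction used by PLINK's --genome estimator)."""
    a = n_alleles.astype(float)
    nA = a * p          # count of B alleles, actually; symmetric below
    nB = a * (1.0 - p)

    def perm(n, k):
        out = np.ones_like(n)
        for i in range(k):
            out = out * np.maximum(n - i, 0.0)
        return out

    d4 = perm(a, 4)
    d3 = perm(a, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        p2q2 = perm(nA, 2) * perm(nB, 2) / d4
        p3q = perm(nA, 3) * nB / d4
        pq3 = nA * perm(nB, 3) / d4
        p4 = perm(nA, 4) / d4
        q4 = perm(nB, 4) / d4
        p2q = perm(nA, 2) * nB / d3
        pq2 = nA * perm(nB, 2) / d3

    e0_ibd0 = 2.0 * p2q2
    e1_ibd0 = 4.0 * p3q + 4.0 * pq3
    e2_ibd0 = p4 + q4 + 4.0 * p2q2
    e1_ibd1 = 2.0 * p2q + 2.0 * pq2
    e2_ibd1 = 1.0 - e1_ibd1
    return e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1


def ibd_pihat(dataset: GenotypeDataset) -> list[RelatednessPair]:
    """Method-of-moments IBD estimation for every sample pair.

    Observed IBS sharing over pairwise non-missing SNPs is compared with its
    expectation given IBD state (computed from sample allele frequencies
    with a small-sample correction); the IBD-state mixture is solved in
    cascade and bounded to the probability simplex.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    freq = allele_frequencies(dataset)
    usable = (freq.n >= 2) & (freq.p > 0) & (freq.p < 1)
    calls = dataset.calls[:, usable]
    e00, e10, e20, e11, e21 = (
        e[None, :] for e in _ibs_expectations(freq.p[usable], 2 * freq.n[usable])
    )

    present = calls != MISSING
    n_samp = dataset.n_samples
    pairs: list[RelatednessPair] = []
    for i in range(n_samp):
        gi = calls[i]
        pi_ok = present[i]
        both = pi_ok[None, :] & present[i + 1 :]
        diff = np.abs(calls[i + 1 :] - gi[None, :])
        ibs0 = both & (diff == 2)
        ibs1 = both & (diff == 1)
        ibs2 = both & (diff == 0)
        n_obs = both.sum(axis=1).astype(float)
        # expected counts over the pairwise-complete SNP set
        E00 = np.where(both, e00, 0.0).sum(axis=1)
        E10 = np.where(both, e10, 0.0).sum(axis=1)
        E20 = np.where(both, e20, 0.0).sum(axis=1)
        E11 = np.where(both, e11, 0.0).sum(axis=1)
        E21 = np.where(both, e21, 0.0).sum(axis=1)
        o0 = ibs0.sum(axis=1)
        o1 = ibs1.sum(axis=1)
        o2 = ibs2.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z0 = np.where(E00 > 0, o0 / np.maximum(E00, 1e-300), 0.0)
            z1 = np.where(E11 > 0, (o1 - z0 * E10) / np.maximum(E11, 1e-300), 0.0)
            z2 = (o2 - z0 * E20 - z1 * E21) / np.maximum(n_obs, 1.0)
        z = np.stack([z0, z1, z2], axis=1)
        z = np.clip(z, 0.0, None)
        tot = z.sum(axis=1, keepdims=True)
        z = np.where(tot > 0, z / np.maximum(tot, 1e-300), np.array([[1.0, 0.0, 0.0]]))
        for k in range(z.shape[0]):
            j = i + 1 + k
            pihat = float(np.clip(z[k, 2] + 0.5 * z[k, 1], 0.0, 1.0))
            pairs.append(
                RelatednessPair(
                    dataset.samples[i],
                    dataset.samples[j],
                    pihat,
                    tuple(float(v) for v in z[k]),
                )
            )
    return pairs


def remove_related(
    dataset: GenotypeDataset,
    pairs: Sequence[RelatednessPair],
    pihat_max: float = config.PIHAT_MAX,
) -> GenotypeDataset:
    """Greedy relatedness exclusion: repeatedly drop the sample in the most
    pairs above ``pihat_max`` (ties: higher missingness, then sample order)
    until no pair exceeds the threshold."""
    over = [(p.sample_a, p.sample_b) for p in pairs if p.pihat > pihat_max]
    if not over:
        return dataset
    missing_rate = {
        s: float((dataset.calls[i] == MISSING).mean())
        for i, s in enumerate(dataset.samples)
    }
    order = {s: i for i, s in enumerate(dataset.samples)}
    dropped: set[str] = set()
    while True:
        live = [(x, y) for x, y in over if x not in dropped and y not in dropped]
        if not live:
            break
        counts: dict[str, int] = {}
        for x, y in live:
            counts[x] = counts.get(x, 0) + 1
            counts[y] = counts.get(y, 0) + 1
        worst = max(counts.values())
        cand = [s for s, c in counts.items() if c == worst]
        cand.sort(key=lambda s: (-missing_rate[s], order[s]))
        dropped.add(cand[0])
    return dataset.subset_samples([s for s in dataset.samples if s not in dropped])
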