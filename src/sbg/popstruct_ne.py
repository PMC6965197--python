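"""Population structure (GRM + PCA) and LD-based effective population size.

The genetic relatedness matrix standardises genotype dosages per SNP by the
HWE mean 2p and variance 2p(1-p); PCA of the GRM with iterative
sigma-threshold outlier removal reproduces the smartPCA workflow contract.
Effective population size uses the linkage-disequilibrium method: Burrows
composite disequilibrium between (by default) interchromosomal locus pairs,
squared correlation averaged over pairs, the published random-mating
sample-size bias correction, and the drift-LD solution for Ne.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from . import config
from .config import MISSING
from .io_core import GenotypeDataset, allele_frequencies

__all__ = [
    "PcaResult",
    "NeEstimate",
    "grm",
    "pca_outlier",
    "ld_ne",
]


@dataclasses.dataclass
class PcaResult:
    """PCA of a relatedness matrix after iterative outlier removal.

    ``outliers`` records (sample id, iteration, component, sigma distance)
    for every removal."""

    samples: list[str]
    eigenvalues: np.ndarray          # top K, non-increasing
    coords: np.ndarray               # |samples| x K, eigvec * sqrt(eigval)
    outliers: list[tuple[str, int, int, float]]


@dataclasses.dataclass
class NeEstimate:
    """LD-method effective population size.

    ``r2_mean`` is the mean squared correlation over the locus pairs used;
    ``r2_drift`` is the bias-corrected drift component; ``ne`` is inf (with
    ``infinite=True``) when the corrected r2 is <= 0."""

    s: float                         # (mean pairwise-complete) sample size
    n_pairs: int
    r2_mean: float
    r2_drift: float
    ne: float
    ci_low: float
    ci_high: float
    infinite: bool = False


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


def grm(dataset: GenotypeDataset) -> np.ndarray:
    """Genetic relatedness matrix from standardised dosages.

    Codes are centred by 2p and scaled by sqrt(2p(1-p)) per SNP (missing
    entries contribute 0 after centring); entry (i, j) is the cross-product
    over SNPs divided by the number of SNPs where both samples are
    non-missing.  SNPs fixed in the sample (p in {0, 1}) are excluded with
    a warning."""
    freq = allele_frequencies(dataset)
    with np.errstate(invalid="ignore"):
        usable = (freq.n > 0) & (freq.p > 0) & (freq.p < 1)
    n_excl = int((~usable).sum())
    if n_excl:
        warnings.warn(f"excluding {n_excl} fixed/empty SNPs from the GRM", stacklevel=2)
    if not usable.any():
        raise ValueError("no polymorphic SNPs for the GRM")
    calls = dataset.calls[:, usable].astype(float)
    p = freq.p[usable]
    present = dataset.calls[:, usable] != MISSING
    z = (calls - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    z[~present] = 0.0
    num = z @ z.T
    cnt = present.astype(float) @ present.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(cnt > 0, num / np.maximum(cnt, 1.0), 0.0)
    return g


# ---------------------------------------------------------------------------
# PCA with sigma-threshold outlier iteration
# ---------------------------------------------------------------------------


def pca_outlier(
    grm_matrix: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    sigma: float = config.PCA_OUTLIER_SIGMA,
    n_evec_checked: int = 10,
    max_iter: int = 5,
    K: int = 10,
) -> PcaResult:
    """Eigendecompose the GRM; iteratively drop samples whose coordinate on
    any of the top ``n_evec_checked`` components lies more than ``sigma``
    standard deviations from that component's mean; recompute on the
    retained submatrix until convergence or ``max_iter`` sweeps.

    ``sigma=inf`` makes the iteration a no-op.  Raises if every sample
    would be removed."""
    g = np.asarray(grm_matrix, float)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("GRM must be square")
    if not np.allclose(g, g.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    n = g.shape[0]
    ids = list(sample_ids) if sample_ids is not None else [f"S{i}" for i in range(n)]
    keep = np.arange(n)
    outliers: list[tuple[str, int, int, float]] = []
    for it in range(max_iter + 1):
        sub = g[np.ix_(keep, keep)]
        w, v = np.linalg.eigh(sub)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        k_eff = min(K, len(keep))
        coords = v[:, :k_eff] * np.sqrt(np.maximum(w[:k_eff], 0.0))[None, :]
        if it == max_iter or not np.isfinite(sigma):
            break
        drop = np.zeros(len(keep), dtype=bool)
        for comp in range(min(n_evec_checked, k_eff)):
            c = coords[:, comp]
            sd = c.std()
            if sd == 0:
                continue
            z = np.abs(c - c.mean()) / sd
            newly = (z > sigma) & ~drop
            for i in np.flatnonzero(newly):
                outliers.append((ids[keep[i]], it + 1, comp + 1, float(z[i])))
            drop |= z > sigma
        if not drop.any():
            break
        if drop.all():
            raise ValueError("outlier iteration removed every sample")
        keep = keep[~drop]
    return PcaResult(
        samples=[ids[i] for i in keep],
        eigenvalues=w[:k_eff].copy(),
        coords=coords,
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# LD-based Ne
# ---------------------------------------------------------------------------


def _ne_from_r2drift(r2d: float, s: float) -> float:
    """Drift-LD solution for Ne under random mating (the published LD
    method): large-sample constants for S >= 30, small-sample otherwise."""
    if r2d <= 0:
        return np.inf
    if s >= 30:
        disc = max(1.0 / 9.0 - 2.76 * r2d, 0.0)
        return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2d)
    disc = max(0.308**2 - 2.08 * r2d, 0.0)
    return (0.308 + np.sqrt(disc)) / (2.0 * r2d)


def _r2_bias(s: float) -> float:
    """Expected sample-size component of r2 under random mating."""
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def ld_ne(
    dataset: GenotypeDataset,
    maf_min: float = config.NE_MAF_MIN,
    pair_scope: str = "interchromosomal",
    min_year: int | None = None,
    max_year: int | None = None,
) -> NeEstimate:
    """Effective population size from the LD method.

    Burrows composite disequilibrium Delta (with the n/(n-1) factor) is
    computed per locus pair from unphased dosages over pairwise-complete
    samples, normalised to a correlation by the allele-frequency variances,
    squared and averaged over eligible pairs (default: interchromosomal
    only, since physical linkage inflates r2 and biases Ne downward).  The
    sample-size expectation is subtracted and Ne solved from the drift
    component; r2' <= 0 flags an infinite estimate.  The parametric CI
    treats n_pairs * r2 / chi2 as the r2 sampling interval (pair count as
    df; anti-conservative under pair non-independence, and so documented).

    ``min_year``/``max_year`` restrict samples by year of birth first.
    """
    if pair_scope not in ("interchromosomal", "all"):
        raise ValueError("pair_scope must be 'interchromosomal' or 'all'")
    ds = dataset
    if min_year is not None or max_year is not None:
        yob = ds.meta["yob"].astype(float)
        keep = yob.notna()
        if min_year is not None:
            keep &= yob >= min_year
        if max_year is not None:
            keep &= yob <= max_year
        ds = ds.subset_samples([s for s, k in zip(ds.samples, keep) if k])
    if ds.n_samples < 10:
        raise ValueError(f"need S >= 10 samples, got {ds.n_samples}")
    if pair_scope == "interchromosomal" and ds.snp_map["chrom"].nunique() < 2:
        raise ValueError("interchromosomal scope needs >= 2 chromosomes")

    freq = allele_frequencies(ds)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq.p, 1.0 - freq.p)
    usable = (freq.n >= 2) & (maf >= maf_min)
    if usable.sum() < 2:
        raise ValueError("fewer than 2 SNPs pass the MAF screen")
    calls = ds.calls[:, usable]
    chrom = ds.snp_map["chrom"].to_numpy(dtype=object)[usable]
    L = calls.shape[1]

    present = (calls != MISSING).astype(float)
    x = np.where(calls != MISSING, calls, 0).astype(float)
    hom = (calls == 2).astype(float)
    n = present.T @ present                      # pairwise-complete S
    sx = x.T @ present                           # sum of x over complete pairs
    sy = sx.T
    sxy = x.T @ x
    shom_a = hom.T @ present                     # homozygote count of locus a
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / n
        mean_y = sy / n
        cov = sxy / n - mean_x * mean_y
        delta = 0.5 * cov * n / np.maximum(n - 1.0, 1.0)   # Burrows composite
        pa = mean_x / 2.0
        pb = mean_y / 2.0
        # Weir's normalisation: p q + D, with D the within-locus departure
        # from HWE (homozygote excess); this is the convention the
        # published sample-size calibration 1/S + 3.19/S^2 assumes.
        da = shom_a / n - pa * pa
        db = da.T
        denom = (pa * (1 - pa) + da) * (pb * (1 - pb) + db)
        r = np.where(denom > 0, delta / np.sqrt(np.where(denom > 0, denom, 1.0)), np.nan)
    r2 = r * r

    iu = np.triu_indices(L, k=1)
    mask = np.isfinite(r2[iu]) & (n[iu] >= 10)
    if pair_scope == "interchromosomal":
        mask &= chrom[iu[0]] != chrom[iu[1]]
    if not mask.any():
        raise ValueError("no eligible locus pairs")
    r2_pairs = r2[iu][mask]
    n_pairs = int(mask.sum())
    s_mean = float(n[iu][mask].mean())
    r2_mean = float(r2_pairs.mean())

    r2_drift = r2_mean - _r2_bias(s_mean)
    ne = _ne_from_r2drift(r2_drift, s_mean)

    df = n_pairs
    r2_hi = df * r2_mean / stats.chi2.ppf(0.025, df)
    r2_lo = df * r2_mean / stats.chi2.ppf(0.975, df)
    ci_low = _ne_from_r2drift(r2_hi - _r2_bias(s_mean), s_mean)
    ci_high = _ne_from_r2drift(r2_lo - _r2_bias(s_mean), s_mean)

    return NeEstimate(
        s=s_mean,
        n_pairs=n_pairs,
        r2_mean=r2_mean,
        r2_drift=r2_drift,
        ne=float(ne),
        ci_low=float(min(ci_low, ci_high)),
        ci_high=float(max(ci_low, ci_high)),
        infinite=not np.isfinite(ne),
    )
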