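"""Sire genotype inference from half-sib progeny plus population frequencies.

With n >= 20 genotyped offspring of one stallion, the offspring genotype
distribution at a locus identifies the sire genotype: offspring receive one
sire allele (Mendelian) and one dam allele at the population frequency
(dams random under HWE).  For each candidate sire genotype a goodness-of-fit
chi-square of the observed offspring class counts against their expectation
is converted to a likelihood by evaluating the chi-square *density* at the
statistic; normalising the three densities gives relative likelihoods and
the maximum is assigned.  Two hard rules operationalise Mendelian logic:
if both homozygote classes occur among offspring the sire must be
heterozygous, and any candidate whose expected class probability is zero
for an observed class is excluded outright.

Throughout this module ``p`` denotes the population frequency of the A
allele (the allele counted as zero by the dosage code); the B-allele
frequency of an :class:`~sbg.io_core.AlleleFrequencyTable` is converted at
the boundary.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import MISSING
from .io_core import AlleleFrequencyTable, GenotypeDataset

__all__ = [
    "SireCallRecord",
    "ConcordanceResult",
    "expected_offspring_distribution",
    "reconstruct_sire",
    "reconstruction_concordance",
    "assigned_calls",
    "records_frame",
]

#: Degrees of freedom of the chi-square density used as a likelihood.  df=1
#: has an unbounded density at 0, which breaks the normalisation whenever a
#: candidate fits perfectly; df=2 is finite everywhere and uniform across
#: candidates, so it is the default (exposed as a parameter).
DEFAULT_DF = 2.0


@dataclasses.dataclass
class SireCallRecord:
    """Per-locus candidate statistics and the assigned sire genotype.

    ``x2``, ``likelihood`` and ``rel_likelihood`` are ordered (AA, AB, BB);
    excluded candidates carry ``x2 = inf`` and likelihood 0.  ``call`` is
    the dosage code of the assigned genotype, or the missing code."""

    snp: str
    n_aa: int
    n_ab: int
    n_bb: int
    n_missing: int
    x2: tuple[float, float, float]
    likelihood: tuple[float, float, float]
    rel_likelihood: tuple[float, float, float]
    call: int
    confidence: float


@dataclasses.dataclass
class ConcordanceResult:
    concordance_pct: float
    call_rate_pct: float
    n_co_called: int


def records_frame(records: Sequence[SireCallRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "snp": r.snp,
                "n_aa": r.n_aa,
                "n_ab": r.n_ab,
                "n_bb": r.n_bb,
                "n_missing": r.n_missing,
                "rel_aa": r.rel_likelihood[0],
                "rel_ab": r.rel_likelihood[1],
                "rel_bb": r.rel_likelihood[2],
                "call": r.call,
                "confidence": r.confidence,
            }
        )
    return pd.DataFrame(rows)


def expected_offspring_distribution(
    sire_genotype: int, p: float
) -> tuple[float, float, float]:
    """Offspring genotype probabilities (AA, AB, BB) given the sire genotype
    and the population frequency ``p`` of the A allele (dam allele drawn
    Bernoulli under HWE): AA -> (p, q, 0); AB -> (p/2, 1/2, q/2);
    BB -> (0, p, q)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    q = 1.0 - p
    if sire_genotype == 0:
        return (p, q, 0.0)
    if sire_genotype == 1:
        return (p / 2.0, 0.5, q / 2.0)
    if sire_genotype == 2:
        return (0.0, p, q)
    raise ValueError(f"sire genotype must be 0, 1 or 2, got {sire_genotype!r}")


def reconstruct_sire(
    offspring: GenotypeDataset,
    pop_freqs: AlleleFrequencyTable | np.ndarray,
    min_offspring: int = 20,
    df: float = DEFAULT_DF,
    confidence_min: float = 0.0,
) -> list[SireCallRecord]:
    """Infer the sire genotype at every SNP from half-sib offspring.

    Per SNP: loci with fewer than ``min_offspring`` non-missing offspring
    calls are left missing; if both homozygote classes are observed the
    candidate set collapses to {AB}; candidates expecting probability zero
    for an observed class are excluded; the chi-square statistic over
    classes with positive expectation is turned into a likelihood via the
    chi-square density (``df`` degrees of freedom) and normalised; the
    argmax is assigned when its relative likelihood reaches
    ``confidence_min``.  Exact ties go to the candidate with the higher
    HWE population genotype frequency, then to the heterozygote.  A locus
    whose candidates are all excluded (e.g. a fixed allele contradicted by
    the offspring) is flagged inconsistent and left missing.
    """
    pB = pop_freqs.p if isinstance(pop_freqs, AlleleFrequencyTable) else np.asarray(pop_freqs, float)
    if len(pB) != offspring.n_snps:
        raise ValueError("freqs must cover all SNPs")
    pA = 1.0 - pB
    qA = pB
    calls = offspring.calls
    n0 = (calls == 0).sum(axis=0).astype(float)
    n1 = (calls == 1).sum(axis=0).astype(float)
    n2 = (calls == 2).sum(axis=0).astype(float)
    n_mis = (calls == MISSING).sum(axis=0)
    n = n0 + n1 + n2
    L = offspring.n_snps

    # expected class probabilities, shape (3 candidates, 3 classes, L)
    zeros = np.zeros(L)
    probs = np.array(
        [
            [pA, qA, zeros],
            [pA / 2.0, np.full(L, 0.5), qA / 2.0],
            [zeros, pA, qA],
        ]
    )
    obs = np.array([n0, n1, n2])  # (3 classes, L)

    candidate_ok = np.ones((3, L), dtype=bool)
    both_homs = (n0 > 0) & (n2 > 0)
    candidate_ok[0, both_homs] = False
    candidate_ok[2, both_homs] = False
    # zero-expectation exclusion
    impossible = (probs == 0.0) & (obs[None, :, :] > 0)
    candidate_ok &= ~impossible.any(axis=1)

    expected = probs * n[None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(
            expected > 0, (obs[None, :, :] - expected) ** 2 / np.where(expected > 0, expected, 1.0), 0.0
        )
    x2 = contrib.sum(axis=1)  # (3, L)
    like = stats.chi2.pdf(x2, df)
    like = np.where(candidate_ok, like, 0.0)
    total = like.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(total > 0, like / np.where(total > 0, total, 1.0), 0.0)

    # deterministic argmax with documented tie-breaking
    hwe = np.array([pA**2, 2.0 * pA * qA, qA**2])  # population genotype freq
    het_pref = np.array([0.0, 1.0, 0.0])[:, None]
    best = rel.max(axis=0)
    tie1 = rel >= best[None, :] - 0.0  # exact max set
    key2 = np.where(tie1, hwe, -np.inf)
    best2 = key2.max(axis=0)
    tie2 = key2 >= best2[None, :]
    key3 = np.where(tie2, het_pref, -np.inf)
    choice = key3.argmax(axis=0)

    enough = n >= min_offspring
    callable_ = enough & (total > 0) & (best >= confidence_min)
    call = np.where(callable_, choice, MISSING).astype(np.int8)

    x2_rec = np.where(candidate_ok, x2, np.inf)
    records: list[SireCallRecord] = []
    for j in range(L):
        records.append(
            SireCallRecord(
                snp=offspring.snps[j],
                n_aa=int(n0[j]),
                n_ab=int(n1[j]),
                n_bb=int(n2[j]),
                n_missing=int(n_mis[j]),
                x2=tuple(float(v) for v in x2_rec[:, j]),
                likelihood=tuple(float(v) for v in like[:, j]),
                rel_likelihood=tuple(float(v) for v in rel[:, j]),
                call=int(call[j]),
                confidence=float(best[j]) if total[j] > 0 else np.nan,
            )
        )
    return records


def assigned_calls(records: Sequence[SireCallRecord]) -> np.ndarray:
    """The assigned genotype codes as a vector (missing code included)."""
    return np.array([r.call for r in records], dtype=np.int8)


def reconstruction_concordance(
    assigned: np.ndarray, truth: np.ndarray
) -> ConcordanceResult:
    """Percentage agreement over loci where both vectors are non-missing,
    plus the call rate of the assigned vector."""
    assigned = np.asarray(assigned)
    truth = np.asarray(truth)
    if assigned.shape != truth.shape:
        raise ValueError("assigned and truth must share the SNP panel")
    both = (assigned != MISSING) & (truth != MISSING)
    n_co = int(both.sum())
    if n_co == 0:
        raise ValueError("no co-called loci")
    concord = 100.0 * float((assigned[both] == truth[both]).sum()) / n_co
    call_rate = 100.0 * float((assigned != MISSING).mean())
    return ConcordanceResult(concord, call_rate, n_co)
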