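from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sbg import GenotypeDataset


def make_dataset(
    calls,
    chrom=None,
    pos=None,
    samples=None,
    snps=None,
    meta: dict | None = None,
) -> GenotypeDataset:
    """Small literal dataset for hand-computed examples."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    samples = samples or [f"S{i + 1}" for i in range(n)]
    snps = snps or [f"M{j + 1}" for j in range(L)]
    chrom = chrom if chrom is not None else ["1"] * L
    pos = pos if pos is not None else list(range(1000, 1000 * (L + 1), 1000))
    md = None
    if meta:
        md = GenotypeDataset.empty_meta(samples)
        for col, vals in meta.items():
            md[col] = vals
    return GenotypeDataset.from_arrays(
        samples, snps, calls, chrom=chrom, pos=pos, meta=md
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n_samples=8, n_snps=20, missing_rate=0.1) -> GenotypeDataset:
    calls = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    mask = rng.random(calls.shape) < missing_rate
    calls[mask] = -1
    n_chrom = max(1, n_snps // 7)
    chrom = [str(1 + j % n_chrom) for j in range(n_snps)]
    # unique increasing positions per chromosome
    pos = []
    counters = {}
    for c in chrom:
        counters[c] = counters.get(c, 0) + 1000 + int(rng.integers(0, 500))
        pos.append(counters[c])
    return make_dataset(calls, chrom=chrom, pos=pos)
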