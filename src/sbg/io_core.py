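"""Domain types and readers/writers for the formats the pipeline touches.

The universal currency is :class:`GenotypeDataset`: a sample x SNP matrix of
B-allele dosage codes {0, 1, 2} with a distinct missing code, a sorted SNP
map and per-sample metadata.  Genotypes enter from PLINK text PED/MAP, leave
as PED/MAP or GENEPOP; gene annotation enters from BED3+ (converted to
1-based inclusive coordinates at the boundary).

Allele orientation: the B allele (the one counted by the dosage code) is the
first-listed allele of an extended MAP line when given, otherwise the
lexicographically later allele observed in the PED.  Orientation affects only
labelling; every downstream statistic is orientation-symmetric or defined
per SNP.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MISSING

__all__ = [
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "GeneTable",
    "read_plink_text",
    "write_plink_text",
    "write_genepop",
    "read_gene_annotation",
    "allele_frequencies",
]


def _chrom_sort_key(label: str) -> tuple[int, int, str]:
    """Natural ordering for chromosome labels: numeric labels first, in
    numeric order, then the rest lexicographically."""
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


@dataclasses.dataclass
class GenotypeDataset:
    """Sample x SNP genotype matrix plus map and metadata.

    Attributes
    ----------
    samples : list of str
        Ordered sample ids (rows of ``calls``).
    snps : list of str
        Ordered SNP ids (columns of ``calls``), sorted by (chromosome,
        position).
    calls : ndarray of int8, shape (n_samples, n_snps)
        B-allele dosage codes 0/1/2; missing is ``config.MISSING`` (-1).
    snp_map : DataFrame
        One row per SNP in column order: ``snp``, ``chrom`` (str),
        ``pos`` (int, 1-based bp), ``allele_a``, ``allele_b``.
    meta : DataFrame indexed by sample id
        Columns ``sire``, ``dam``, ``sex``, ``yob``, ``region``; any entry
        may be missing (None/NaN) and is rejected only by operations that
        need it.
    """

    samples: list[str]
    snps: list[str]
    calls: np.ndarray
    snp_map: pd.DataFrame
    meta: pd.DataFrame

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def empty_meta(samples: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {"sire": None, "dam": None, "sex": None, "yob": np.nan, "region": None},
            index=pd.Index(list(samples), name="sample"),
        )

    @classmethod
    def from_arrays(
        cls,
        samples: Sequence[str],
        snps: Sequence[str],
        calls: np.ndarray,
        chrom: Sequence[str],
        pos: Sequence[int],
        allele_a: Sequence[str] | None = None,
        allele_b: Sequence[str] | None = None,
        meta: pd.DataFrame | None = None,
    ) -> "GenotypeDataset":
        n_snps = len(snps)
        snp_map = pd.DataFrame(
            {
                "snp": list(snps),
                "chrom": [str(c) for c in chrom],
                "pos": np.asarray(pos, dtype=np.int64),
                "allele_a": list(allele_a) if allele_a is not None else ["A"] * n_snps,
                "allele_b": list(allele_b) if allele_b is not None else ["B"] * n_snps,
            }
        )
        ds = cls(
            samples=list(samples),
            snps=list(snps),
            calls=np.asarray(calls, dtype=np.int8),
            snp_map=snp_map,
            meta=meta if meta is not None else cls.empty_meta(samples),
        )
        ds._sort_map()
        ds.validate()
        return ds

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample id")
        if list(self.snp_map["snp"]) != self.snps:
            raise ValueError("snp_map order disagrees with snps")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,missing}")
        # positions strictly increasing within each chromosome
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")

    def _sort_map(self) -> None:
        order = sorted(
            range(len(self.snps)),
            key=lambda i: (
                _chrom_sort_key(self.snp_map["chrom"].iat[i]),
                self.snp_map["pos"].iat[i],
            ),
        )
        if order != list(range(len(self.snps))):
            self.calls = self.calls[:, order]
            self.snp_map = self.snp_map.iloc[order].reset_index(drop=True)
            self.snps = list(self.snp_map["snp"])

    # -- conveniences --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeDataset":
        idx = self.sample_indices(ids)
        return GenotypeDataset(
            samples=[self.samples[i] for i in idx],
            snps=list(self.snps),
            calls=self.calls[idx],
            snp_map=self.snp_map.copy(),
            meta=self.meta.iloc[idx].copy(),
        )

    def subset_snps(self, keep: np.ndarray | Sequence[str]) -> "GenotypeDataset":
        """Subset SNPs by boolean mask (map order) or by SNP ids."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            wanted = set(keep)
            mask = np.array([s in wanted for s in self.snps])
        return GenotypeDataset(
            samples=list(self.samples),
            snps=[s for s, k in zip(self.snps, mask) if k],
            calls=self.calls[:, mask],
            snp_map=self.snp_map.loc[mask].reset_index(drop=True),
            meta=self.meta.copy(),
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.calls, other.calls)
            and self.snp_map.reset_index(drop=True).equals(
                other.snp_map.reset_index(drop=True)
            )
        )


@dataclasses.dataclass
class AlleleFrequencyTable:
    """Per-SNP B-allele frequency ``p`` and non-missing sample count ``n``
    in a named sample set.  SNPs with ``n == 0`` carry ``p = NaN`` (flagged)."""

    snps: list[str]
    p: np.ndarray
    n: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        ok = self.n > 0
        if np.any((self.p[ok] < 0) | (self.p[ok] > 1)):
            raise ValueError("allele frequency outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp": self.snps, "p": self.p, "n": self.n})


@dataclasses.dataclass
class GeneTable:
    """Gene annotation with 1-based inclusive coordinates, sorted by
    (chromosome, start)."""

    genes: pd.DataFrame  # columns: name, chrom, start, end

    def __post_init__(self) -> None:
        g = self.genes
        if len(g) and np.any(g["start"].to_numpy() > g["end"].to_numpy()):
            raise ValueError("gene with start > end")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

_SEX_FROM_PED = {"1": "M", "2": "F"}
_SEX_TO_PED = {"M": "1", "F": "2"}


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read PLINK text PED/MAP into a :class:`GenotypeDataset`.

    The MAP may have 4 columns (chrom, id, cM, bp) or 6 (plus the B and A
    alleles, in that order).  Without declared alleles the B allele is the
    lexicographically later observed allele; a lone observed allele is taken
    as A (dosage 0).  ``0 0`` and half-missing pairs are the missing code.
    SNPs are sorted by (chromosome, position) on load.
    """
    map_df = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str, comment="#")
    if map_df.shape[1] not in (4, 5, 6):
        raise ValueError(f"MAP must have 4-6 columns, got {map_df.shape[1]}")
    snp_ids = map_df[1].tolist()
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError("duplicated SNP id in MAP")
    n_snps = len(snp_ids)
    declared_b = map_df[4].tolist() if map_df.shape[1] >= 5 else [None] * n_snps
    declared_a = map_df[5].tolist() if map_df.shape[1] == 6 else [None] * n_snps

    try:
        ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        ped = pd.DataFrame()
    if len(ped) and ped.shape[1] != 6 + 2 * n_snps:
        raise ValueError(
            f"PED has {ped.shape[1]} columns; expected {6 + 2 * n_snps} "
            f"for {n_snps} MAP rows"
        )
    n_samples = len(ped)
    samples = ped[1].tolist() if n_samples else []
    if len(set(samples)) != len(samples):
        dup = pd.Series(samples).value_counts().idxmax()
        raise ValueError(f"duplicated sample id {dup!r}")

    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    allele_a = ["0"] * n_snps
    allele_b = ["0"] * n_snps
    if n_samples:
        tok = ped.iloc[:, 6:].to_numpy(dtype=object)
    for j in range(n_snps):
        if n_samples:
            a1 = tok[:, 2 * j]
            a2 = tok[:, 2 * j + 1]
            present = (a1 != "0") & (a2 != "0")
            observed = sorted(set(a1[present]) | set(a2[present]))
        else:
            observed = []
        b, a = declared_b[j], declared_a[j]
        rest = [x for x in observed if x not in (a, b)]
        if b is None:
            if len(rest) > 2:
                raise ValueError(f"SNP {snp_ids[j]!r} has >2 alleles: {observed}")
            if len(rest) == 2:
                a, b = rest[0], rest[1]       # lexicographically later -> B
            elif len(rest) == 1:
                a = rest[0]                   # single observed allele -> A
        else:
            if a is None and rest:
                a = rest.pop(0)
            if rest:
                raise ValueError(f"SNP {snp_ids[j]!r} has >2 alleles: {observed}")
        allele_a[j] = a if a is not None else "0"
        allele_b[j] = b if b is not None else "0"
        if n_samples:
            code = (a1 == b).astype(np.int8) + (a2 == b).astype(np.int8)
            code[~present] = MISSING
            calls[:, j] = code

    meta = GenotypeDataset.empty_meta(samples)
    if n_samples:
        meta["sire"] = [s if s != "0" else None for s in ped[2]]
        meta["dam"] = [s if s != "0" else None for s in ped[3]]
        meta["sex"] = [_SEX_FROM_PED.get(s) for s in ped[4]]

    return GenotypeDataset.from_arrays(
        samples,
        snp_ids,
        calls,
        chrom=map_df[0].tolist(),
        pos=map_df[3].astype(np.int64).tolist(),
        allele_a=allele_a,
        allele_b=allele_b,
        meta=meta,
    )


def write_plink_text(
    dataset: GenotypeDataset,
    ped_path: str | Path,
    map_path: str | Path,
    include_alleles: bool = True,
) -> None:
    """Write PED/MAP readable by :func:`read_plink_text` and standard tools.

    With ``include_alleles`` (default) the MAP carries two extra columns
    (B allele, A allele) so a read/write cycle reproduces the dataset
    exactly; ``include_alleles=False`` writes the strict 4-column dialect.
    Missing genotypes are written ``0 0``.
    """
    m = dataset.snp_map
    with open(map_path, "w") as fh:
        for i in range(len(m)):
            row = [m["chrom"].iat[i], m["snp"].iat[i], "0", str(int(m["pos"].iat[i]))]
            if include_alleles:
                row += [m["allele_b"].iat[i], m["allele_a"].iat[i]]
            fh.write("\t".join(row) + "\n")

    a = m["allele_a"].to_numpy(dtype=object)
    b = m["allele_b"].to_numpy(dtype=object)
    # geno_tokens[code][j] = the two allele tokens of code at SNP j
    first = {0: a, 1: a, 2: b, MISSING: np.full(len(m), "0", dtype=object)}
    second = {0: a, 1: b, 2: b, MISSING: np.full(len(m), "0", dtype=object)}
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(dataset.samples):
            meta = dataset.meta.loc[sample]
            sire = meta["sire"] if isinstance(meta["sire"], str) else "0"
            dam = meta["dam"] if isinstance(meta["dam"], str) else "0"
            sex = _SEX_TO_PED.get(meta["sex"], "0")
            row = [sample, sample, sire, dam, sex, "-9"]
            codes = dataset.calls[i]
            pair = np.empty(2 * len(codes), dtype=object)
            for c in (0, 1, 2, MISSING):
                sel = codes == c
                pair[0::2][sel] = first[c][sel]
                pair[1::2][sel] = second[c][sel]
            fh.write(" ".join(row) + (" " if len(pair) else "") + " ".join(pair) + "\n")


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------


def write_genepop(
    dataset: GenotypeDataset,
    path: str | Path,
    populations: Mapping[str, Sequence[str]] | None = None,
    title: str = "sbg export",
) -> None:
    """Write the dataset in GENEPOP dialect.

    ``populations`` maps population name -> sample ids (a partition of the
    samples; default: one population with every sample).  Two-digit allele
    coding: A -> 01, B -> 02; dosage 1 is written ``0102`` (canonical order);
    missing is ``0000``.
    """
    if populations is None:
        populations = {"pop1": list(dataset.samples)}
    code_to_str = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for snp in dataset.snps:
            fh.write(snp + "\n")
        for _, members in populations.items():
            fh.write("Pop\n")
            idx = dataset.sample_indices(members)
            for i in idx:
                geno = " ".join(code_to_str[int(c)] for c in dataset.calls[i])
                fh.write(f"{dataset.samples[i]} , {geno}\n")


# ---------------------------------------------------------------------------
# BED gene annotation
# ---------------------------------------------------------------------------


def read_gene_annotation(bed_path: str | Path) -> GeneTable:
    """Read BED3+ (chrom, start, end, name, ...) gene annotation.

    BED half-open 0-based [start, end) becomes 1-based inclusive
    [start+1, end].  Rows with end <= start raise an error naming the line.
    Output is sorted by (chromosome, start).
    """
    rows = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"BED line {ln}: need >=4 columns (BED3+name)")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if end <= start:
                raise ValueError(f"BED line {ln}: end <= start ({start}, {end})")
            rows.append((name, chrom, start + 1, end))
    df = pd.DataFrame(rows, columns=["name", "chrom", "start", "end"])
    if len(df):
        df = df.sort_values(
            by=["chrom", "start"],
            key=lambda col: (
                col.map(_chrom_sort_key) if col.name == "chrom" else col
            ),
            kind="stable",
        ).reset_index(drop=True)
    return GeneTable(df)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(
    dataset: GenotypeDataset,
    sample_subset: Sequence[str] | None = None,
    name: str = "",
) -> AlleleFrequencyTable:
    """B-allele frequency p = (2 n_BB + n_AB) / (2 n_j) per SNP over a
    sample set (default: all samples).  n_j counts non-missing calls; SNPs
    with n_j = 0 get p = NaN."""
    if sample_subset is not None:
        if len(sample_subset) == 0:
            raise ValueError("empty sample subset")
        idx = dataset.sample_indices(sample_subset)
        calls = dataset.calls[idx]
    else:
        calls = dataset.calls
    present = calls != MISSING
    n = present.sum(axis=0)
    dosage = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, dosage / (2.0 * np.maximum(n, 1)), np.nan)
    return AlleleFrequencyTable(list(dataset.snps), p, n.astype(np.int64), name=name)
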