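"""Encoding of genotype calls, phenotype labels and the multi-contributor
partition function.

A biallelic genotype column over ``{AA, Aa, aa}`` is represented by two
integer vectors: ``x_AA`` with entry 2 for an ``AA`` subject (0 otherwise)
and ``x_Aa`` with entry 1 for an ``Aa`` subject.  Their element-wise sum is
the per-subject dosage of allele ``A``, so scalar products against a binary
case vector or an all-ones vector yield allele counts directly.

The partition function ``π(x, q)`` zeroes every element not owned by
contributor ``q``; summing over all contributors reconstructs ``x``, which
is what makes homomorphic aggregation of contributor uploads exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GenotypeMatrix",
    "PhenotypeVector",
    "EncodedSNP",
    "PartitionAssignment",
    "encode_snp",
    "encode_phenotype",
    "apply_partition",
    "read_genotype_tsv",
    "read_phenotype_tsv",
    "read_vcf",
]

GENOTYPE_ALPHABET = ("AA", "Aa", "aa")
_DOSAGE_TO_CALL = {"2": "AA", "1": "Aa", "0": "aa", 2: "AA", 1: "Aa", 0: "aa"}
_CASE_LABELS = {"case": 1, "1": 1, 1: 1, "control": 0, "0": 0, 0: 0}


class ValidationError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """M subjects × N SNPs of calls in ``{AA, Aa, aa}`` (no missing calls)."""

    subject_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    calls: np.ndarray  # (M, N) array of str

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=object)
        if calls.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(calls, GENOTYPE_ALPHABET)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"invalid genotype call {calls[i, j]!r} for subject "
                f"{self.subject_ids[i]!r} at SNP {self.snp_ids[j]!r}; "
                f"expected one of {GENOTYPE_ALPHABET}"
            )
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "snp_ids", tuple(str(s) for s in self.snp_ids))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        j = self.snp_ids.index(str(snp_id))
        return self.calls[:, j]

    def dosage(self) -> np.ndarray:
        """(M, N) integer copies of allele A per subject (AA=2, Aa=1, aa=0)."""
        out = np.zeros(self.calls.shape, dtype=np.int64)
        out[self.calls == "AA"] = 2
        out[self.calls == "Aa"] = 1
        return out

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.calls, index=list(self.subject_ids), columns=list(self.snp_ids)
        )
        df.to_csv(path, sep="\t", index_label="subject_id")


@dataclass(frozen=True)
class PhenotypeVector:
    """Binary case/control status per subject (1 = case, 0 = control)."""

    subject_ids: tuple[str, ...]
    status: np.ndarray  # (M,) int in {0, 1}

    def __post_init__(self) -> None:
        status = np.asarray(self.status, dtype=np.int64)
        if status.shape != (len(self.subject_ids),):
            raise ValidationError("one status per subject required")
        if not np.isin(status, (0, 1)).all():
            raise ValidationError("phenotype status values must be 0 or 1")
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"subject_id": list(self.subject_ids), "status": self.status}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EncodedSNP:
    """The (x_AA, x_Aa) integer-vector pair for one SNP across M subjects."""

    x_AA: np.ndarray  # entries in {0, 2}
    x_Aa: np.ndarray  # entries in {0, 1}

    def __post_init__(self) -> None:
        x_AA = np.asarray(self.x_AA, dtype=np.int64)
        x_Aa = np.asarray(self.x_Aa, dtype=np.int64)
        if x_AA.shape != x_Aa.shape or x_AA.ndim != 1:
            raise ValidationError("x_AA and x_Aa must be 1-d vectors of equal length")
        ok = ((x_AA == 2) & (x_Aa == 0)) | ((x_AA == 0) & (x_Aa == 1)) | (
            (x_AA == 0) & (x_Aa == 0)
        )
        if not ok.all():
            raise ValidationError("per-subject (x_AA, x_Aa) must be (2,0), (0,1) or (0,0)")
        object.__setattr__(self, "x_AA", x_AA)
        object.__setattr__(self, "x_Aa", x_Aa)

    @property
    def dosage(self) -> np.ndarray:
        return self.x_AA + self.x_Aa


def encode_snp(calls: Sequence[str]) -> EncodedSNP:
    """Encode one genotype column as the (x_AA, x_Aa) vector pair."""
    arr = np.asarray(list(calls), dtype=object)
    bad = ~np.isin(arr, GENOTYPE_ALPHABET)
    if bad.any():
        idx = [int(i) for i in np.flatnonzero(bad)]
        raise ValidationError(
            f"unknown genotype symbol(s) {sorted(set(arr[bad]))} at subject "
            f"indices {idx}; expected {GENOTYPE_ALPHABET}"
        )
    return EncodedSNP(
        x_AA=np.where(arr == "AA", 2, 0),
        x_Aa=np.where(arr == "Aa", 1, 0),
    )


def encode_phenotype(statuses: Iterable) -> np.ndarray:
    """Encode case/control labels as a binary vector (case → 1)."""
    out = []
    for i, s in enumerate(statuses):
        key = s.strip().lower() if isinstance(s, str) else int(s)
        if key not in _CASE_LABELS:
            raise ValidationError(
                f"unknown phenotype label {s!r} at subject index {i}; "
                "expected case/control or 1/0"
            )
        out.append(_CASE_LABELS[key])
    return np.asarray(out, dtype=np.int64)


@dataclass(frozen=True)
class PartitionAssignment:
    """Ownership of every data element by exactly one of Q contributors.

    ``genotype_owner[i, j]`` and ``phenotype_owner[i]`` hold contributor
    indices in ``1..Q``.  Horizontal and vertical partitions are both just
    special owner maps.
    """

    Q: int
    genotype_owner: np.ndarray  # (M, N)
    phenotype_owner: np.ndarray  # (M,)

    def __post_init__(self) -> None:
        g = np.asarray(self.genotype_owner, dtype=np.int64)
        p = np.asarray(self.phenotype_owner, dtype=np.int64)
        if self.Q < 1:
            raise ValidationError("Q must be >= 1")
        if g.ndim != 2 or p.ndim != 1 or g.shape[0] != p.shape[0]:
            raise ValidationError("owner maps must be (M, N) and (M,) with equal M")
        for name, arr in (("genotype", g), ("phenotype", p)):
            if arr.min(initial=1) < 1 or arr.max(initial=1) > self.Q:
                raise ValidationError(f"{name} owner indices must lie in 1..{self.Q}")
        object.__setattr__(self, "genotype_owner", g)
        object.__setattr__(self, "phenotype_owner", p)

    @property
    def n_subjects(self) -> int:
        return self.genotype_owner.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotype_owner.shape[1]


def apply_partition(x: np.ndarray, owners: np.ndarray, q: int, Q: int) -> np.ndarray:
    """``π(x, q)``: keep elements owned by contributor ``q``, zero the rest."""
    if not 1 <= q <= Q:
        raise ValidationError(f"contributor index {q} outside 1..{Q}")
    x = np.asarray(x, dtype=np.int64)
    owners = np.asarray(owners, dtype=np.int64)
    if x.shape != owners.shape:
        raise ValidationError("vector and owner map lengths differ")
    return np.where(owners == q, x, 0)


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

def _normalise_call(value, subject, snp) -> str:
    if isinstance(value, str):
        v = value.strip()
        if v in GENOTYPE_ALPHABET:
            return v
        if v in _DOSAGE_TO_CALL:
            return _DOSAGE_TO_CALL[v]
    elif isinstance(value, (int, np.integer)) and int(value) in (0, 1, 2):
        return _DOSAGE_TO_CALL[int(value)]
    raise ValidationError(
        f"invalid genotype value {value!r} for subject {subject!r} at SNP {snp!r}"
    )


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read the genotype TSV dialect: header of SNP ids, one row per subject.

    Calls may be given as ``AA/Aa/aa`` or as allele-A dosages ``2/1/0``.
    """
    df = pd.read_csv(path, sep="\t", dtype=object)
    if df.shape[1] < 2:
        raise ValidationError("genotype TSV needs a subject_id column and >= 1 SNP column")
    subject_ids = [str(s) for s in df.iloc[:, 0]]
    snp_ids = [str(c) for c in df.columns[1:]]
    calls = np.empty((len(subject_ids), len(snp_ids)), dtype=object)
    for j, snp in enumerate(snp_ids):
        col = df.iloc[:, j + 1]
        for i, value in enumerate(col):
            calls[i, j] = _normalise_call(value, subject_ids[i], snp)
    return GenotypeMatrix(tuple(subject_ids), tuple(snp_ids), calls)


def read_phenotype_tsv(path) -> PhenotypeVector:
    """Read the phenotype TSV dialect: subject_id, status ∈ {case,control,1,0}."""
    df = pd.read_csv(path, sep="\t", dtype=object)
    if df.shape[1] != 2:
        raise ValidationError("phenotype TSV must have exactly two columns")
    subject_ids = [str(s) for s in df.iloc[:, 0]]
    status = encode_phenotype(df.iloc[:, 1])
    return PhenotypeVector(tuple(subject_ids), status)


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF; REF is allele A, ALT allele a.

    GT ``0/0 → AA``, ``0/1`` or ``1/0 → Aa``, ``1/1 → aa``.  Multi-allelic
    records and missing or half-missing genotypes are rejected.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        subject_ids = tuple(str(s) for s in vcf.header.samples)
        snp_ids: list[str] = []
        columns: list[list[str]] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValidationError(
                    f"record {rec.chrom}:{rec.pos} is not biallelic"
                )
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            col = []
            for sample in subject_ids:
                gt = rec.samples[sample].get("GT")
                if gt is None or len(gt) != 2 or any(g is None for g in gt):
                    raise ValidationError(
                        f"missing/half-missing GT for sample {sample!r} at {snp_id}"
                    )
                if any(g not in (0, 1) for g in gt):
                    raise ValidationError(
                        f"non-biallelic GT {gt} for sample {sample!r} at {snp_id}"
                    )
                col.append({0: "AA", 1: "Aa", 2: "aa"}[gt[0] + gt[1]])
            snp_ids.append(snp_id)
            columns.append(col)
    calls = np.array(columns, dtype=object).T if columns else np.empty((len(subject_ids), 0), dtype=object)
    return GenotypeMatrix(subject_ids, tuple(snp_ids), calls)
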