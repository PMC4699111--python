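"""The three-role outsourcing protocol.

*Contributors* encode their share of the genotype/phenotype data, mask it
with the partition function, pack each vector block-wise both forward and
backward (four packed copies per SNP), encrypt and upload.  The untrusted
*cloud* aggregates uploads by homomorphic addition — by packing linearity
and ``Σ_q π(x, q) = x`` each aggregate encrypts the packing of the full
vector — then reduces each SNP (or SNP pair) to a handful of encrypted
scalar products: one ciphertext×ciphertext multiplication per allele-count
statistic and cheap plaintext multiplications against packed all-ones
vectors for the margins.  The *researcher* decrypts only those sufficient
statistics and reconstructs the frequency tables; no per-subject data ever
reaches cloud or researcher in the clear.

Per block the allelic table costs exactly 3 homomorphic multiplications
(one of them ciphertext×ciphertext) and a two-marker genotype table costs 6
(four ciphertext×ciphertext).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .backends import Ciphertext, KeyPair, _BaseBackend
from .encoding import (
    GenotypeMatrix,
    PartitionAssignment,
    PhenotypeVector,
    ValidationError,
    apply_partition,
    encode_phenotype,
    encode_snp,
)
from .packing import pack_backward, pack_forward, partition_vector
from .ring import ParameterError, RingElement, centered_mod, constant_term

__all__ = [
    "EncryptedBlockSet",
    "SnpUpload",
    "ContributorUpload",
    "AggregatedStore",
    "EncryptedAllelicStats",
    "EncryptedGenotypePairStats",
    "contributor_prepare",
    "cloud_aggregate",
    "cloud_allelic_products",
    "cloud_genotype_products",
    "cloud_genotype_margin_products",
    "researcher_decrypt_allelic",
    "researcher_decrypt_genotype",
    "researcher_decrypt_counts",
]


@dataclass(frozen=True)
class EncryptedBlockSet:
    """Ciphertexts of the packed blocks of one logical vector."""

    cts: tuple[Ciphertext, ...]
    direction: str
    block_lengths: tuple[int, ...]


@dataclass(frozen=True)
class SnpUpload:
    """The four packed-and-encrypted copies of one SNP's encoding."""

    fw_AA: EncryptedBlockSet
    bw_AA: EncryptedBlockSet
    fw_Aa: EncryptedBlockSet
    bw_Aa: EncryptedBlockSet


@dataclass(frozen=True)
class ContributorUpload:
    q: int
    M: int
    snp_ids: tuple[str, ...]
    snps: dict  # snp_id -> SnpUpload
    phenotype_bw: EncryptedBlockSet
    block_lengths: tuple[int, ...]


@dataclass(frozen=True)
class AggregatedStore:
    """Cloud-side store of homomorphically aggregated uploads."""

    M: int
    Q: int
    snp_ids: tuple[str, ...]
    snps: dict  # snp_id -> SnpUpload (aggregated)
    phenotype_bw: EncryptedBlockSet
    block_lengths: tuple[int, ...]


@dataclass(frozen=True)
class EncryptedAllelicStats:
    """Encrypted (o1, ⟨x_AA+x_Aa, 1⟩, ⟨y_case, 1⟩) for one SNP."""

    snp_id: str
    e_o1: Ciphertext
    e_colA: Ciphertext
    e_cases: Ciphertext


@dataclass(frozen=True)
class EncryptedGenotypePairStats:
    """Encrypted six scalar products for a two-marker genotype table."""

    snp_i: str
    snp_j: str
    e_s1: Ciphertext  # ⟨x_AA, x_BB⟩ = 4·o11
    e_s2: Ciphertext  # ⟨x_Aa, x_BB⟩ = 2·o12
    e_s3: Ciphertext  # ⟨x_AA, x_Bb⟩ = 2·o21
    e_s4: Ciphertext  # ⟨x_Aa, x_Bb⟩ = o22
    e_s5: Ciphertext  # ⟨x_AA + x_Aa, 1⟩
    e_s6: Ciphertext  # ⟨x_BB + x_Bb, 1⟩


def _pack_encrypt(
    vec: np.ndarray,
    direction: str,
    block_lengths: Sequence[int],
    backend: _BaseBackend,
    pk,
) -> EncryptedBlockSet:
    packer = pack_forward if direction == "forward" else pack_backward
    params = backend.params.ring
    cts, pos = [], 0
    for length in block_lengths:
        block = vec[pos : pos + length]
        pos += length
        cts.append(backend.encrypt(pk, packer(block, params)))
    return EncryptedBlockSet(tuple(cts), direction, tuple(block_lengths))


def contributor_prepare(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    assignment: PartitionAssignment,
    q: int,
    backend: _BaseBackend,
    pk,
) -> ContributorUpload:
    """Steps 1.1–1.2: encode, mask with π, block-pack and encrypt.

    Uploads four ciphertext block-sets per SNP (forward and backward packed
    ``x_AA`` and ``x_Aa``) plus one backward-packed phenotype block-set.
    """
    if genotypes.subject_ids != phenotypes.subject_ids:
        raise ValidationError(
            "genotype and phenotype subject orderings differ; inputs must be "
            "pre-aligned on identical subject ids"
        )
    M = genotypes.n_subjects
    t = backend.params.ring.t
    if 8 * M >= t:
        raise ParameterError(
            f"overflow guard: need t > 8*M = {8 * M} (largest genotype-table "
            f"scalar product is 4M), got t = {t}"
        )
    if (M, genotypes.n_snps) != (assignment.n_subjects, assignment.n_snps):
        raise ValidationError("assignment shape does not match the data")
    block_lengths = tuple(
        len(b) for b in partition_vector(np.zeros(M, dtype=np.int64), backend.params.ring.n)
    )
    snps = {}
    for j, snp_id in enumerate(genotypes.snp_ids):
        enc = encode_snp(genotypes.calls[:, j])
        owners = assignment.genotype_owner[:, j]
        x_AA = apply_partition(enc.x_AA, owners, q, assignment.Q)
        x_Aa = apply_partition(enc.x_Aa, owners, q, assignment.Q)
        snps[snp_id] = SnpUpload(
            fw_AA=_pack_encrypt(x_AA, "forward", block_lengths, backend, pk),
            bw_AA=_pack_encrypt(x_AA, "backward", block_lengths, backend, pk),
            fw_Aa=_pack_encrypt(x_Aa, "forward", block_lengths, backend, pk),
            bw_Aa=_pack_encrypt(x_Aa, "backward", block_lengths, backend, pk),
        )
    y = apply_partition(
        phenotypes.status, assignment.phenotype_owner, q, assignment.Q
    )
    return ContributorUpload(
        q=q,
        M=M,
        snp_ids=genotypes.snp_ids,
        snps=snps,
        phenotype_bw=_pack_encrypt(y, "backward", block_lengths, backend, pk),
        block_lengths=block_lengths,
    )


def _hadd_sets(
    a: EncryptedBlockSet, b: EncryptedBlockSet, backend: _BaseBackend
) -> EncryptedBlockSet:
    if a.direction != b.direction or a.block_lengths != b.block_lengths:
        raise ValidationError("uploads have mismatched block structure")
    return EncryptedBlockSet(
        tuple(backend.hadd(x, y) for x, y in zip(a.cts, b.cts)),
        a.direction,
        a.block_lengths,
    )


def cloud_aggregate(
    uploads: Sequence[ContributorUpload], backend: _BaseBackend
) -> AggregatedStore:
    """Step 2: homomorphic addition of all contributor uploads."""
    if not uploads:
        raise ValidationError("no uploads to aggregate")
    qs = sorted(u.q for u in uploads)
    Q = len(uploads)
    if qs != list(range(1, Q + 1)):
        raise ValidationError(
            f"expected uploads from contributors 1..{Q}, got {qs} (missing or duplicate)"
        )
    first = uploads[0]
    for u in uploads[1:]:
        if (u.M, u.snp_ids, u.block_lengths) != (
            first.M,
            first.snp_ids,
            first.block_lengths,
        ):
            raise ValidationError("uploads have mismatched shapes")
    snps = {s: u for s, u in uploads[0].snps.items()}
    pheno = uploads[0].phenotype_bw
    for u in uploads[1:]:
        for s in first.snp_ids:
            prev, cur = snps[s], u.snps[s]
            snps[s] = SnpUpload(
                fw_AA=_hadd_sets(prev.fw_AA, cur.fw_AA, backend),
                bw_AA=_hadd_sets(prev.bw_AA, cur.bw_AA, backend),
                fw_Aa=_hadd_sets(prev.fw_Aa, cur.fw_Aa, backend),
                bw_Aa=_hadd_sets(prev.bw_Aa, cur.bw_Aa, backend),
            )
        pheno = _hadd_sets(pheno, u.phenotype_bw, backend)
    return AggregatedStore(
        M=first.M,
        Q=Q,
        snp_ids=first.snp_ids,
        snps=snps,
        phenotype_bw=pheno,
        block_lengths=first.block_lengths,
    )


def _ones_plain(length: int, direction: str, backend: _BaseBackend) -> RingElement:
    packer = pack_forward if direction == "forward" else pack_backward
    return packer(np.ones(length, dtype=np.int64), backend.params.ring)


def _hadd_accumulate(acc, ct, backend):
    return ct if acc is None else backend.hadd(acc, ct)


def cloud_allelic_products(
    store: AggregatedStore, snp_id: str, backend: _BaseBackend
) -> EncryptedAllelicStats:
    """Step 3.1: encrypted sufficient statistics of the allelic table.

    Per block: one ciphertext×ciphertext multiplication for
    ``o1 = ⟨x_AA + x_Aa, y_case⟩`` and two plaintext multiplications against
    packed all-ones vectors for the margins — 3 multiplications in total.
    Per-block products are summed homomorphically, so the researcher
    decrypts a single ciphertext per statistic.
    """
    snp = store.snps[snp_id]
    e_o1 = e_col = e_cases = None
    for b, length in enumerate(store.block_lengths):
        fw_dose = backend.hadd(snp.fw_AA.cts[b], snp.fw_Aa.cts[b])
        bw_y = store.phenotype_bw.cts[b]
        e_o1 = _hadd_accumulate(e_o1, backend.hmult(fw_dose, bw_y), backend)
        e_col = _hadd_accumulate(
            e_col,
            backend.mult_plain(fw_dose, _ones_plain(length, "backward", backend)),
            backend,
        )
        e_cases = _hadd_accumulate(
            e_cases,
            backend.mult_plain(bw_y, _ones_plain(length, "forward", backend)),
            backend,
        )
    return EncryptedAllelicStats(snp_id=snp_id, e_o1=e_o1, e_colA=e_col, e_cases=e_cases)


def cloud_genotype_products(
    store: AggregatedStore, snp_i: str, snp_j: str, backend: _BaseBackend
) -> EncryptedGenotypePairStats:
    """Step 3.2: the six encrypted scalar products for a marker pair.

    Marker ``i`` plays alleles A/a and marker ``j`` plays B/b.  Per block:
    four ciphertext×ciphertext multiplications (s1..s4) plus two plaintext
    multiplications for the margins (s5, s6) — 6 in total.
    """
    if snp_i == snp_j:
        raise ValidationError("genotype pair requires two distinct SNPs")
    a, b_ = store.snps[snp_i], store.snps[snp_j]
    acc = [None] * 6
    for b, length in enumerate(store.block_lengths):
        prods = (
            backend.hmult(a.fw_AA.cts[b], b_.bw_AA.cts[b]),  # ⟨x_AA, x_BB⟩
            backend.hmult(a.fw_Aa.cts[b], b_.bw_AA.cts[b]),  # ⟨x_Aa, x_BB⟩
            backend.hmult(a.fw_AA.cts[b], b_.bw_Aa.cts[b]),  # ⟨x_AA, x_Bb⟩
            backend.hmult(a.fw_Aa.cts[b], b_.bw_Aa.cts[b]),  # ⟨x_Aa, x_Bb⟩
            backend.mult_plain(
                backend.hadd(a.fw_AA.cts[b], a.fw_Aa.cts[b]),
                _ones_plain(length, "backward", backend),
            ),
            backend.mult_plain(
                backend.hadd(b_.bw_AA.cts[b], b_.bw_Aa.cts[b]),
                _ones_plain(length, "forward", backend),
            ),
        )
        acc = [_hadd_accumulate(x, p, backend) for x, p in zip(acc, prods)]
    return EncryptedGenotypePairStats(snp_i, snp_j, *acc)


def cloud_genotype_margin_products(
    store: AggregatedStore, snp_id: str, backend: _BaseBackend
) -> tuple[Ciphertext, Ciphertext]:
    """Encrypted (⟨x_AA, 1⟩, ⟨x_Aa, 1⟩) — genotype counts for the HWE test.

    Not part of the minimal allelic reduction; two extra plaintext
    multiplications per block.
    """
    snp = store.snps[snp_id]
    e_AA = e_Aa = None
    for b, length in enumerate(store.block_lengths):
        ones_bw = _ones_plain(length, "backward", backend)
        e_AA = _hadd_accumulate(
            e_AA, backend.mult_plain(snp.fw_AA.cts[b], ones_bw), backend
        )
        e_Aa = _hadd_accumulate(
            e_Aa, backend.mult_plain(snp.fw_Aa.cts[b], ones_bw), backend
        )
    return e_AA, e_Aa


def _decrypt_count(backend: _BaseBackend, sk, ct: Ciphertext) -> int:
    return centered_mod(constant_term(backend.decrypt(sk, ct)), backend.params.ring.t)


def researcher_decrypt_allelic(
    backend: _BaseBackend, sk, stats: EncryptedAllelicStats
) -> tuple[int, int, int]:
    """Decrypt (o1, ⟨x_AA+x_Aa, 1⟩, case count) for one SNP."""
    return (
        _decrypt_count(backend, sk, stats.e_o1),
        _decrypt_count(backend, sk, stats.e_colA),
        _decrypt_count(backend, sk, stats.e_cases),
    )


def researcher_decrypt_genotype(
    backend: _BaseBackend, sk, stats: EncryptedGenotypePairStats
) -> tuple[int, int, int, int, int, int]:
    """Decrypt the six scalar products (s1..s6) for one marker pair."""
    return tuple(
        _decrypt_count(backend, sk, ct)
        for ct in (stats.e_s1, stats.e_s2, stats.e_s3, stats.e_s4, stats.e_s5, stats.e_s6)
    )


def researcher_decrypt_counts(
    backend: _BaseBackend, sk, cts: Sequence[Ciphertext]
) -> tuple[int, ...]:
    """Decrypt a sequence of count-carrying ciphertexts (constant terms)."""
    return tuple(_decrypt_count(backend, sk, ct) for ct in cts)
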