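"""Three-role protocol: uploads, aggregation, encrypted scalar products."""

import numpy as np
import pytest

from hegwas.backends import BackendParams, SecurityParams, make_backend
from hegwas.encoding import (
    GenotypeMatrix,
    PartitionAssignment,
    PhenotypeVector,
    ValidationError,
)
from hegwas.packing import pack_forward
from hegwas.protocol import (
    cloud_aggregate,
    cloud_allelic_products,
    cloud_genotype_margin_products,
    cloud_genotype_products,
    contributor_prepare,
    researcher_decrypt_allelic,
    researcher_decrypt_counts,
    researcher_decrypt_genotype,
)
from hegwas.ring import ParameterError, RingParams
from hegwas.simulate import SimulationConfig, simulate_dataset, split_across_contributors


PARAMS32 = BackendParams(ring=RingParams(32, 640007), security=SecurityParams(L=6, kappa=80))


def single_owner(M, N):
    return PartitionAssignment(
        Q=1,
        genotype_owner=np.ones((M, N), dtype=int),
        phenotype_owner=np.ones(M, dtype=int),
    )


def plaintext_scalar_products(genotypes, phenotypes):
    """Direct counting oracle for the allelic sufficient statistics."""
    dosage = genotypes.dosage()
    y = phenotypes.status
    return {
        snp: (
            int(dosage[:, j] @ y),
            int(dosage[:, j].sum()),
            int(y.sum()),
        )
        for j, snp in enumerate(genotypes.snp_ids)
    }


def plaintext_pair_products(genotypes, snp_i, snp_j):
    """Direct counting oracle for the six genotype-pair scalar products."""
    ci, cj = genotypes.column(snp_i), genotypes.column(snp_j)
    x_AA = np.where(ci == "AA", 2, 0)
    x_Aa = np.where(ci == "Aa", 1, 0)
    x_BB = np.where(cj == "AA", 2, 0)
    x_Bb = np.where(cj == "Aa", 1, 0)
    return (
        int(x_AA @ x_BB),
        int(x_Aa @ x_BB),
        int(x_AA @ x_Bb),
        int(x_Aa @ x_Bb),
        int((x_AA + x_Aa).sum()),
        int((x_BB + x_Bb).sum()),
    )


def run_to_store(genotypes, phenotypes, assignment, backend):
    keys = backend.keygen(1)
    uploads = [
        contributor_prepare(genotypes, phenotypes, assignment, q, backend, keys.pk)
        for q in range(1, assignment.Q + 1)
    ]
    return cloud_aggregate(uploads, backend), keys


def test_upload_shape_and_blocks(worked_four_subjects):
    genotypes, phenotypes = worked_four_subjects
    backend = make_backend("exact", PARAMS32)
    keys = backend.keygen()
    upload = contributor_prepare(
        genotypes, phenotypes, single_owner(4, 2), 1, backend, keys.pk
    )
    assert set(upload.snps) == {"m1", "m2"}
    for snp_upload in upload.snps.values():
        for bs in (snp_upload.fw_AA, snp_upload.bw_AA, snp_upload.fw_Aa, snp_upload.bw_Aa):
            assert len(bs.cts) == 1  # M=4 fits one block at n=32
    assert upload.phenotype_bw.direction == "backward"


def test_two_blocks_when_subjects_exceed_capacity():
    cfg = SimulationConfig(M=50, N=2, Q=1, seed=0)
    genotypes, phenotypes, assignment = simulate_dataset(cfg)
    backend = make_backend("exact", PARAMS32)
    keys = backend.keygen()
    upload = contributor_prepare(genotypes, phenotypes, assignment, 1, backend, keys.pk)
    assert upload.block_lengths == (25, 25)
    assert len(upload.snps["snp1"].fw_AA.cts) == 2


def test_overflow_guard():
    cfg = SimulationConfig(M=100, N=1, Q=1, seed=0)
    genotypes, phenotypes, assignment = simulate_dataset(cfg)
    tiny_t = BackendParams(
        ring=RingParams(128, 113), security=SecurityParams(L=1, kappa=1)
    )
    backend = make_backend("exact", tiny_t)
    keys = backend.keygen()
    with pytest.raises(ParameterError, match="t > 8"):
        contributor_prepare(genotypes, phenotypes, assignment, 1, backend, keys.pk)


def test_subject_misalignment_rejected(worked_four_subjects):
    genotypes, phenotypes = worked_four_subjects
    shuffled = PhenotypeVector(
        ("s4", "s2", "s3", "s1"), np.array([1, 0, 0, 1])
    )
    backend = make_backend("exact", PARAMS32)
    keys = backend.keygen()
    with pytest.raises(ValidationError, match="pre-aligned"):
        contributor_prepare(genotypes, shuffled, single_owner(4, 2), 1, backend, keys.pk)


def test_aggregate_reconstructs_full_vectors():
    """Aggregating Q=5 partitioned uploads decrypts to the packing of the
    full encoded vectors (plaintext-sum oracle via the exact backend)."""
    cfg = SimulationConfig(M=60, N=3, Q=5, partition_mode="horizontal", seed=8)
    genotypes, phenotypes, assignment = simulate_dataset(cfg)
    backend = make_backend("exact", BackendParams(ring=RingParams(64, 640007)))
    store, keys = run_to_store(genotypes, phenotypes, assignment, backend)
    from hegwas.encoding import encode_snp

    enc = encode_snp(genotypes.calls[:, 0])
    expected = pack_forward(enc.x_AA, backend.params.ring)
    got = backend.decrypt(keys.sk, store.snps["snp1"].fw_AA.cts[0])
    assert got == expected


def test_aggregate_missing_contributor_rejected(worked_four_subjects):
    genotypes, phenotypes = worked_four_subjects
    assignment = split_across_contributors(4, 2, 2, "horizontal")
    backend = make_backend("exact", PARAMS32)
    keys = backend.keygen()
    upload2 = contributor_prepare(genotypes, phenotypes, assignment, 2, backend, keys.pk)
    with pytest.raises(ValidationError, match="missing"):
        cloud_aggregate([upload2], backend)


def test_worked_allelic_statistics(worked_four_subjects):
    """Genotypes (AA, Aa, aa, AA), phenotype (1, 0, 0, 1): the decrypted
    sufficient statistics are (o1, column total, cases) = (4, 5, 2)."""
    genotypes, phenotypes = worked_four_subjects
    backend = make_backend("exact", PARAMS32)
    store, keys = run_to_store(genotypes, phenotypes, single_owner(4, 2), backend)
    stats = cloud_allelic_products(store, "m1", backend)
    assert researcher_decrypt_allelic(backend, keys.sk, stats) == (4, 5, 2)


def test_worked_genotype_pair_statistics(worked_four_subjects):
    """Marker pair (AA,Aa,aa,AA) x (AA,AA,Aa,aa): hand dot products give
    (s1..s6) = (4, 2, 0, 0, 5, 5)."""
    genotypes, phenotypes = worked_four_subjects
    backend = make_backend("exact", PARAMS32)
    store, keys = run_to_store(genotypes, phenotypes, single_owner(4, 2), backend)
    stats = cloud_genotype_products(store, "m1", "m2", backend)
    assert researcher_decrypt_genotype(backend, keys.sk, stats) == (4, 2, 0, 0, 5, 5)
    assert plaintext_pair_products(genotypes, "m1", "m2") == (4, 2, 0, 0, 5, 5)


def test_all_control_phenotype_zeroes_o1(worked_four_subjects):
    genotypes, _ = worked_four_subjects
    controls = PhenotypeVector(genotypes.subject_ids, np.zeros(4, dtype=int))
    backend = make_backend("exact", PARAMS32)
    store, keys = run_to_store(genotypes, controls, single_owner(4, 2), backend)
    o1, colA, cases = researcher_decrypt_allelic(
        backend, keys.sk, cloud_allelic_products(store, "m1", backend)
    )
    assert (o1, cases) == (0, 0) and colA == 5


def test_identical_all_AA_markers_pair_product():
    genotypes = GenotypeMatrix(
        ("s1", "s2", "s3"),
        ("m1", "m2"),
        np.array([["AA", "AA"]] * 3, dtype=object),
    )
    phenotypes = PhenotypeVector(("s1", "s2", "s3"), np.array([1, 0, 1]))
    backend = make_backend("exact", PARAMS32)
    store, keys = run_to_store(genotypes, phenotypes, single_owner(3, 2), backend)
    s = researcher_decrypt_genotype(
        backend, keys.sk, cloud_genotype_products(store, "m1", "m2", backend)
    )
    assert s[0] == 4 * 3  # <2*ones, 2*ones> = 4M


def test_same_snp_pair_rejected(worked_four_subjects):
    genotypes, phenotypes = worked_four_subjects
    backend = make_backend("exact", PARAMS32)
    store, _ = run_to_store(genotypes, phenotypes, single_owner(4, 2), backend)
    with pytest.raises(ValidationError):
        cloud_genotype_products(store, "m1", "m1", backend)


@pytest.mark.parametrize("M,n_expected_blocks", [(20, 1), (50, 2), (100, 4)])
def test_multiplication_accounting(M, n_expected_blocks):
    """3 multiplications per block for the allelic table, 6 per block for a
    genotype pair; exactly 1 resp. 4 of them ciphertext x ciphertext."""
    cfg = SimulationConfig(M=M, N=2, Q=1, seed=3)
    genotypes, phenotypes, assignment = simulate_dataset(cfg)
    backend = make_backend("exact", PARAMS32)
    store, keys = run_to_store(genotypes, phenotypes, assignment, backend)
    B = len(store.block_lengths)
    assert B == n_expected_blocks

    backend.reset_counts()
    cloud_allelic_products(store, "snp1", backend)
    assert backend.multiplication_count == 3 * B
    assert backend.counts["hmult"] == B

    backend.reset_counts()
    cloud_genotype_products(store, "snp1", "snp2", backend)
    assert backend.multiplication_count == 6 * B
    assert backend.counts["hmult"] == 4 * B


def test_hwe_margin_products():
    cfg = SimulationConfig(M=40, N=1, Q=1, seed=5)
    genotypes, phenotypes, assignment = simulate_dataset(cfg)
    backend = make_backend("exact", PARAMS32)
    store, keys = run_to_store(genotypes, phenotypes, assignment, backend)
    e_AA, e_Aa = cloud_genotype_margin_products(store, "snp1", backend)
    sAA, sAa = researcher_decrypt_counts(backend, keys.sk, (e_AA, e_Aa))
    calls = genotypes.calls[:, 0]
    assert sAA == 2 * int((calls == "AA").sum())
    assert sAa == int((calls == "Aa").sum())


@pytest.mark.parametrize("mode", ["horizontal", "vertical", "random"])
@pytest.mark.parametrize("Q", [1, 2, 5])
def test_end_to_end_equals_plaintext_counting_exact(mode, Q):
    """Decrypted sufficient statistics equal direct counting for every
    contributor count and partition mode (exact backend)."""
    cfg = SimulationConfig(M=120, N=4, Q=Q, partition_mode=mode, seed=Q * 10 + 1)
    genotypes, phenotypes, assignment = simulate_dataset(cfg)
    backend = make_backend("exact", BackendParams(ring=RingParams(64, 640007)))
    store, keys = run_to_store(genotypes, phenotypes, assignment, backend)
    oracle = plaintext_scalar_products(genotypes, phenotypes)
    for snp in genotypes.snp_ids:
        stats = cloud_allelic_products(store, snp, backend)
        assert researcher_decrypt_allelic(backend, keys.sk, stats) == oracle[snp]
    s = researcher_decrypt_genotype(
        backend, keys.sk, cloud_genotype_products(store, "snp1", "snp2", backend)
    )
    assert s == plaintext_pair_products(genotypes, "snp1", "snp2")


@pytest.mark.parametrize("mode", ["horizontal", "vertical"])
def test_end_to_end_equals_plaintext_counting_rlwe(mode):
    """Same equality under genuine RLWE encryption (smaller M for speed)."""
    cfg = SimulationConfig(M=40, N=3, Q=2, partition_mode=mode, seed=21)
    genotypes, phenotypes, assignment = simulate_dataset(cfg)
    backend = make_backend("rlwe", PARAMS32, seed=13)
    store, keys = run_to_store(genotypes, phenotypes, assignment, backend)
    oracle = plaintext_scalar_products(genotypes, phenotypes)
    for snp in genotypes.snp_ids:
        stats = cloud_allelic_products(store, snp, backend)
        assert researcher_decrypt_allelic(backend, keys.sk, stats) == oracle[snp]
    s = researcher_decrypt_genotype(
        backend, keys.sk, cloud_genotype_products(store, "snp1", "snp3", backend)
    )
    assert s == plaintext_pair_products(genotypes, "snp1", "snp3")


def test_partition_invariance():
    """Any owner map over the same data yields identical decrypted
    statistics."""
    cfg = SimulationConfig(M=60, N=2, Q=3, seed=2)
    genotypes, phenotypes, _ = simulate_dataset(cfg)
    backend = make_backend("exact", BackendParams(ring=RingParams(64, 640007)))
    results = []
    for mode in ("horizontal", "vertical", "random"):
        assignment = split_across_contributors(60, 2, 3, mode, seed=99)
        store, keys = run_to_store(genotypes, phenotypes, assignment, backend)
        results.append(
            researcher_decrypt_allelic(
                backend, keys.sk, cloud_allelic_products(store, "snp1", backend)
            )
        )
    assert results[0] == results[1] == results[2]
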