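"""Synthetic case-control genotype data with known statistical structure.

Genotypes are drawn per SNP under Hardy-Weinberg proportions at an
allele-A frequency sampled from a configurable range (allele ``A`` is the
minor allele, so the frequency range is interpreted as a MAF range).
Phenotypes follow a logistic disease model with per-allele odds ratios for
a chosen set of effect SNPs and an intercept solved numerically so that the
expected case fraction matches the configuration; null SNPs have odds
ratio 1, which is what the type-I-error calibration of the chi-square test
relies on.  LD marker pairs are simulated at the haplotype level with the
standard (p_AB, p_Ab, p_aB, p_ab) parameterisation at a target D, then
haplotypes are paired at random into genotypes (random mating).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .encoding import (
    GenotypeMatrix,
    PartitionAssignment,
    PhenotypeVector,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "feasible_D_range",
    "simulate_genotypes",
    "simulate_ld_pair",
    "simulate_phenotypes",
    "split_across_contributors",
    "simulate_dataset",
]

_CALLS = np.array(["aa", "Aa", "AA"], dtype=object)  # indexed by allele-A dosage


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for one synthetic dataset.

    Defaults give a small case-control panel (500 subjects, 10 independent
    SNPs, MAF uniform on [0.05, 0.5], balanced phenotype, 3 contributors
    holding disjoint subject blocks) that exercises every protocol stage in
    seconds.
    """

    M: int = 500
    N: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    case_fraction: float = 0.5
    effect_snps: dict = field(default_factory=dict)  # snp_id -> allelic odds ratio
    ld_pairs: tuple = ()  # (pA, pB, target D) triples
    Q: int = 3
    partition_mode: str = "horizontal"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if not 0 < self.case_fraction < 1:
            raise ValidationError("case_fraction must be in (0, 1)")
        if self.M < 1 or self.N < 0 or self.Q < 1:
            raise ValidationError("M >= 1, N >= 0 and Q >= 1 required")
        for pA, pB, D in self.ld_pairs:
            lo_D, hi_D = feasible_D_range(pA, pB)
            if not lo_D <= D <= hi_D:
                raise ValidationError(
                    f"target D={D} infeasible for (pA={pA}, pB={pB}); "
                    f"feasible range [{lo_D:.4f}, {hi_D:.4f}]"
                )


def feasible_D_range(pA: float, pB: float) -> tuple[float, float]:
    """The interval of D values compatible with marginal frequencies pA, pB."""
    if not (0 <= pA <= 1 and 0 <= pB <= 1):
        raise ValidationError("allele frequencies must lie in [0, 1]")
    return (
        -min(pA * pB, (1 - pA) * (1 - pB)),
        min(pA * (1 - pB), (1 - pA) * pB),
    )


def _dosage_to_calls(dosage: np.ndarray) -> np.ndarray:
    return _CALLS[dosage]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Independent SNPs under HWE; per-SNP MAF uniform on ``maf_range``.

    LD pairs configured in ``config.ld_pairs`` are appended after the ``N``
    independent SNPs, two columns per pair (ids ``ldkA``/``ldkB``).
    """
    rng = np.random.default_rng(config.seed)
    snp_ids = [f"snp{j + 1}" for j in range(config.N)]
    columns = []
    lo, hi = config.maf_range
    for _ in range(config.N):
        maf = rng.uniform(lo, hi)
        dosage = rng.binomial(2, maf, size=config.M)
        columns.append(_dosage_to_calls(dosage))
    for k, (pA, pB, D) in enumerate(config.ld_pairs):
        seed_k = int(rng.integers(0, 2**31 - 1))
        col_a, col_b = simulate_ld_pair(pA, pB, D, config.M, seed_k)
        snp_ids += [f"ld{k + 1}A", f"ld{k + 1}B"]
        columns += [col_a, col_b]
    subject_ids = tuple(f"s{i + 1}" for i in range(config.M))
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((config.M, 0), dtype=object)
    )
    return GenotypeMatrix(subject_ids, tuple(snp_ids), calls)


def simulate_ld_pair(
    pA: float, pB: float, D: float, M: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two genotype columns with target composite LD coefficient D.

    Haplotypes AB/Ab/aB/ab are drawn with frequencies
    ``(pA·pB + D, pA(1-pB) - D, (1-pA)pB - D, (1-pA)(1-pB) + D)`` and paired
    consecutively into diploid genotypes.
    """
    lo_D, hi_D = feasible_D_range(pA, pB)
    if not lo_D <= D <= hi_D:
        raise ValidationError(
            f"target D={D} infeasible for (pA={pA}, pB={pB})"
        )
    freqs = np.array(
        [
            pA * pB + D,
            pA * (1 - pB) - D,
            (1 - pA) * pB - D,
            (1 - pA) * (1 - pB) + D,
        ]
    )
    freqs = np.clip(freqs, 0.0, None)
    freqs = freqs / freqs.sum()
    rng = np.random.default_rng(seed)
    haplotypes = rng.choice(4, size=2 * M, p=freqs)
    carries_A = (haplotypes < 2).astype(np.int64)  # AB or Ab
    carries_B = (haplotypes % 2 == 0).astype(np.int64)  # AB or aB
    dose_a = carries_A[0::2] + carries_A[1::2]
    dose_b = carries_B[0::2] + carries_B[1::2]
    return _dosage_to_calls(dose_a), _dosage_to_calls(dose_b)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> PhenotypeVector:
    """Case/control labels from a logistic model on allele-A dosage.

    ``logit P(case_i) = b0 + Σ_j log(OR_j)·dosage_ij`` over the configured
    effect SNPs; ``b0`` is solved so the expected case fraction equals
    ``config.case_fraction``.  With no effect SNPs the phenotype is
    independent of all genotypes.
    """
    for snp in config.effect_snps:
        if snp not in genotypes.snp_ids:
            raise ValidationError(f"effect SNP {snp!r} not present in the genotypes")
    rng = np.random.default_rng(config.seed + 1)
    linear = np.zeros(genotypes.n_subjects)
    dosage = genotypes.dosage()
    for snp, odds_ratio in config.effect_snps.items():
        j = genotypes.snp_ids.index(snp)
        linear += np.log(odds_ratio) * dosage[:, j]

    def mean_risk(b0: float) -> float:
        return float(expit(b0 + linear).mean()) - config.case_fraction

    b0 = brentq(mean_risk, -40.0, 40.0) if config.effect_snps else float(
        np.log(config.case_fraction / (1 - config.case_fraction))
    )
    status = (rng.random(genotypes.n_subjects) < expit(b0 + linear)).astype(np.int64)
    return PhenotypeVector(genotypes.subject_ids, status)


def split_across_contributors(
    M: int, N: int, Q: int, mode: str = "horizontal", seed: int = 0
) -> PartitionAssignment:
    """Owner maps for Q contributors.

    ``horizontal``: subjects in Q contiguous near-equal groups (each
    contributor holds all columns of its subjects, phenotype included).
    ``vertical``: SNP columns dealt round-robin; the phenotype goes to
    contributor 1.  ``random``: every element owned uniformly at random.
    """
    if Q < 1:
        raise ValidationError("Q must be >= 1")
    if mode == "horizontal":
        if Q > M:
            raise ValidationError(f"horizontal split needs Q <= M (Q={Q}, M={M})")
        bounds = np.linspace(0, M, Q + 1).astype(int)
        owner_subject = np.empty(M, dtype=np.int64)
        for q in range(Q):
            owner_subject[bounds[q] : bounds[q + 1]] = q + 1
        genotype_owner = np.repeat(owner_subject[:, None], N, axis=1)
        phenotype_owner = owner_subject
    elif mode == "vertical":
        owner_col = (np.arange(N) % Q) + 1
        genotype_owner = np.repeat(owner_col[None, :], M, axis=0)
        phenotype_owner = np.ones(M, dtype=np.int64)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        genotype_owner = rng.integers(1, Q + 1, size=(M, N))
        phenotype_owner = rng.integers(1, Q + 1, size=M)
    else:
        raise ValidationError(f"unknown partition mode {mode!r}")
    return PartitionAssignment(
        Q=Q, genotype_owner=genotype_owner, phenotype_owner=phenotype_owner
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PhenotypeVector, PartitionAssignment]:
    """Genotypes + phenotypes + contributor assignment in one call."""
    genotypes = simulate_genotypes(config)
    phenotypes = simulate_phenotypes(genotypes, config)
    assignment = split_across_contributors(
        genotypes.n_subjects,
        genotypes.n_snps,
        config.Q,
        config.partition_mode,
        config.seed + 2,
    )
    return genotypes, phenotypes, assignment
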