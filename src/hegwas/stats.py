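"""Frequency-table reconstruction and association / LD statistics.

The decrypted protocol output is a handful of integer scalar products per
SNP (or SNP pair).  Because the 2×2 allelic table has one degree of freedom
once the subject count ``M`` is known, three integers — ``o1`` (allele-A
count among cases), the allele-A column total and the case count — fix the
whole table.  The additive-model chi-square

    χ²_a = 2M (o2(o3+o4) - o4(o1+o2))² / (N1 N2 N1' N2')

is then the classical 1-df Pearson statistic on that table.  For a marker
pair, six scalar products yield the genotype-pair cells needed for the
composite LD estimate: D = p_AB - p_A p_B with the double-heterozygote
count ``o22`` left out of p_A and p_B to dodge haplotype-phase ambiguity,
and D′ is D over its Lewontin feasibility bound.

All count arithmetic is exact-integer; only the final statistics are
floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "InconsistencyError",
    "AllelicTable",
    "GenotypePairStats",
    "Chi2Result",
    "LDResult",
    "reconstruct_allelic_table",
    "chi2_additive",
    "reconstruct_genotype_pair",
    "ld_measures",
    "composite_ld_expectation",
    "hwe_chi2",
]


class InconsistencyError(ValueError):
    """Scalar products inconsistent with any valid frequency table."""


@dataclass(frozen=True)
class AllelicTable:
    """2×2 case/control × allele-type count table with margins.

    Rows: case (o1, o2), control (o3, o4); columns: allele A, allele a.
    ``N1, N2`` are row totals, ``N1p, N2p`` column totals; the grand total
    is ``2M`` alleles.
    """

    o1: int
    o2: int
    o3: int
    o4: int
    M: int

    def __post_init__(self) -> None:
        if min(self.o1, self.o2, self.o3, self.o4) < 0:
            raise InconsistencyError(
                f"negative allele count in table {(self.o1, self.o2, self.o3, self.o4)}"
            )
        if self.o1 + self.o2 + self.o3 + self.o4 != 2 * self.M:
            raise InconsistencyError("allele counts do not sum to 2M")

    @property
    def N1(self) -> int:
        return self.o1 + self.o2

    @property
    def N2(self) -> int:
        return self.o3 + self.o4

    @property
    def N1p(self) -> int:
        return self.o1 + self.o3

    @property
    def N2p(self) -> int:
        return self.o2 + self.o4


@dataclass(frozen=True)
class GenotypePairStats:
    """Counts recovered from the six marker-pair scalar products.

    ``o11, o12, o21, o22`` are the AABB / AaBB / AABb / AaBb subject counts;
    ``mA = 2·N_AA + N_Aa`` and ``mB = 2·N_BB + N_Bb`` are allele-dosage
    margins over all subjects.
    """

    o11: int
    o12: int
    o21: int
    o22: int
    mA: int
    mB: int
    M: int


@dataclass(frozen=True)
class Chi2Result:
    """A 1-df chi-square statistic; ``undefined`` flags degenerate tables."""

    statistic: float
    undefined: bool = False
    df: int = 1

    @property
    def p_value(self) -> float:
        if self.undefined:
            return float("nan")
        return float(_chi2_dist.sf(self.statistic, self.df))


@dataclass(frozen=True)
class LDResult:
    pAB: float
    pA: float
    pB: float
    D: float
    Dprime: float
    undefined: bool = False  # Dprime undefined (fixed locus)


def reconstruct_allelic_table(o1: int, colA: int, cases: int, M: int) -> AllelicTable:
    """Rebuild the full allelic table from its three sufficient statistics.

    ``o1``: allele-A count among cases; ``colA``: allele-A column total
    ``⟨x_AA + x_Aa, 1⟩``; ``cases``: number of case subjects.  Row totals are
    2×(subject counts) since each subject carries two alleles.
    """
    o1, colA, cases, M = int(o1), int(colA), int(cases), int(M)
    N1 = 2 * cases
    N1p = colA
    o2 = N1 - o1
    o3 = N1p - o1
    o4 = (2 * M - N1p) - o2
    if min(o1, o2, o3, o4) < 0:
        raise InconsistencyError(
            f"statistics (o1={o1}, colA={colA}, cases={cases}, M={M}) imply a "
            f"negative cell: {(o1, o2, o3, o4)}"
        )
    return AllelicTable(o1=o1, o2=o2, o3=o3, o4=o4, M=M)


def chi2_additive(table: AllelicTable) -> Chi2Result:
    """Additive-model 1-df chi-square on the allelic table.

    Returns an ``undefined`` result when any margin is zero (monomorphic
    site or single-class phenotype).
    """
    N1, N2, N1p, N2p = table.N1, table.N2, table.N1p, table.N2p
    if 0 in (N1, N2, N1p, N2p):
        return Chi2Result(statistic=float("nan"), undefined=True)
    num = 2 * table.M * (table.o2 * N2 - table.o4 * N1) ** 2
    return Chi2Result(statistic=num / (N1 * N2 * N1p * N2p))


def reconstruct_genotype_pair(
    s1: int, s2: int, s3: int, s4: int, s5: int, s6: int, M: int
) -> GenotypePairStats:
    """Recover pair counts from the six scalar products.

    ``s1 = 4·o11``, ``s2 = 2·o12``, ``s3 = 2·o21``, ``s4 = o22``,
    ``s5 = mA``, ``s6 = mB``; divisibility violations signal corrupted
    statistics and raise.
    """
    s = tuple(int(v) for v in (s1, s2, s3, s4, s5, s6))
    if s[0] % 4 != 0:
        raise InconsistencyError(f"s1 = {s[0]} is not divisible by 4")
    if s[1] % 2 != 0 or s[2] % 2 != 0:
        raise InconsistencyError(f"s2 = {s[1]} and s3 = {s[2]} must be even")
    if any(v < 0 or v > 4 * M for v in s):
        raise InconsistencyError(f"scalar products {s} outside [0, 4M] for M={M}")
    return GenotypePairStats(
        o11=s[0] // 4, o12=s[1] // 2, o21=s[2] // 2, o22=s[3], mA=s[4], mB=s[5], M=int(M)
    )


def ld_measures(g: GenotypePairStats) -> LDResult:
    """Composite LD coefficient D and Lewontin's D′ from pair counts.

    ``p_AB = (2·o11 + o12 + o21)/2M``; ``p_A = (mA - o22)/2M`` and
    ``p_B = (mB - o22)/2M`` drop the ambiguous double heterozygotes.
    D′ normalises D by its feasibility bound given (p_A, p_B); it is 0 at
    D = 0 and flagged undefined when the bound vanishes (fixed locus).
    """
    if g.M < 1:
        raise InconsistencyError("M must be >= 1")
    two_m = 2 * g.M
    pAB = (2 * g.o11 + g.o12 + g.o21) / two_m
    pA = (g.mA - g.o22) / two_m
    pB = (g.mB - g.o22) / two_m
    D = pAB - pA * pB
    if D > 0:
        Dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        Dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return LDResult(pAB=pAB, pA=pA, pB=pB, D=0.0, Dprime=0.0)
    if Dmax == 0:
        return LDResult(pAB=pAB, pA=pA, pB=pB, D=D, Dprime=float("nan"), undefined=True)
    return LDResult(pAB=pAB, pA=pA, pB=pB, D=D, Dprime=D / Dmax)


def composite_ld_expectation(pA: float, pB: float, D: float) -> LDResult:
    """Exact sampling expectation of the genotype-based LD statistic.

    The statistic computed by :func:`ld_measures` drops the phase-ambiguous
    double heterozygotes, so it is *not* an unbiased estimator of the
    haplotype-level coefficient D.  Under random mating with haplotype
    frequencies ``(pA·pB + D, pA(1-pB) - D, (1-pA)pB - D, (1-pA)(1-pB) + D)``
    the per-subject cell probabilities give, in closed form,

        E[p̂_AB] = p_AB (1 - p_ab)
        E[p̂_A]  = p_A - (p_AB p_ab + p_Ab p_aB)      (and symmetrically p̂_B)

    since an AaBb subject arises from AB/ab or Ab/aB haplotype pairs.  This
    is the population value the genotype-table pipeline converges to; use
    it as the reference when validating simulations.  (At the feasibility
    boundary the bias vanishes and D′ still reaches ±1.)
    """
    pAB = pA * pB + D
    pAb = pA * (1 - pB) - D
    paB = (1 - pA) * pB - D
    pab = (1 - pA) * (1 - pB) + D
    if min(pAB, pAb, paB, pab) < -1e-12:
        raise InconsistencyError(f"D={D} infeasible for (pA={pA}, pB={pB})")
    exp_pAB = pAB * (1 - pab)
    ambiguous = pAB * pab + pAb * paB
    exp_pA = pA - ambiguous
    exp_pB = pB - ambiguous
    exp_D = exp_pAB - exp_pA * exp_pB
    if exp_D > 0:
        Dmax = min(exp_pA * (1 - exp_pB), (1 - exp_pA) * exp_pB)
    elif exp_D < 0:
        Dmax = min(exp_pA * exp_pB, (1 - exp_pA) * (1 - exp_pB))
    else:
        return LDResult(pAB=exp_pAB, pA=exp_pA, pB=exp_pB, D=0.0, Dprime=0.0)
    if Dmax == 0:
        return LDResult(
            pAB=exp_pAB, pA=exp_pA, pB=exp_pB, D=exp_D, Dprime=float("nan"), undefined=True
        )
    return LDResult(pAB=exp_pAB, pA=exp_pA, pB=exp_pB, D=exp_D, Dprime=exp_D / Dmax)


def hwe_chi2(nAA: int, nAa: int, naa: int) -> Chi2Result:
    """1-df goodness-of-fit test of Hardy-Weinberg proportions.

    Expected counts come from the estimated allele frequency
    ``p̂ = (2·nAA + nAa) / 2M``; a monomorphic sample is flagged undefined.
    """
    nAA, nAa, naa = int(nAA), int(nAa), int(naa)
    if min(nAA, nAa, naa) < 0:
        raise InconsistencyError("genotype counts must be non-negative")
    M = nAA + nAa + naa
    if M < 1:
        raise InconsistencyError("at least one subject required")
    p = (2 * nAA + nAa) / (2 * M)
    if p in (0.0, 1.0):
        return Chi2Result(statistic=float("nan"), undefined=True)
    expected = (M * p * p, 2 * M * p * (1 - p), M * (1 - p) * (1 - p))
    stat = sum(
        (obs - exp) ** 2 / exp for obs, exp in zip((nAA, nAa, naa), expected)
    )
    return Chi2Result(statistic=float(stat))
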