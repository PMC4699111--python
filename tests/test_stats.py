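"""Frequency-table reconstruction, chi-square, HWE and LD statistics."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from hegwas.stats import (
    AllelicTable,
    Chi2Result,
    GenotypePairStats,
    InconsistencyError,
    chi2_additive,
    hwe_chi2,
    ld_measures,
    reconstruct_allelic_table,
    reconstruct_genotype_pair,
)


# -- allelic table ----------------------------------------------------------

def test_reconstruct_allelic_table_zeros():
    table = reconstruct_allelic_table(0, 0, 0, 5)
    assert (table.o1, table.o2, table.o3) == (0, 0, 0)
    assert table.o4 == 10  # all controls, all minor-homozygous
    assert table.N2 == 10 and table.N2p == 10


def test_reconstruct_allelic_table_worked():
    table = reconstruct_allelic_table(30, 50, 20, 40)
    assert (table.o1, table.o2, table.o3, table.o4) == (30, 10, 20, 20)
    assert (table.N1, table.N2, table.N1p, table.N2p) == (40, 40, 50, 30)


def test_reconstruct_allelic_table_four_subject_protocol_set():
    table = reconstruct_allelic_table(4, 5, 2, 4)
    assert (table.o2, table.o3, table.o4) == (0, 1, 3)


def test_reconstruct_allelic_table_inconsistency():
    with pytest.raises(InconsistencyError):
        reconstruct_allelic_table(5, 4, 2, 4)  # o3 = colA - o1 < 0


def test_allelic_margin_identities_random():
    rng = np.random.default_rng(0)
    for _ in range(200):
        M = int(rng.integers(1, 200))
        cases = int(rng.integers(0, M + 1))
        colA = int(rng.integers(0, 2 * M + 1))
        o1 = int(rng.integers(max(0, colA - 2 * (M - cases)), min(2 * cases, colA) + 1))
        table = reconstruct_allelic_table(o1, colA, cases, M)
        assert table.o1 + table.o2 == table.N1 == 2 * cases
        assert table.o3 + table.o4 == table.N2
        assert table.o1 + table.o3 == table.N1p == colA
        assert table.o2 + table.o4 == table.N2p
        assert table.N1 + table.N2 == 2 * M == table.N1p + table.N2p


# -- additive chi-square ----------------------------------------------------

def test_chi2_additive_worked_value():
    table = AllelicTable(30, 10, 20, 20, M=40)
    assert chi2_additive(table).statistic == pytest.approx(16 / 3)


def test_chi2_additive_null_table():
    # proportional rows: no association
    assert chi2_additive(AllelicTable(30, 10, 30, 10, M=40)).statistic == 0.0


def test_chi2_additive_monomorphic_flagged():
    result = chi2_additive(AllelicTable(40, 0, 40, 0, M=40))
    assert result.undefined and np.isnan(result.p_value)


def test_chi2_additive_equals_pearson_on_random_tables():
    """The additive statistic is algebraically the Pearson 2x2 statistic
    N (ad - bc)^2 / (r1 r2 c1 c2); checked on >= 1000 random tables."""
    rng = np.random.default_rng(1)
    checked = 0
    while checked < 1000:
        o = rng.integers(1, 80, 4)
        M2 = int(o.sum())
        if M2 % 2:
            continue
        table = AllelicTable(int(o[0]), int(o[1]), int(o[2]), int(o[3]), M=M2 // 2)
        a, b, c, d = (int(v) for v in o)
        pearson = (
            (a + b + c + d)
            * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        assert chi2_additive(table).statistic == pytest.approx(pearson, rel=1e-12)
        checked += 1


def test_chi2_additive_matches_scipy_uncorrected():
    observed = np.array([[30, 10], [20, 20]])
    expected = chi2_contingency(observed, correction=False).statistic
    assert chi2_additive(AllelicTable(30, 10, 20, 20, M=40)).statistic == (
        pytest.approx(expected)
    )


def test_chi2_p_value_range():
    result = chi2_additive(AllelicTable(30, 10, 20, 20, M=40))
    assert 0 < result.p_value < 0.05  # 16/3 > 3.84 at 1 df


# -- genotype-pair reconstruction ------------------------------------------

def test_reconstruct_genotype_pair_zero():
    g = reconstruct_genotype_pair(0, 0, 0, 0, 0, 0, M=4)
    assert (g.o11, g.o12, g.o21, g.o22, g.mA, g.mB) == (0, 0, 0, 0, 0, 0)


def test_reconstruct_genotype_pair_worked():
    g = reconstruct_genotype_pair(4, 2, 0, 0, 5, 5, M=4)
    assert (g.o11, g.o12, g.o21, g.o22) == (1, 1, 0, 0)
    assert (g.mA, g.mB) == (5, 5)


def test_reconstruct_genotype_pair_divisibility():
    with pytest.raises(InconsistencyError):
        reconstruct_genotype_pair(2, 0, 0, 0, 0, 0, M=4)
    with pytest.raises(InconsistencyError):
        reconstruct_genotype_pair(4, 3, 0, 0, 0, 0, M=4)
    with pytest.raises(InconsistencyError):
        reconstruct_genotype_pair(4, 2, 2, 0, 99, 0, M=4)  # s5 > 4M


# -- LD measures ------------------------------------------------------------

def test_ld_worked_example():
    g = GenotypePairStats(o11=20, o12=10, o21=10, o22=5, mA=75, mB=75, M=50)
    ld = ld_measures(g)
    assert ld.pAB == pytest.approx(0.6)
    assert ld.pA == pytest.approx(0.7)
    assert ld.pB == pytest.approx(0.7)
    assert ld.D == pytest.approx(0.11)
    assert ld.Dprime == pytest.approx(0.11 / 0.21)


def test_ld_fixed_loci():
    # every subject AABB: pAB = pA = pB = 1, D = 0 by convention D' = 0
    g = GenotypePairStats(o11=10, o12=0, o21=0, o22=0, mA=20, mB=20, M=10)
    ld = ld_measures(g)
    assert (ld.pAB, ld.pA, ld.pB) == (1.0, 1.0, 1.0)
    assert ld.D == 0.0 and ld.Dprime == 0.0


def test_ld_negative_D_normalisation():
    g = GenotypePairStats(o11=0, o12=2, o21=2, o22=0, mA=20, mB=20, M=20)
    ld = ld_measures(g)
    assert ld.D == pytest.approx(-0.15)
    assert ld.Dprime == pytest.approx(-0.6)


def test_ld_independent_loci_simulation_matches_expectation():
    """Independent haplotype draws reproduce the statistic's closed-form
    expectation (which is non-zero: omitting o22 biases D upward here)."""
    from hegwas.stats import composite_ld_expectation

    rng = np.random.default_rng(2)
    M = 20000
    pA, pB = 0.6, 0.3
    hap_A = rng.random(2 * M) < pA
    hap_B = rng.random(2 * M) < pB
    dose_A = hap_A[0::2].astype(int) + hap_A[1::2].astype(int)
    dose_B = hap_B[0::2].astype(int) + hap_B[1::2].astype(int)
    x_AA, x_Aa = 2 * (dose_A == 2), (dose_A == 1).astype(int)
    x_BB, x_Bb = 2 * (dose_B == 2), (dose_B == 1).astype(int)
    g = reconstruct_genotype_pair(
        int(x_AA @ x_BB),
        int(x_Aa @ x_BB),
        int(x_AA @ x_Bb),
        int(x_Aa @ x_Bb),
        int((x_AA + x_Aa).sum()),
        int((x_BB + x_Bb).sum()),
        M=M,
    )
    ld = ld_measures(g)
    expected = composite_ld_expectation(pA, pB, 0.0)
    assert ld.D == pytest.approx(expected.D, abs=0.01)
    assert ld.pA == pytest.approx(expected.pA, abs=0.01)
    assert ld.pAB == pytest.approx(expected.pAB, abs=0.01)


def test_composite_ld_expectation_worked_values():
    """Closed-form expectation checked against hand computation:
    (pA, pB, D) = (0.7, 0.7, 0.11) -> haplotypes (0.6, 0.1, 0.1, 0.2);
    E[pAB] = 0.6 * 0.8 = 0.48; ambiguous mass = 0.6*0.2 + 0.1*0.1 = 0.13;
    E[pA] = E[pB] = 0.57; E[D] = 0.48 - 0.57^2 = 0.1551."""
    from hegwas.stats import composite_ld_expectation

    exp = composite_ld_expectation(0.7, 0.7, 0.11)
    assert exp.pAB == pytest.approx(0.48)
    assert exp.pA == pytest.approx(0.57)
    assert exp.D == pytest.approx(0.1551)
    # at the feasibility boundary the estimator still reaches D' = 1
    exp_max = composite_ld_expectation(0.5, 0.5, 0.25)
    assert exp_max.Dprime == pytest.approx(1.0)
    # and it is exact when no double heterozygotes can occur (D = 0 with a
    # fixed locus)
    exp_fixed = composite_ld_expectation(1.0, 0.3, 0.0)
    assert exp_fixed.D == pytest.approx(0.0)


# -- HWE --------------------------------------------------------------------

def test_hwe_exact_proportions():
    assert hwe_chi2(25, 50, 25).statistic == 0.0


def test_hwe_worked_value():
    # p = 0.5, expected (25, 50, 25), observed (30, 40, 30) -> 1 + 2 + 1
    assert hwe_chi2(30, 40, 30).statistic == pytest.approx(4.0)


def test_hwe_monomorphic_flagged():
    assert hwe_chi2(50, 0, 0).undefined
    assert hwe_chi2(0, 0, 50).undefined


def test_hwe_input_validation():
    with pytest.raises(InconsistencyError):
        hwe_chi2(-1, 2, 3)
    with pytest.raises(InconsistencyError):
        hwe_chi2(0, 0, 0)
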