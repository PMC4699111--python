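import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def schoolbook_negacyclic(a, b, t):
    """Independent O(n^2) oracle: polynomial product mod (x^n + 1, t), centered."""
    n = len(a)
    full = [0] * (2 * n)
    for i in range(n):
        for j in range(n):
            full[i + j] += int(a[i]) * int(b[j])
    folded = [(full[k] - full[k + n]) % t for k in range(n)]
    return [c - t if c > t // 2 else c for c in folded]


@pytest.fixture(scope="session")
def worked_four_subjects():
    """Hand-checked 4-subject dataset used across protocol/stats tests.

    Marker 1: (AA, Aa, aa, AA); marker 2: (AA, AA, Aa, aa);
    phenotype (case, control, control, case).
    Hand counts: o1 = <(2,1,0,2),(1,0,0,1)> = 4, column total = 5, cases = 2;
    pair products s = (<x_AA,x_BB>, <x_Aa,x_BB>, <x_AA,x_Bb>, <x_Aa,x_Bb>,
    margins) = (4, 2, 0, 0, 5, 5).
    """
    from hegwas.encoding import GenotypeMatrix, PhenotypeVector

    genotypes = GenotypeMatrix(
        subject_ids=("s1", "s2", "s3", "s4"),
        snp_ids=("m1", "m2"),
        calls=np.array(
            [["AA", "AA"], ["Aa", "AA"], ["aa", "Aa"], ["AA", "aa"]], dtype=object
        ),
    )
    phenotypes = PhenotypeVector(("s1", "s2", "s3", "s4"), np.array([1, 0, 0, 1]))
    return genotypes, phenotypes
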