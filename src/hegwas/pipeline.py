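"""End-to-end orchestration: configuration, full protocol runs, reports.

`run_gwas` plays all three roles in-process (keygen → contributor uploads →
cloud aggregation and reduction → researcher decryption → statistics) and
returns tidy per-SNP and per-pair DataFrames.  It is what the CLI and the
reproduction script drive; the individual role functions in
:mod:`hegwas.protocol` remain available for staged, file-based operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import pandas as pd
import yaml

from .backends import BackendParams, SecurityParams, make_backend
from .encoding import GenotypeMatrix, PartitionAssignment, PhenotypeVector
from .protocol import (
    cloud_aggregate,
    cloud_allelic_products,
    cloud_genotype_margin_products,
    cloud_genotype_products,
    contributor_prepare,
    researcher_decrypt_allelic,
    researcher_decrypt_counts,
    researcher_decrypt_genotype,
)
from .ring import RingParams
from .stats import (
    chi2_additive,
    hwe_chi2,
    ld_measures,
    reconstruct_allelic_table,
    reconstruct_genotype_pair,
)

__all__ = ["ProtocolConfig", "GWASResults", "run_gwas"]


@dataclass(frozen=True)
class ProtocolConfig:
    """One protocol run's parameters (ring, security, backend, seed).

    Defaults reproduce the reference configuration ``n = 8192``,
    ``t = 640007``, ``L = 6`` with the exact backend.
    """

    n: int = 8192
    t: int = 640007
    L: int = 6
    kappa: int = 80
    backend: str = "exact"
    seed: int = 0
    addition_budget: int = 1024

    def backend_params(self) -> BackendParams:
        return BackendParams(
            ring=RingParams(n=self.n, t=self.t),
            security=SecurityParams(L=self.L, kappa=self.kappa),
            addition_budget=self.addition_budget,
        )

    @classmethod
    def from_yaml(cls, path) -> "ProtocolConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__}, fh
            )


@dataclass(frozen=True)
class GWASResults:
    """Per-SNP association table and per-pair LD table."""

    chi2: pd.DataFrame
    ld: pd.DataFrame
    multiplications: dict


def run_gwas(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    assignment: PartitionAssignment,
    config: ProtocolConfig = ProtocolConfig(),
    ld_pairs: Optional[Sequence[tuple[str, str]]] = "all",
    with_hwe: bool = True,
) -> GWASResults:
    """Run the full secure pipeline and reconstruct all statistics.

    ``ld_pairs`` may be "all" (every unordered SNP pair), an explicit list
    of id pairs, or None to skip LD.  Bonferroni-adjusted p-values are
    emitted alongside the raw ones for convenience; the raw statistics are
    the protocol's output.
    """
    backend = make_backend(config.backend, config.backend_params(), seed=config.seed)
    keys = backend.keygen(config.seed)
    uploads = [
        contributor_prepare(genotypes, phenotypes, assignment, q, backend, keys.pk)
        for q in range(1, assignment.Q + 1)
    ]
    store = cloud_aggregate(uploads, backend)
    n_blocks = len(store.block_lengths)

    chi2_rows = []
    allelic_mults = 0
    for snp in store.snp_ids:
        backend.reset_counts()
        enc_stats = cloud_allelic_products(store, snp, backend)
        allelic_mults += backend.multiplication_count
        o1, colA, cases = researcher_decrypt_allelic(backend, keys.sk, enc_stats)
        table = reconstruct_allelic_table(o1, colA, cases, store.M)
        result = chi2_additive(table)
        row = {
            "snp": snp,
            "o1": table.o1,
            "o2": table.o2,
            "o3": table.o3,
            "o4": table.o4,
            "N1": table.N1,
            "N2": table.N2,
            "N1p": table.N1p,
            "N2p": table.N2p,
            "chi2": result.statistic,
            "p": result.p_value,
        }
        if with_hwe:
            e_AA, e_Aa = cloud_genotype_margin_products(store, snp, backend)
            sAA, sAa = researcher_decrypt_counts(backend, keys.sk, (e_AA, e_Aa))
            n_AA, n_Aa = sAA // 2, sAa
            hwe = hwe_chi2(n_AA, n_Aa, store.M - n_AA - n_Aa)
            row.update({"hwe_chi2": hwe.statistic, "hwe_p": hwe.p_value})
        chi2_rows.append(row)
    chi2_df = pd.DataFrame(chi2_rows)
    if not chi2_df.empty:
        chi2_df["p_bonferroni"] = (chi2_df["p"] * len(chi2_df)).clip(upper=1.0)

    if ld_pairs == "all":
        pairs = list(combinations(store.snp_ids, 2))
    else:
        pairs = list(ld_pairs or [])
    ld_rows = []
    ld_mults = 0
    for snp_i, snp_j in pairs:
        backend.reset_counts()
        enc_pair = cloud_genotype_products(store, snp_i, snp_j, backend)
        ld_mults += backend.multiplication_count
        s = researcher_decrypt_genotype(backend, keys.sk, enc_pair)
        g = reconstruct_genotype_pair(*s, M=store.M)
        ld = ld_measures(g)
        ld_rows.append(
            {
                "snp_i": snp_i,
                "snp_j": snp_j,
                "s1": s[0],
                "s2": s[1],
                "s3": s[2],
                "s4": s[3],
                "s5": s[4],
                "s6": s[5],
                "pAB": ld.pAB,
                "pA": ld.pA,
                "pB": ld.pB,
                "D": ld.D,
                "Dprime": ld.Dprime,
            }
        )
    return GWASResults(
        chi2=chi2_df,
        ld=pd.DataFrame(ld_rows),
        multiplications={
            "blocks": n_blocks,
            "allelic_total": allelic_mults,
            "ld_total": ld_mults,
            "per_chi2": 3 * n_blocks,
            "per_ld": 6 * n_blocks,
        },
    )
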