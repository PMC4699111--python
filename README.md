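# hegwas

Secure outsourcing of genome-wide association statistics with packed
homomorphic encryption.

## The problem

A GWAS compares allele counts between cases and controls at hundreds of
thousands of biallelic markers (SNPs). The raw genotypes are highly
sensitive, which blocks the obvious move of shipping them to a cloud for
computation. `hegwas` implements a three-party protocol in which that
tension dissolves:

- **data contributors** (hospitals, cohorts, individual subjects) encrypt
  their genotype/phenotype shares under a public key and upload ciphertexts;
- **the cloud** — untrusted, honest-but-curious — aggregates the uploads and
  reduces each SNP (or SNP pair) to a handful of *encrypted scalar
  products*, without ever decrypting anything;
- **the researcher** decrypts only those few integers per marker, which are
  sufficient statistics for the frequency tables, and computes the usual
  statistics in the clear: the additive-model χ² test, Hardy–Weinberg
  equilibrium, and linkage disequilibrium (D, Lewontin's D′).

The cloud learns nothing beyond ciphertext shapes and the subject count M;
the researcher learns nothing beyond what the frequency tables reveal.

## The method

**Encoding.** A genotype column over {AA, Aa, aa} becomes two integer
vectors: `x_AA` (2 for AA subjects, else 0) and `x_Aa` (1 for Aa, else 0),
so `x_AA + x_Aa` is the per-subject dosage of allele A. The phenotype is a
binary case vector `y`. Allele-count cells of the 2×2 case/control table
are then scalar products, e.g. the allele-A count among cases is
`o₁ = ⟨x_AA + x_Aa, y⟩`; since the table has one degree of freedom given M,
three scalar products determine it entirely. A two-marker genotype table
needs six, e.g. `4·o₁₁ = ⟨x_AA, x_BB⟩`.

**Packing.** Plaintexts of the BGV-family ring-LWE scheme live in
`A_t = Z_t[x]/(xⁿ+1)` with n a power of two and t prime, coefficients
centered in `(−t/2, t/2]`. A vector u packs *forward* as `Σ uᵢ xⁱ`, v packs
*backward* as `−Σ vⱼ x^(n−j)`; because `xⁿ ≡ −1`, the constant term of the
ring product of the two packings is exactly `⟨u, v⟩`. One homomorphic
multiplication therefore evaluates one encrypted scalar product over up to
n subjects; longer cohorts are split into `⌈M/n⌉` near-equal blocks whose
per-block constant terms are summed homomorphically. Each χ² test costs
exactly 3 homomorphic multiplications per block (one of them
ciphertext×ciphertext) and each LD evaluation costs 6.

**Statistics.** From the reconstructed table the researcher computes the
1-df additive χ²

```
χ²_a = 2M (o₂(o₃+o₄) − o₄(o₁+o₂))² / (N₁ N₂ N₁′ N₂′),
```

algebraically identical to the Pearson 2×2 statistic, plus the HWE
goodness-of-fit χ² and the composite LD coefficient
`D = p_AB − p_A p_B` with D′ = D/D_max. The double-heterozygote count o₂₂
is omitted from p_AB, p_A and p_B because its haplotype phase is ambiguous;
`hegwas.stats.composite_ld_expectation` gives the exact population value of
this estimator (which differs from the haplotype-level D away from the
feasibility boundary — see `docs/methods.md`).

**Security parameters.** The lattice dimension follows the standard
inequality `n > (L(log₂ n + 23) − 8.5)(κ + 110)/7.2`; at depth budget L = 6
and κ = 80 bits the selector returns n = 8192, and the reference
configuration is n = 8192, t = 640007. Two interchangeable backends run the
identical protocol: `exact` (identity encryption, the oracle and
plaintext-scale path) and `rlwe` (genuine public-key ring-LWE encryption,
depth 1, with a ciphertext modulus derived from a worst-case noise bound).

## Worked example

```python
from hegwas import SimulationConfig, simulate_dataset, run_gwas, ProtocolConfig

cfg = SimulationConfig(
    M=1000, N=4, Q=3, partition_mode="horizontal",
    effect_snps={"snp1": 1.6}, ld_pairs=((0.7, 0.7, 0.11),), seed=7,
)
genotypes, phenotypes, assignment = simulate_dataset(cfg)
results = run_gwas(
    genotypes, phenotypes, assignment,
    ProtocolConfig(n=1024, t=640007, backend="exact", seed=7),
    ld_pairs=[("ld1A", "ld1B")],
)
print(results.chi2[["snp", "o1", "o2", "o3", "o4", "chi2", "p", "hwe_chi2"]]
      .round(4).to_string(index=False))
print(results.ld[["snp_i", "snp_j", "pAB", "pA", "pB", "D", "Dprime"]]
      .round(4).to_string(index=False))
print(results.multiplications)
```

prints

```
 snp  o1  o2  o3  o4    chi2      p  hwe_chi2
snp1 384 640 270 706 21.9685 0.0000    0.0768
snp2 468 556 431 545  0.4810 0.4880    0.0000
snp3 488 536 465 511  0.0000 0.9954    0.3934
snp4 465 559 439 537  0.0374 0.8466    0.1185
ld1A 694 330 690 286  2.0036 0.1569    0.5208
ld1B 679 345 697 279  6.0677 0.0138    0.1192

snp_i snp_j    pAB    pA    pB      D  Dprime
 ld1A  ld1B 0.4635 0.555 0.551 0.1577  0.6431

{'blocks': 1, 'allelic_total': 18, 'ld_total': 6, 'per_chi2': 3, 'per_ld': 6}
```

Each row of the first table is one SNP's reconstructed allelic table
(`o1..o4`), its additive χ² with p-value and the HWE χ². The simulated risk
SNP `snp1` (per-allele odds ratio 1.6) stands out at χ² ≈ 22, the null SNPs
sit near their expectation of 1, and the LD pair simulated at haplotype
D = 0.11 yields the composite estimate D ≈ 0.158 (its exact expectation is
0.1551, see the methods note). Every statistic was computed from decrypted
scalar products only — here with one ciphertext block, at 3 homomorphic
multiplications per χ² and 6 per LD.

The same run works role-by-role through files:

```
hegwas simulate -M 1000 -N 4 -Q 3 -o data/
hegwas keygen -c config.yaml -o keys/
hegwas contribute -c config.yaml -g data/genotypes.tsv -p data/phenotypes.tsv \
    -a data/assignment.yaml -k keys/public.key -q 1 -o uploads/u1.bin
...
hegwas aggregate -o store.bin uploads/u*.bin
hegwas eval-chi2 -s store.bin -o chi2_stats.bin
hegwas eval-ld -s store.bin -o ld_stats.bin
hegwas decrypt-report -k keys/secret.key -o report chi2_stats.bin ld_stats.bin
```

Genotypes may also be read from a biallelic VCF (`--vcf`; REF plays
allele A).

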