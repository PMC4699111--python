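# Methods

## Protocol model and assumptions

`hegwas` evaluates case-control GWAS statistics over encrypted data by
reducing every statistic to integer scalar products of encoded
genotype/phenotype vectors, evaluated under a BGV-family ring-LWE
homomorphic scheme via vector packing.

Threat model: the cloud is honest-but-curious and does not collude with the
researcher; key distribution and transport channels are assumed correct and
are out of scope (the package exchanges files, not network messages).
Inputs are assumed pre-aligned: genotype and phenotype files must carry an
identical subject-id ordering, which is checked by exact sequence equality
and not repaired (record linkage through obfuscated identifiers is the
responsibility of an upstream step). Missing genotype calls are rejected at
validation rather than imputed or silently encoded as zero, because a zero
pair (x_AA, x_Aa) = (0, 0) is indistinguishable from a valid aa call and
would corrupt the table margins.

Each contributor's share is defined by an ownership map π over
(subject, column) cells; horizontal (disjoint subjects), vertical (disjoint
markers) and random partitions are all just owner maps. Since
Σ_q π(x, q) = x element-wise and packing is linear, homomorphic addition of
the contributors' uploads yields exactly the encryption of the full packed
vectors; this is the only aggregation step the cloud performs besides the
scalar-product multiplications.

## Ring, packing and blocks

The plaintext space is A_t = Z_t[x]/(xⁿ+1), n a power of two, t an odd
prime, with every coefficient kept centered in (−t/2, t/2] after every
operation so that signed constant terms read off directly. Multiplication
is negacyclic convolution, computed exactly over the integers by Kronecker
substitution on Python big integers (pack coefficients into one big
integer with a digit base wider than n·(mod−1)², multiply once, unfold,
fold with the x^n ≡ −1 sign); there is no floating point and no modular
approximation anywhere in the arithmetic. An independent O(n²) schoolbook
convolution serves as the oracle in the test suite only.

Forward packing ρ_fw(u) = Σ uᵢ xⁱ and backward packing
ρ_bw(v) = −Σ vⱼ x^(n−j) make the constant term of ρ_fw(u)·ρ_bw(v) equal
⟨u, v⟩ provided all entries and the scalar product itself lie in
(−t/2, t/2] and the vectors are no longer than n. The j = 0 backward term
−v₀xⁿ reduces to +v₀; the implementation stores the reduced form. Cohorts
with M > n subjects are split into ⌈M/n⌉ contiguous blocks with lengths as
equal as possible (differing by at most one — at M = 10⁴ and n = 8192 this
is two blocks of 5000), and per-block products are summed homomorphically
so the researcher decrypts a single ciphertext per statistic.

Overflow guard: the largest scalar product the protocol produces is
⟨x_AA, x_BB⟩ ≤ 4M, so contributor preparation requires t > 8M; with the
default t = 640007 that allows M up to 80 000.

## Homomorphic backends

Two backends implement the same interface (keygen / encrypt / decrypt /
hadd / hmult / add_plain / mult_plain) and are interchangeable anywhere in
the protocol:

- **exact** — identity encryption; ciphertexts are ring elements and the
  four homomorphic operations are the ring operations. It exists as the
  oracle for backend-equivalence tests and as the fast path for
  plaintext-scale runs, with the same depth bookkeeping as the real scheme.
- **rlwe** — public-key ring-LWE with the message in the least-significant
  residue mod t. Secret key ternary; noise from a rounded Gaussian with
  σ = 3.2 (a common ring-LWE default) truncated at B_e = ⌈6σ⌉ = 20;
  encryption c = (b·u + t·e₀ + m, a·u + t·e₁) with b = −a·s + t·e, so the
  phase c₀ + c₁·s equals m + t·(noise).

Every computation the cloud performs is additions plus exactly one
multiplication per scalar product, so the backend supports multiplicative
depth 1 and no more: a product ciphertext has three components, is
decrypted directly against (1, s, s²), and a second multiplication raises
`DepthBudgetError` instead of corrupting silently. No relinearization,
modulus switching or bootstrapping is implemented because the protocol
never needs them; the depth parameter L enters only the security
inequality for n.

The ciphertext modulus q is chosen at parameter-construction time as the
next prime above four times a worst-case phase bound for the supported
circuit family: fresh phase ≤ t/2 + t·B_e·(2n+1) (ternary secrets make
‖e·u‖∞ ≤ B_e·n exact), scaled by the addition budget A (default 1024, in
units of homomorphic additions before and after the multiplication), then
squared times n for the single multiplication, and scaled by A again.
Using a prime guarantees gcd(q, t) = 1 and keeps uniform sampling simple;
a keygen self-check refuses configurations whose q violates the bound, and
constructing deliberately undersized parameters requires an explicit
override (used by the noise-overflow test). At n = 8192, t = 640007 this
gives q ≈ 2¹²¹. Worst-case bounds are deliberately conservative: they cost
ciphertext size, never correctness.

The security inequality n > (L(log₂ n + 23) − 8.5)(κ + 110)/7.2 is
evaluated with log base 2, which reproduces n = 8192 at L = 6, κ = 80
(4096 fails the bound at ≈ 5317; 8192 clears ≈ 5476). κ is exposed but the
reference configuration fixes (n, t, L) = (8192, 640007, 6).

## Statistics

The allelic 2×2 table is reconstructed from (o₁, ⟨x_AA+x_Aa, 1⟩, case
count): row totals are twice the subject counts because each subject
carries two alleles. One naming subtlety: the decrypted phenotype product
⟨y, 1⟩ is the number of case *subjects*, while the table's row total N₁ is
an *allele* count; the reconstruction sets N₁ = 2·⟨y, 1⟩, the only reading
under which the grand total is 2M. Any negative derived cell raises an
inconsistency error rather than producing a nonsense table.

χ²_a = 2M(o₂(o₃+o₄) − o₄(o₁+o₂))²/(N₁N₂N₁′N₂′) is the 1-df additive-model
statistic and is algebraically the Pearson 2×2 statistic; the suite checks
the identity numerically on 1000+ random tables and the null calibration
(type-I error 0.046–0.059 at nominal 0.05 across seeds, 2000 replicates of
M = 2000 in the reproduction script). Degenerate margins (monomorphic
marker, single-class phenotype) yield a flagged `undefined` result, not an
exception and not a zero. P-values use the χ²(1) survival function; a
Bonferroni column is emitted for convenience but no correction is applied
to the reported statistics. HWE is the standard 1-df goodness-of-fit on
genotype counts (nAA, nAa, naa) against p̂², 2p̂(1−p̂), (1−p̂)², with the
genotype counts obtained from two extra plaintext products ⟨x_AA, 1⟩ and
⟨x_Aa, 1⟩ (not part of the minimal 3-multiplication reduction).

### The composite LD statistic and its bias

LD is computed from the six pair products as D = p̂_AB − p̂_A·p̂_B with
p̂_AB = (2o₁₁+o₁₂+o₂₁)/2M, p̂_A = (mA−o₂₂)/2M, p̂_B = (mB−o₂₂)/2M: the
double heterozygotes o₂₂ are omitted throughout because their haplotype
phase is ambiguous, and no EM phase reconstruction is attempted. D′ uses
the Lewontin normalization (D/D_max with the feasibility bound matching the
sign of D), is defined as 0 at D = 0, and is flagged undefined when the
bound vanishes (fixed locus).

Omitting o₂₂ makes this estimator *biased* for the haplotype-level D.
Under random mating with haplotype frequencies (p_AB, p_Ab, p_aB, p_ab),

    E[p̂_AB] = p_AB (1 − p_ab)
    E[p̂_A]  = p_A − (p_AB·p_ab + p_Ab·p_aB),  symmetrically for p̂_B,

because an AaBb subject arises from AB/ab or Ab/aB pairs. At
(p_A, p_B, D) = (0.7, 0.7, 0.11) the expectation of the statistic is
0.1551, not 0.11; simulations reproduce this to within Monte-Carlo error,
and `composite_ld_expectation` exposes the closed form so users can relate
the statistic to haplotype-level parameters. The bias vanishes in D′ at
the feasibility boundary (|D′| still reaches 1) and wherever double
heterozygotes cannot occur. All simulation tests and the reproduction
script therefore validate the statistic against its exact sampling
expectation, which is the quantity the pipeline actually estimates.

## Synthetic data generator

The generator emulates the study design the protocol targets: M subjects,
N independent SNPs drawn under Hardy-Weinberg proportions at a per-SNP
allele-A frequency uniform on a configurable MAF range (default
[0.05, 0.5]; allele A is the minor allele, so MAF → 0 gives all-aa
columns); a binary phenotype from a logistic model with per-allele odds
ratios at chosen effect SNPs (OR 1 elsewhere) and an intercept solved
numerically (Brent) for the target case fraction, default 0.5; optional LD
pairs simulated at the haplotype level with frequencies
(p_Ap_B+D, p_A(1−p_B)−D, (1−p_A)p_B−D, (1−p_A)(1−p_B)+D) and random
pairing into diploids; and contributor splits (horizontal, vertical or
random ownership). Everything is deterministic given the seed.

Defaults are sized for routine runs (M = 500, N = 10, Q = 3); the
reproduction script uses the study-scale configuration M = 10⁴, Q = 5,
n = 8192 through the exact backend, and exercises the RLWE backend on a
scaled-down dataset (M = 60, n = 32), since the two backends are proven
equivalent on identical inputs by the congruence and pipeline-equality
suites, including a reduced congruence run at n = 8192 under RLWE.

What the generator does not emulate — and what passing tests therefore do
not establish about real data: population structure and relatedness,
genotyping error and missingness, phased haplotypes, X-chromosome/ploidy
exceptions, multi-allelic sites, and realistic allele-frequency spectra or
LD decay along a chromosome. The generator validates the machinery
(exactness of the encrypted reduction and the statistics' sampling
behaviour under the model), not robustness of χ² inference to confounding.

## Numerical and design choices

- All homomorphic work is exact integer arithmetic; probabilities and χ²
  statistics are computed in floating point only after reconstruction.
- Phenotypes are uploaded only backward-packed; case counts use a plaintext
  forward-packed all-ones vector (`mult_plain`), which is cheaper and
  noise-lighter than ciphertext×ciphertext and gives the same result. The
  four-copy upload applies to genotype vectors, where both packing roles
  are needed across the χ² and LD reductions.
- Margin products (⟨·, 1⟩) likewise use plaintext multiplication.
- Cross-block sums are performed homomorphically by the cloud so exactly
  one ciphertext per statistic reaches the researcher; the addition budget
  A = 1024 comfortably covers 2·⌈M/n⌉-block protocols at the guard-rail
  subject counts.
- SNP jobs are evaluated independently in deterministic id order; results
  are owner-map-invariant (tested) so any partition of the same data gives
  identical output.
- Serialization uses a versioned binary container (JSON header + fixed
  width little-endian coefficient arrays) for keys, uploads, stores and
  encrypted statistics; plaintext-side data stay in TSV/YAML.

## Known limitations

- Honest-but-curious only: no malicious-adversary hardening, no collusion
  detection, no differential-privacy noise on the released tables.
- Depth-1 homomorphic evaluation only, by design; circuits needing deeper
  multiplication chains are out of scope.
- The RLWE backend is a clear, correct reference implementation in Python
  big-integer arithmetic; it makes no claim to the throughput of optimized
  C++ lattice libraries, and wall-clock performance is explicitly not a
  validated quantity of this package.
- o₂₂-omitting LD is reported as published; users wanting unbiased
  haplotype-level D should interpret results through
  `composite_ld_expectation` or use phased data elsewhere.
- The researcher API reveals M and the sufficient statistics; anything
  inferable from a frequency table (including small-cell disclosure risks)
  is inherently revealed.
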