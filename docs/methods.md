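# Methods

`hegenome` evaluates two families of genomic computations on encrypted data:
GWAS summary statistics (minor allele frequency and the allelic chi-square)
and pairwise sequence-comparison distances (Hamming and an approximate edit
distance), under two somewhat-homomorphic encryption (SHE) schemes. This
note records the models, the numerical choices, and what the test suite
does and does not establish.

## Rings, plaintexts, noise

Both schemes work in `R_q = Z_q[x]/Phi_m(x)` with centered coefficient
representatives in `(-q/2, q/2]`. Coefficients are arbitrary-precision
Python integers; ring multiplication maps a polynomial product onto a
single big-integer multiplication (Kronecker substitution: pack the
coefficients as fixed-width base-2^b digits, multiply, unpack; negative
coefficients are handled by a positive/negative split into four
non-negative products). A schoolbook multiply-and-long-divide oracle checks
it exactly in the tests. No NTT/FFT is used: the target workloads are test
scale, and correctness, not throughput, is the contract.

Plaintexts live in `R_t`. When `Phi_m` factors mod `t` into `ell`
irreducible degree-`d` factors, `R_t` is a product of `ell` finite rings —
the *slots* — and one ciphertext carries `ell` values in parallel. The slot
machinery:

- `slot_count(m, t)` computes `(ell, d)` from the multiplicative order of
  the prime base of `t` mod `m` (cheap even at `m = 8191` or `16384`);
- `slot_layout(m, t)` actually factors `Phi_m` mod `p` (sympy's
  distinct-degree factorization), Hensel-lifts the factors to `p^r` when
  `t = p^r`, and precomputes the CRT idempotents `b_i` (`b_i = 1 mod f_i`,
  `0 mod f_j`). Packing integer slot values is then one scalar
  multiplication per slot; unpacking reads the constant coefficient of the
  residue mod each factor. Inverses mod a factor are computed over `GF(p)`
  by polynomial extended Euclid and Newton-lifted to `p^r`.

Slot order is the order in which the factorization routine emits the
factors: deterministic and fixed, otherwise arbitrary (nothing downstream
depends on it).

Noise: errors are truncated discrete Gaussians (`sigma = 3.2` for the
modulus-switching scheme, `sigma = 8` for the scale-invariant one, bound
`B = 6 sigma`), secrets are ternary — sparse with exact Hamming weight `h`
for the first scheme, dense uniform for the second. Ciphertexts carry a
heuristic `noise_est`; all correctness tests measure the *actual* noise
with the secret key instead of trusting the estimate.

## The modulus-switching scheme (BGV style)

Chain `q_0 < q_1 < ... < q_{L-1}`, each `q_i` a product of consecutive
primes of roughly `prime_bits` bits. Every chain prime and the
key-switching factor `P` are chosen `= 1 (mod t)` so that rescaling is an
exact division after subtracting the correction `t [t^{-1} c]_F` (which is
`= c mod F` and `= 0 mod t`); this keeps the plaintext invariant without
any parity bookkeeping.

Key switching is the modulus-raising variant: the evaluation key is an
encryption of `P s^2` over `R_{P q_{L-2}}`. Because the evk modulus is
`P q_{L-2}`, a fresh top-level ciphertext is switched down to level `L-2`
before its first multiplication (this is the "initial modulus switch" the
level budget `L = M d + 2` already accounts for). Each multiplication then
consumes exactly one level: tensor at `q_l`, switch the `s^2` component
back to `s` at modulus `P q_l`, rescale by `P`, and modulus-switch to
`q_{l-1}`. Multiplication at level 1 lands on `q_0`, where no further
multiplication is possible — so `L-2` sequential multiplications fit.

Decryption measures `[c_0 - s c_1]_{q_l}` and raises a `DecryptionFailure`
when its infinity norm exceeds `q_l / 4`. The provable wrap bound is
`q_l / 2`, but past it a corrupted ciphertext is indistinguishable from a
quieter encryption of a different message, so the guard deliberately sits
at half the bound; legitimate pipelines at generated parameters stay
orders of magnitude below it.

## The scale-invariant scheme (YASHE style)

Power-of-two `m = 2n`, single prime `q = 1 (mod m)`, secret
`f = [t f' + 1]_q` (retried up to 32 times if singular), public key
`h_pub = [t g f^{-1}]_q`. Multiplication scales the exact integer product
of the centered representatives by `t/q`, rounds half away from zero
(ties cannot occur: `q` is odd), and key-switches with the balanced
base-`omega` word decomposition against
`gamma_i = [omega^i f + e_i + h_pub s_i]_q`. The production word size is
`omega = 2^128`; toy profiles use `2^12 .. 2^16` so that `ell_w >= 2` and
the decomposition path is actually exercised.

Inherent noise is measured as `||[f ct]_q - floor(q/t) [m]_t||_inf`; the
failure guard is `Delta/4` with `Delta = floor(q/t)`, for the same reason
as above. The modulus size for `M` multiplicative levels is the closed-form
budget `log2 q >= 2 M log2(n t) + log2(12 sigma ell_w omega)` (iterated
twice because `ell_w` depends on `q`; it converges immediately), and for
`M = 0` a fresh-noise-plus-addition budget. The budget is a worst-case
bound; measured noise in the tests runs far below it, which is why `M`
sequential squarings succeed with wide margin at generated parameters.

The scheme keeps `h` for the secret-key Hamming weight and names the
public key `h_pub` to avoid the symbol collision.

## Genomic encodings

Genotypes: `AA -> 2, AB -> 1, BB -> 0`, i.e. the per-person count of the
`A` allele, so group sums are allele counts.

Sequence comparison starts from two VCF-subset files (CHROM, POS, REF,
ALT, and an SVTYPE in {SUB, INS, DEL}; inferred from the REF/ALT length
relation when absent). Positions are merged into a list `L`; a one-sided
position carries an absent marker. Per side and site the encoding is:

- `e`: presence flag (0 for absent);
- `f`: 0 iff the record is an insertion or deletion; an *absent* side gets
  `f = 1`, which is what lets the `f f'` product in the Hamming circuit
  preserve the "one side missing counts as 1" branch;
- `s`: a 15-bit string — 2 bits per base (`A->00 G->01 C->10 T->11`), a
  marker, zero padding; absent sites are the all-zero string;
- `D`: the record's length (REF length for a deletion, ALT length
  otherwise, 0 when absent), carried as `mu` bits LSB-first with `mu` the
  smallest width covering the dataset (capped at 4).

Which sequence feeds `s`, and the marker, are the one place the encoding
has to be designed rather than transcribed: the edit-distance circuit
reduces "records identical" to "s-strings equal". Encoding the ALT for
every class fails that reduction — two deletions of different spans share
their single-base ALT. Here a substitution/insertion encodes its ALT with
marker `1` (last one-bit at an odd position) and a deletion encodes its
REF — the deleted span — with marker `01` (last one-bit at an even
position). The two code sets are provably disjoint and each is injective,
so string equality coincides with record identity for all record pairs the
circuits must separate. Consequences: deleted spans are capped at 6 bases
(12 payload + 2 marker bits), and a "deletion" whose ALT is not the
retained anchor base would not be distinguished from one that is — simple
deletions in normalized VCF always anchor, so this is logged, not fatal.
Multi-allelic ALT fields are rejected. Two same-position substitution
records with conflicting REF strings are algorithmically "distance 0"
(the reference algorithms fall through); this is almost certainly a data
problem and is logged loudly.

## Circuits

Every circuit exists in a binary form (`t = 2`: XOR is addition, AND is
multiplication) and an arithmetic form (prime `t`, bit inputs:
`x XOR y = (x-y)^2`, `x AND y = x y`), written once over a minimal
add/sub/mul/add-const engine interface. The same circuit code therefore
runs on plaintext slot vectors and on ciphertexts of either scheme, which
is how the three-way equality tests (plaintext circuit = homomorphic
circuit = reference algorithm) are stated. The printed arithmetic
comparison seed `c_1 = 1 - x_1 y_1` is a typo for `(1 - x_1) y_1` — the
corrected form is the one that matches the binary circuit exhaustively,
and is what is implemented.

Products are arranged in balanced trees. Static depth accounting
(`circuit_depths`): 15-bit equality costs 4 levels binary / 5 arithmetic
(the squarings); the Hamming term 6 / 7; the edit term 6 / 7 at `mu = 4`
(the `mu`-step comparison ripple dominates one branch). Toy parameters are
generated for exactly these depths (`L = 8` / `M = 7`), and the
depth-budget errors are raised *before* evaluation from the accounting,
never discovered as noise overflow.

Lengths enter the comparison bit-sliced (one slot vector per bit); the
per-bit edit outputs `l_{i,j}` are decrypted and recombined as
`sum_j l_{i,j} 2^(j-1)` — max recombination happens after decryption, not
homomorphically. Site counts beyond the slot capacity are block-partitioned
and processed identically per block.

## GWAS pipelines

Homomorphic work is additions only. Slot packing (scheme 1): one SNV per
slot, one ciphertext per person, fresh ciphertexts switched down one level
before aggregation so `L = 3` suffices. Coefficient packing (scheme 2):
one SNV per coefficient and `n' = floor(n/s)` persons per polynomial;
addition-only, so no evaluation key is generated and `M = 0` parameters
apply. After decryption, per-SNV counts give
`MAF = min(m_j, 2N - m_j)/2N` and, from the case/control sum and
difference, `chi2 = 4N d^2 / (s (4N - s))` — algebraically identical to
the allelic contingency-table statistic (verified exhaustively for
`N <= 10` in exact rationals). Differences decode signed: values above
`t/2` drop by `t`; the boundary `v = t/2` maps to `+t/2`, but the
wrap-around validation (`2N < t` per group, `4N < t` for the sums) rejects
any configuration that could reach it. Monomorphic sites yield a `None`
statistic with a warning rather than a fake zero. All statistics are exact
`Fraction`s; division never happens under encryption.

## Parameter calculator

Closed forms for desk planning: per-multiplication switch count
`d_{n,t} = log2(h n t^4)/36` (applied with a ceiling when building integer
chains), chain length `L = M ceil(d) + 2`, modulus size
`log2 q = 24 + 1.5 log2 n + (L-2)(11 + 0.5 log2 n)`, ciphertext sizes
`2 n log2 q` vs `n log2 q` bits, the scale-invariant noise floor above,
and the RLWE floor `phi(m) >= (L(log2 m + 23) - 8.5)(lam + 110)/7.2`
(its printed grouping is ambiguous; this reading is validated as a
consistency check against the deployed rings, not as an equality).
Display rounding: nearest integer half-up for the constant and the
scale-invariant per-level term; *ceiling* for the chain's per-level
increment — a per-level budget is a provision, and rounding 17.4998 down
to 17 would under-build the chain that the published 18-bit step builds.
Size display uses 1 kB = 1024 bytes, nearest integer.

`plan_table` emits the derivable row per (task, scheme): the plaintext
modulus from the wrap-around bound (smallest power of two above `2N` for
counts, `4N` for chi-square; the coefficient-packing scheme uses the
chi-square bound for both), slot counts from `slot_count`, and sizes from
the formulas — or from an explicitly supplied modulus when sizing an
existing deployment.

## Synthetic data

The generator defines the study conditions and is first-class, tested
code. GWAS: per-SNV allele frequencies uniform on `[0.05, 0.5]`, genotype
codes `Binomial(2, p_j)` per person under Hardy-Weinberg; defaults 200+200
persons x 311 SNVs (the evaluation scale); an optional single-SNV case
shift `delta` plants an association. Calibration is tested: at `delta = 0`
about 5% of sites exceed the chi-square(1) critical value 3.84; at
`delta = 0.2` the planted site wins the scan in >= 95% of replicates.

VCF pairs: one chromosome, positions shared with probability `p_shared`,
a shared position byte-identical on both sides with probability
`p_identical` (default 0.5 — two genomes agree on most variants;
this field is an addition to the spec'd shape, without it distance-0
shared sites would be vanishingly rare). Every position owns a fixed
reference base, so same-position substitutions always share REF — the
regime in which circuits and reference algorithms provably agree.
SV mix defaults to 60/20/20 SUB/INS/DEL, ALT lengths <= 7, deleted spans
<= 6. Every dataset carries ground truth computed by the *reference*
algorithms (not the pipelines), so generated data is self-checking.

Not modeled: linkage disequilibrium, population structure, realistic
mutation spectra, genotyping error. Passing tests therefore demonstrate
*cryptographic and algorithmic* exactness — decrypted results equal the
plaintext computation — not robustness of the statistics to real-data
artifacts.

## Problem sizes and toy profiles

The homomorphic test runs use deliberately small rings, chosen for their
slot structure: `m = 257` (16 slots of degree 16, `t = 2^9`) and `m = 85`
(8 slots, `t = 2`) for the odd-`m` scheme; `n = 64` with `t = 127 = 2n-1`
(32 quadratic slots) and `t = 2^10` (coefficient packing) for the
power-of-two scheme. End-to-end checks run 20+20 persons x 16 SNVs and 50
merged variant sites; scheme-level checks run 1000 encrypt/decrypt trials
plus 200 homomorphic add/mult trials per scheme. These rings provide no
meaningful RLWE security — `bgv_toy_params` says so — and exist so that
exactness can be verified broadly; generating parameters at a real
security level goes through `bgv_params_gen` / `yashe_params_gen`, whose
security floor makes even a nominal 20-bit request choose `phi(m) > 1500`.

## Known limitations

- No constant-time arithmetic, no side-channel hardening, no bootstrapping,
  no rotations; security estimation beyond the printed floor is out of
  scope (use a lattice estimator before deploying any parameter set).
- The approximate edit distance is a set-difference surrogate, not
  Wagner-Fischer; it inherits that approximation's blind spots (e.g.
  same-position INS/DEL pairs score by length max, and a conflicting-REF
  substitution pair scores 0).
- The scale-invariant key-switching "hybrid" shortcut (skipping key
  switching between some multiplications) is not implemented.
- Pure-Python big-int arithmetic is desk-scale: fine for thousands of
  ciphertext operations at toy rings, not for the 8K-dimension production
  rings.
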