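# hegenome

Privacy-preserving genome analysis with somewhat-homomorphic encryption
(SHE). A data owner uploads *encrypted* genotype panels or variant call
sets to an untrusted evaluator; the evaluator computes GWAS statistics or
sequence-comparison distances directly on the ciphertexts and returns
encrypted results; only the key holder ever sees plaintext. The package is
aimed at people studying the cryptographic workflow itself — what these
pipelines cost, which parameters they need, and that they are *exact* —
at desk scale, in readable Python.

Two RLWE-based schemes are implemented side by side:

- a **leveled modulus-switching scheme** (BGV style) over
  `Z_q[x]/Phi_m(x)`, odd `m`, with a chain of moduli, sparse ternary
  secrets, and modulus-raising key switching;
- a **scale-invariant scheme** (YASHE style) over `Z_q[x]/(x^n+1)`, a
  single prime modulus, secret `f = t f' + 1`, and word-decomposition key
  switching.

On top of them:

- **Task 1 — encrypted GWAS.** Genotypes `AA/AB/BB -> 2/1/0` are packed one
  SNV per CRT *slot* (scheme 1) or per polynomial *coefficient* (scheme 2);
  homomorphic additions aggregate allele counts `n_A^(j)`, and after
  decryption the minor allele frequency `min(m_j, 2N-m_j)/2N` and the
  allelic chi-square

  `chi^2 = 4N (n_A - n_A')^2 / ((n_A + n_A')(4N - n_A - n_A'))`

  are computed exactly (rationals; no division under encryption).
- **Task 2 — encrypted sequence comparison.** Two VCF subsets are merged
  position-wise; each site becomes a presence flag `e`, an indel flag `f`,
  a 15-bit sequence code `s`, and a bit-sliced length `D`. Boolean (t = 2)
  or arithmetic (prime t) circuits — 15-bit equality, a ripple comparator,
  max, and the per-site terms — evaluate the Hamming distance and the
  set-difference *approximate edit distance* `sum_i max(D_i, D_i')` over
  slots, one merged site per slot.
- **Plaintext reference algorithms** (`hegenome.oracle`) used as ground
  truth everywhere, a **parameter calculator** (`hegenome.paramsel`) for
  depth/modulus/ciphertext-size budgets, a seeded **synthetic-data
  generator** (`hegenome.synth`), and a file-based **CLI** mirroring the
  keygen / encrypt / evaluate / decrypt role separation.

See `docs/methods.md` for the models, encodings, and numerical choices.

## Worked example

```
$ hegenome synth gwas --out-dir data --seed 7 --n-case 20 --n-control 20 -s 16
wrote case/control (20+20 x 16) to data
$ hegenome keygen --scheme bgv --task task1 --out keys.bin --seed 7
bgv/task1 keys -> keys.bin
$ hegenome encrypt gwas --keys keys.bin --case data/case.csv \
      --control data/control.csv --out cts.bin --seed 8
encrypted 20+20 persons x 16 SNVs -> cts.bin
$ hegenome eval chi2 --keys keys.bin --cts cts.bin --out eval.bin
evaluated chi2 -> eval.bin
$ hegenome decrypt gwas --keys keys.bin --cts eval.bin --out results.tsv
decrypted statistics for 16 SNVs -> results.tsv
$ head -4 results.tsv
snv     n_A     n_A_prime       maf_case        maf_control     chi2
SNV1    10      15      0.25    0.375   1.4545454545454546
SNV2    22      16      0.45    0.4     1.8045112781954886
SNV3    15      18      0.375   0.45    0.46421663442940037
```

`n_A` / `n_A_prime` are the decrypted case/control allele counts at each
SNV (out of `2N = 40` alleles per group), the MAF columns their
minor-allele frequencies, and `chi2` the allelic association statistic —
e.g. SNV1: 10 vs 15 copies of allele A gives MAFs 0.25 / 0.375 and
chi-square 1.45, nowhere near the 3.84 critical value, so no association.
Every number equals the plaintext computation on `data/*.csv` exactly
(`data/truth.json` holds the generator's own ground truth). The evaluator
stage touched only ciphertext containers; at this toy ring (`m = 257`,
`t = 2^9`, `L = 3` — demonstration-sized, not secure) the 40 person
ciphertexts occupy ~240 kB.

The sequence side works the same way with `synth vcf`,
`encrypt vcf`, `eval hamming|edit`, `decrypt vcf`; and

```
$ hegenome params estimate --task maf --scheme bgv
{"task": "maf", "scheme": "bgv", "t": 512, "m": 8191, "n": 8190,
 "ell": 630, "L": 3, "log2_q": 60.99, "ct_bytes": 124897, "ct_kB": 122, ...}
```

reproduces the publication-scale parameter rows (t = 2^9 for MAF at
N = 200 per group, 630 slots at m = 8191, 122 kB ciphertexts, ...).

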