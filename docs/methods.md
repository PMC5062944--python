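# Methods

This note documents the models and procedures implemented in `genoprivacy`,
the assumptions behind them, the defaults and why, and what the synthetic
generators do and do not establish.

## Threat model

All protocols assume a **semi-honest (honest-but-curious) adversary**: every
party follows the protocol but may inspect everything it observes to infer
private data.  Malicious security, garbled circuits, oblivious transfer, and
three-party variants are out of scope.  The security floor is the classic
**80-bit level**, mapped to 1024-bit factoring-based moduli (Paillier) and a
2048-bit discrete-log group (PSI-CA).  Both cryptosystems expose loudly
labeled insecure test parameters (`allow_insecure` Paillier keys,
`TEST_GROUP_512`) used where a test exercises correctness, never secrecy.

## Variant model

A genome is a set of keys `(chrom, pos, ref, alt, zygosity)` read from a
single-sample VCF.  Conventions:

* 1-based, inclusive VCF coordinates everywhere; alleles uppercased; **no
  left-alignment or trimming of indels** — keys compare representations
  byte-for-byte.  Two VCFs that encode the same indel differently will not
  match; revisit if exactness against externally called VCFs is needed.
* Only FILTER `PASS`/`.` records are kept; multi-allelic records split into
  one key per alternate allele.
* Default key mode is **zygosity-aware** (het vs hom-alt at the same site are
  different keys): a genotype difference at a shared site is a genomic
  difference.  Site-only keys are available for sensitivity analysis; the
  two modes are never comparable and mixing them raises.

## GWAS statistics

2×2 **allelic** Pearson χ² (1 df) on (case/control) × (minor/major) allele
counts, no Yates correction, p-values from the χ²₁ survival function.  The
genotypic 2×3 test is deliberately not implemented.  Choices that make the
secure pipelines exactly reproducible:

* counts are integers end to end; the statistic is an exact rational
  `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` evaluated once, in one code path shared
  by the plaintext, encrypted, and secret-shared pipelines;
* the minor allele is defined on the **combined cohort** (ties resolve to
  the alternate allele), since per-group definitions can disagree;
* missing genotypes are excluded per site (dosage k contributes k alt and
  2−k ref alleles; a missing sample contributes nothing to that site's
  denominator); an all-missing site or zero marginal is reported as NA,
  never as 0.

## Distances

* `edit_distance_dp` — exact Levenshtein, unit costs, rolling two-row DP
  with a vectorized row update (the left-to-right dependency is a prefix
  minimum of `t[j]−j`).  An optional band prunes the DP but is off by
  default (correctness first); it is only valid when the true distance fits
  in the band.
* `hamming_distance` — |A Δ B| on keyed variant sets.  Defined on sets, not
  aligned strings, because positional alignment is undefined for
  indel-bearing genomes.
* `approx_edit_distance` — the set-difference approximation.  "Set
  difference" is read as the **symmetric** difference: a one-sided
  difference is asymmetric and cannot approximate a symmetric distance.  In
  cardinality mode (default) it equals the Hamming distance by construction;
  indel-length mode weights each key by
  `max(len(ref), len(alt)) − shared-prefix` (≥ 1) as a refinement for
  multi-base indels.
* Deviation convention: `|approx − true| / true`, as a percentage rounded to
  one decimal — percentages are of the TRUE distance (28 vs 27 → 3.7 %).
  A pair with true distance 0 and nonzero approximation has undefined
  deviation and is reported as such.

## Paillier outsourcing

Simplified `g = n+1` Paillier: `E(m;r) = (1+mn)·rⁿ mod n²`; decryption via
`λ = lcm(p−1,q−1)`, `μ = λ⁻¹ mod n`.  Primality by sympy (Baillie–PSW plus
strong tests; error far below 2⁻⁸⁰ for random candidates); keys of exactly
the requested bit size (top two bits of each prime forced).  Randomness
comes from OS entropy by default, or a seeded generator for reproducible
tests.

Protocol: the client encrypts, per sample and per site, the alternate-allele
dosage and 2× the non-missing indicator (so missingness aggregates
correctly); group labels travel in the clear (they are the analysis design,
not the protected genotypes).  The server — which structurally cannot be
constructed with a private key — multiplies ciphertexts into four encrypted
accumulators per site and returns them; the client decrypts the four
integers per site and finishes MAF/χ² in the clear.  Per-sample encryption
is the protocol boundary: encrypting locally pre-aggregated counts would not
be outsourcing.  Ciphertext packing/batching is out of scope.  Aggregate
counts (≤ 1600) cannot approach the modulus; an overflow guard asserts this
anyway.

The didactic `rsa_homomorphism_demo` verifies the multiplicative
homomorphism of unpadded RSA, `E(x₁)E(x₂) mod m = E(x₁x₂)` — a worked
illustration of why a single-operation homomorphic scheme cannot also
deliver the additions the χ² pipeline needs.  It is labeled insecure and is
not part of any protocol.

## Two-party protocols

* **Shares**: additive secret sharing over the Mersenne prime 2⁶¹−1 (counts
  never exceed 1600, so no wraparound).  Each party splits its per-site
  integer counts; only the pooled per-site sums are reconstructed.
  Disclosure boundary: pooled counts (not just the final χ²) are revealed —
  hiding them would require circuit-based techniques that are out of scope.
  Every transcript message except the final aggregates is a uniform field
  element; a byte-entropy test checks this empirically.
* **PSI-CA**: keys are hashed (counter-expanded SHA-256) into the
  quadratic-residue subgroup of a safe prime by squaring; each party
  exponentiates with a secret, the counterpart re-exponentiates and returns
  the vector **shuffled** (mandatory — it destroys the element/key
  correspondence).  Equal double-exponentiated elements ⇔ equal keys; hash
  collisions are detected and raise.  Secrets are 160-bit short exponents —
  standard at the 80-bit level and ~13× faster in pure Python than
  full-length exponents.  The default group is RFC 3526's 2048-bit MODP
  safe prime.
* **Transport**: an in-process, byte-counted, append-only channel with fixed
  serialization (4-byte length prefix + fixed-width big-endian integers;
  party A sends first), so transcripts and byte counts are reproducible.  A
  socket transport is intentionally omitted; the channel abstraction is the
  seam where one would go.

## Synthetic data

The generators state a fixed world; their defaults are not tuning knobs.

* **Genotypes** (`simulate_genotypes`): 200 cases + 200 controls over 311
  sites by default; per-site MAF uniform on [0.05, 0.5]; individuals draw
  two haplotypes from a simulated pool of 2×174 founder haplotypes (pool
  mode), or i.i.d. binomial (iid mode).  At null sites cases and controls
  are sampled *identically from the same pool* — if only controls were
  pool-sampled, finite-pool frequency jitter would inflate the null χ² by
  ~1.6× and the test would not be calibrated; an exchangeable null requires
  identical sampling.  Associated sites shift the case allele frequency to
  a chosen allelic odds ratio (cases there are binomial).  Missingness is
  i.i.d.  The generator records seed, config, and the planted site ids in
  `GenotypeMatrix.meta`.
* **Genome pairs** (`simulate_genome_pair`): shared-core-plus-private
  construction over a large position universe; sizes exact, shared count
  `round(overlap × min size)`.  Defaults (5000 keys/side, 70 % shared)
  reflect that two personal genomes share most of their common variants;
  10 % of keys are single-base indels.  Emits round-trippable VCFs.
* **Segment pairs** (`simulate_segment_pairs`): each pair derives from one
  random reference of 5000 nt; each side draws 25–50 variant positions
  (spacing ≥ 5 within a side), 90 % SNVs / 10 % single-base indels.  Every
  reference position carries **one predetermined variant form shared by both
  sides** — emulating biallelic polymorphic sites.  A position hit by both
  sides therefore produces the same key and cancels in the symmetric
  difference exactly as it cancels in the true edit distance.  Residual
  deviations come only from rare interacting indels (an insertion adjacent
  to equal bases can be equivalent to a shifted variant), each typically
  costing 1 edit on true distances of 60–90: across seeds, 18–20 of 20
  pairs are exact and the worst observed deviation is ~1.4 %.  Had each
  side drawn independent alternate alleles, ~25 % of suites would over-count
  at a colliding site — biologically wrong (human SNPs are overwhelmingly
  biallelic) and outside the observed mostly-exact regime this recipe is
  meant to occupy.

What a green test does **not** establish: no LD, recombination,
demography, or realistic site-frequency spectra are modelled; the
case-effect mechanism is a frequency shift, not real genotypes; variant
density and indel composition of real resequenced segments may differ from
the segment recipe.

## Evaluation harness

`bench.run_task` executes any task (plaintext, outsourced, two-party),
always computes the plaintext oracle on the same inputs, and embeds the
comparison in a schema-validated report (accuracy, security bits, per-phase
time, serialized storage bytes, per-direction communication bytes, seed,
config hash).  A mismatch raises with a per-item diff — the harness cannot
emit a report without an oracle comparison.  Timing is reported, never
asserted; storage/memory is a serialized-size proxy (deterministic and
portable, unlike RSS).

## Numerical and degenerate-input conventions

* χ² on a zero marginal, and any statistic on an all-missing site: NA
  (`None`), propagated identically through every pipeline.
* MAF ties (p = 0.5) keep the alternate allele as "minor".
* Deviations rounded half-even to 1 decimal by Python's `round`.
* `select_sites` orders keys canonically before sampling, so subsets depend
  only on the seed, not on set-iteration order; paired selection draws from
  the union of the two genomes' (chrom, pos) coordinates so both genomes
  are restricted to one common site panel.

## Known limitations

* Pure-Python big-integer arithmetic: a 1024-bit Paillier encryption is
  ~13 ms, so production-scale runs at full key size are minutes, not
  seconds; tests use small labeled-insecure keys.
* No indel normalization means set distances are representation-sensitive
  across variant callers.
* PSI-CA leaks set sizes (inherent to the protocol family) and assumes both
  parties agree on the key mode and group parameters.
* The secret-sharing GWAS reveals pooled per-site counts by design (the
  agreed disclosure boundary).
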