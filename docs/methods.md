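# Methods

## The screening problem

ALPS-sFAS is caused by a somatic *FAS* mutation confined to a lymphocyte
subpopulation — predominantly the expanded double-negative T cells (DNT),
with an additional contribution from roughly 10–20% of single-positive
mononuclear cells. Whole-blood DNA therefore carries the mutation at a
variant allele frequency (VAF) of only a few percent: a heterozygous
mutation present in a mutant-cell fraction *c* of the sequenced DNA has
expected VAF *c*/2. The pipeline screens targeted amplicon sequencing of
*FAS* exons 7–9 and their splice flanks (GRCh37 chr10) for such low-VAF
variants, classifies what it finds, and quantifies when detection is
possible at all.

## Filter chain

Each candidate (site, allele) with stranded read counts passes through, in
order:

1. **min_vaf** — VAF = (alt_fwd + alt_rev)/depth must be ≥ 0.01.
2. **min_allele_cov** — at least 3 supporting reads.
3. **min_strand_cov** — disabled by default (0): no per-strand coverage
   requirement.
4. **strand_bias** — removed only when **both** the bias score exceeds
   0.85 **and** the two-sided Fisher exact p-value on the 2×2 strand table
   `[[alt_fwd, ref_fwd], [alt_rev, ref_rev]]` is below 0.05. The
   conjunction is deliberate: an extreme score on 3–4 reads is not
   significant and is kept.

Rejected records are retained with classification `rejected` and the names
of the failed filters; output order is position, then alt allele
lexicographically.

**Strand-bias score.** With per-strand rates r_f = alt_fwd/depth_fwd and
r_r = alt_rev/depth_rev, the score is max(r_f, r_r)/(r_f + r_r): 0.5 for
balanced rates, 1.0 when one strand has no variant reads, symmetric under
strand swap. This is the package's own documented statistic on the
conventional 0.5–1 range; vendor implementations use undisclosed formulas,
so scores from other tools are comparable in range and threshold but not
digit-for-digit. When the input lacks per-strand total depths they are
imputed as an even split (ties to forward), clamped so the observed
per-strand alt counts remain feasible; real per-strand depths override the
imputation whenever present.

**Classification.** Passing calls with VAF in [0.35, 0.65] are
`germline_het`, ≥ 0.90 `germline_hom`, otherwise `somatic`. The band is
wide enough to cover observed germline heterozygotes (0.48–0.56) with
margin and is configurable; it stands in for a separate germline caller,
which is out of scope.

**Reporting convention.** VAFs print as percentages rounded half-up to one
decimal (10/239 → 4.2). Sensitivity and specificity print truncated
(floored) to one decimal — the convention under which 41/44 = 93.18%
prints as 93.1.

## Limit of detection

Two layers:

- **Deterministic floor** — `min_detectable_vaf(depth) =
  max(min_vaf, min_allele_cov/depth)`, 1.0 when depth < min_allele_cov.
  This is pure threshold arithmetic and reproduces the assay's observed
  limits: 8 reads of 101 → 7.9% VAF; 4 reads of 212 → 1.9%.
- **Exact-binomial power** — supporting reads X ~ Binomial(depth, p) with
  p = vaf + ε(1 − vaf), ε the per-base miscall probability toward the
  variant allele (default 1e-3; a single-parameter error model, no
  per-base qualities). Detection requires X ≥ k* =
  max(min_allele_cov, ceil(min_vaf·depth)); the power is the exact tail
  sum. `required_depth` finds the smallest depth reaching a target power
  (default 0.95) by exponential bounding plus an exact vectorized scan —
  power is not strictly monotone in depth because ceil(min_vaf·depth)
  introduces small saw-teeth, so bisection alone would be unsafe. When
  p ≤ min_vaf the demanded read count grows proportionally with depth and
  no finite depth suffices; this raises `UndetectableVariantError`.

The power model deliberately **ignores the strand-bias filter** (balanced
strands assumed). The omission costs ~1–1.5% detection probability in the
regime of ~5–15 supporting reads — where a one-sided split of all reads is
both plausible and Fisher-significant — and is negligible below ~5 reads
(never significant) and above ~20 (splits concentrate). The power sweep
quantifies the residual empirically; model-validation grids are placed in
regimes where the omission is below the Monte-Carlo resolution (e.g. depth
101 at cell fraction 0.04; depth 300 at 0.307; very deep coverage), and
the mid-read-count regime is reported by the sweep rather than asserted
against the reduced model.

## Synthetic cohorts

The simulator emulates the validation study's conditions at the level the
caller consumes — stranded counts per panel site — not at read level (no
FASTQ, no flow-space or homopolymer error model, no PCR duplicates).

Defaults (the study conditions):

| parameter | default | meaning |
|---|---|---|
| n_patients / n_controls | 8 / 44 | the 52-sample validation cohort shape |
| dnt_range | [4, 30.7] % | observed patient DNT percentages |
| sp_fraction_range | [0.10, 0.20] | single-positive mutant-cell contribution |
| sp_patient_proportion | 1.0 | fraction of patients with that contribution (unquantified in the source; applied to all, flagged as an assumption) |
| dnt_carrier_fraction | 1.0 | fraction of DNT carrying the mutation; configurable downward |
| lymphocyte_scale | 1.0 | multiplier on (f_DNT + f_SP); < 1 models T-cell lymphopenia, e.g. under immunosuppression |
| depth_median / depth_sigma | 200 / 0.35 | per-site lognormal depth; ±2σ ≈ 100–400, covering the observed 101–399 |
| error_rate | 1e-3 | per-base miscall toward the variant allele |
| strand_balance | 0.5 | probability a read is forward |
| germline_snp_rate | 0.05 | per-sample probability of one heterozygous in-region SNP — calibrated to the two sporadic germline hets among 52 samples; the near-fixed recurrent polymorphism seen in most real samples is *not* emulated by default, since it would dominate the strict specificity accounting |
| indel_fraction | 0.25 | fraction of somatic events that are deletions (two of the eight causal variants in the study are deletions) |
| n_sites | 120 | panel positions, evenly spaced across the target regions |

Generation per site: depth ~ lognormal; depth_fwd ~ Binomial(depth,
strand_balance); then alt_fwd ~ Binomial(depth_fwd, p) and alt_rev ~
Binomial(depth_rev, p), so alt ~ Binomial(depth, p) marginally and every
count invariant (alt_s ≤ depth_s, depths summing) holds by construction.
A patient receives one somatic variant at a uniformly chosen site with
p = c/2 + ε(1 − c/2); germline SNPs use p = 0.5; background sites use
p = ε. Reference/alt bases come from a stable position hash (no genome is
bundled); whole-blood cell composition is collapsed into the single
mutant-cell fraction c, since the caller sees only allele counts.

Determinism: all randomness flows from the master seed through
`numpy.random.SeedSequence(seed, spawn_key=(sample_index,))`, one child
stream per sample, so cohorts are bit-reproducible across runs and
platforms.

What passing simulation tests do **not** show about real data: no
alignment or mapping artifacts, no homopolymer-context indel errors (a
known weakness of the semiconductor chemistry this assay runs on), no
amplicon-edge effects, no sample contamination, and a single common
recurrent polymorphism is absent by default. Fixture-based validation
(real printed counts) covers the accounting; the simulator covers the
sampling model.

## Validation accounting

- A **patient** is a true positive iff some passing, somatic-classified
  call matches its known causal variant's site and alleles exactly. A
  patient whose causal variant is documented but below the support floor
  (P8: 3-bp deletion, one read) is a false negative by construction.
- A **control** is a true negative only if it has *no* passing call of any
  classification — a germline polymorphism call counts against it. This
  strict accounting is an inference (the source does not state its
  denominator), but it is the only one consistent with the printed
  specificity: 41 call-free controls of 44 → 93.1% truncated. Re-scoring
  controls after annotation-based interpretation (which would discount
  benign calls and raise specificity to 100%) requires pathogenicity
  annotation, which is out of scope.
- The multi-sample report row shared by P1 and P4 is credited to both; the
  recurrent-variant row is not attributable to named samples and is
  excluded from per-sample accounting.

## Numerical choices and edge cases

- Coordinates are 1-based inclusive internally; BED converts on read,
  VCF deletions are anchored on write (anchor base N — no reference genome
  is bundled) and un-anchored on read, making write→read the identity.
- VAF at zero depth, strand-bias on zero variant reads, and regions with
  start > end are errors, not sentinel values.
- Fisher p-values come from `scipy.stats.fisher_exact`; the test suite
  verifies them against brute-force hypergeometric enumeration with exact
  integer weights on every 2×2 table with per-strand depths ≤ 30
  (agreement to 1e-9).
- Two of the twelve bundled report rows print VAFs inconsistent with their
  own counts (count/coverage division gives 55.8 vs printed 54.2, and 54.4
  vs 54.1), plausibly from caller-internal downsampling; the package
  computes from counts and does not reproduce those two printed values.
  Printed strand-bias scores are likewise carried as metadata only.
- `load_fixtures` returns call skeletons with computed VAF/strand
  statistics but classification `"unset"`; classification is the filter
  chain's job.

## Known limitations

- No read-level or error-context realism in the simulator (above).
- The germline VAF-band classifier is a simplification; a real workflow
  would run a dedicated germline caller first.
- The power model treats the minimum-VAF limit as read-count-bound; if the
  true limit at high depth is chemistry-bound, the model is optimistic
  beyond the depths observed in the validation data.
- Specificity accounting is strict-by-call; interpretation-aware
  specificity is documented but not computed (annotation out of scope).
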