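# Methods

## Scope and model

`exoqc` operates on unphased diploid genotypes at biallelic SNVs in a
multi-sample VCF. Genotype identity is the unordered allele pair
(`0/1 ≡ 1/0`); phase is discarded. Variant identity is the full
`(chrom, pos, ref, alt)` key with 1-based VCF coordinates. Indels,
symbolic alleles and half-called genotypes are outside the model: non-SNV
records are skipped with a logged count, and half calls (`0/.`) are coerced
to missing as a unit, also logged. Multiallelic records are split into one
site per ALT by default (other ALT alleles recode as REF, matching
`bcftools norm -m-`); splitting can be disabled, in which case such records
are skipped. The FILTER column is consumed as an upstream VQSR verdict:
`PASS` and `.` both count as passing (callers emit `.` before any
filtering), anything else as failing. Recomputing VQSR itself, alignment,
variant calling and the imputation computation are out of scope; their
outputs are inputs here.

## Genotype filters

A called genotype is masked — set to missing — when `DP < min_dp` or
`GQ < min_gq`. Masking rather than deletion is deliberate: the call-rate
filter downstream must see filtered genotypes as missing, which is what
couples the two filter levels. Homozygous-reference calls are filtered
like any other genotype. A called genotype *lacking* the DP (or GQ) field
fails an active DP (or GQ) filter — the conservative reading — while a
filter passed as `None` is fully disabled, which the sweep machinery uses
to isolate one filter at a time.

The default thresholds encode ~99% genotype confidence analytically rather
than empirically:

* `min_dp = 8`: under a two-tailed binomial model in which each read of a
  true heterozygote carries either allele with probability 1/2, the chance
  that all `DP` reads show one allele is `min(1, 2·(1/2)^DP)` —
  0.78% at 8 reads (`het_mono_probability`). The 99.9% criterion would
  require 11 reads (`min_dp_for_confidence(0.001)`).
* `min_gq = 20`: Phred-scaled quality implies accuracy `1 − 10^(−GQ/10)`,
  i.e. 99% at 20 and 99.9% at 30 (`phred_accuracy`).

## Variant filters

Applied, in the default order, to genotype-masked data:

1. **Hardy-Weinberg exact test.** With the minor-allele count and diploid
   sample size fixed, each achievable heterozygote count has an exact
   probability under random mating; the p-value sums the probabilities of
   all configurations no more probable than the observed one. The
   implementation uses the numerically stable two-sided recurrence from
   the distribution's mode; ties are included with a relative tolerance of
   1e-9 so exactly symmetric configurations are not dropped to float
   rounding. A chi-square approximation is deliberately avoided: it is
   anti-conservative at rare minor-allele frequencies, which is exactly
   where exome data concentrate. A site is removed when `p ≤ α/N`
   (default α = 0.05), where `N` is the number of variants with at least
   one called genotype in the dataset being filtered — per batch when
   batching. Monomorphic sites have p = 1 and are never removed.
2. **Average GQ ≥ 35**, the mean GQ over called genotypes. Because
   genotype masking precedes this stage, the metric is computed over
   surviving genotypes only; sweeps of this metric therefore show no
   effect below the genotype-level GQ threshold.
3. **Call rate ≥ 0.88**, the fraction of cohort samples with a called
   genotype (masked genotypes count as missing; the denominator is the
   full batch sample count).
4. **VQSR verdict** — keep `vqsr_pass` variants. Position is configurable:
   after the manual filters (default), before them, or off.

All thresholds are "keep if metric ≥ threshold"; HWE removes on
`p ≤ corrected α` (boundary equality removes). A variant with *no* called
genotypes cannot satisfy a positive average-GQ or call-rate threshold and
is removed at the first such stage; with a zero threshold it is kept, so
all-permissive thresholds are exactly the identity. Defaults for average
GQ and call rate are cohort-calibrated quantities, not universal constants:
the sweep module exists to re-derive them (the analytic genotype thresholds
are universal).

Because every site filter is a per-variant predicate, the VQSR verdict's
position changes the outcome only through the Bonferroni denominator `N`
(VQSR-first tests fewer variants, giving a slightly laxer corrected
threshold). On synthetic cohorts the resulting survivor-set differences
are accordingly tiny and direction-unstable, so the order-comparison
report (`compare_filter_orders`) is validated against a set-algebra oracle
rather than against a fixed inequality between the two orders' Ti/Tv.

## Evaluation

**Concordance.** Each (sample, site) pair present in both the sequencing
dataset and the array gold standard is classified by alternate-allele
counting: identical hom-ref pair → TN; identical het/hom-alt pair → TP;
sequencing missing at least one alternate allele → FN; at least one extra →
FP; missing sequencing genotype → excluded. Exclusion (not FN) of missing
genotypes is what lets a genotype filter "remove" discordant comparisons.
Concordance is reported separately for array hom-ref and array non-ref
comparisons so reference matches cannot inflate it; under this
classification non-reference concordance coincides with sensitivity
`TP/(TP+FN)` and reference concordance with specificity `TN/(TN+FP)`.
Pairs are matched on the exact variant key; shared positions with
disagreeing alleles are logged and excluded (no strand flipping or allele
harmonisation is attempted — array data are assumed already in genome
orientation). Array records below a GenCall score threshold (default 0.30)
are dropped at read time.

**Ti/Tv.** Transitions are `A↔G` and `C↔T`; each variant counts once
regardless of call rate. Ratios are reported for all variants and within
known (dbSNP-style), novel (= not known) and truth (HapMap-style) strata.
Whether a filter removed more transversions than a uniform draw would is
tested with a one-tailed hypergeometric upper tail `P(X ≥ tv_removed)` on
the pre-filter pool of the stage under test.

**Sweeps.** A genotype sweep re-runs a single DP or GQ filter over a grid
and records discordant-removed / concordant-retained fractions relative to
the unfiltered comparison plus sensitivity and specificity; a variant
sweep records stratified Ti/Tv and truth-set retention. Threshold
selection takes the *largest* grid value whose retention metric still
meets the target — the formalisation of "capture most of the quality gain
while losing a minimal fraction of true variants". Every sweep point is,
by construction and by test, identical to an independent single-threshold
run.

## Batched filtering

The cohort is split by a user-supplied sample→batch table (batch discovery
is not attempted); each batch runs the full cascade independently; the
merged output is the union of variant keys passing in at least one batch.
For a merged variant, genotypes come from the batches where it passed and
are set missing for samples of batches where it failed — a declared policy
(the conservative alternative, carrying failed-batch genotypes through,
would reintroduce exactly the low-quality calls the batch split is meant to
contain). Merge soundness — every merged variant passes all filters in at
least one batch — is asserted by re-checking filters per batch in the test
suite.

## Imputed-genotype filtering

Imputed panels carry per-genotype GQ and a per-variant allelic R² from the
imputation engine (consumed as given, never re-estimated). Genotypes with
GQ < 20 are masked; variants are then classed as `no_genotype` (nothing
left), `monoallelic` (all survivors homozygous for one identical allele —
all-hom-ref and all-hom-alt both qualify), or `polymorphic`, and only
polymorphic variants are kept. The baseline comparison keeps variants with
R² strictly greater than 0.3, untouched genotypes included; when errors
are GQ-driven the GQ route removes a larger fraction of truth-discordant
genotypes, which the acceptance suite verifies on synthetic panels.

## Synthetic data

The generator emulates the structure the filters assume, with all
randomness drawn from one integer-seeded `numpy` generator (fixed seed ⇒
bit-identical output). Defaults define the study conditions used
throughout the tests: 200 samples × 20,000 variants in two batches (75% /
25% of samples, mirroring a dominant-batch design), with 10% of sites
private to each batch's capture target.

* **Sites.** 85% *true* variants with ref/alt drawn at Ti/Tv 2.8 (the
  expectation for clean exome sets) and a rare-skewed MAF spectrum
  (`0.5·Beta(0.3, 2.5)`, floored at one allele copy); 15% *false* artifact
  sites at Ti/Tv 0.5 (the random expectation) whose true genotype is
  hom-ref in every sample — so quality filters carry Ti/Tv signal by
  construction. 5% of sites are drawn with a heterozygote excess
  (inbreeding-like F = −0.4 at MAF 0.3–0.5, the regime where a
  200-sample exact test has power), emulating the clustering artifacts the
  HWE filter targets.
* **Coverage and quality.** Read depth is gamma-Poisson: mean 30 on-target
  (shape 4), mean 6 at artifact sites (shape 2), mean 0.4 off the batch's
  target; zero-depth genotypes are missing. GQ grows with depth
  (`3·DP·lognormal(σ=0.35)`, capped at 99), and each called genotype is
  corrupted with probability exactly `10^(−GQ/10)`, biased toward the
  adjacent class (hom↔het 9:1 over hom-ref↔hom-alt), matching the
  dominant het/hom error directions in real callers. The calibration is
  asserted: genotypes at GQ 20 err at 1% within binomial error.
* **Verdicts and membership.** VQSR fails 70% of artifact sites vs 5% of
  true sites; 64% of true and 20% of false sites are "known"; the truth
  set is half of the known true sites; the array assays 40% of known
  sites on a 10-sample subset with configurable error rate (default 0.1%)
  and GenCall scores of which ~1.2% fall below 0.30.
* **Imputed panel.** Per-variant R² is a mixture — 55% well-imputed
  (`Beta(8, 1.6)`, mean ≈ 0.83) and 45% poorly imputed (`Beta(1, 16)`,
  mean ≈ 0.06), GQ scales with R² (`50·R²·lognormal`), and errors again
  follow `10^(−GQ/10)`, so poorly imputed variants end up in the
  `no_genotype` class and GQ-driven errors dominate.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, read-level artifacts (strand bias, mapping error),
per-sample quality variation, indels, and relatedness. Passing tests
demonstrate that the filters recover planted structure under the model's
assumptions — Phred-calibrated errors, coverage-driven missingness,
batch-private targets — not that the default variant thresholds are
optimal for any particular real cohort.

## Numerical choices and edge cases

* Exact-test tie inclusion uses a 1e-9 relative epsilon; both exact tests
  match exhaustive exact-arithmetic oracles to better than 1e-12 over all
  configurations with ≤ 50 diploids / pools ≤ 30.
* The hypergeometric upper tail from zero removals is 1 by definition
  (short-circuited to avoid degenerate-parameter NaNs in the backend).
* Undefined metrics (zero denominators, all-missing variants) raise a
  dedicated error for that metric only; sweep curves record them as NaN.
* Ti/Tv of a stratum with no transversions is NaN, never infinite.
* `truth_retention` is 1.0 by convention when the input holds no truth
  variants.
* All pipeline stages are deterministic given inputs and configuration;
  reruns are bit-identical.

## Known limitations

* The Bonferroni denominator is the per-dataset (per-batch) tested-variant
  count; studies correcting over a genome-wide constant will remove
  slightly different HWE tails.
* Concordance requires exact key matches; array data on the opposite
  strand must be harmonised upstream.
* The order-comparison machinery reproduces only the multiple-testing
  route by which filter order can matter here (see above); effect sizes
  observed on real cohorts may involve pipeline interactions outside this
  model.
* Batched filtering assumes batch labels are correct and exhaustive; no
  attempt is made to detect batch structure from the data.
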