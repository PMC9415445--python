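# Methods

## Model and procedure

All inference is built on within-sample relative expression orderings
(REOs): for genes A and B in sample s, the only quantity consumed is
sign(x_As − x_Bs). Any batch effect acting as a strictly increasing
per-sample transform leaves every REO unchanged, so every statistic in this
package is batch-invariant by construction (and tested to be bit-identical
under random monotone distortions).

**Stable and reversal pairs.** A pair is stable in a phenotype when its
majority ordering holds in ≥ θ of samples (θ = 0.9). Exactly equal values
are ties: they count toward neither direction but remain in the
denominator, so tie-heavy pairs fail the threshold rather than pass it — a
conservative choice, since the alternative (dropping tied samples from the
denominator) inflates support. The stability threshold is inclusive (≥) at
the discovery stage and strict (>) at the consistency-filter stage; both
semantics are explicit flags because the two stages of the original
procedure use different wordings of the 90% rule. Thresholds ≤ 0.5 are
rejected outright: below a majority the two directions are not mutually
exclusive and "the" stable direction is ill-defined.

**Signature construction.** Per platform, reversal pairs are those stable
in both phenotypes with opposite orderings. Per-platform sets are
intersected requiring *identical orientation* in both groups, not mere
co-occurrence — a pair reversed one way on one platform and the other way
on another is contradictory evidence, not support. Survivors must show
their normal-phenotype ordering in > θ of an independent normal-only filter
cohort. Pairs with a gene unmeasured on the filter platform are dropped and
counted. The signature records its build configuration in '#' header lines
of its TSV serialisation, and a read/write round-trip is lossless.

**Risk score.** For one sample, m = signature pairs with both genes
measured and untied, n = those showing the cancer ordering, score = n/m.
Missing and tied pairs leave both numerator and denominator so that scores
from platforms with partial gene coverage remain comparable; the evaluable
fraction (coverage) is always reported and a configurable floor (default
0.5) turns silent extrapolation into a hard error. Majority vote classifies
score > 0.5 as cancer-like, with exact ties called normal-like
(conservative). AUC uses the rank/Mann–Whitney construction with ties
counted ½; its confidence interval is a seeded percentile bootstrap over
samples (2000 resamples) since no analytic CI is prescribed by the
procedure this mirrors. Group comparisons use the two-sided Wilcoxon
rank-sum test: exact null when the combined n ≤ 20 without ties, normal
approximation with tie correction otherwise (the switch point is an
argument).

**Stage correlation.** Each signature pair contributes a per-sample binary
indicator (1 = cancer ordering, ties missing). The indicator is correlated
with ordinal stage (moderate = 1 < severe = 2; the coding map is
extensible) by Spearman's ρ with tie correction. Because the indicator is
binary and stages are heavily tied, the asymptotic t approximation is
unreliable at small n; below n = 12 usable samples an exact permutation
null is used, enumerating the distinct multiset permutations of the stage
labels (they are equiprobable under uniform permutation) and capping the
enumeration at 10^5 arrangements, beyond which the t approximation is used.
Constant-indicator pairs are excluded and counted. Multiple testing is
Benjamini–Hochberg throughout.

**Hypergeometric tail.** P(X ≥ k) is computed as a log-space sum of
log-binomial terms (gammaln + logsumexp) — algebraically identical to the
one-minus-lower-sum form but safe for N in the thousands. The same function
serves pathway enrichment (against GMT sets, with the universe size N a
required explicit argument, never inferred from the GMT) and list-overlap
significance. An uncorrected p < α significance mode for enrichment exists
behind a flag (off by default) for the low-power small-list situation.

**Differential expression and treatment reversal.** Fold-change is the
ratio of arithmetic group means on the loaded (linear) intensity scale;
significance is the pooled-variance two-sample Student t (df = n₁+n₂−2),
chosen because the published 6-vs-6 reference statistics this module is
validated against are exactly consistent with df = 10 (the test suite
verifies all 16 rows to 4 significant figures); Welch is available behind a
flag. Genes with zero pooled variance get p = NaN and a logged warning, not
a silent zero. Reversal counting is by p-value alone — the published
reference counts are reproduced by pure p-counting with no
effect-direction requirement — while a direction-checked mode (treatment t
must oppose the disease t) is provided, off by default. Ortholog
translation keeps only strict 1:1 mappings; zero- or multi-target genes are
counted as unmapped.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
microarray physics. Intensities are log-normal (baseline log-means
N(6, 1), i.e. median intensity ≈ 400 in arbitrary units). The two genes of
a planted pair share a per-sample latent log-intensity (SD 2 around the
pair's base) and the planted signal is the pair's log-ratio, drawn
N(+gap, noise_sd²) in normal samples and N(−gap, noise_sd²) in cancer-like
samples. This co-expression structure mirrors how reversal pairs behave in
real data — two co-regulated genes whose relative order flips — and it is
what makes planted truth recoverable: within-pair orderings have margin
gap against noise of SD noise_sd, while any comparison crossing pair
boundaries fluctuates with two independent latent intensities (SD ≈ 2·√2)
and cannot reach a 90% stability threshold by accident. Background genes
are i.i.d. across phenotypes.

Defaults are the package's study conditions: 1000 genes, 200 planted pairs
(disjoint genes, so recall and contamination are unambiguous), 50 samples
per phenotype per platform, gap 2, noise SD 1, two discovery platforms
(fractions 1.0 and 0.9 of the genome; platform subsets retain planted genes
unless a flag drops them) plus a filter cohort, batch distortion on. At
these conditions the per-sample within-pair concordance is Φ(2) ≈ 0.977,
which passes five independent ≥90%-of-50-samples gates with probability
≈ 0.98 — hence the expected recall just below 1 and essentially zero
contamination that the recovery tests assert.

Batch distortion applies to each sample its own x → a·x^b + c with
a ∈ [0.5, 2] and b ∈ [0.7, 1.4] log-uniform, c uniform in [0, column
median] — strictly increasing on positives, hence REO-preserving exactly.

Stage cohorts fix the ordering of each planted pair per sample by a
Bernoulli draw with the stage's probability (stage-related pairs; the rest
use the lowest-stage probability), with pair-member values jittered within
±gap/4 so the drawn ordering is never overturned — flip probabilities are
therefore exact, which the calibration tests rely on. The planted layout
and stage-pair selection depend only on the config seed; a separate sample
seed draws independent cohorts over the same biology, emulating two
datasets measuring the same disease.

The treatment design is six replicates per group, 2000 genes, 100
differential genes shifted by ±1.0 on log scale (sign random per gene),
log-scale noise SD 0.5 — at 6 vs 6 this gives partial power (≈ 0.77),
deliberately in the regime where a p < 0.05 screen both misses true genes
and admits false ones. Each of four treatments pulls a random half of the
differential genes fully back toward control.

What the generator does **not** emulate: probe-level structure, dye and
array-region artefacts, realistic gene–gene correlation beyond the planted
pairs, heavy-tailed noise, or missing values. Passing the recovery tests
therefore demonstrates correctness of the pipeline's logic under its own
assumptions, not performance on real microarray data.

## Numerical choices and degenerate inputs

- Stability counting is blocked over the pair space (block size
  configurable); the result is asserted bit-identical to the naive
  triple loop on exhaustive small instances.
- Matrix TSVs are written at %.17g and read with round-trip float parsing,
  so write/read cycles are bitwise lossless.
- Zeros and missing values are rejected at load (orderings need strictly
  positive, observed intensities); a pseudo-floor option rescues matrices
  with zeros. Probes absent from the probe→gene map are a hard error,
  and probe maps listing a probe on several rows are unioned before the
  zero/multi-gene discard rule is applied.
- Exact Wilcoxon and exact permutation nulls are used only in tie-free /
  small-n regimes where they are correct and cheap; the switch points are
  arguments, logged in result metadata.
- p-values are clamped into (0, 1]; |ρ| = 1 in the t-approximation branch
  maps to the smallest positive float rather than 0.

## Problem sizes

The test suite and analysis scripts run everything at the study conditions
above (seconds per stage on one CPU); exhaustive-oracle tests use G ≤ 50,
S ≤ 20 for pair counting, N ≤ 20 for hypergeometric enumeration and
n ≤ 30 for AUC brute force, sizes at which full enumeration is exact and
fast. The invariance suite runs 100 independent distortion trials.

## Known limitations

- Stability thresholds are applied to pooled samples per platform (with the
  per-dataset alternative available by calling `stable_pairs` per dataset);
  pooling matches the cohort-level counts the procedure reports.
- The hypergeometric universe for pair-list overlap is the signature size,
  which ignores the dependence between pairs sharing genes.
- Spearman on a binary indicator equals a rank-biserial correlation up to
  scaling; effect sizes are not comparable to Spearman on continuous data.
- The exact permutation null caps at 10^5 distinct arrangements; above the
  cap at small n the t approximation may be anticonservative under heavy
  ties.
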