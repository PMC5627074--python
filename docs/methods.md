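# Methods

## Data model and error channel

A CpG unit is the dinucleotide treated as a single locus with one
cytosine per strand; the minus-strand cytosine at plus-position `pos+1`
is keyed to `pos`, so strand-resolved counts of one unit share a key.
Coordinates are 1-based internally (matching Bismark cytosine reports);
BED output converts to 0-based half-open. For non-directional amplicon
libraries, complementary bisulfite strands are collapsed onto the
original strand they report on (OT/CTOT → plus, OB/CTOB → minus).

Bisulfite reads are modelled as passing each cytosine through an
asymmetric binary channel: an unmethylated C survives conversion and
reads as methylated with probability ε (non-conversion, default 0.01),
and a methylated C is inappropriately converted with probability δ
(default 0; the parameter exists because pattern-frequency estimators in
this family support two-sided error, but only non-conversion is
corrected for by default). Both rates are required to be below 0.5 for
identifiability.

## Site and region detection

Methylation calls use the pooled strand counts: the one-sided binomial
p-value P[Bin(M+U, ε) ≥ M], BH-corrected across units, with
`called_methylated ⇔ q < α` (α = 0.05). One-sided because ε is a floor
on the observed methylated fraction, not a symmetric null. Coverage
filtering requires ≥10 reads on *each* strand and total coverage at or
below the empirical 95th percentile; the percentile is computed (linear
interpolation) among units that pass the per-strand minimum, ties at the
cut are retained, and the realised cut is recorded in the result's
`attrs` so that refiltering an already-filtered table reuses it rather
than shaving a fresh 5% tail — that recorded cut is what makes the
filter idempotent. Whether the percentile should be computed before or
after the per-strand minimum is not determined by the procedure's
description; "after" is the recorded choice.

Site asymmetry uses the two-sided Fisher exact test on
[[M⁺, U⁺], [M⁻, U⁻]], computed by enumerating the hypergeometric support
and summing probabilities of tables no more likely than the observed one;
the tie comparison uses relative tolerance 1e-7, which makes the discrete
tie set reproducible across platforms. Only methylation-called units
enter the test, and BH runs across exactly that population (testing all
covered units would be the other defensible choice; this one is
recorded). The implementation is vectorised over the whole methylome
(padded support grids), which is what makes 100-fold shuffle scans cheap.

Region detection tiles fixed-width windows (default 1800 bp) along each
chromosome on a step grid (default 300 bp = window/6 — a step is not part
of the original procedure's description; 300 bp localises 1800 bp
effects without exploding the number of tests, and it is configurable).
A window is testable when it holds ≥8 methylation-called units covered on
both strands. The paired t-test pairs per-CpG levels across strands
(d_i = b⁺_i − b⁻_i, df = n−1, two-sided). Degenerate windows: all d_i
exactly 0 gives (t = 0, p = 1); zero variance with nonzero mean reports a
signed infinite t with the smallest positive double as an underflow-safe
p. BH is applied across windows (not across member CpGs — "across
windows" is the recorded reading), and overlapping flagged windows merge
into maximal regions.

## Strand-shuffle null

The false-positive yield of both scans is estimated by re-dealing each
unit's pooled methylated/unmethylated labels onto the strands without
replacement, preserving per-strand coverage exactly (the plus strand
draws its coverage from the pooled labels, hypergeometrically). This
choice — rather than i.i.d. coin-flip assignment, which is available
behind a flag — keeps the per-strand ≥10-read filter and the tests'
power structure identical between observed and shuffled data. Pooled
counts are conserved, so methylation calls need not be recomputed. Each
of the (default 100) shuffle replicates uses an independent stream
derived from (seed, replicate index).

## Epiallele extraction and EM frequency estimation

Patterns are binary strings over a locus's ordered reference CpG set.
Reads with calls at non-reference positions (phantom CpGs) are
discarded, then reads not covering every reference CpG (truncated), so
surviving patterns are equal-length and aligned; finally patterns with
count below 1% of the sample–strand coverage (computed after the first
two filters — the filter order is a recorded choice) are removed. The
pattern space is 2ⁿ, computed exactly in arbitrary precision.

Per (sample, strand), true pattern frequencies f over the observed
support maximise the multinomial likelihood with cell probabilities
(A f), where A[o, t] = Π_sites P(observed state | true state) under the
error channel. EM iterates responsibility-weighted re-estimation until
max |Δf| < 1e-8 or 10⁴ iterations (non-convergence is flagged with the
last iterate kept); the log-likelihood is asserted non-decreasing at
every step, and frequencies are renormalised on the support each step.
Restricting the support to observed patterns is deliberate: the full 2ⁿ
support is both intractable and unidentifiable at amplicon depth. Two
consequences are worth knowing. First, with ε = δ = 0 the estimates
equal observed proportions exactly, and for a single CpG the estimator
reduces to the closed-form deconvolution (p̂ − ε)/(1 − ε). Second,
because the abundance filter removes a little probability mass that the
channel model does not condition on, the estimator carries a small
truncation-induced bias even at infinite depth; at the depths and locus
sizes used here it is an order of magnitude below the sampling noise and
is covered by the recovery tolerance the acceptance checks enforce.

Uncertainty on per-pattern strand differences (f⁺ − f⁻) uses a
percentile bootstrap: reads are resampled with replacement within each
sample–strand stratum (multinomially over observed patterns), EM is
re-run per resample (default 1000), and the 2.5/97.5 percentiles bound
the difference. Patterns absent from one strand's support contribute
frequency 0 there. The original top/bottom pairing of patterns on
individual fragments is *not* recoverable from strand-split data and the
package makes no attempt to infer it.

## Models

The multinomial logistic model treats each read's pattern as a
categorical outcome with softmax-linear dependence on treatment-coded
factors (strand, replicate, group), fitted by maximising the exact
cell-count likelihood with a fixed ridge penalty of 1e-6 on the
coefficients. The ridge guarantees a unique optimum under complete
separation — the realistic case of a pattern abundant on one strand and
absent from the other — at a bias far below statistical noise;
separation is additionally flagged when any |coefficient| exceeds 15.
The reference pattern is the most abundant pooled pattern (ties broken
lexicographically). Residual deviance is −2·loglik, so nested designs
compare by deviance difference against χ² with the parameter-count
difference as df; per-pattern factor effects use Wald tests from the
exact penalised Hessian. Fitting on read counts (the default) gives a
proper likelihood; an option substitutes EM-estimated frequencies times
stratum coverage as effective counts for analyses phrased in terms of
estimated frequencies.

Strand effects on amplicon methylation *levels* use a linear mixed model
`level ~ strand` with a random intercept per sample: REML for the
reported variance components and fixed effect, and a likelihood-ratio
test of ML fits with and without strand (χ², df = 1) for the p-value.
When the ML likelihood degenerates at the zero-variance boundary the
p-value falls back to the Wald test on the REML strand coefficient; with
a single sample the model is degenerate and a paired t-test across CpG
units is used instead, with a warning. In the amplicon workflow, levels
are first corrected for non-conversion with the explicit transform
b_corr = max(0, (b − ε)/(1 − ε)) — never silently.

## Simulator

Site mode draws per-strand read counts Poisson around the specified
coverage and methylates each read with probability p(1−δ) + (1−p)ε. A
vectorised count-level variant (`simulate_methylome_counts`) produces
the identical distribution for genome-scale methylomes without
materialising per-read rows. Amplicon mode draws fragments from a joint
distribution over (top, bottom) pattern pairs, sequences each strand of
a fragment as one full-length read (fixed depth — amplicon sequencing is
deep and fixed-depth in practice, unlike shotgun coverage), and flips
states through the error channel. Randomness is keyed per
(seed, locus/sample), so any locus regenerates independently.

What the simulator does not emulate: PCR duplicates, alignment and
mapping bias, position-within-read error profiles (end-trimming is
supported on reading, not simulated), SNP-destroyed CpGs, and
non-CpG contexts. Passing tests therefore demonstrate statistical
correctness of the pipeline under the stated sampling model, not
robustness to those artefacts.

## Problem sizes and default parameters

Defaults: ε = 0.01, δ = 0, α = 0.05 everywhere, ≥10 reads/strand, 95th
coverage percentile, 1800 bp windows with ≥8 methylated CpGs and 300 bp
step, 100 shuffles, 1% pattern-abundance floor, 1000 bootstrap
resamples, EM tolerance 1e-8, ridge 1e-6.

The acceptance script measures the pipeline at these conditions: a
10⁴-CpG symmetric methylome at ~30 reads/strand for the shuffle null;
100 replicate simulations of a 0.92/0.05 hemimethylated site at 1000
reads/strand against a 2000-site background; a 3-CpG amplicon with true
frequencies (0.5, 0.3, 0.2) at 10⁴ reads/strand, with the EM error
summarised as the mean L1 over six replicate strata; 500 null
simulations for likelihood-ratio calibration plus one strong
strand-effect dataset (pattern frequency 0.8 vs 0.2, 5000 reads/strand);
and 60 simulated two-CpG loci with 500 bootstrap resamples each for CI
coverage. The strand-level correlation readout uses a Beta(2, 0.5) true-
level mixture at 60 reads/strand — most methylated CpGs nearly fully
methylated with a tail of partial methylation, at combined-replicate
depth. The analysis scripts use a 5000-site methylome at the same depth
with deep (1000×) three-replicate amplicons for two groups.

## Known limitations

- The Fisher test is conservative at low coverage (discreteness), so
  realized false-positive counts under shuffling typically sit below the
  nominal FDR bound.
- Percentile bootstrap CIs can undercover slightly for patterns near
  frequency 0 or 1 at modest depth.
- The EM support restriction plus abundance floor yields the small
  truncation bias described above; a retention-conditioned likelihood
  would remove it at the cost of coupling the estimator to the filter.
- BH across overlapping windows ignores their positive dependence
  (conservative on the merged-region scale).
- The mixed model with very few samples (e.g. three replicates) leans on
  asymptotic χ²/Wald approximations; its p-values at that size are
  indicative rather than exact.
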