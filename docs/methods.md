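# Methods

This note records the models the package implements, the defaults and why,
what the synthetic-data generators do and do not emulate, and the numerical
choices made where the underlying descriptions left the design open.

## Splicing-event model and filters

An event is a genomic interval (0-based half-open, BED convention) with a
class in {CE, RI, MXE, A3SS, A5SS}, a differential-splicing p-value, read
support for inclusion and exclusion, and Ψ (PSI) in both conditions with
ΔΨ = Ψ_treated − Ψ_control. The significance filter keeps events with
p ≤ 0.05, inclusion reads ≥ 1, exclusion reads ≥ 1, total reads ≥ 10, and
|ΔΨ| ≥ 0.10; every comparison is inclusive, and the ΔΨ test is applied to
the absolute value because both preferential inclusion (ΔΨ > 0) and
preferential exclusion (ΔΨ < 0) are biology of interest downstream. The ΔΨ
comparison tolerates 1e-12 of floating error so a difference computed as
0.6 − 0.5 still passes the 0.10 boundary. All thresholds live in
`PipelineConfig` and can be overridden per run.

Cross-sample consolidation declares two events the same when their
intervals overlap reciprocally by ≥ 95% (each interval covered to 95% of
its own length), on the same chromosome and strand. We additionally
require the same event class: a cassette exon and a retained intron
sharing coordinates are different biology. An event is reported when a
match exists in *every* sample; the representative record comes from the
first table in input order (deterministic and documented), with per-sample
ΔΨ retained. When several candidates match, the one with the largest
minimum overlap fraction wins.

## Protein-impact classification

Events are mapped to transcript exon chains by complete-inclusion /
complete-exclusion rules: a retained intron maps when some transcript
carries the interval strictly inside one exon (the retained form, flanked
by exonic sequence on both sides); exon-centred classes map when one
transcript contains the segment within an exon and another has no exonic
overlap at all. Mapped events whose length is not a multiple of 3 are
frameshifting; multiples of 3 preserve frame unless a supplied nucleotide
segment contains a stop codon on the codon grid anchored at the mapping
transcript's coding start (minus-strand segments are reverse-complemented
first). Unmapped events are `unknown`. The direction-versus-disruption
association is a 2×2 Fisher's exact test ({ΔΨ>0, ΔΨ<0} × {disruptive,
not}), two-sided by default with a one-sided option, returning p = 1 with
a warning on degenerate (zero-margin) tables.

## RT-PCR PSI

Ψ = L/(L+S) from the measured concentrations of the long and short
amplicons. The isoform pair is selected once per assay as the two amplicon
sizes with the largest concentration totals summed over *all* samples of
the assay — not per sample, so a sample in which one isoform vanishes
reads out as Ψ = 0 or 1 rather than adopting a noise peak. Ties on total
concentration resolve toward the larger amplicon. Ψ is undefined (missing)
only when both selected peaks are absent in a sample; one missing sample
never affects another.

## Dose–response

Readout time is the 95th percentile (nearest-rank) of the per-well times
to first reach 100% confluence among vehicle controls, snapped to the
nearest observed timepoint at or before it. Responses are fractions of the
vehicle mean, clipped to [0,1] (clipping recorded) so the AAC stays on the
0–1 scale. AAC is the trapezoidal integral of (1 − response) over
log₁₀(dose) across the observed points, normalized by the tested
log-range; this observed-point construction is the standard normalized AAC
and depends only on the log-spacing of doses. EC50 comes from least
squares on response = E_inf + (1 − E_inf)/(1 + (d/EC50)^h), with the top
fixed at 1 (responses are control-normalized, which keeps the model
identifiable at nine doses), E_inf ∈ [0,1], h ∈ [0.1,10], and log₁₀EC50
bounded one decade beyond the tested range. EC50 is reported undefined for
flat curves (response range < 0.1), fits at the upper bound, or
non-convergence; optimizer tolerances are 1e-15 so noiseless curves are
recovered to ~1e-9 relative. Sensitivity is EC50 < 250 nM (configurable);
responder labels split at the cohort median AAC by default — the published
cohort's split threshold is not stated, so it is a parameter, with the
degenerate all-equal cohort documented as all-good under the ≥-median
rule.

## Baseline splicing signature

Three criteria, applied to a baseline Ψ matrix with good/poor responder
labels: (1) the event is quantified (non-missing Ψ) in ≥ 75% of all
samples — the quantifiability and group membership descriptions do not
specify per-group fractions, so the fraction is over all samples; (2)
intra-group variation < inter-group variation, where "intra" is the root
of the average of the two within-group variances and "inter" is the
standard deviation of the two group means (equal to |dΨ|/√2 for two
groups) — the estimators are not pinned down by the source description, so
both values are emitted on every event to keep the criterion auditable;
(3) |mean Ψ_good − mean Ψ_poor| ≥ 0.20 on the fraction scale. Events with
fewer than two quantified samples in a group are skipped with a recorded
reason. Ranking is by |dΨ| descending ("top" events need a key; it is
configurable), ties by event id. A sample scores
mean over quantified signature events of sign(dΨ)·(Ψ − midpoint of the two
group means); positive predicts a good responder.

## Proteome enrichment

Proteins are ranked ascending by mean log₂ fold change with undetected
proteins entered at 0 (the stated convention) and ties broken by gene id
for determinism. For a gene set of size K in a universe of N, with k
members in the top n, fold = k/(n·K/N) and p is the one-sided
hypergeometric upper tail P(X ≥ k) — this sidedness reproduces the
published p = 1.3e-7 at (N=5355, K=194, n=50, k=12), fixing the
convention. The bootstrap SE resamples whole protein rows with
replacement B = 100 times, re-ranks each resample (duplicates count as
distinct universe members), and takes the sd of the folds. RNA–protein
correlation is Pearson over the gene intersection, undetected proteins at
0, with n (= df + 2) reported. The GSEA ranking statistic is
sign(LFC)·(−log₁₀ adjusted p); genes with adjusted p = 0 are placed at
sign(LFC)·(max finite |score| + u), u ~ Uniform(0,1) from the run seed, so
they stay extreme with distinct scores.

## Limiting dilution

Under the single-hit model a well seeded with d cells is negative with
probability e^(−f·d). Well positivity is therefore a binomial GLM with
complementary log-log link and offset log d; the intercept is log f. This
is the construction used by the standard extreme-limiting-dilution
software. Confidence intervals are Wald on log f, exponentiated
(profile-likelihood was considered and left as future work; Wald matches
the standard tool's default). Saturated doses (0% or 100% positive) enter
through the likelihood without continuity correction. Group inequality is
the likelihood-ratio chi-square between a shared-f fit and per-arm
frequencies (df = arms − 1); single-hit adequacy frees the slope on log d
and Wald-tests slope = 1 (a slope near 2 indicates two-hit kinetics).
Frequencies are reported both as f and as "1 in 1/f cells". Designs with
all wells positive or all negative raise a non-identifiability error with
guidance rather than returning a boundary estimate.

## Synthetic-data generators

The generators emit the exact input shapes the pipeline consumes at the
study's design points, with planted truth for recovery testing:

- **Event tables** — planted shared events share coordinates, class,
  strand and ΔΨ sign across samples and pass every filter (p drawn as
  0.05·Beta(0.5, 5), concentrated near 0; reads 5–99 each; |ΔΨ| uniform on
  [0.10, 0.60]); background events start from a passing draw and then
  break one filter at random (p > 0.05, zero inclusion or exclusion reads,
  total < 10, or |ΔΨ| < 0.10), the standard uniform/Beta p-value mixture.
- **Baseline Ψ matrix** — 19 good and 12 poor responders by default in
  tests; signature events separate the group means by δ (default runs use
  δ = 0.3) with Gaussian within-group noise (sd 0.05) clipped to [0,1];
  entries go missing independently (rate 0.1). Noise is Gaussian on Ψ, not
  a read-count model.
- **Dose–response** — the nine half-log doses 3 nM–30 µM, Hill response
  plus Gaussian noise, three technical replicates averaged.
- **Proteome** — log₂FC from N(0, 0.5); a planted fraction of the gene set
  shifted down by 2; 5% undetected rows.
- **Limiting dilution** — the printed seeding scheme 2000, 1000, 500, 250,
  125, 63, 31, 16, 8, 4 cells/well (the numbers as printed, not exact
  halving), six wells per dose, Bernoulli positivity 1 − e^(−f·d), the
  literal single-hit assumption.
- **Amplicons** — long/short peaks at Ψ·total and (1−Ψ)·total plus
  spurious peaks each below 10% of total.

What the generators do *not* emulate: read-level coverage and mapping
artifacts, batch and line-to-line effects, correlated missingness,
electropherogram signal processing, plate-position effects, biological
replicate structure in LDA. Passing recovery tests therefore demonstrate
correctness of the statistical machinery under the stated models, not
robustness to the full noise structure of real cohort data.

## Problem sizes and calibration checks

The test suite and acceptance script run at sizes chosen to estimate each
property stably: 10,000 events for filter/oracle agreement, 1000 events ×
31 samples × 25–50 seeds for signature recovery, 500 simulated assays for
LDA CI coverage, 200 seeds for null calibrations, 100 seeds for noisy EC50
recovery. One numerical point deserves note: the hypergeometric tail p is
discrete (its largest atom at the top-50 design is ≈ 0.16), so under the
null it is super-uniform and a raw Kolmogorov–Smirnov test against
Uniform(0,1) rejects by construction. Calibration is therefore checked on
the randomized probability-integral transform u = P(X > k) + V·P(X = k),
V ~ Uniform(0,1), which is exactly uniform when the null model holds; the
near-continuous LDA likelihood-ratio p is tested raw.

## Known limitations

- The protein-impact fallback rules cover complete inclusion/exclusion
  only; partial-overlap transcript structures map to `unknown`.
- The 2×2 direction-versus-disruption table is one faithful construction
  of that association; other contingency layouts are possible and the
  package does not claim to reproduce any particular published statistic
  for it.
- Wald LDA intervals can undercover at extreme frequencies where few doses
  are informative; the coverage check is run at f = 0.01 on the standard
  scheme.
- Hill fits report an undefined EC50 rather than extrapolating when the
  optimum sits at the dose-range bound; downstream sensitivity calls treat
  undefined as not sensitive.
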