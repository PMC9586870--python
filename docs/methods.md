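# Methods

`cfmethyl` implements a window-level analysis of methylation-capture
(MBD/MeDIP-style) sequencing of cell-free DNA: quantification of fragment
counts into CpG-density-calibrated β-values, negative-binomial
differential methylation, in-silico spike-in mixtures, an ensemble
tumor/healthy detector, a sequential transcription-factor subtype caller
for SCLC, and a prognostic methylation score. Because the real cohorts
such a pipeline is built for are controlled-access, every stage is
developed and validated against a synthetic-cohort generator that encodes
the statistical structure the pipeline assumes. This note documents both
the generator (what it emulates, what it deliberately does not) and the
analysis models, with the reasoning behind the numerical choices.

## The capture forward model

A genomic window with CpG count *d* and methylation level β ∈ [0, 1]
captures fragments in proportion to

    w(β, d) = c₀ + β · g(d),      g(d) = dᵃ / (kᵃ + dᵃ)

where `c₀` (`background_capture`, default 0.01) is nonspecific pull-down
and `g` is a saturating Hill-type response in CpG density (defaults
a = 3, k = 8). Per-window counts for a sample with library size *L* are
negative binomial with mean `L · w_j / Σ w` and dispersion φ
(`var = μ + φμ²`), so expected totals equal the library size exactly.
Excluded (blacklist-like) windows have zero capture weight.

This family was chosen because it reproduces the three facts the
downstream pipeline relies on — enrichment grows with methylation, grows
and saturates with CpG density, and counts are over-dispersed — while
being exactly invertible by the calibration stage, which makes
β-recovery a well-posed parameter-recovery experiment rather than a
tautology (the calibration never sees the true parameters).

Parameter rationale:

- **a = 3, k = 8, c₀ = 0.01.** Methyl-CpG-binding-domain affinity rises
  steeply with the number of methylated CpGs per fragment; a shallow
  response with a strong nonspecific floor would spread reads nearly
  uniformly and no sample could reach the relative-enrichment QC bound
  of 2.5 that real capture libraries meet. With these values a good
  simulated sample scores ≈ 2.5–2.6.
- **Library size 2 × 10⁶ over 20,000 windows (~100 fragments/window),
  φ = 0.005.** The per-window β standard error is approximately
  `sqrt(μ + φμ²) / span`, with a CV floor of `sqrt(φ)` from the
  dispersion term alone. These defaults put single-sample β noise at
  0.02–0.10 depending on density and level — the regime in which
  window-level β estimates are individually usable, which is what the
  package's own recovery target (RMSE < 0.08 at d ≥ 5) expresses.
  φ here is single-library technical over-dispersion; biological
  between-replicate dispersion shows up in the DMR model's estimated
  dispersions instead.

## The synthetic genome and methylomes

Windows are 300 bp, half-open, on one synthetic contig. CGI-like islands
are geometric runs (mean 4 windows) covering 15% of windows; CpG counts
are Poisson(15) inside islands and Poisson(2) outside. One percent of
windows are flagged excluded. 200 background windows form an
always-methylated QC subset (β = 1 in every class), a scaled stand-in
for the hundreds of constitutively methylated control windows used for
sample QC in real data.

The normal methylome is bimodal: island windows are unmethylated
(β ≈ 0.08) except a 25% constitutively methylated minority; background
windows are methylated (β ≈ 0.8) except a 10% unmethylated minority.
Both minorities matter for identifiability of the *blind* calibration:
the unmethylated background minority anchors the β = 0 level in
CpG-sparse strata, and the methylated island minority anchors the high
level in CpG-dense strata. Neither is an artifice — real open sea is not
uniformly methylated and a substantial fraction of CGIs (shores,
intragenic islands) is methylated.

Tumor methylomes share pan-tumor DMRs: `n_dmrs` (default 300) windows
with an exact ±0.8 β shift, 69% hypermethylated in tumor, 75% placed in
CGI/shore/shelf context. Each of the three subtypes (ASCL1, NEUROD1,
double-negative) additionally gets blocks of windows hyper- and
hypomethylated only in that subtype (default 60 per direction). Spiked
DMRs are restricted to windows with ≥ 3 CpGs: differential methylation
of a window with almost no CpGs is biologically meaningless and carries
no capture signal, so it could never be recovered by any
enrichment-based assay.

cfDNA samples are convex mixtures: β_mix = tf · β_tumor + (1 − tf) ·
β_normal at known tumor fraction. Array profiles place ≥ 1 probe on
every non-excluded window (30% carry 2–3) with truncated Gaussian noise
(σ = 0.03). Expression truth for subtyping draws the defining
transcription factor at ~11 and the others at ~5 normalized units around
the threshold of 9. Survival times are exponential with log-hazard
`log(3.6) · tf / 0.25` over a baseline with 12-month median, with
independent exponential censoring calibrated to ~30%.

What the generator does **not** emulate: read-level artifacts (mapping,
duplicates, fragment-size biology), copy-number signal, inter-individual
epigenetic variability beyond NB noise and cell-line jitter, batch
effects by default, and realistic genome geometry (the island fraction
is far above the genomic ~1% so that desk-scale cohorts contain enough
CpG-dense windows). Passing tests therefore demonstrate that the
*pipeline logic* is correct and well-calibrated under its stated
assumptions — not that the assay itself performs at these levels on
clinical material.

## Quantification and blind calibration

Fragments with MAPQ ≥ 10 and length 50–1,000 bp are assigned to the
window containing their midpoint (`floor((start+end)/2)`; boundary
midpoints go to the right window; trailing partial windows are dropped
at tiling). Counts are normalized to nrpm (normalized reads per million)
with a TMM factor against a pooled reference of the training
normal-control (NCC) cfDNA samples: weighted trimmed mean of log-ratios,
30% trim on M, 5% on A, delta-method precision weights, reference factor
≡ 1. The trimmed mean is scale-exact; the precision weights retain a
~10⁻⁴ relative depth dependence, which the tests document.

Blind calibration maps nrpm to β per CpG-density stratum (distinct CpG
counts greedily merged to ≥ 50 windows). Within a stratum, the mean nrpm
of the least-enriched decile anchors β = 0, and the most-enriched decile
is assumed to sit at β₀ = 0.8, giving
`full(d) = bg(d) + (upper decile − bg(d)) / β₀`. `full(d)` is made
non-decreasing in density by support-weighted isotonic regression, and
both anchors are interpolated linearly in density between stratum means
(a step function biases windows at merged-stratum edges). Then
`β = clamp((nrpm − bg) / (full − bg), 0, 1)`, returned as missing where
the dynamic range `full − bg` is below 1 nrpm or the window is excluded.

Two properties are worth separating. With the forward model's *true*
anchors, the estimator inverts the model exactly (tested to 10⁻⁹). The
*blind* anchors carry a bounded systematic bias — the most-enriched
decile's true β slightly exceeds β₀ because always-methylated windows
land in it — which is the price of calibrating without external
standards; a constant methylome (all β equal) is fundamentally
unidentifiable for any blind scheme. At default depth the combined
bias-plus-noise error is RMSE ≈ 0.07 over windows with ≥ 5 CpGs.

Sample QC follows the capture literature: relative enrichment (count-
weighted mean CpG density over its unweighted mean, pass ≥ 2.5) and the
always-methylated check (≥ 40% of QC windows at β ≥ 0.8, missing counted
as failing).

## Differential methylation

Each window is tested with a negative-binomial GLM on counts: offsets
`log(library_size · norm_factor)`, a two-group design, and a
likelihood-ratio test of the group term (χ², 1 df). The density-dependent
capture weight of a window is identical across samples, so it is
absorbed by the window's intercept and does not need to enter the
offset. Dispersions are method-of-moments estimates from the group-mean
fit (small-sample corrected), shrunk toward a CpG-density trend (binned
medians) with 20 prior degrees of freedom. Windows failing the
`nrpm > 1 in ≥ 1 sample` prefilter are never tested;
Benjamini–Hochberg q-values are computed across tested windows only.
Effect size is Δβ, the difference of group-mean β-values, filtered at
|Δβ| ≥ 0.5 for tissue contrasts and ≥ 0.3 for cfDNA contrasts at
FDR 0.001.

The fitter is a vectorized Fisher-scoring routine (one log-mean
parameter per window per group), which makes genome-scale null studies
cheap; it agrees with `statsmodels` GLM fits to six decimals on shared
panels, and the test suite keeps that dual route. Under a 10 vs 10 null
simulation the realized fraction of windows at q ≤ 0.001 is ~0; power
for Δβ = 0.8 spikes is 1.0 at default depth. Numerically null fits
(LRT < 10⁻¹⁰) report p = 1 exactly. Non-convergent windows are kept with
p = 1 and flagged.

CGI context uses the generator's island intervals: CGI if overlapping,
shore within 2 kb, shelf within a further 2 kb, else open sea, with
CGI > shore > shelf precedence.

## Spike-in mixtures

Mixtures are built at count level: a multinomial downsample of
`round(p · M)` fragments from the tumor source plus `M − round(p · M)`
from a background cfDNA sample. Negative mixtures combine two distinct
backgrounds the same way. Fragment totals are drawn log-uniformly
(default between a quarter of and the full default library). Count-level
mixing matches what the classifiers consume and is exchangeable (in
expectation) with simulating the mixed methylome directly, which the
suite checks. Every mixture's sources, proportion, depth and seed are
recorded in a manifest so that source-aware subsetting and leakage
checks remain possible downstream.

## Detection ensemble

Detection windows are the direction-consistent intersection of two
filtered DMR tables: tumor tissue vs healthy tissue and tumor tissue vs
training NCC cfDNA (both FDR 0.001, |Δβ| ≥ 0.5). Features are β-values
over these windows with missing encoded as 0 — bounded and
depth-invariant, so mixtures at different fragment totals are
comparable; zero is a safe missing code here because detection windows
are overwhelmingly tumor-hypermethylated. The ensemble trains 100
gradient-boosted members (500 trees, learning rate 0.02, other
hyperparameters at xgboost defaults), each on mixtures whose *every*
source lies in that member's random 80% subsets of tumor and background
sources; members drawing a single-class subset are resampled a bounded
number of times. A sample's score is the median over members, optionally
restricted to members whose sources avoid a sample's matched tumor model
(leakage-free prediction).

The decision cutoff maximizes balanced accuracy of out-of-bag median
scores (each training mixture scored only by members that could not have
seen it) over a 0.01-step grid, returning the smallest optimal grid
value — a deterministic tie-break that favors sensitivity. The grid
search is property-tested against exhaustive enumeration.

At desk scale (4,000 windows, 20-member ensembles, ~150 detection
windows) the detector reaches held-out balanced accuracy ≳ 0.92 for
mixtures at 2–5% tumor content, and its median score rises monotonically
along an 11-point dilution ladder. Ladder points are summarized as the
median over 11 independent dilution experiments per proportion, and
monotonicity is measured with the Kendall gamma variant (concordant
minus discordant over their sum): above its detection limit the ensemble
saturates at indistinguishable scores, and tie-penalizing variants would
misread that saturation as non-monotonicity.

## Subtype caller

Cell-line array profiles are converted to pseudo capture counts through
the calibration lookup: per window the maximum probe β (a window may
hold several probes), then `nrpm = bg(d) + β · (full(d) − bg(d))`,
scaled to integer counts at the pooled-reference depth. These columns
are *constructed on* the reference nrpm scale, so they keep that scale
(factor 1) rather than re-estimating TMM against a normal reference —
which would be biased by the tumor methylome. Windows without probes are
masked, not zero-filled, since arrays cover a window subset and zeros
would mimic hypomethylation.

Per target (NEUROD1, ASCL1), DMRs against each other subtype group are
ranked by Δβ and the 50 most hyper- and 50 most hypomethylated
significant windows per contrast are pooled and deduplicated. Two
ensembles train on 5–40% mixtures of cell-line counts into training
NCCs; every member takes 80% of the NEUROD1 and double-negative source
pools and undersamples the (majority) ASCL1 pool to the same combined
count (±1) for class balance.

Cutoffs are derived jointly and sequentially on out-of-bag scores: for
each grid pair (c_N, c_A), NEUROD1 balanced accuracy is evaluated on all
mixtures at c_N and ASCL1 balanced accuracy at c_A only on mixtures the
NEUROD1 classifier left unclassified; the objective is the mean of the
two, ties resolve to the lexicographically smallest pair, and undefined
cells (no eligible positives or negatives) are skipped. Calling is
sequential with a mandatory tumor-fraction gate (default 4%): below the
gate a sample is not evaluable; otherwise NEUROD1 at its cutoff, then
ASCL1, else double negative. The NEUROD1 call never consults the ASCL1
score, and lowering the gate can only convert not-evaluable samples into
calls, never change one.

Expression-based truth assignment mirrors its two use cases: cell lines
threshold each factor at 9 normalized units (co-expression of ASCL1 and
NEUROD1 excluded; POU2F3/YAP1-only samples are double negative), tumor
models arg-max over ASCL1/NEUROD1/POU2F3 with co-expression resolved to
NEUROD1.

## Methylation score and survival

The methylation score is the mean β over the detection windows, with
missing windows excluded from numerator and denominator (zero-filling
would deflate scores of shallow samples toward "healthy"); it correlates
at r ≈ 0.98 with true tumor fraction in simulation. Scores are
dichotomized at the cohort median, ties to the low group, so "high"
means strictly above the median. Survival analysis uses lifelines:
Kaplan–Meier curves with per-group median OS, a two-sided log-rank test
(validated against the textbook statistic on a toy dataset), and Cox
proportional-hazards models — univariable for the score (continuous and
dichotomized) and each clinical covariate, multivariable adjusting for
age, sex (male indicator) and stage (binary limited/extensive), compared
by partial AIC, a BIC using the event count, and the concordance index,
with Schoenfeld-style proportional-hazards diagnostics per covariate.
Sparse-event fits warn rather than fail.

In the survival recovery study (80 patients per replicate, true log-HR
log 3.6 per burden unit z = tf/0.25), the dichotomized-score log-rank
test rejects at α = 0.05 in ≥ 95% of replicates and the Cox CI covers
the true coefficient at the nominal ~95%.

## Problem sizes used in the validation suite

The test suite and the acceptance script run the full-size
quantification stages (20,000 windows, ~50 samples, 2 × 10⁶ fragments
each) and scale the heavily repeated stages the way the analyses
themselves prescribe scaling: DMR null/power studies on 5,000-window
genomes, classifier studies on a 4,000-window cohort with 20-member
ensembles (the ensemble size is a config knob; 100 remains the
production default), and 30–50 survival replicates on 2,000-window
genomes. All stochastic stages derive from a single seed and are
bit-reproducible; cohorts and fitted model bundles serialize
byte-identically across repeated runs.

## Known limitations

- The blind calibration's β₀ anchor is an assumption; methylomes whose
  most-enriched windows per stratum are far from β ≈ 0.8 will calibrate
  with proportional bias.
- The NB dispersion trend is a binned-median moderation, adequate for
  error control here but cruder than full empirical-Bayes machinery.
- Count-level mixing cannot reproduce fragment-size or duplicate
  structure; limit-of-detection statements transfer to read-level data
  only insofar as window counts are sufficient statistics.
- Subtype features assume array coverage of the subtype windows;
  platforms with sparse probe coverage would shrink the usable panels.
- The generator's class methylomes are fixed per cohort (plus cell-line
  jitter), so between-patient epigenetic heterogeneity is understated;
  classifier accuracies on synthetic cohorts are upper bounds.
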