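# Methods

This note documents the models, statistics and numerical choices behind
wormclock, and what the synthetic-data generators do and do not emulate.

## Locomotor model and the behavioral generator

A simulated animal is a draw of `IndividualParams`: a continuum position
`rhythm_strength` s ∈ [0, 1], a preferred phase offset (uniform on ±3 h
around lights-off), a baseline rate b (default 0.05 activity units per
minute), a masking factor m (default 0.5), and a frozen 48-bin *bout
profile* p (Dirichlet over 30-min bins; concentration 1.5 inside the
animal's 8-h night window, 0.15 outside). The mean activity rate is

    λ(t) = b · (1 + s · g · 48 · p[bin(t)]),         g = 8 (bout gain),

multiplied by (1 − m) while lights are on under LD. The profile is drawn
once per individual and reused in repeat runs; that frozen, spiky profile is
the mechanism behind individual-stable behavior ("personality"): each animal
has its own reproducible set of preferred activity windows, not just a
phase. At s = 0 the mean is flat and the animal has no stable pattern — the
continuum couples rhythmicity and individuality, which is the structure the
downstream reproducibility statistics are designed to detect.

Noise is bout-structured gamma–Poisson: one gamma intensity multiplier
(mean 1, variance = `noise_dispersion`, default 1.0) is drawn per 30-min
window, and per-sample counts are Poisson around λ·multiplier. Locomotion
comes in bouts lasting minutes to tens of minutes, so neighboring samples
share the bout state and windows without a bout stay fully quiescent; this
is what makes 30-min binarized activity vectors informative rather than
saturated. Setting `noise_dispersion = 0` returns the exact mean function
(the noiseless limit used by determinism contracts). What the generator does
*not* emulate: within-bout kinematics, arousal responses to handling, lunar
modulation (sampling is assumed fixed at one lunar phase), or maturation
drift — so passing tests demonstrate the statistics work on data with this
correlation structure, not that real traces look like these.

Default recording design: 4 days of 16 h:8 h LD followed by 4 days of DD at
one sample per minute, ZT0 = lights-on; under DD the same reference
continues as circadian time. QC follows the ≥3-days-per-phase rule with
maturation/escape flags excluding an animal everywhere.

## Rhythm power and classification

Periodograms are classical variance-normalized Lomb–Scargle (raw
least-squares spectral power divided by the series variance) on a 20–28 h
period grid (step 0.1 h), computed on mean-subtracted activity pre-binned to
10 min (the pre-periodogram bin width is exposed; the smoothing alignment is
a centered moving average with shrinking edges — phase-neutral). Band maxima
tie-break to the shorter period. Expected band power increases monotonically
with `rhythm_strength` and saturates (multiplicative bout noise grows with
the rhythmic amplitude, capping the signal-to-variance ratio around 50 on
this normalization for the default generator).

Absolute power values are normalization-dependent, so the >150 rhythmic /
<150 arrhythmic convention is transported via a calibration factor:
`calibrate_power_scale` maps the geometric midpoint between labelled classes
(max arrhythmic vs min rhythmic band power, falling back to an
error-minimizing cut when classes overlap) onto the threshold. The decision
boundary, not the absolute scale, is the reproducible object. The
classification rule itself is monotone in power; visual-inspection overrides
may force either call (never "intermediate") and are always logged.

Group comparisons use a fixed diagnostic-driven selection: Shapiro–Wilk per
group and Brown–Forsythe across groups, both at α = 0.05; two groups get a t
test or Mann–Whitney U, three or more get one-way ANOVA + Holm–Šidák,
Welch's ANOVA + a Dunnett-T3-style post hoc, or Kruskal–Wallis + Dunn,
according to the two diagnostic bits. The T3 post hoc uses pairwise Welch t
statistics with Šidák adjustment (approximating the studentized-maximum-
modulus quantile); Dunn's test is pooled-rank z tests with Holm adjustment.

## Reproducibility statistics

Binarization threshold defaults to 0 (any movement in a 30-min bin counts);
the score of two fully inactive runs is defined as 1.0 with a warning. The
overlap activity score is exactly the Jaccard index of active-bin sets. The
KS similarity is the two-sample KS p-value on the 48 pooled bin values of
each run's mean 24-h profile — the p-value is used as a similarity proxy
(higher = more similar), which is legitimate here because every comparison
has identical data structure. The per-individual one-sample signed-rank test
is two-sided with the direction (more/less similar than controls) reported,
since real cohorts contain both outcomes; BH families are all individuals
within one phase, LD and DD corrected separately.

## Cycling detection

The detector is a nonparametric, waveform-agnostic test for 24-h cycling in
independent-samples diel designs (each timepoint an independent pool of
animals, ≥4 timepoints, ≥2 replicates each). The alternative is a *cyclic
umbrella*: expression rises from a trough timepoint to a peak timepoint and
falls back around the period wrap. `peak_border = (0.3, 0.7)` constrains the
waveform asymmetry — the fraction of the period spent rising — while the
peak position is scanned over all timepoints, so every phase is detectable
(a rise-fraction window that instead pinned the trough to ZT0 would make
half the phase range structurally invisible). For the default 6-timepoint
design this yields 18 shapes; for a 4-timepoint design, 4.

Each shape is scored by summing, over consecutive cyclic timepoint pairs,
the one-sided Mann–Whitney count of sample pairs ordered in the hypothesized
direction (ties counted half). The statistic depends only on
within-transcript ranks, so p-values are invariant under any strictly
increasing transformation of a transcript's values — which is also why the
variance-stabilizing transform of the original tooling can be replaced by
median-of-ratios + log2(x+1) without affecting the test (only the variance
analyses see the transform, and those compare phenotypes under identical
treatment).

Shape multiplicity is absorbed into the permutation calibration rather than
Bonferroni-corrected: per arrangement, each shape's statistic is converted
to a mid-p within the pooled permutation distribution, the transcript
statistic is the minimum over shapes, and the reported p is the mid-p of the
observed minimum within its own permutation distribution (the observed
arrangement counts as one member of the null set). With strongly overlapping
shapes a Bonferroni minimum is grossly conservative and visibly
super-uniform under the null; the min-p calibration restores uniformity.
Mid-p (half weight on ties) is used at both stages because the rank
statistic is discrete. Permutations are Monte-Carlo sampled (default 1999,
seeded, shared across transcripts) except for small designs: when n! ≤
45000 the full permutation group is enumerated and the p-values are exact.

Downstream: BH correction per phenotype (families = transcripts within
phenotype), categories from the two significance bits at α = 0.05 on
adjusted values, peak phase = ZT of maximum mean normalized expression (ties
to the earliest ZT), heatmap rows min–max mapped to [−1, 1] jointly over
both phenotypes' timepoint means (constant rows emitted as zeros, flagged)
and sorted by peak phase. The expression filter's ambiguous sentence is
implemented as "keep iff nonzero summed expression at ≥2 timepoints in each
phenotype" with the removal-reading (`rule="remove"`) behind a flag. Both
the 5-point (ZT0,4,8,16,20) and even 6-point diel layouts are supported; the
count generator defaults to 6 because the variance analysis is defined on 6
timepoints.

The variance comparison (scenario A vs B) computes, per transcript and
phenotype, the SD across replicates at each timepoint and then the mean of
those SDs, compared across a transcript set by a paired two-sided t test.
In the count generator, `desync_A` transcripts draw an independent phase per
replicate sample in the arrhythmic phenotype — each replicate is a different
pool of individuals with its own phase — which flattens the population mean
while inflating exactly this statistic.

## GO enrichment

The ontology is an is_a-only DAG (obsolete terms dropped; cycles and
dangling parents are hard errors). Annotations are propagated to ancestors
on load (propagation is idempotent and monotone). Terms are tested by
one-sided Fisher's exact test (hypergeometric upper tail) in
most-specific-first order; a term reaching the elimination cutoff (default
0.01, the conventional choice for this algorithm) has its annotated universe
genes removed from all ancestors before they are tested, preventing general
terms from inheriting a specific descendant's signal. Namespace defaults to
biological_process; the reporting filter is p ≤ 0.05 and ≥3 study
transcripts. An optional `evalue` column in the annotation TSV is thresholded
at 1e-3 (pooling of annotation sources is the producer's concern).

## Dose–response

The 4PL model y = floor + (ceil − floor) / (1 + 10^(hill·(log10 EC50 −
log10 c))) is fitted by least squares on log10 concentration with
multi-start over a 7-point log-spaced EC50 grid × two slope starts, which
avoids plateau-dominated local minima. A fit is non-identifiable when the
±2 SE interval of log10 EC50 extends more than one decade beyond the tested
range or the fitted dynamic range is under 4 residual SDs (flat controls).
Replicate-level fitting is the default; per-concentration means are an
option.

## Problem sizes and acceptance quantities

`scripts/acceptance.py` uses: 1500 null + 300 planted transcripts (6
timepoints × 3 replicates, amplitude 0.8, base mean 500, NB dispersion 0.05,
1999 permutations) for detector calibration; a 16-animal calibration cohort
and a 50-animal two-extreme cohort for label recovery; one 30-animal cohort
with repeats per phase for the overlap statistics plus 60 Monte-Carlo
cohorts for the shuffled-identity null; 25 desync transcripts for the
variance signature; and a 10-decade, 12-replicate synthetic titration for
EC50 recovery. The test suite uses comparable sizes (2000 + 400 transcripts
for calibration; 200 Monte-Carlo cohorts for the behavioral null). The
partition arithmetic runs on the study's printed per-category counts, which
are inputs, not outputs.

## Known limitations

* The cycling detector is anchored to an exhaustive-permutation oracle and
  calibration properties, not to numerical equivalence with the original
  R implementation; p-values on identical data will differ in detail.
* MC-mode p-values inherit extra jitter from cross-shape tie-breaking in
  the min-p calibration; exact mode removes this for small designs.
* Lomb–Scargle power is normalization-dependent; cross-software threshold
  transfer always requires the calibration step.
* The KS similarity uses the 48 binned values (not cumulative profiles);
  alternatives would change individual p-values but not the test logic.
* The behavioral generator produces stationary within-phase statistics; it
  cannot emulate transients at the LD→DD transition.
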