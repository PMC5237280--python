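# Methods

This note records the modelling and numerical choices behind `strokemrs`,
what the synthetic cohorts do and do not emulate, and the known limits of
the analysis.

## Data model

A spectrum is a vector of 1383 real-part intensities on a chemical-shift
axis stored in display order (index 0 = 4.5 ppm, descending to 0 ppm;
spacing 4.5/1382 ≈ 0.00326 ppm). Cohorts carry per-spectrum metadata
(animal, region, phase, hemisphere, class label, train/test split) and a
contralateral map pairing every spectrum with its same-animal
non-infarcted reference. On disk everything is delimited text; the reader
sniffs tab vs comma and tolerates missing ppm headers (synthesizing the
default axis).

## Preprocessing

**Chemical-shift referencing.** The total-creatine maximum is located in a
±0.15 ppm window around 3.03 ppm and the intensity vector is rolled by a
whole number of datapoints (edges repeated, never interpolated) so the
maximum sits on the datapoint nearest 3.03 ppm. A flat window or an
edge-touching maximum leaves the spectrum unshifted with a warning —
preferable to a blind shift toward a neighbouring resonance.

**UL₂CA normalization.** Each datapoint is divided by the Euclidean norm
of the (already referenced) contralateral spectrum over the full stored
0–4.5 ppm vector and multiplied by 100. Consequences used throughout:
a self-normalized spectrum has norm exactly 100, and the operation is
invariant under any joint rescaling of spectrum and reference — raw
scanner units cancel. Reference pairing: lesion spectra normalize to the
same animal's contralateral non-infarcted spectrum; a spectrum that *is*
the designated reference normalizes to itself (whether healthy hemispheres
were self- or cross-normalized in practice is not knowable from summary
data; both are supported, self is the default for reference spectra).

## Feature selection

Greedy forward search over all 1383 datapoints under the CFS merit
`k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`. The search is incremental (the
feature–feature term is maintained as running sums, so one step costs one
correlation sweep), deterministic, and breaks merit ties toward the lower
datapoint index (higher ppm). A floating variant (conditional exclusion
with the standard best-subset-per-size guard that keeps the search finite)
is available but off by default.

Three feature–class correlation encodings:

- **rank (default).** Point-biserial correlation on rank-transformed
  heights, averaged over the three one-vs-rest indicators; feature–feature
  redundancy is the absolute Spearman correlation.
- **pearson.** The same construction on raw heights.
- **su.** Symmetric uncertainty on Fayyad–Irani MDL-discretized features
  with the class as a nominal variable — Hall's original formulation.

The rank default is deliberate. The normalized peak heights are strongly
non-normal (the univariate checks in this pipeline show it, and the
subacute lipid/lactate heights are heavy-tailed by an order of magnitude).
Under such skew the raw linear correlation systematically understates the
class association of exactly the most diagnostic datapoints: with the
published per-class effect sizes the asymptotic Pearson class correlation
of the 1.33 ppm datapoint falls below creatine's, so a Pearson-CFS ranks
creatine first regardless of sample, while rank and SU encodings rank the
lactate/lipid datapoint first. Robustness to monotone distortion is also
Hall's own motivation for discretizing before computing CFS correlations.

The model-size guideline `floor(min class size / 3)` (clamped to ≥2) is
reported and a warning is raised when the sweep exceeds it, but the sweep
itself is allowed to go to 20 features.

## Classification

Multi-class Fisher LDA: between-class scatter `S_b = Σ n_c (m_c−m)(m_c−m)ᵀ`
vs pooled within-class scatter, solved as a symmetric generalized
eigenproblem; the top two eigenvectors (classes − 1) span the latent
plane, with a deterministic sign convention (largest-magnitude loading
positive) so refits are bit-identical. When `cond(S_w) > 1e10` a ridge of
`1e-6·trace(S_w)/p` is added to the diagonal and recorded on the model —
this arises whenever features approach the per-class case count.
Classification is nearest centroid in the latent plane under Euclidean
distance (equal priors); a Mahalanobis rule using the pooled latent
covariance is available behind a flag. Exact distance ties go to the first
class in declared order.

## Evaluation

- **BER** is the unweighted mean over the three classes of the per-class
  misclassification proportion, ×100; it treats a 5-case class like a
  50-case class. Undefined when a class has no cases.
- **CCC** is pooled accuracy ×100. The bootstrap draws cases with
  replacement (replicates missing a class, or with a degenerate class of
  fewer than two cases, are redrawn and logged), refits the LDA on the
  fixed feature set, and scores on the full original training set; an
  out-of-bag option exists. Mean and SD (ddof = 1) over 1000 replicates by
  default, driven by a single integer seed through `SeedSequence`, so runs
  are reproducible bit-for-bit.
- **Feature sweep.** One forward selection to k_max = 20; for each k the
  first k features are refit, bootstrap CCC and test BER recorded. The
  selected k is the smallest k whose test BER is no larger than both
  neighbours (first local minimum) — larger models with marginally lower
  BER are treated as overtraining risk; a global-minimum rule is optional.
  Whether the historical software refit per k exactly this way is not
  documented; refitting on the training set only is the defensible
  default.
- **One-vs-rest diagnostics.** tp/fn/fp/tn from the collapsed confusion;
  a metric with a zero denominator is reported as NaN, never 0. The ROC
  score for AUC is the package's own construction — distance to the
  nearest other centroid minus distance to the target centroid — since a
  latent nearest-centroid rule has no canonical posterior; AUC uses the
  rank (Mann–Whitney, tie-corrected) estimator and the Hanley–McNeil SE.
- **Chronological split.** Whole animals, sorted by numeric ID (earlier
  enrolment = lower ID), enter the training set until it holds ≥ 2/3 of
  spectra; everything later is test. No animal straddles the split.

## Univariate statistics

Kruskal–Wallis (tie-corrected, χ² p, df = 2) across classes;
Dunn's rank-based pairwise z tests with Bonferroni ×3 for post hoc;
Lilliefors-corrected KS and Levene for distribution checks. Median/IQR
summaries default to type-7 (linear interpolation) percentiles with the
type-6 (Weibull) rule selectable, because IQR reproduction across software
packages hinges on this convention.

## Synthetic cohorts

The generator works on the normalized (UL₂CA) scale and makes raw spectra
by an arbitrary per-animal gain that normalization cancels.

- **Resonances.** Canonical rat-brain peaks (ML 0.85, Lac+ML 1.33, NAA
  2.02, Glx 2.35, TCr 3.03, Cho 3.21, Tau/Glc 3.42, Myo 3.62, TCr 3.93)
  as Lorentzian/Gaussian lineshapes. The 1.33 ppm feature is a narrow
  lactate component plus a broader lipid-methylene component (FWHM
  0.035 / 0.065 ppm) sharing one amplitude so the summed height follows
  one lognormal. The TCr linewidth (0.077 ppm FWHM) is derived from the
  published height ratio between the 3.04 and 3.05 ppm datapoints of a
  single line centred at 3.03 ppm (≈1.19), which a narrower line cannot
  produce.
- **Amplitudes** are lognormal — positive and right-skewed, matching the
  non-normality of the real heights — parameterized by the published
  per-class median and quartile *ratio* (`σ = ln(q75/q25)/2z₀.₇₅`); a
  two-parameter law cannot also match both quartile positions of the
  strongly asymmetric subacute IQRs. Non-diagnostic resonances get
  class-invariant amplitudes (quartile ratio 1.35) so only the published
  biomarkers carry class signal. Metabolite amplitudes are drawn
  independently within class; true metabolic covariance is unknown and
  this is a stated limitation.
- **Calibration.** A fixed-point loop solves each diagnostic peak's
  per-class amplitude so the *total* noiseless height at the target
  datapoint (peak + other peaks' tails + background) equals the published
  median (least squares when one peak serves two target datapoints, as
  creatine does at 3.04/3.05), and simultaneously scales a residual-water
  shoulder (exponentially rising toward 4.5 ppm, far from every biomarker)
  so the noiseless control spectrum has Euclidean norm exactly 100 — the
  value contralateral self-normalization enforces, and the condition under
  which post-normalization heights land on the published scale. Monte
  Carlo at n = 300–500 per class puts empirical medians within ~5% of the
  targets (the test tolerance is 15%).
- **Nuisance terms.** A smooth macromolecule hump with per-spectrum
  lognormal amplitude (σ = 0.15); a per-spectrum lognormal water-shoulder
  amplitude (σ = 0.15); a smooth random 3-cosine baseline wiggle
  (0.25 UL₂CA units); Gaussian noise (SD 0.3 UL₂CA units ≈ SNR 30 on NAA)
  convolved with the 4 Hz line-broadening kernel so neighbouring
  datapoints share noise, as apodized spectra do; and a global
  chemical-shift jitter (SD 0.004 ppm) that the referencing step undoes.
- **Cohorts.** Study-sized by default (48/20/14 and 48/82/34 spectra).
  Each first-class animal contributes one non-infarcted spectrum that
  doubles as the contralateral reference; lesion spectra are spread evenly
  over the animal-ID range so every class straddles the chronological
  split in similar proportion. All randomness flows from one
  `numpy.random.Generator` (PCG64) seeded via `SeedSequence`, so cohorts
  are reproducible across platforms.

**What the simulator does not emulate:** J-coupling evolution and
multiplet structure, water-suppression artifacts, field-inhomogeneity
lineshape distortion, within-class metabolite covariance, longitudinal
repeated measures of one animal, and any spatial structure. Passing tests
therefore demonstrate the *pipeline's* correctness and its behaviour under
the published effect sizes — not performance on real spectra.

## Problem sizes and runtime

Default analyses run at the study's own scale (82 and 164 spectra, 1383
datapoints, sweep 2–20, bootstrap ×1000), a few seconds per scenario on
one CPU; the recovery experiment uses 20 cohorts with the bootstrap
skipped (the selected model size depends only on test BER). Monte-Carlo
calibration checks use 300 spectra per class.

## Known limitations

- The greedy third selection is the least stable part of the pipeline: the
  third biomarker's class signal is partially redundant (in class
  information) with the first two, and the CFS penalty treats that as
  feature redundancy, so across seeded cohorts the {1.33, 3.05} pair is
  recovered far more reliably than the full {1.33, 3.05, 0.85} triple.
  This held under all three correlation encodings.
- The SVZ scenario is intrinsically harder: its pattern differs from
  non-infarcted parenchyma only subtly (myoinositol up ~25%), and the
  synthetic cohorts show correspondingly higher test BER for the
  brain-regions classifier than for infarct evolution.
- ROC AUCs depend on the package's own centroid-distance score; other
  reasonable scores would shift AUC values (not the confusion-derived
  metrics).
- Dichotomized metrics and post-hoc p-values reproduce published-style
  tables only up to the percentile and post-hoc conventions of the
  software that produced them; both conventions are configurable here.
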