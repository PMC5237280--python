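# strokemrs

Pattern-recognition analysis of in vivo single-voxel ¹H-MRS spectra from
experimental (rat MCAO) stroke: the pipeline separates non-infarcted
parenchyma from acute and subacute infarct, and non-infarcted tissue from
the subventricular zone (SVZ) and infarcted parenchyma, using a handful of
individual spectral datapoints as biomarkers.

It is written for MRS / preclinical-imaging groups who want a transparent,
scriptable implementation of the classical MRS pattern-recognition
workflow — normalization, datapoint-level feature selection, Fisher LDA,
balanced-error-rate model selection — plus a calibrated synthetic cohort
generator so the whole analysis can be exercised, tested and benchmarked
without animal data.

## The method

Spectra are real-part intensity vectors on a 0–4.5 ppm axis digitized with
1383 datapoints, referenced to the total-creatine (TCr) maximum at
3.03 ppm. Each spectrum *h* is normalized to unit length against the same
animal's contralateral (non-infarcted) spectrum *h*<sub>CA</sub>
(**UL₂CA**):

$$h_i^{\mathrm{UL_2CA}} = \frac{h_i}{\sqrt{\sum_{0}^{4.5\,\mathrm{ppm}} (h^{CA})^2}} \cdot 100$$

so a spectrum normalized against itself has Euclidean norm exactly 100.

**Feature selection** is sequential forward search over the 1383 datapoints
under the CFS (correlation-based feature subset) merit

$$M_S = \frac{k\,\bar r_{cf}}{\sqrt{k + k(k-1)\,\bar r_{ff}}}$$

with $\bar r_{cf}$ the mean feature–class correlation of the subset and
$\bar r_{ff}$ the mean absolute pairwise feature–feature correlation.
Feature–class correlation defaults to the rank-transformed point-biserial
correlation averaged over the three one-vs-rest class indicators (plain
Pearson and Hall-style symmetric uncertainty on MDL-discretized data are
selectable); see `docs/methods.md` for why.

**Classification** is 3-class Fisher LDA: the generalized eigenproblem
$S_b v = \lambda S_w v$ on the selected columns, keeping the top
$C-1 = 2$ eigenvectors; new spectra are assigned the class of the nearest
centroid in the 2-D latent plane.

**Evaluation**: the number of features k is swept from 2 to 20; for each k
the training-set CCC (correctly classified cases, %) is estimated by
refitting on 1000 bootstrap resamples, and the balanced error rate

$$BER = \frac{1}{3}\sum_{c=1}^{3}\frac{\text{misclassified}_c}{\text{total}_c}\cdot 100$$

is scored on a held-out test set formed by a chronological whole-animal
2/3–1/3 split. The selected model size is the first local minimum of the
test-BER curve. Per-class diagnostics (sensitivity, specificity, PPV, NPV,
rank-based ROC AUC with Hanley–McNeil SE) and nonparametric univariate
statistics (Kruskal–Wallis, Dunn–Bonferroni post hoc, median/IQR) complete
the report.

The synthetic generator draws Lorentzian/Gaussian metabolite resonances
with lognormal amplitudes calibrated so the class-conditional heights at
the diagnostic datapoints (0.85, 1.33, 3.04/3.05, 3.62 ppm) match the
published per-class medians and IQRs, on top of a macromolecule background,
a residual-water shoulder, line-broadened noise and chemical-shift jitter.

## Worked example

The numbered scripts under `analysis/` run the whole study desk-side:

```bash
python analysis/01_simulate_cohorts.py            # write both cohorts
python analysis/02_infarct_evolution_classifier.py --n-boot 200
```

prints (seed 42):

```
selected model size: 2 features
selected datapoints (ppm): [1.335, 3.038]
training CCC (bootstrap): 90.2 +/- 2.2%
training BER: 19.0%   test BER: 4.2%
```

i.e. on this cohort the sweep stops at two datapoints — the lactate /
mobile-lipid methylene resonance (1.33 ppm, raised in infarct) and total
creatine (3.03–3.05 ppm, lowered in infarct) — which classify the held-out
animals with a 4.2% balanced error rate; the bootstrap puts the training
accuracy at 90 ± 2%. `analysis/03_brain_regions_classifier.py` runs the
harder SVZ scenario, `analysis/04_published_table_arithmetic.py`
recomputes the diagnostic percentages implied by the published confusion
counts, and `analysis/05_biomarker_recovery.py` measures how often the
three infarct-evolution biomarkers are recovered across 20 seeded cohorts.

The same workflow is available as a CLI (`strokemrs simulate`,
`strokemrs run --scenario brain_regions --seed 7 --out results/br`).

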