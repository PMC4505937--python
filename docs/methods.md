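# Methods

This note documents the models, conventions and numerical choices behind
`tmakb`, in the spirit of a methods appendix: what is simulated, how each
pipeline stage works, which parameters matter, and what the validation
battery does and does not establish.

## Scientific setting

The pipeline quantifies nuclear localization of two NF-κB transcription-factor
subunits — p65/RelA (classical pathway) and RelB (alternative pathway) — in
prostate tissue-microarray (TMA) cores stained by multiplex
immunofluorescence. Four channels are used: DAPI (nuclei), a CK18/CK19/PSA
cocktail (epithelium), RelB (A488) and p65 (Cy5). The core readout is the
*nuclear frequency*: the percentage of epithelial nuclei in a core whose mean
channel intensity exceeds a positivity threshold, including the
double-positive (co-localization) frequency. Patient-level frequencies feed
survival analysis against biochemical recurrence (BCR), defined as a
post-prostatectomy PSA rise strictly above 0.3 ng/ml.

## Synthetic data

No patient images or tables ship with the package; a simulator provides both,
with exact ground truth.

**Core images.** Glands are annular epithelial rings (lumen inside) placed
without overlap in stroma; epithelial nuclei are non-overlapping discs inside
the rings, stromal nuclei are scattered outside at `stromal_nucleus_density`
per 1000 px². Positivity is assigned *jointly*: with `n` epithelial nuclei,
`round(f_double·n)` nuclei are double-positive and the single-positive
remainders are disjoint random sets, so the double-positive fraction is an
independent dial rather than a product of independence — co-localization is
the readout of interest, so it must be controllable. Positive nuclei are
painted at `intensity_pos` (default 0.7) in the corresponding channel;
negative nuclei carry no specific stain (`intensity_neg` defaults to 0,
i.e. background only). All channels receive a smooth autofluorescence field
(blurred white noise scaled to `background_amplitude`, default 0.05) plus
i.i.d. Gaussian pixel noise (`noise_sd`, default 0.02), clipped to [0, 1].
Intensities are arbitrary units in [0, 1] held as float; file export scales
to 16-bit OME-TIFF. True frequencies are exact counts
(100 × flagged / total), so recovery experiments are free of binomial
sampling noise in the reference value.

A negative control renders identical tissue geometry with *no* specific
signal in the p65/RelB channels (background + noise only), emulating a slide
incubated without primary antibodies.

What the image model deliberately omits: tissue texture, spectral
bleed-through, focus/illumination gradients, benign-vs-malignant gland
distinction, necrosis and inflammation. Passing recovery tests therefore
demonstrates correctness of the measurement chain under clean gland-structured
geometry, not robustness to every real-world artifact.

**Cohorts.** Defaults emulate a radical-prostatectomy cohort of 189 patients
with duplicate tumor and duplicate normal-adjacent cores. Patient-true
frequencies are truncated normals on the percent scale: tumor p65 25 ± 15,
normal p65 15 ± 10, tumor RelB 8 ± 6, normal RelB 12 ± 8 — qualitatively,
nuclear p65 enriched in tumor and RelB in normal tissue. Duplicate cores are
the patient-true value plus Gaussian noise with SD 9.8, chosen once so the
theoretical duplicate-core intraclass correlation is
15²/(15² + 9.8²) ≈ 0.70, matching the reproducibility regime the pipeline is
meant to operate in (truncation at 0 lowers the realized value slightly).
BCR times are exponential with baseline hazard 0.002/month, multiplied by
`exp(log_hr_p65)` (default log 2) when the true tumor p65 frequency exceeds
20%; administrative censoring at 120 months yields roughly a 28% event rate.
Clinicopathological covariates (Gleason 6–9 at 7/44/35/14%, stage 3 at 25%,
positive margins 32%, extraprostatic extension 26%, seminal-vesicle
involvement 9.5%, lymph-node invasion 3%, log-normal pre-operative PSA) are
drawn independently of outcome: the simulated hazard acts only through p65
status, which keeps the ground truth of every survival analysis unambiguous.

## Segmentation

**Epithelial mask (ROI #1).** Gaussian smoothing (σ = 2 px) → Otsu threshold
→ morphological closing (disk radius 2) → filling of holes up to 64 px
(deliberately small, so gland lumens — genuine non-epithelial space — stay
open) → removal of components under 200 px. A contrast-free channel yields an
empty mask. The commercial software used in the original workflow is
unpublished and unavailable; this chain is the simplest reproducible
surrogate, and every parameter lives in `MaskConfig`.

**Nuclei (ROI #2).** DAPI is smoothed (σ = 1 px) and Otsu-thresholded *using
only intensities inside the mask*, then touching nuclei are split by a
watershed on the negated distance transform seeded at distance maxima
(minimum peak separation 4 px). Components outside [10, 500] px are
discarded and labels renumbered from 1. Boundary pixels belong to the label
the deterministic flooding order assigns. Mean DAPI/RelB/p65 intensity per
nucleus is measured over the label's pixels. An empty mask returns an empty
nucleus set rather than an error.

**QC.** An automated surrogate for manual core review: cores with fewer than
20 nuclei (inclusive bound — exactly 20 passes) or epithelial area below 2%
of the core are flagged excluded with reason codes. Manual exclusion of
necrotic/inflamed regions is out of scope because it is not reproducible.

## Scoring

A nucleus is positive for a channel when its mean intensity **strictly
exceeds** threshold = mean + sample SD (ddof 1) of a reference population.
The reference scope is configurable:

- `per_core` (default): the core's own nuclei. Self-normalizing across
  staining batches, but biased upward when a large fraction of nuclei is
  genuinely positive (the positives inflate both mean and SD; beyond roughly
  a 45% positive fraction at default intensities the threshold can exceed the
  positive level entirely).
- `negative_control`: nuclei of a matched control core. Estimates pure
  background — but mean + SD of any roughly symmetric background population
  sits near its 84th percentile, so this scope carries an irreducible
  background false-positive rate of ~15%. This is precisely why core-level
  positivity requires a margin over background (below).
- `reference`: an externally calibrated cutoff. For synthetic data,
  `reference_thresholds()` returns the midpoint between the maximal
  background level and `intensity_pos`, which separates the two populations
  exactly; recovery experiments against exact ground truth use this scope so
  that they measure the pipeline's error rather than the threshold rule's
  intrinsic bias.

Core frequencies are 100 × positives / n (NaN and flagged undefined at
n = 0); double-positive = above both thresholds, so
`freq_double ≤ min(freq_p65, freq_relb)` holds by construction. Duplicate
cores of a patient/tissue are combined by arithmetic mean over non-excluded
cores. Core-level positivity ("the core is positive for nuclear NF-κB") is
`freq ≥ background_freq + 5` percentage points, inclusive, with the scored
negative-control frequency (or 0) as background.

**ICC.** Duplicate agreement is the one-way random-effects single-measure
ICC(1,1): with n patients and k = 2 interchangeable cores,
ICC = (MSB − MSW)/(MSB + (k−1)·MSW). The variant is one-way because
duplicate cores have no rater identity. All-constant input is an error
(undefined ratio), as are fewer than 3 pairs.

## Stratification

High/low status per subunit uses strict `>` against the cutoffs (defaults:
20% for p65, 5% for RelB); a value exactly at the cutoff is *low*, a
convention forced by the inherently open interval pair ">20% / <20%". The
four-group κB status crosses the two booleans (negative / p65 only / RelB
only / both). For double-positive patients the p65:RelB ratio r is
categorized with a two-fold band: r ≥ 2 p65-dominant, r ≤ 0.5 RelB-dominant,
otherwise balanced — the dominant categories are inclusive ("at least
2-fold"), making the balanced band open at both ends.

ROC-derived cutoffs maximize Youden's J = sensitivity + specificity − 1 over
midpoints between consecutive sorted unique frequencies (with guard
candidates outside the data range), calling frequency > cutoff positive; ties
break toward the lower threshold. The outcome variable is the BCR event
indicator, since the cutoff feeds BCR survival curves.

## Survival statistics

- BCR from a PSA series: event at the first measurement strictly above
  0.3 ng/ml, else censoring at the last measurement.
- Tumor vs normal: two-sided Wilcoxon signed-rank on paired patient means,
  dropping incomplete pairs (≥ 5 required). All-zero differences are
  reported as p = 1 (no evidence) rather than an error, which degenerate
  synthetic fixtures need.
- Clinicopathological correlations: Spearman rank, pairwise deletion,
  ≥ 10 complete pairs, constant inputs rejected.
- Kaplan–Meier per stratum plus the k-group log-rank test (lifelines).
  Curves are non-increasing step functions with S(0) = 1; both properties
  are asserted in tests, and the log-rank statistic is validated against an
  explicit risk-set enumeration oracle.
- Cox proportional hazards with Efron tie handling (lifelines); Breslow is
  selectable via statsmodels' PHReg for comparison with software whose
  default is Breslow. Missing values are listwise-deleted; times of 0 are
  shifted to 0.01 months to keep risk sets defined. Multivariate models
  enter all supplied covariates simultaneously and report estimates only
  when events ≥ 10 × covariates (the events-per-variable rule); the gate can
  be forced. The multivariate candidate set is the p65 status plus every
  covariate with univariate p < 0.05.

## Validation battery and problem sizes

The test battery was sized to run comfortably on one CPU:

- *Scoring recovery*: 20 seeds at each true positive fraction
  {5, 20, 50, 80}%, 192-px cores with ~60–80 epithelial nuclei; measured
  frequency within 5 percentage points of exact truth in ≥ 90% per level.
- *Oracle agreement*: ICC vs a hand-built ANOVA decomposition (5 pairs,
  10⁻⁶), log-rank vs risk-set enumeration (6 subjects, 10⁻⁶), Cox vs
  grid + golden-section maximization of the Efron partial likelihood
  (28 subjects with ties, 10⁻³ on the log HR).
- *Calibration*: Wilcoxon empirical size in [0.04, 0.06] over 2000 null
  replicates of 100 pairs; Cox 95% CI coverage in [0.93, 0.97] over 500
  replicates with true HR = 1 (n = 150). Both bands are ±2 binomial SEs
  around nominal, so a correct implementation passes ~95% of the time per
  band; the replicate streams are fixed by seed.
- *End-to-end recovery*: 20 master seeds; each simulates 40 patients with a
  true p65 hazard ratio of 2 acting through true p65 status, renders and
  scores 80 tumor-core images, stratifies at the 20% cutoff and fits the
  Cox model on *measured* status. The CI must cover 2 in ≥ 85% of seeds —
  the margin absorbs both sampling noise (~20–25 events per seed) and the
  attenuation from status misclassification near the cutoff (duplicate noise
  SD 9.8 against a cutoff at 20 on a 25 ± 15 distribution misclassifies
  roughly 10–15% of patients, biasing the log HR toward 0 by roughly a
  third).
- The patient-table path (`tmakb.supplement`) is validated on a synthetic
  stand-in table generated by the cohort simulator, since no real deposited
  table can be redistributed.

## Known limitations

- The threshold rule (mean + SD) is the workflow's convention, not an
  optimal classifier; its per-core variant saturates at high positive
  fractions and its control variant has a fixed false-positive floor (both
  documented above and in `tmakb.scoring`).
- Segmentation is classical (Otsu + watershed); heavily overlapping nuclei
  or low-SNR DAPI will under-segment. The simulator's non-overlapping discs
  do not exercise that regime.
- The cohort simulator draws covariates independent of outcome; it cannot be
  used to study confounding between clinicopathological variables and NF-κB
  status.
- Proportional-hazards diagnostics, competing risks and time-dependent
  covariates are out of scope.
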