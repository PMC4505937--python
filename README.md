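# tmakb

Quantitative multiplex-immunofluorescence scoring of nuclear NF-κB in
tissue-microarray (TMA) cores, with survival-biomarker statistics and a
fully synthetic data source.

## The problem

Activation of the classical (p65/RelA) and alternative (RelB) NF-κB pathways
is read out by nuclear translocation of the respective subunit. In prostate
cancer TMAs stained with four fluorescent channels — DAPI (nuclei), a
CK18/CK19/PSA cocktail (epithelium), RelB (A488) and p65 (Cy5) — the
quantity of interest for each core is the **nuclear frequency**

> % of epithelial nuclei whose mean channel intensity exceeds a positivity
> threshold (mean + SD of a reference intensity population),

including the **double-positive frequency**, the co-localization readout for
cross-talk between the two pathways. Patient-level frequencies (averaged
over duplicate cores) are then stratified — high/low per subunit, four-group
κB status, two-fold p65:RelB ratio bands — and tested against biochemical
recurrence (BCR: post-prostatectomy PSA > 0.3 ng/ml) with Kaplan–Meier /
log-rank and Cox proportional-hazards models gated by the
10-events-per-variable rule.

`tmakb` implements this chain end to end for anyone who wants to score
multiplexed TMA IF data reproducibly, or to study the statistical behaviour
of frequency-based nuclear biomarkers on simulated cohorts:

| stage | module |
|---|---|
| synthetic cores + cohorts with exact ground truth | `tmakb.simulate` |
| epithelial mask (ROI #1), nuclei (ROI #2) | `tmakb.segment` |
| thresholds, frequencies, duplicate ICC | `tmakb.scoring` |
| cutoffs (ROC/Youden), κB status, ratio bands | `tmakb.stratify` |
| Wilcoxon, Spearman, KM/log-rank, Cox | `tmakb.survival` |
| orchestration and CLI | `tmakb.pipeline`, `tmakb.cli` |
| external patient-table analysis | `tmakb.supplement` |

No patient data are included or required: the simulator generates
gland-structured cores (annular epithelium, non-overlapping nuclear discs,
autofluorescence background, pixel noise) with controllable true positive
fractions — including the joint double-positive fraction — and cohorts with
duplicate cores, clinicopathological covariates and an exponential BCR model
whose hazard depends on true p65 status.

## Worked example

```python
import numpy as np
from tmakb import SimImageParams, generate_core_image
from tmakb.simulate import reference_thresholds
from tmakb.pipeline import score_core_image

params = SimImageParams(f_p65=0.25, f_relb=0.10, f_double=0.05, seed=7)
core, truth = generate_core_image(params)
score = score_core_image(core, thresholds=reference_thresholds(params))
print(f"true  p65 {truth.freq_p65:.2f}%  relb {truth.freq_relb:.2f}%  "
      f"double {truth.freq_double:.2f}%  (n={truth.n_nuclei})")
print(f"meas. p65 {score.freq_p65:.2f}%  relb {score.freq_relb:.2f}%  "
      f"double {score.freq_double:.2f}%  (n={score.n_nuclei})")
```

```
true  p65 24.71%  relb 9.41%  double 4.71%  (n=85)
meas. p65 24.71%  relb 9.41%  double 4.71%  (n=85)
```

The generator placed 85 epithelial nuclei and flagged 21 of them
p65-positive (24.71%); the pipeline re-detected all 85 nuclei from the
rendered image and reproduced all three frequencies exactly. At the default
noise level errors of a nucleus or two appear on some seeds; the validation
suite requires agreement within 5 percentage points in ≥ 90% of seeds at
true fractions from 5% to 80%.

A full simulated study from the shell:

```bash
mkdir out
tmakb run-all --outdir out --seed 1 --n-patients 8
```

writes OME-TIFF cores, per-core/per-patient score CSVs, stratified tables,
Table-style correlation and Cox CSVs, Kaplan–Meier coordinates and plot, a
run report with every default echoed, and content-digest manifests
(`tmakb simulate/score/stratify/analyze` run the stages individually).

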