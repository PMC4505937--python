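"""End-to-end orchestration: images → scores → stratification → statistics.

Thin glue over the library modules, shared by the command-line interface, the
test-suite and the reproduction script.  All randomness flows from explicit
seeds; child seeds are drawn from ``numpy.random.SeedSequence`` spawns so the
same master seed always yields the same cohort, images and results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from tmakb.images import CoreImage
from tmakb.scoring import (
    CoreScore,
    ThresholdSpec,
    aggregate_patient,
    compute_threshold,
    score_core,
)
from tmakb.segment import (
    MaskConfig,
    QCConfig,
    SegConfig,
    build_epithelial_mask,
    qc_core,
    segment_nuclei,
)
from tmakb.simulate import (
    SimCohortParams,
    SimImageParams,
    generate_core_image,
    generate_cohort,
    generate_negative_control,
    reference_thresholds,
)
from tmakb.stratify import CutoffConfig, stratify_patients
from tmakb.survival import cox_fit, km_logrank, paired_tumor_normal_test

__all__ = [
    "segment_core",
    "control_thresholds",
    "score_core_image",
    "score_simulated_cohort",
    "analyze_cohort",
]


def segment_core(
    core: CoreImage,
    mask_cfg: MaskConfig | None = None,
    seg_cfg: SegConfig | None = None,
):
    """Mask + nuclear segmentation for one core; returns (mask, nuclei)."""
    mask = build_epithelial_mask(core, mask_cfg)
    nuclei = segment_nuclei(core, mask, seg_cfg)
    return mask, nuclei


def control_thresholds(
    control: CoreImage,
    mask_cfg: MaskConfig | None = None,
    seg_cfg: SegConfig | None = None,
) -> tuple[ThresholdSpec, ThresholdSpec]:
    """Negative-control thresholds: mean + SD of control nuclear intensities."""
    _, nuclei = segment_core(control, mask_cfg, seg_cfg)
    if nuclei.n_nuclei == 0:
        raise ValueError("negative control yielded no nuclei; cannot set thresholds")
    thr_p65 = compute_threshold(
        nuclei.mean_intensities("p65"), "p65", scope="negative_control"
    )
    thr_relb = compute_threshold(
        nuclei.mean_intensities("relb"), "relb", scope="negative_control"
    )
    return thr_p65, thr_relb


def score_core_image(
    core: CoreImage,
    mask_cfg: MaskConfig | None = None,
    seg_cfg: SegConfig | None = None,
    qc_cfg: QCConfig | None = None,
    thresholds: tuple[ThresholdSpec, ThresholdSpec] | None = None,
) -> CoreScore:
    """Full single-core scoring.

    When ``thresholds`` is None the per-core scope is used (mean + SD of the
    core's own nuclear intensities per channel); otherwise the supplied
    (p65, RelB) thresholds — typically from a negative control — apply.
    """
    mask, nuclei = segment_core(core, mask_cfg, seg_cfg)
    report = qc_core(nuclei, qc_cfg, mask=mask)
    if thresholds is None:
        if nuclei.n_nuclei == 0:
            thr_p65 = ThresholdSpec("p65", 0.0, 0.0)
            thr_relb = ThresholdSpec("relb", 0.0, 0.0)
        else:
            thr_p65 = compute_threshold(nuclei.mean_intensities("p65"), "p65")
            thr_relb = compute_threshold(nuclei.mean_intensities("relb"), "relb")
    else:
        thr_p65, thr_relb = thresholds
    return score_core(
        nuclei,
        thr_p65,
        thr_relb,
        core_id=core.core_id,
        patient_id=core.patient_id,
        tissue_type=core.tissue_type,
        excluded=report.excluded,
    )


def _image_params_for(template: SimImageParams, f_p65, f_relb, f_double, seed):
    f_p65 = float(np.clip(f_p65, 0.0, 1.0))
    f_relb = float(np.clip(f_relb, 0.0, 1.0))
    f_double = float(np.clip(f_double, 0.0, min(f_p65, f_relb)))
    return replace(template, f_p65=f_p65, f_relb=f_relb, f_double=f_double, seed=int(seed))


def score_simulated_cohort(
    cohort_params: SimCohortParams,
    image_params: SimImageParams | None = None,
    tissues: tuple[str, ...] = ("tumor",),
    mask_cfg: MaskConfig | None = None,
    seg_cfg: SegConfig | None = None,
    qc_cfg: QCConfig | None = None,
    threshold_source: str = "reference",
) -> pd.DataFrame:
    """Simulate a cohort *through the imaging arm* and score every core.

    For each patient and requested tissue type, the duplicate per-core true
    frequencies from :func:`generate_cohort` are rendered as synthetic core
    images, segmented and scored, then averaged per patient.  Returns the
    cohort table with added ``freq_{marker}`` (tumor) / ``normal_freq_{marker}``
    measured columns.

    ``threshold_source`` picks the positivity cutoffs:

    - ``"reference"`` (default) — the generator's calibrated midpoint cutoffs
      (:func:`~tmakb.simulate.reference_thresholds`), appropriate when the
      quantity of interest is recovery against exact ground truth;
    - ``"control"`` — mean + SD of a matched negative-control core's nuclear
      intensities, emulating a background-referenced study design (carries a
      background false-positive rate by construction);
    - ``"per_core"`` — each core's own mean + SD.

    This is the full measurement chain — gland geometry, masking, watershed
    segmentation and threshold scoring all contribute realistic error.
    """
    if threshold_source not in ("reference", "control", "per_core"):
        raise ValueError("threshold_source must be 'reference', 'control' or 'per_core'")
    image_params = image_params or SimImageParams()
    cohort = generate_cohort(cohort_params)
    ss = np.random.SeedSequence([cohort_params.seed, 0xC0DE])
    # one child stream per (patient, tissue, duplicate) plus one for the control
    n_children = len(cohort) * len(tissues) * cohort_params.cores_per_tissue + 1
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_children)]
    seed_iter = iter(child_seeds)

    control_seed = next(seed_iter)
    if threshold_source == "reference":
        thresholds = reference_thresholds(image_params)
    elif threshold_source == "control":
        control = generate_negative_control(replace(image_params, seed=control_seed))
        thresholds = control_thresholds(control, mask_cfg, seg_cfg)
    else:
        thresholds = None

    measured: dict[str, list] = {}
    for tissue in tissues:
        prefix = "" if tissue == "tumor" else "normal_"
        for marker in ("p65", "relb", "double"):
            measured[f"{prefix}freq_{marker}"] = []

    for _, row in cohort.iterrows():
        for tissue in tissues:
            prefix = "" if tissue == "tumor" else "normal_"
            scores = []
            for j in range(1, cohort_params.cores_per_tissue + 1):
                params = _image_params_for(
                    image_params,
                    row[f"{tissue}_p65_core{j}"] / 100.0,
                    row[f"{tissue}_relb_core{j}"] / 100.0,
                    row[f"{tissue}_double_core{j}"] / 100.0,
                    next(seed_iter),
                )
                core, _ = generate_core_image(
                    params,
                    core_id=f"{row['patient_id']}_{tissue}_{j}",
                    patient_id=row["patient_id"],
                    tissue_type="tumor" if tissue == "tumor" else "normal_adjacent",
                )
                scores.append(
                    score_core_image(core, mask_cfg, seg_cfg, qc_cfg, thresholds)
                )
            try:
                agg = aggregate_patient(scores)
                measured[f"{prefix}freq_p65"].append(agg.freq_p65)
                measured[f"{prefix}freq_relb"].append(agg.freq_relb)
                measured[f"{prefix}freq_double"].append(agg.freq_double)
            except ValueError:
                for marker in ("p65", "relb", "double"):
                    measured[f"{prefix}freq_{marker}"].append(np.nan)

    for col, vals in measured.items():
        cohort[col] = vals
    return cohort


CLINICAL_COVARIATES = (
    "gleason",
    "stage",
    "surgical_margin",
    "extraprostatic_extension",
    "seminal_vesicle",
    "lymph_node",
    "preop_psa",
)


def analyze_cohort(
    cohort: pd.DataFrame,
    cutoffs: CutoffConfig | None = None,
    covariates: tuple[str, ...] = CLINICAL_COVARIATES,
    alpha: float = 0.05,
) -> dict:
    """Stratify a scored cohort and run the statistical battery.

    Expects measured tumor frequencies in ``freq_p65``/``freq_relb`` (and
    optionally ``normal_freq_*``), plus ``bcr_time_months``/``bcr_event`` and
    clinicopathological covariates.  Returns a dict with the stratified
    table, the tumor-vs-normal comparison, the Spearman correlation table,
    Kaplan–Meier/log-rank results per stratification and Cox tables.
    Multivariate Cox enters the p65 status together with every covariate whose
    univariate p-value is below ``alpha``.
    """
    cutoffs = cutoffs or CutoffConfig()
    out: dict = {}
    strat = stratify_patients(cohort, cutoffs)
    out["stratified"] = strat

    if "normal_freq_p65" in strat.columns:
        pairs = {}
        for marker in ("p65", "relb", "double"):
            t = strat[f"freq_{marker}"]
            m = strat[f"normal_freq_{marker}"]
            try:
                stat, p = paired_tumor_normal_test(t, m)
                pairs[marker] = {"statistic": stat, "p": p}
            except ValueError as err:
                pairs[marker] = {"error": str(err)}
        out["tumor_vs_normal"] = pairs

    from tmakb.survival import correlate_clinical

    corr_rows = []
    for cov in covariates:
        if cov not in strat.columns:
            continue
        row = {"covariate": cov}
        for marker in ("p65", "relb"):
            try:
                rho, p = correlate_clinical(strat[f"freq_{marker}"], strat[cov])
                row[f"rho_{marker}"], row[f"p_{marker}"] = rho, p
            except ValueError:
                row[f"rho_{marker}"], row[f"p_{marker}"] = np.nan, np.nan
        corr_rows.append(row)
    out["correlations"] = pd.DataFrame(corr_rows)

    usable = strat.dropna(subset=["freq_p65", "freq_relb", "bcr_time_months"])
    n_events = int(usable["bcr_event"].sum())
    out["n"] = len(usable)
    out["n_events"] = n_events

    km = {}
    for name, col in (("p65_high", "p65_high"), ("relb_high", "relb_high"),
                      ("kb_status", "kb_status")):
        groups = usable[col].astype(str)
        if groups.nunique() < 2:
            km[name] = {"error": "single group"}
            continue
        curves, chi2, p = km_logrank(
            usable["bcr_time_months"], usable["bcr_event"], groups
        )
        km[name] = {"curves": curves, "chi2": chi2, "p": p}
    out["km"] = km

    if n_events == 0:
        out["cox"] = {"skipped": "no events: Cox models not fitted"}
        return out

    unidf = usable.copy()
    unidf["p65_high"] = unidf["p65_high"].astype(float)
    unidf["relb_high"] = unidf["relb_high"].astype(float)
    missing = [c for c in covariates if c not in unidf]
    if missing:
        raise ValueError(f"unknown covariate columns: {missing}")
    uni_covs = [
        c
        for c in ["p65_high", "relb_high", *covariates]
        if unidf[c].nunique() > 1  # constant covariates cannot be fitted
    ]
    uni = cox_fit(unidf, uni_covs, multivariate=False)

    significant = [
        c
        for c in uni_covs
        if c not in ("p65_high", "relb_high") and uni.p(c) < alpha
    ]
    if "p65_high" in uni_covs:
        multi_covs = ["p65_high"] + significant
        multi = cox_fit(unidf, multi_covs, multivariate=True)
    else:
        multi_covs, multi = [], None
    out["cox"] = {"univariate": uni, "multivariate": multi,
                  "multivariate_covariates": multi_covs}
    return out
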