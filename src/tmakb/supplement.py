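"""Analysis of an externally supplied tissue-microarray patient table.

When a study's deposited patient-level table is available (XLSX or CSV with
per-patient nuclear frequencies and follow-up), this module recomputes the
cohort-level quantities from it: descriptives (n, BCR rate), the conditional
subgroup means (nuclear p65 frequency in RelB-present versus RelB-absent
cores and vice versa), the log-rank statistic for high/low nuclear p65, and
the univariate Cox hazard ratio for p65 status.

No such table ships with this package — it contains patient data and must be
obtained by the user.  The expected column dictionary is :data:`COLUMNS`;
:func:`load_patient_table` renames common alternative spellings.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from tmakb.scoring import core_is_positive
from tmakb.stratify import CutoffConfig, stratify_patients
from tmakb.survival import cox_fit, km_logrank

__all__ = ["COLUMNS", "load_patient_table", "analyze_patient_table"]

#: required columns of a patient-level table
COLUMNS = {
    "patient_id": "patient identifier",
    "freq_p65": "mean % p65-positive epithelial nuclei, tumor cores",
    "freq_relb": "mean % RelB-positive epithelial nuclei, tumor cores",
    "bcr_event": "biochemical recurrence indicator (0/1)",
    "bcr_time_months": "months from surgery to recurrence or censoring",
}

_ALIASES = {
    "p65": "freq_p65",
    "nuclear_p65": "freq_p65",
    "relb": "freq_relb",
    "nuclear_relb": "freq_relb",
    "bcr": "bcr_event",
    "event": "bcr_event",
    "time": "bcr_time_months",
    "bcr_time": "bcr_time_months",
    "followup_months": "bcr_time_months",
}


def load_patient_table(path: str | Path) -> pd.DataFrame:
    """Load a patient-level table from XLSX or CSV and normalise columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"patient table not found at {path}; supply the deposited "
            "per-patient table (not distributed with this package)"
        )
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df = df.rename(columns={c: _ALIASES.get(str(c).strip().lower(), str(c).strip().lower())
                            for c in df.columns})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table lacks required columns: {missing}")
    return df


def analyze_patient_table(
    df: pd.DataFrame, cutoffs: CutoffConfig | None = None
) -> dict:
    """Cohort-level statistics from a patient table.

    Returns a dict with ``n``, ``bcr_rate_pct``, the conditional subgroup
    means of each subunit given presence/absence of the other (presence =
    core-positive, i.e. frequency at least 5 points over background),
    ``logrank_chi2``/``logrank_p`` for high/low p65, and the univariate Cox
    ``hr_p65`` with its CI and p-value.
    """
    cutoffs = cutoffs or CutoffConfig()
    work = df.dropna(subset=["freq_p65", "freq_relb", "bcr_time_months", "bcr_event"])
    strat = stratify_patients(work, cutoffs)

    relb_present = work["freq_relb"].map(lambda f: core_is_positive(float(f)))
    p65_present = work["freq_p65"].map(lambda f: core_is_positive(float(f)))

    result: dict = {
        "n": int(len(work)),
        "bcr_rate_pct": 100.0 * float(work["bcr_event"].mean()),
        "mean_p65_when_relb_present": float(work.loc[relb_present, "freq_p65"].mean()),
        "mean_p65_when_relb_absent": float(work.loc[~relb_present, "freq_p65"].mean()),
        "mean_relb_when_p65_present": float(work.loc[p65_present, "freq_relb"].mean()),
        "mean_relb_when_p65_absent": float(work.loc[~p65_present, "freq_relb"].mean()),
    }

    if strat["p65_high"].astype(float).nunique() > 1:
        _, chi2, p = km_logrank(
            work["bcr_time_months"], work["bcr_event"], strat["p65_high"].astype(int)
        )
        result["logrank_chi2"], result["logrank_p"] = chi2, p
        fit_df = work.copy()
        fit_df["p65_high"] = strat["p65_high"].astype(float)
        cox = cox_fit(fit_df, ["p65_high"])
        result["hr_p65"] = cox.hr("p65_high")
        result["hr_p65_ci"] = cox.ci("p65_high")
        result["hr_p65_p"] = cox.p("p65_high")
    return result
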