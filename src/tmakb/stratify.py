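"""Patient stratification: high/low cutoffs, κB status, p65:RelB ratio.

Patient-level nuclear frequencies are converted into the analysis groups used
for survival comparisons:

- dichotomised high/low status per subunit (default cutoffs 20 % for p65 and
  5 % for RelB, or ROC-derived via Youden's J);
- a four-group κB status (negative / p65 only / RelB only / both);
- for double-positive patients, a p65:RelB ratio category with a two-fold
  band: ratio >= 2 → p65-dominant, <= 0.5 → RelB-dominant, otherwise balanced.

Cutoff boundary convention: a frequency exactly at the cutoff is classified
*low* (strict ``>`` for high).  Ratio boundaries are inclusive for the
dominant categories ("at least 2-fold"), so the balanced band is open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CutoffConfig",
    "StratificationLabel",
    "roc_cutoff",
    "classify_kb_status",
    "ratio_category",
    "stratify_patients",
]

KB_STATUSES = ("kb_negative", "p65_only", "relb_only", "both")
RATIO_CATEGORIES = ("p65_gt_relb", "balanced", "relb_gt_p65", "undefined")


@dataclass
class CutoffConfig:
    """High/low cutoffs on the percent scale."""

    p65_cutoff: float = 20.0
    relb_cutoff: float = 5.0
    source: str = "default_paper"

    def __post_init__(self) -> None:
        for name in ("p65_cutoff", "relb_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.source not in ("default_paper", "roc"):
            raise ValueError("source must be 'default_paper' or 'roc'")


@dataclass(frozen=True)
class StratificationLabel:
    """Per-patient group labels derived from the two nuclear frequencies."""

    kb_status: str
    ratio_value: float  # NaN when undefined
    ratio_category: str


def roc_cutoff(
    freqs: Sequence[float], outcome: Sequence[int]
) -> float:
    """ROC-optimal frequency cutoff maximising Youden's J.

    Candidate thresholds are midpoints between consecutive sorted unique
    frequencies (plus guards below the minimum and above the maximum); a
    subject is test-positive when its frequency strictly exceeds the
    candidate.  J = sensitivity + specificity - 1; ties are broken toward the
    lower threshold.  Requires both outcome classes to be present.
    """
    f = np.asarray(freqs, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("freqs and outcome must be 1-D and equal length")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both outcome classes must be present for a ROC cutoff")
    uniq = np.unique(f)
    if uniq.size == 1:
        return float(uniq[0])
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best_j = -np.inf
    best_cut = candidates[0]
    for cut in candidates:
        called = f > cut
        sens = int((called & (y == 1)).sum()) / n_pos
        spec = int((~called & (y == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:  # strict improvement; ties keep the lower cut
            best_j = j
            best_cut = cut
    return float(best_cut)


def youden_j(freqs: Sequence[float], outcome: Sequence[int], cutoff: float) -> float:
    """Youden's J achieved by calling frequency > cutoff positive."""
    f = np.asarray(freqs, dtype=float)
    y = np.asarray(outcome, dtype=int)
    called = f > cutoff
    sens = int((called & (y == 1)).sum()) / max(int((y == 1).sum()), 1)
    spec = int((~called & (y == 0)).sum()) / max(int((y == 0).sum()), 1)
    return sens + spec - 1.0


def classify_kb_status(
    freq_p65: float, freq_relb: float, cfg: CutoffConfig | None = None
) -> str:
    """Four-group κB status from the two nuclear frequencies.

    A subunit is "high" when its frequency strictly exceeds its cutoff.
    """
    cfg = cfg or CutoffConfig()
    for name, v in (("freq_p65", freq_p65), ("freq_relb", freq_relb)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {v}")
    p65_high = freq_p65 > cfg.p65_cutoff
    relb_high = freq_relb > cfg.relb_cutoff
    if p65_high and relb_high:
        return "both"
    if p65_high:
        return "p65_only"
    if relb_high:
        return "relb_only"
    return "kb_negative"


def ratio_category(freq_p65: float, freq_relb: float) -> str:
    """Two-fold ratio category for double-positive patients.

    r = freq_p65 / freq_relb; r >= 2 → ``p65_gt_relb``, r <= 0.5 →
    ``relb_gt_p65``, otherwise ``balanced``.  Both frequencies must be
    strictly positive (callers route only double-positive patients here).
    """
    if freq_p65 <= 0 or freq_relb <= 0:
        raise ValueError("ratio requires strictly positive frequencies")
    r = freq_p65 / freq_relb
    if r >= 2.0:
        return "p65_gt_relb"
    if r <= 0.5:
        return "relb_gt_p65"
    return "balanced"


def label_patient(
    freq_p65: float, freq_relb: float, cfg: CutoffConfig | None = None
) -> StratificationLabel:
    """Full stratification label for one patient."""
    cfg = cfg or CutoffConfig()
    status = classify_kb_status(freq_p65, freq_relb, cfg)
    if status == "both":
        ratio = freq_p65 / freq_relb if freq_relb > 0 else float("nan")
        category = ratio_category(freq_p65, freq_relb)
    else:
        ratio = float("nan")
        category = "undefined"
    return StratificationLabel(kb_status=status, ratio_value=ratio, ratio_category=category)


def stratify_patients(
    scores: pd.DataFrame,
    cfg: CutoffConfig | None = None,
    p65_col: str = "freq_p65",
    relb_col: str = "freq_relb",
) -> pd.DataFrame:
    """Add stratification columns to a patient-score table.

    Adds ``p65_high``, ``relb_high``, ``kb_status``, ``ratio_value`` and
    ``ratio_category``.  Rows with missing frequencies get NaN/``undefined``.
    """
    cfg = cfg or CutoffConfig()
    out = scores.copy()
    labels = []
    for p65, relb in zip(out[p65_col], out[relb_col]):
        if pd.isna(p65) or pd.isna(relb):
            labels.append(StratificationLabel("undefined", float("nan"), "undefined"))
        else:
            labels.append(label_patient(float(p65), float(relb), cfg))
    out["p65_high"] = (out[p65_col] > cfg.p65_cutoff).astype("Int64")
    out["relb_high"] = (out[relb_col] > cfg.relb_cutoff).astype("Int64")
    out["kb_status"] = [lab.kb_status for lab in labels]
    out["ratio_value"] = [lab.ratio_value for lab in labels]
    out["ratio_category"] = [lab.ratio_category for lab in labels]
    return out
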