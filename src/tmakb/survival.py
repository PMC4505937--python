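"""Survival-biomarker statistics for biochemical recurrence (BCR).

Covers the downstream statistical battery: deriving the BCR endpoint from a
post-operative PSA series (relapse strictly above 0.3 ng/ml), the paired
Wilcoxon comparison of tumor versus normal-adjacent frequencies, Spearman
correlations with clinicopathological covariates, Kaplan–Meier curves with
log-rank tests across strata, and Cox proportional-hazards models (Efron tie
handling by default, Breslow switchable) with a 10-events-per-variable gate
before multivariate estimates are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "CoxResult",
    "bcr_event_from_psa",
    "paired_tumor_normal_test",
    "correlate_clinical",
    "km_logrank",
    "cox_fit",
]

#: PSA relapse threshold defining biochemical recurrence, ng/ml
BCR_PSA_THRESHOLD = 0.3

#: minimum events per covariate before multivariate estimates are reported
EVENTS_PER_VARIABLE = 10

#: patients recurring at time 0 are shifted here to keep risk sets defined
MIN_EVENT_TIME = 0.01


def bcr_event_from_psa(
    psa_series: Sequence[tuple[float, float]]
) -> tuple[bool, float]:
    """Derive (event, time) from a post-operative PSA series.

    The event occurs at the first measurement with PSA strictly above
    0.3 ng/ml; otherwise the patient is censored at the last measurement time.
    The series must be non-empty, time-sorted, with strictly positive times.
    """
    if len(psa_series) == 0:
        raise ValueError("empty PSA series")
    times = [t for t, _ in psa_series]
    if any(t <= 0 for t in times):
        raise ValueError("PSA measurement times must be > 0")
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("PSA series must be sorted by time")
    for t, psa in psa_series:
        if psa > BCR_PSA_THRESHOLD:
            return True, float(t)
    return False, float(times[-1])


def paired_tumor_normal_test(
    tumor_freqs: Sequence[float], normal_freqs: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired tumor/normal frequencies.

    Pairs with a missing member are dropped (at least 5 complete pairs are
    required).  All-zero differences carry no evidence against the null and
    are reported as (0.0, 1.0) rather than an error.
    """
    t = np.asarray(tumor_freqs, dtype=float)
    m = np.asarray(normal_freqs, dtype=float)
    if t.shape != m.shape or t.ndim != 1:
        raise ValueError("paired lists must be 1-D and equal length")
    ok = ~(np.isnan(t) | np.isnan(m))
    t, m = t[ok], m[ok]
    if t.size < 5:
        raise ValueError(f"need >= 5 complete pairs, got {t.size}")
    if np.all(t == m):
        return 0.0, 1.0
    res = stats.wilcoxon(t, m, alternative="two-sided", zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def correlate_clinical(
    freqs: Sequence[float], covariate: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of missing values."""
    f = np.asarray(freqs, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if f.shape != c.shape or f.ndim != 1:
        raise ValueError("lists must be 1-D and equal length")
    ok = ~(np.isnan(f) | np.isnan(c))
    f, c = f[ok], c[ok]
    if f.size < 10:
        raise ValueError(f"need >= 10 complete pairs, got {f.size}")
    if np.ptp(c) == 0 or np.ptp(f) == 0:
        raise ValueError("constant variable: Spearman correlation undefined")
    rho, p = stats.spearmanr(f, c)
    return float(rho), float(p)


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    group_labels: Sequence,
) -> tuple[dict, float, float]:
    """Kaplan–Meier curves per group plus a log-rank test across groups.

    Returns ``(curves, chi2, p)`` where ``curves`` maps each group label to a
    DataFrame with columns ``time`` and ``survival`` (a non-increasing step
    function starting at S(0) = 1).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    if not (t.shape == e.shape == g.shape) or t.ndim != 1:
        raise ValueError("times, events, group_labels must be 1-D, equal length")
    groups = pd.unique(g)
    if len(groups) < 2:
        raise ValueError("log-rank requires at least 2 groups")
    curves = {}
    for grp in groups:
        sel = g == grp
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=str(grp))
        sf = kmf.survival_function_
        curves[grp] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(t, g, e)
    return curves, float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """A fitted Cox proportional-hazards model.

    ``table`` has one row per covariate: ``hr``, ``ci_low``, ``ci_high``,
    ``p``.  For a multivariate model failing the events-per-variable gate
    (``n_events < 10 * n_covariates``), ``epv_ok`` is False and ``table`` is
    empty unless the fit was forced.
    """

    model_type: str
    n: int
    n_events: int
    epv_ok: bool
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    tie_method: str = "efron"

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.table.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "p"])


def _fit_efron(df: pd.DataFrame, duration_col: str, event_col: str) -> pd.DataFrame:
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    summ = cph.summary
    return pd.DataFrame(
        {
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )


def _fit_breslow(df: pd.DataFrame, duration_col: str, event_col: str) -> pd.DataFrame:
    from statsmodels.duration.hazard_regression import PHReg

    covs = [c for c in df.columns if c not in (duration_col, event_col)]
    model = PHReg(
        df[duration_col], df[covs], status=df[event_col], ties="breslow"
    )
    res = model.fit()
    hr = np.exp(res.params)
    ci = np.exp(res.conf_int())
    return pd.DataFrame(
        {
            "hr": hr,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": res.pvalues,
        },
        index=covs,
    )


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "bcr_time_months",
    event_col: str = "bcr_event",
    multivariate: bool = False,
    tie_method: str = "efron",
    force: bool = False,
) -> CoxResult:
    """Cox proportional-hazards fit with an events-per-variable gate.

    Univariate mode fits each covariate alone (one pooled table of the
    single-covariate fits when several are supplied); multivariate mode enters
    all covariates simultaneously.  Rows with missing values in the used
    columns are listwise-deleted.  Times of 0 are shifted to 0.01 months so
    risk sets stay defined.

    Multivariate estimates are only reported when ``n_events >= 10 *
    n_covariates`` (``epv_ok``); pass ``force=True`` to override the gate.
    """
    if tie_method not in ("efron", "breslow"):
        raise ValueError("tie_method must be 'efron' or 'breslow'")
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates supplied")
    missing = [c for c in covariates + [duration_col, event_col] if c not in records]
    if missing:
        raise ValueError(f"columns not in records: {missing}")

    df = records[covariates + [duration_col, event_col]].dropna().copy()
    df[duration_col] = df[duration_col].clip(lower=MIN_EVENT_TIME)
    n = len(df)
    n_events = int(df[event_col].sum())
    if n_events < 1:
        raise ValueError("no events: Cox model cannot be fitted")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"constant covariate {c!r}: Cox fit is undefined")

    fit = _fit_efron if tie_method == "efron" else _fit_breslow

    if multivariate:
        epv_ok = n_events >= EVENTS_PER_VARIABLE * len(covariates)
        if not epv_ok and not force:
            return CoxResult(
                model_type="multivariate",
                n=n,
                n_events=n_events,
                epv_ok=False,
                table=pd.DataFrame(columns=["hr", "ci_low", "ci_high", "p"]),
                tie_method=tie_method,
            )
        table = fit(df, duration_col, event_col)
        return CoxResult(
            model_type="multivariate",
            n=n,
            n_events=n_events,
            epv_ok=epv_ok,
            table=table,
            tie_method=tie_method,
        )

    rows = []
    for c in covariates:
        sub = df[[c, duration_col, event_col]]
        rows.append(fit(sub, duration_col, event_col))
    table = pd.concat(rows)
    return CoxResult(
        model_type="univariate",
        n=n,
        n_events=n_events,
        epv_ok=n_events >= EVENTS_PER_VARIABLE,
        table=table,
        tie_method=tie_method,
    )
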