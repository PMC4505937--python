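"""Independent brute-force oracles used to validate the statistical routines.

Everything here is deliberately written from first principles — explicit loops
over subjects, risk sets and tied event groups — and shares no code path with
the package implementations it checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "icc_oneway_anova",
    "logrank_chi2_enumerated",
    "efron_beta_bruteforce",
]


def icc_oneway_anova(pairs: list[tuple[float, float]]) -> float:
    """ICC(1,1) by explicit one-way ANOVA sums of squares over subject loops."""
    n = len(pairs)
    k = 2
    grand = sum(a + b for a, b in pairs) / (n * k)
    ss_between = 0.0
    ss_within = 0.0
    for a, b in pairs:
        m = (a + b) / 2.0
        ss_between += k * (m - grand) ** 2
        ss_within += (a - m) ** 2 + (b - m) ** 2
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def logrank_chi2_enumerated(times, events, groups) -> float:
    """Log-rank chi-square by enumerating risk sets at each distinct event time.

    Supports any number of groups; uses the standard hypergeometric variance
    with the quadratic form over the first k-1 groups.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()), key=str)
    k = len(labels)
    event_times = sorted(set(times[events == 1].tolist()))

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_j = int(at_risk.sum())
        d_j = int(((times == t) & (events == 1)).sum())
        if n_j == 0:
            continue
        n_gj = np.array([int((at_risk & (groups == g)).sum()) for g in labels], dtype=float)
        d_gj = np.array(
            [int(((times == t) & (events == 1) & (groups == g)).sum()) for g in labels],
            dtype=float,
        )
        observed += d_gj
        expected += d_j * n_gj / n_j
        if n_j > 1:
            frac = n_gj / n_j
            mult = d_j * (n_j - d_j) / (n_j - 1)
            for a in range(k):
                for b in range(k):
                    delta = 1.0 if a == b else 0.0
                    cov[a, b] += mult * frac[a] * (delta - frac[b])
    diff = (observed - expected)[: k - 1]
    vmat = cov[: k - 1, : k - 1]
    return float(diff @ np.linalg.solve(vmat, diff))


def _efron_loglik(beta: float, times, events, x) -> float:
    """Efron partial log-likelihood for a single covariate, explicit loops."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in sorted(set(times[events == 1].tolist())):
        tied = (times == t) & (events == 1)
        at_risk = times >= t
        d = int(tied.sum())
        sum_tied_bx = float((beta * x[tied]).sum())
        risk_exp = float(np.exp(beta * x[at_risk]).sum())
        tied_exp = float(np.exp(beta * x[tied]).sum())
        ll += sum_tied_bx
        for ell in range(d):
            ll -= np.log(risk_exp - (ell / d) * tied_exp)
    return ll


def efron_beta_bruteforce(times, events, x, lo=-6.0, hi=6.0, tol=1e-8) -> float:
    """Maximise the Efron partial likelihood by grid + golden-section search."""
    grid = np.linspace(lo, hi, 121)
    vals = [_efron_loglik(b, times, events, x) for b in grid]
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _efron_loglik(c, times, events, x)
    fd = _efron_loglik(d, times, events, x)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _efron_loglik(c, times, events, x)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _efron_loglik(d, times, events, x)
    return float((a + b) / 2.0)
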