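"""BCR derivation, Wilcoxon, Spearman, Kaplan–Meier/log-rank, Cox models."""

import numpy as np
import pandas as pd
import pytest

from tests.oracles import efron_beta_bruteforce, logrank_chi2_enumerated
from tmakb.survival import (
    bcr_event_from_psa,
    correlate_clinical,
    cox_fit,
    km_logrank,
    paired_tumor_normal_test,
)


class TestBcrFromPsa:
    def test_first_crossing(self):
        assert bcr_event_from_psa([(6, 0.1), (12, 0.2), (18, 0.5)]) == (True, 18.0)

    def test_all_below_censored_at_last(self):
        assert bcr_event_from_psa([(6, 0.1), (24, 0.3)]) == (False, 24.0)

    def test_strictly_above_threshold(self):
        assert bcr_event_from_psa([(6, 0.31)]) == (True, 6.0)

    def test_bad_series_rejected(self):
        with pytest.raises(ValueError):
            bcr_event_from_psa([])
        with pytest.raises(ValueError):
            bcr_event_from_psa([(12, 0.1), (6, 0.2)])
        with pytest.raises(ValueError):
            bcr_event_from_psa([(0, 0.1)])


class TestPairedWilcoxon:
    def test_no_difference_no_evidence(self):
        vals = [10.0, 12.0, 14.0, 16.0, 18.0]
        stat, p = paired_tumor_normal_test(vals, vals)
        assert p == 1.0

    def test_missing_pairs_dropped(self):
        t = [10, 20, 30, 40, 50, np.nan, 60.0]
        m = [5, 15, 25, 35, 45, 50, 55.0]
        stat, p = paired_tumor_normal_test(t, m)
        assert p < 0.1  # consistent shift in the 6 usable pairs

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_tumor_normal_test([1, 2, 3, 4], [1, 2, 3, 5])

    def test_power_against_shift(self):
        """Tumor shifted +10 points, n = 100 pairs: p < 0.001 nearly always."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            normal = rng.normal(15, 8, 100).clip(0, 100)
            tumor = (normal + 10 + rng.normal(0, 6, 100)).clip(0, 100)
            _, p = paired_tumor_normal_test(tumor, normal)
            hits += p < 0.001
        assert hits >= 95


class TestSpearman:
    def test_perfect_monotone(self):
        freqs = [1.0, 2.0, 3.0, 5.0, 8.0, 13.0, 21.0, 34.0, 55.0, 89.0]
        ranks = list(range(10))
        rho, _ = correlate_clinical(freqs, ranks)
        assert rho == pytest.approx(1.0)
        rho_rev, _ = correlate_clinical(freqs, ranks[::-1])
        assert rho_rev == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        low = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            rho, _ = correlate_clinical(rng.random(1000), rng.random(1000))
            low += abs(rho) < 0.1
        assert low >= 38

    def test_constant_covariate_is_error(self):
        with pytest.raises(ValueError):
            correlate_clinical(list(range(10)), [3.0] * 10)


class TestKmLogrank:
    def test_identical_groups_chi2_zero(self):
        times = [5, 10, 15, 20, 25, 30] * 2
        events = [1, 0, 1, 1, 0, 1] * 2
        groups = ["a"] * 6 + ["b"] * 6
        curves, chi2, p = km_logrank(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_curves_are_valid_survival_functions(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(50, 80)
        events = rng.integers(0, 2, 80)
        groups = rng.integers(0, 2, 80)
        curves, _, _ = km_logrank(times, events, groups)
        for curve in curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)  # S(0) = 1
            assert np.all(np.diff(s) <= 1e-12)  # non-increasing

    def test_six_subject_fixture_matches_enumeration(self):
        """Log-rank chi2 equals the hand-enumerated risk-set computation."""
        times = [6.0, 7.0, 10.0, 15.0, 19.0, 25.0]
        events = [1, 1, 0, 1, 1, 1]
        groups = ["a", "b", "a", "b", "a", "b"]
        _, chi2, _ = km_logrank(times, events, groups)
        expected = logrank_chi2_enumerated(times, events, groups)
        assert chi2 == pytest.approx(expected, abs=1e-9)

    def test_three_groups_match_enumeration(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(40, 60).round(1)
        events = rng.integers(0, 2, 60)
        groups = rng.integers(0, 3, 60)
        _, chi2, _ = km_logrank(times, events, groups)
        assert chi2 == pytest.approx(
            logrank_chi2_enumerated(times, events, groups), rel=1e-6
        )

    def test_power_doubled_hazard(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t0 = rng.exponential(100, 500)
            t1 = rng.exponential(50, 500)
            times = np.concatenate([t0, t1]).clip(max=120)
            events = (np.concatenate([t0, t1]) <= 120).astype(int)
            groups = np.repeat([0, 1], 500)
            _, _, p = km_logrank(times, events, groups)
            hits += p < 0.05
        assert hits >= 45

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3], [1, 1, 0], ["a", "a", "a"])


def _sim_cox_frame(rng, n, hr, censor=120.0, h0=0.004):
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (h0 * hr**x))
    return pd.DataFrame(
        {
            "x": x.astype(float),
            "bcr_time_months": np.minimum(t, censor),
            "bcr_event": (t <= censor).astype(int),
        }
    )


class TestCox:
    def test_binary_covariate_matches_bruteforce_efron(self):
        """n <= 30 fixture with ties: coefficient matches brute-force Efron."""
        times = [3, 3, 5, 7, 7, 7, 9, 12, 12, 15, 18, 20, 22, 22, 25,
                 28, 30, 33, 35, 35, 40, 44, 47, 50, 52, 55, 58, 60]
        events = [1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 1,
                  0, 1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 0]
        x = [1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1,
             1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 0]
        df = pd.DataFrame(
            {"x": np.asarray(x, float), "bcr_time_months": times, "bcr_event": events}
        )
        res = cox_fit(df, ["x"])
        beta_ref = efron_beta_bruteforce(times, events, x)
        assert np.log(res.hr("x")) == pytest.approx(beta_ref, abs=1e-3)

    def test_hr_recovery(self):
        """True HR = 2, 500 subjects per arm, no censoring: estimate near truth.

        At this size the log-HR sampling SD is ~0.06, so [1.7, 2.35] is a
        ~99%-per-seed event and the check is diagnostic rather than noisy.
        """
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            df = _sim_cox_frame(rng, 1000, 2.0, censor=np.inf)
            hr = cox_fit(df, ["x"]).hr("x")
            hits += 1.7 <= hr <= 2.35
        assert hits >= 45

    def test_epv_gate(self):
        """15 events with 2 covariates: gate trips, no estimates reported."""
        rng = np.random.default_rng(2)
        n = 60
        df = pd.DataFrame(
            {
                "x1": rng.integers(0, 2, n).astype(float),
                "x2": rng.normal(size=n),
                "bcr_time_months": rng.exponential(100, n),
                "bcr_event": np.r_[np.ones(15), np.zeros(n - 15)],
            }
        )
        res = cox_fit(df, ["x1", "x2"], multivariate=True)
        assert res.n_events == 15
        assert not res.epv_ok
        assert res.table.empty
        forced = cox_fit(df, ["x1", "x2"], multivariate=True, force=True)
        assert not forced.epv_ok
        assert len(forced.table) == 2

    def test_constant_covariate_is_error(self):
        df = pd.DataFrame(
            {
                "x": np.ones(20),
                "bcr_time_months": np.arange(1, 21, dtype=float),
                "bcr_event": [1, 0] * 10,
            }
        )
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])

    def test_no_events_is_error(self):
        df = pd.DataFrame(
            {
                "x": [0.0, 1.0] * 10,
                "bcr_time_months": np.arange(1, 21, dtype=float),
                "bcr_event": np.zeros(20, int),
            }
        )
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["x"])

    def test_breslow_close_to_efron_with_few_ties(self):
        rng = np.random.default_rng(6)
        df = _sim_cox_frame(rng, 300, 2.0)
        df["bcr_time_months"] = df["bcr_time_months"].round(2)  # mild ties
        efron = cox_fit(df, ["x"], tie_method="efron")
        breslow = cox_fit(df, ["x"], tie_method="breslow")
        assert breslow.hr("x") == pytest.approx(efron.hr("x"), rel=0.05)

    def test_zero_times_shifted(self):
        df = pd.DataFrame(
            {
                "x": [0.0, 1.0] * 10,
                "bcr_time_months": [0.0] + list(np.arange(1.0, 20.0)),
                "bcr_event": [1] * 20,
            }
        )
        res = cox_fit(df, ["x"])  # must not raise on the zero time
        assert res.n_events == 20
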