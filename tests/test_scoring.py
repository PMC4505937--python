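"""Thresholds, per-core frequencies, duplicate aggregation, ICC, positivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tests.conftest import make_nucleus_set
from tests.oracles import icc_oneway_anova
from tmakb.scoring import (
    ThresholdSpec,
    aggregate_patient,
    compute_threshold,
    core_is_positive,
    duplicate_icc,
    score_core,
)


class TestComputeThreshold:
    def test_hand_computable(self):
        spec = compute_threshold([1.0, 2.0, 3.0], "p65")
        assert spec.mean == pytest.approx(2.0)
        assert spec.sd == pytest.approx(1.0)
        assert spec.threshold == pytest.approx(3.0)

    def test_constant_values_sd_zero(self):
        spec = compute_threshold([5.0, 5.0, 5.0], "relb")
        assert spec.threshold == pytest.approx(5.0)

    def test_single_value_allowed(self):
        assert compute_threshold([2.5], "p65").threshold == pytest.approx(2.5)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            compute_threshold([], "p65")

    def test_monte_carlo_normal(self):
        """On 1e5 normal draws the threshold approaches mu + sigma."""
        rng = np.random.default_rng(42)
        mu, sigma = 0.3, 0.08
        spec = compute_threshold(rng.normal(mu, sigma, 100_000), "p65")
        assert spec.threshold == pytest.approx(mu + sigma, rel=0.01)


class TestScoreCore:
    def test_simple_fraction(self):
        p65 = np.array([0.9] * 3 + [0.1] * 7)
        nuclei = make_nucleus_set(p65, np.full(10, 0.1))
        thr = ThresholdSpec("p65", 0.5, 0.0)
        score = score_core(nuclei, thr, ThresholdSpec("relb", 0.5, 0.0))
        assert score.freq_p65 == pytest.approx(30.0)
        assert score.freq_relb == 0.0
        assert score.freq_double == 0.0

    def test_all_above_both(self):
        nuclei = make_nucleus_set(np.full(8, 0.9), np.full(8, 0.9))
        score = score_core(
            nuclei, ThresholdSpec("p65", 0.5, 0.0), ThresholdSpec("relb", 0.5, 0.0)
        )
        assert score.freq_p65 == score.freq_relb == score.freq_double == 100.0

    def test_strict_comparison_at_threshold(self):
        nuclei = make_nucleus_set([0.5], [0.5])
        score = score_core(
            nuclei, ThresholdSpec("p65", 0.5, 0.0), ThresholdSpec("relb", 0.5, 0.0)
        )
        assert score.freq_p65 == 0.0  # equality is not positivity

    def test_empty_core_flagged_undefined(self):
        nuclei = make_nucleus_set([], [])
        score = score_core(
            nuclei, ThresholdSpec("p65", 0.5, 0.0), ThresholdSpec("relb", 0.5, 0.0)
        )
        assert score.undefined
        assert np.isnan(score.freq_p65)
        assert score.excluded

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_double_conservation(self, seed):
        """freq_double never exceeds either single frequency."""
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 40)
        nuclei = make_nucleus_set(rng.random(n), rng.random(n))
        score = score_core(
            nuclei, ThresholdSpec("p65", 0.4, 0.1), ThresholdSpec("relb", 0.3, 0.2)
        )
        assert score.freq_double <= min(score.freq_p65, score.freq_relb) + 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.integers(0, 2**32 - 1),
        st.floats(0.05, 50.0, allow_nan=False),
    )
    def test_scale_equivariance(self, seed, c):
        """Rescaling intensities and threshold sources leaves frequencies fixed."""
        rng = np.random.default_rng(seed)
        n = 25
        p65 = rng.random(n)
        relb = rng.random(n)
        base_p = compute_threshold(p65, "p65")
        base_r = compute_threshold(relb, "relb")
        s1 = score_core(make_nucleus_set(p65, relb), base_p, base_r)
        scaled_p = compute_threshold(p65 * c, "p65")
        scaled_r = compute_threshold(relb * c, "relb")
        s2 = score_core(make_nucleus_set(p65 * c, relb * c), scaled_p, scaled_r)
        assert s1.freq_p65 == pytest.approx(s2.freq_p65)
        assert s1.freq_relb == pytest.approx(s2.freq_relb)
        assert s1.freq_double == pytest.approx(s2.freq_double)


class TestAggregatePatient:
    def _score(self, freq, pid="P1", tissue="tumor", excluded=False):
        nuclei = make_nucleus_set(
            np.array([0.9] * int(freq) + [0.0] * (100 - int(freq))), np.zeros(100)
        )
        return score_core(
            nuclei,
            ThresholdSpec("p65", 0.5, 0.0),
            ThresholdSpec("relb", 0.5, 0.0),
            patient_id=pid,
            tissue_type=tissue,
            excluded=excluded,
        )

    def test_mean_of_duplicates(self):
        agg = aggregate_patient([self._score(20), self._score(30)])
        assert agg.freq_p65 == pytest.approx(25.0)
        assert agg.n_cores_used == 2

    def test_single_core(self):
        assert aggregate_patient([self._score(40)]).freq_p65 == pytest.approx(40.0)

    def test_three_cores(self):
        agg = aggregate_patient([self._score(10), self._score(20), self._score(30)])
        assert agg.freq_p65 == pytest.approx(20.0)

    def test_excluded_cores_dropped(self):
        agg = aggregate_patient([self._score(20), self._score(90, excluded=True)])
        assert agg.freq_p65 == pytest.approx(20.0)
        assert agg.n_cores_used == 1

    def test_all_excluded_is_missing(self):
        with pytest.raises(ValueError, match="missing"):
            aggregate_patient([self._score(20, excluded=True)])

    def test_aggregate_between_min_and_max(self):
        rng = np.random.default_rng(0)
        freqs = rng.integers(0, 100, 4)
        agg = aggregate_patient([self._score(int(f)) for f in freqs])
        assert min(freqs) <= agg.freq_p65 <= max(freqs)


class TestDuplicateICC:
    def test_identical_columns(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert duplicate_icc(vals, vals) == pytest.approx(1.0)

    def test_matches_anova_oracle(self):
        pairs = [(1, 2), (2, 1), (3, 4), (4, 3), (5, 6)]
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        assert duplicate_icc(a, b) == pytest.approx(icc_oneway_anova(pairs), abs=1e-12)

    def test_matches_pingouin(self):
        """Cross-check against an independent ICC implementation."""
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        subject = rng.normal(30, 10, 40)
        a = subject + rng.normal(0, 5, 40)
        b = subject + rng.normal(0, 5, 40)
        ours = duplicate_icc(a, b)
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(40), 2),
                "raters": np.tile([0, 1], 40),
                "ratings": np.column_stack([a, b]).ravel(),
            }
        )
        table = pg.intraclass_corr(
            long, targets="targets", raters="raters", ratings="ratings"
        )
        icc1 = table.loc[table["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
        assert ours == pytest.approx(float(icc1), abs=1e-9)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(8)
        icc = duplicate_icc(rng.normal(0, 1, 2000), rng.normal(0, 1, 2000))
        assert abs(icc) < 0.1

    def test_errors(self):
        with pytest.raises(ValueError):
            duplicate_icc([1, 2], [1, 2])  # too few pairs
        with pytest.raises(ValueError):
            duplicate_icc([1, 2, 3], [1, 2])  # unequal
        with pytest.raises(ValueError):
            duplicate_icc([2, 2, 2], [2, 2, 2])  # constant


class TestCoreIsPositive:
    @pytest.mark.parametrize(
        "freq,background,expected",
        [
            (6.0, 0.5, True),
            (4.9, 0.0, False),
            (5.0, 0.0, True),  # inclusive "at least 5 points over"
            (14.9, 10.0, False),
            (15.0, 10.0, True),
        ],
    )
    def test_margin(self, freq, background, expected):
        assert core_is_positive(freq, background) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            core_is_positive(101.0)
        with pytest.raises(ValueError):
            core_is_positive(50.0, -1.0)
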