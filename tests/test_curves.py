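"""Tests for OD conversion, lag estimators and relative-biomass tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qnq.curves import (CONVERSION_COEFFS, GrowthCurve, biomass_to_od,
                        lag_max_growth, lag_threshold, od_to_biomass,
                        relative_biomass_env, relative_biomass_vs_mixed)


class TestConversion:
    @pytest.mark.parametrize("od,expected", [
        (0.0, 220_300.0),        # calibration intercept
        (0.8, 20_796_300.0),     # direct polynomial evaluation
        (1.0, 31_220_300.0),
    ])
    def test_polynomial_values(self, od, expected):
        assert od_to_biomass(od) == pytest.approx(expected)

    def test_polynomial_strictly_increasing_on_calibration_range(self):
        od = np.linspace(0.0, 2.0, 2001)
        assert np.all(np.diff(od_to_biomass(od)) > 0)

    def test_inverse_intercept(self):
        assert biomass_to_od(220_300.0) == 0.0

    def test_inverse_matches_evaluation(self):
        assert biomass_to_od(20_796_300.0) == pytest.approx(0.8, abs=1e-9)

    @pytest.mark.parametrize("od", [0.1, 0.5, 1.5])
    def test_roundtrip_identity(self, od):
        assert biomass_to_od(od_to_biomass(od)) == pytest.approx(od, abs=1e-9)

    def test_out_of_range_biomass_rejected(self):
        with pytest.raises(ValueError, match="range"):
            biomass_to_od(1e3)

    def test_out_of_range_od_policy(self):
        with pytest.raises(ValueError, match="range"):
            od_to_biomass(2.5)
        with pytest.warns(UserWarning):
            od_to_biomass(2.5, on_range="warn")


class TestLagThreshold:
    def test_constant_curve_returns_sentinel(self):
        curve = GrowthCurve(np.arange(0, 5, 0.5), np.full(10, 0.2))
        assert lag_threshold(curve) is None

    def test_first_crossing_time(self):
        times = np.arange(0, 6.5, 0.5)
        od = np.full_like(times, 0.100)
        od[times >= 3.0] = 0.111
        assert lag_threshold(GrowthCurve(times, od)) == 3.0

    def test_immediate_crossing_at_first_sample(self):
        curve = GrowthCurve([0.0, 0.5, 1.0], [0.10, 0.12, 0.14])
        assert lag_threshold(curve) == 0.5

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            GrowthCurve([0.0], [0.1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.integers(0, 10), offset=st.floats(-0.05, 0.5))
    def test_translation_covariance_and_offset_invariance(self, shift, offset):
        times = np.arange(0, 24.5, 0.5)
        base = 0.1 + 0.05 * np.maximum(0.0, times - 4.0)
        shifted = np.concatenate([np.full(shift, base[0]), base])[:len(times)]
        lag0 = lag_threshold(GrowthCurve(times, base + offset))
        lag1 = lag_threshold(GrowthCurve(times, shifted + offset))
        assert lag1 == pytest.approx(lag0 + 0.5 * shift)


class TestLagMaxGrowth:
    def test_logistic_curve_peaks_at_inflection(self):
        # symmetric logistic biomass: max dB/dt at the midpoint t0
        times = np.arange(0.0, 24.5, 0.5)
        t0, rate, cap = 10.0, 0.6, 3.0e7
        biomass = 2.5e5 + cap / (1.0 + np.exp(-rate * (times - t0)))
        od = np.array([biomass_to_od(b) for b in biomass])
        assert lag_max_growth(GrowthCurve(times, od)) == pytest.approx(t0)

    def test_exponential_curve_peaks_at_last_interior_point(self):
        times = np.arange(0.0, 10.5, 0.5)
        biomass = 1e6 * np.exp(0.3 * times)
        od = np.array([biomass_to_od(b) for b in biomass])
        assert lag_max_growth(GrowthCurve(times, od)) == times[-2]

    def test_flat_curve_returns_sentinel(self):
        curve = GrowthCurve(np.arange(0, 5, 0.5), np.full(10, 0.3))
        assert lag_max_growth(curve) is None

    def test_second_derivative_variant_peaks_before_inflection(self):
        times = np.arange(0.0, 24.5, 0.5)
        biomass = 2.5e5 + 3.0e7 / (1.0 + np.exp(-0.6 * (times - 10.0)))
        od = np.array([biomass_to_od(b) for b in biomass])
        t2 = lag_max_growth(GrowthCurve(times, od), second_derivative=True)
        assert t2 < 10.0


def _plate_frame(rng, types=("Q", "NQ", "mixed"), n_rep=3, n_t=5):
    rows = []
    for ct in types:
        for rep in range(1, n_rep + 1):
            for i in range(n_t):
                rows.append({
                    "culture_type": ct, "replicate": rep,
                    "time_h": 0.5 * i,
                    "biomass": float(rng.uniform(1e6, 3e7)),
                })
    return pd.DataFrame(rows)


class TestRelativeBiomass:
    def test_two_mixed_replicates_normalise_to_half_and_three_halves(self):
        df = pd.DataFrame({
            "culture_type": ["mixed", "mixed", "Q"],
            "replicate": [1, 2, 1],
            "time_h": [0.0, 0.0, 0.0],
            "biomass": [1e6, 3e6, 2e6],
        })
        out = relative_biomass_vs_mixed(df)
        mixed = out[out.culture_type == "mixed"]["relative_biomass"]
        assert sorted(mixed) == pytest.approx([0.5, 1.5])
        assert out[out.culture_type == "Q"]["relative_biomass"].iloc[0] == 1.0

    def test_monoculture_at_twice_mixed_mean_scores_two(self):
        df = pd.DataFrame({
            "culture_type": ["mixed", "Q"],
            "replicate": [1, 1],
            "time_h": [0.0, 0.0],
            "biomass": [1e6, 2e6],
        })
        out = relative_biomass_vs_mixed(df)
        assert out[out.culture_type == "Q"]["relative_biomass"].iloc[0] == 2.0

    def test_mixed_mean_is_exactly_one_on_random_data(self):
        rng = np.random.default_rng(11)
        out = relative_biomass_vs_mixed(_plate_frame(rng))
        mixed = out[out.culture_type == "mixed"]
        means = mixed.groupby("time_h")["relative_biomass"].mean()
        np.testing.assert_allclose(means.to_numpy(), 1.0, rtol=1e-12)

    def test_missing_mixed_reference_rejected(self):
        rng = np.random.default_rng(1)
        df = _plate_frame(rng, types=("Q", "NQ"))
        with pytest.raises(ValueError, match="mixed"):
            relative_biomass_vs_mixed(df)

    def test_env_ratio_identity_for_identical_trajectories(self):
        rng = np.random.default_rng(3)
        df = _plate_frame(rng).assign(week=1)
        out = relative_biomass_env(df, df.copy())
        np.testing.assert_allclose(out["relative_biomass"], 1.0)

    def test_env_ratio_reports_fold_change(self):
        df_s = pd.DataFrame({"culture_type": "NQ", "week": 4,
                             "time_h": [0.0], "replicate": 1, "biomass": [1e6]})
        df_c = df_s.assign(biomass=[11e6])
        out = relative_biomass_env(df_c, df_s)
        assert out["relative_biomass"].iloc[0] == pytest.approx(11.0)

    def test_env_ratio_grid_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        df = _plate_frame(rng).assign(week=1)
        with pytest.raises(ValueError, match="align"):
            relative_biomass_env(df, df[df.time_h > 0.0])

    def test_env_ratio_zero_reference_rejected(self):
        df_s = pd.DataFrame({"culture_type": "NQ", "week": 1,
                             "time_h": [0.0], "replicate": 1, "biomass": [0.0]})
        with pytest.raises(ZeroDivisionError):
            relative_biomass_env(df_s.assign(biomass=[1e6]), df_s)
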