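"""Kinetic metrics against closed forms on analytic curves."""

import numpy as np
import pytest

from tonguechip.flowcell import NoPeakError
from tonguechip.kinetics import (
    DegenerateCurveError,
    PercentCurve,
    kinetic_metrics,
    lingering,
    normalize_and_sync,
    onset,
    peak_fwhm,
    slope_metrics,
)

DT = 1.0
T = np.arange(0.0, 400.0, DT)


def gaussian(center=150.0, sigma=20.0, base=1.0, amp=0.5):
    return base + amp * np.exp(-((T - center) ** 2) / (2 * sigma**2))


def pct(values, valve=100.0, smooth=1):
    return normalize_and_sync(T, values, valve_time=valve, smooth_window=smooth)


class TestNormalizeAndSync:
    def test_maximum_is_exactly_100(self):
        c = pct(gaussian())
        assert c.values.max() == pytest.approx(100.0)

    def test_valve_lands_on_sync_time(self):
        c = normalize_and_sync(T, gaussian(), valve_time=120.0, sync_time=50.0,
                               smooth_window=1)
        assert c.times[0] == pytest.approx(T[0] - 120.0 + 50.0)

    def test_pointwise_formula(self):
        y = gaussian(base=2.0, amp=0.8)
        c = pct(y)
        base_mask = (T >= 90.0) & (T < 100.0)
        b, p = y[base_mask].mean(), y.max()
        assert np.allclose(c.values, (y - b) / (p - b) * 100.0)

    def test_already_normalized_curve_unchanged(self):
        c = pct(gaussian())
        again = normalize_and_sync(
            c.times, c.values, valve_time=50.0, sync_time=50.0, smooth_window=1
        )
        assert np.allclose(again.values, c.values)

    def test_flat_curve_rejected(self):
        with pytest.raises(DegenerateCurveError):
            pct(np.full_like(T, 3.0))


class TestPeakFwhm:
    def test_boxcar_width(self):
        y = np.where((T >= 150) & (T < 230), 100.0, 0.0)
        assert peak_fwhm(PercentCurve(T, y)) == pytest.approx(80.0, abs=DT)

    def test_gaussian_closed_form(self):
        c = pct(gaussian(sigma=20.0))
        assert peak_fwhm(c) == pytest.approx(2.3548 * 20.0, abs=DT)

    def test_triangle_half_base(self):
        y = np.clip(100.0 * (1 - np.abs(T - 200.0) / 60.0), 0.0, None)
        assert peak_fwhm(PercentCurve(T, y)) == pytest.approx(60.0, abs=DT)

    def test_no_crossing_raises(self):
        y = np.full_like(T, 80.0)
        with pytest.raises(NoPeakError):
            peak_fwhm(PercentCurve(T, y))


class TestOnset:
    def test_self_comparison_is_zero(self):
        c = pct(gaussian())
        delay, unc = onset(c, c)
        assert delay == 0.0
        assert unc == DT

    def test_translation_recovered_exactly(self):
        resp = pct(gaussian(center=170.0))
        ref = pct(gaussian(center=150.0))
        delay, _ = onset(resp, ref)
        assert delay == pytest.approx(20.0, abs=DT)

    def test_p90_mode_on_shifted_curves(self):
        resp = pct(gaussian(center=170.0))
        ref = pct(gaussian(center=150.0))
        delay, _ = onset(resp, ref, mode="p90")
        assert delay == pytest.approx(20.0, abs=DT)

    def test_time_translation_invariance(self):
        resp = pct(gaussian(center=170.0))
        ref = pct(gaussian(center=150.0))
        shifted_resp = PercentCurve(resp.times + 33.0, resp.values)
        shifted_ref = PercentCurve(ref.times + 33.0, ref.values)
        assert onset(shifted_resp, shifted_ref)[0] == onset(resp, ref)[0]

    def test_amplitude_invariance_through_normalization(self):
        raw = gaussian(amp=0.5)
        rescaled = 7.0 * raw + 3.0
        a = pct(raw)
        b = pct(rescaled)
        assert np.allclose(a.values, b.values)


class TestLingeringAndSlopes:
    def test_equal_curves_have_no_lingering(self):
        c = pct(gaussian())
        assert lingering(c, c) is None

    def test_wider_response_reports_excess_width(self):
        # centers far from the baseline window so normalization is clean
        resp = pct(gaussian(center=250.0, sigma=30.0))
        ref = pct(gaussian(center=250.0, sigma=20.0))
        assert lingering(resp, ref) == pytest.approx(2.3548 * 10.0, abs=2 * DT)

    def test_equal_curves_have_100pct_relative_slopes(self):
        c = pct(gaussian())
        _, _, rel_rise, rel_fall = slope_metrics(c, c)
        assert rel_rise == pytest.approx(100.0)
        assert rel_fall == pytest.approx(100.0)

    def test_linear_ramp_slope(self):
        ramp = np.clip((T - 100.0), 0.0, 200.0) / 2.0  # 0 -> 100% over 200 s
        c = PercentCurve(T, ramp)
        rise, _, rel_rise, _ = slope_metrics(c, c)
        assert rise == pytest.approx(0.5, abs=1e-6)
        assert rel_rise == pytest.approx(100.0)

    def test_doubled_time_axis_halves_relative_rise(self):
        # a 2x slower curve (doubled sigma) has half the extreme slopes
        resp = pct(gaussian(center=200.0, sigma=40.0))
        ref = pct(gaussian(center=200.0, sigma=20.0))
        _, _, rel_rise, rel_fall = slope_metrics(resp, ref)
        assert rel_rise == pytest.approx(50.0, rel=0.05)
        assert rel_fall == pytest.approx(50.0, rel=0.05)


def test_full_metrics_bundle_consistency():
    resp = pct(gaussian(center=270.0, sigma=30.0))
    ref = pct(gaussian(center=250.0, sigma=20.0))
    m = kinetic_metrics(resp, ref)
    assert m.onset == pytest.approx(20.0, abs=DT)
    assert m.fwhm == pytest.approx(2.3548 * 30.0, abs=DT)
    assert m.delta_fwhm_lingering == pytest.approx(2.3548 * 10.0, abs=2 * DT)
    assert m.rel_rise < 100.0  # broader peak rises more slowly
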