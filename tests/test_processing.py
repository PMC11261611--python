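"""Ratio computation, QC filtering and iRatio extraction."""

import numpy as np
import pytest

from tonguechip.array import (
    ChannelTrace,
    Injection,
    InjectionSchedule,
    SpotRecord,
)
from tonguechip.processing import (
    AllFilteredError,
    DataError,
    compute_ratio,
    iratio_response,
    mean_ratio_trace,
    qc_filter,
    reference_correct,
    RatioTrace,
)


def spot(sid, receptor="TAS1R2_R3", px=30):
    return SpotRecord(spot_id=sid, receptor=receptor, pixel_count=px, position_delay=0.0)


def flat_trace(n=200, dt=2.0, cfp=1000.0, yfp=2000.0):
    t = np.arange(n) * dt
    return ChannelTrace(
        cfp_times=t, cfp=np.full(n, cfp), yfp_times=t + dt / 2, yfp=np.full(n, yfp)
    )


SCHEDULE = InjectionSchedule(
    (Injection(valve_time=100.0, sample_id="s1", composition={}),)
)


class TestQcFilter:
    def test_pixel_boundary_is_strict(self):
        spots = [spot(f"a{i}", px=15) for i in range(5)] + [spot("small", px=14)]
        kept = qc_filter(spots)
        assert {s.spot_id for s in kept} == {f"a{i}" for i in range(5)}

    def test_underreplicated_groups_removed_entirely(self):
        spots = [spot(f"a{i}") for i in range(5)] + [
            spot(f"b{i}", receptor="TAS2R8") for i in range(4)
        ]
        kept = qc_filter(spots)
        assert all(s.receptor == "TAS1R2_R3" for s in kept)
        assert len(kept) == 5

    def test_five_replicates_survive(self):
        spots = [spot(f"b{i}", receptor="TAS2R8") for i in range(5)]
        assert len(qc_filter(spots)) == 5

    def test_idempotent(self):
        spots = [spot(f"a{i}", px=10 + 2 * i) for i in range(10)]
        once = qc_filter(spots)
        assert qc_filter(once) == once

    def test_all_filtered_raises(self):
        with pytest.raises(AllFilteredError):
            qc_filter([spot("tiny", px=3)])


class TestComputeRatio:
    def test_constant_channels_give_constant_ratio(self):
        rt = compute_ratio(flat_trace(), "s")
        assert np.allclose(rt.ratio, 2.0)

    def test_common_scaling_leaves_ratio_unchanged(self):
        tr = flat_trace()
        scaled = ChannelTrace(
            cfp_times=tr.cfp_times, cfp=tr.cfp * 3.7,
            yfp_times=tr.yfp_times, yfp=tr.yfp * 3.7,
        )
        a = compute_ratio(tr, "s")
        b = compute_ratio(scaled, "s")
        assert np.allclose(a.ratio, b.ratio)

    def test_interleaved_sampling_recovers_analytic_ratio(self):
        # slowly varying transient; after interpolation the ratio should
        # match its dense-grid evaluation to ~1e-3
        dt = 2.0
        t_c = np.arange(0, 600, dt)
        t_y = t_c + dt / 2
        s = lambda t: 0.2 * np.exp(-((t - 300.0) ** 2) / (2 * 40.0**2))
        tr = ChannelTrace(
            cfp_times=t_c, cfp=1000.0 * (1 - 0.15 * s(t_c)),
            yfp_times=t_y, yfp=1000.0 * (1 + 0.15 * s(t_y)),
        )
        rt = compute_ratio(tr, "s", smooth_window=1, dt_out=1.0)
        expected = (1 + 0.15 * s(rt.times)) / (1 - 0.15 * s(rt.times))
        assert np.max(np.abs(rt.ratio - expected)) < 1e-3

    def test_peak_location_matches_injected_transient(self):
        dt = 2.0
        t = np.arange(0, 600, dt)
        s = np.exp(-((t - 250.0) ** 2) / (2 * 25.0**2))
        tr = ChannelTrace(
            cfp_times=t, cfp=1000.0 * (1 - 0.1 * s),
            yfp_times=t + dt / 2, yfp=1000.0 * (1 + 0.1 * s),
        )
        rt = compute_ratio(tr, "s")
        assert abs(rt.times[np.argmax(rt.ratio)] - 250.0) <= 2.0

    def test_non_positive_intensity_raises_with_location(self):
        tr = flat_trace()
        bad = ChannelTrace(
            cfp_times=tr.cfp_times, cfp=tr.cfp.copy(),
            yfp_times=tr.yfp_times, yfp=tr.yfp.copy(),
        )
        bad.cfp[10] = 0.0
        with pytest.raises(DataError, match="CFP"):
            compute_ratio(bad, "spotX")


class TestIratioResponse:
    def test_flat_trace_gives_zero(self):
        rt = compute_ratio(flat_trace(), "s")
        out = iratio_response(rt, SCHEDULE, exposure_duration=60.0)
        assert out[0].iratio == 0.0

    def test_dip_is_floored_at_zero(self):
        t = np.arange(0, 400.0, 1.0)
        dip = -0.2 * np.exp(-((t - 150.0) ** 2) / (2 * 20.0**2))
        rt = RatioTrace("s", t, 2.0 + dip)
        out = iratio_response(rt, SCHEDULE, exposure_duration=60.0)
        assert 0.0 <= out[0].iratio < 0.005  # never negative, at most ~0

    def test_known_peak_height_recovered(self):
        t = np.arange(0, 400.0, 1.0)
        h = 0.31
        peak = np.where((t >= 140) & (t <= 180), h, 0.0)
        rt = RatioTrace("s", t, 2.0 + peak)
        out = iratio_response(rt, SCHEDULE, exposure_duration=60.0)
        assert out[0].iratio == pytest.approx(h, abs=1e-6)


class TestReferenceCorrect:
    def grids(self):
        t = np.arange(0, 400.0, 1.0)
        dip = -0.1 * np.exp(-((t - 150.0) ** 2) / (2 * 20.0**2))
        peak = 0.25 * np.exp(-((t - 160.0) ** 2) / (2 * 15.0**2))
        return t, dip, peak

    def test_flat_reference_is_identity(self):
        t, dip, peak = self.grids()
        target = RatioTrace("t", t, 2.0 + peak)
        ref = RatioTrace("r", t, np.full_like(t, 1.8))
        out = reference_correct(target, ref)
        assert np.allclose(out.ratio, target.ratio)

    def test_shared_dip_removed_exactly(self):
        t, dip, peak = self.grids()
        target = RatioTrace("t", t, 2.0 + peak + dip)
        ref = RatioTrace("r", t, 1.8 + dip)
        out = reference_correct(target, ref)
        assert np.max(np.abs(out.ratio - (2.0 + peak))) < 1e-9

    def test_identical_curves_flatten(self):
        t, dip, _ = self.grids()
        target = RatioTrace("t", t, 2.0 + dip)
        ref = RatioTrace("r", t, 2.0 + dip)
        out = reference_correct(target, ref)
        assert np.allclose(out.ratio, 2.0)

    def test_grid_mismatch_raises(self):
        t, dip, _ = self.grids()
        with pytest.raises(DataError):
            reference_correct(
                RatioTrace("t", t, 2.0 + dip), RatioTrace("r", t[:-1], (2.0 + dip)[:-1])
            )


def test_mean_trace_requires_common_grid():
    t = np.arange(0, 10.0, 1.0)
    a = RatioTrace("a", t, np.ones_like(t))
    b = RatioTrace("b", t + 0.5, np.ones_like(t))
    with pytest.raises(DataError):
        mean_ratio_trace([a, b])
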