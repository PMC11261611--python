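"""Generator contracts: determinism, receptor phenomenology, controls."""

import numpy as np
import pytest

from tonguechip.array import (
    FLUORESCEIN,
    MOCK,
    SWEET,
    YC_CONTROL,
    AgonistSite,
    ConfigError,
    Injection,
    InjectionSchedule,
    NoiseConfig,
    ReceptorModel,
    make_array,
    saturating_dose,
    simulate_traces,
)
from tonguechip.flowcell import FlowConfig

FLOW = FlowConfig(50.0, 300.0, 300.0)


def model(**kw):
    defaults = dict(
        agonists={"sucrose": AgonistSite(ec50=35.0, hill=1.0, amplitude=0.8)},
        k_act=0.5,
        k_dec=0.2,
        linger_weight=0.1,
        linger_tau=30.0,
    )
    defaults.update(kw)
    return ReceptorModel(**defaults)


def schedule(*comps, spacing=300.0):
    return InjectionSchedule(
        tuple(
            Injection(valve_time=100.0 + i * spacing, sample_id=f"inj{i + 1}",
                      composition=c)
            for i, c in enumerate(comps)
        )
    )


class TestMakeArray:
    def test_deterministic_for_fixed_seed(self):
        a = make_array({SWEET: 11, MOCK: 5}, seed=3)
        b = make_array({SWEET: 11, MOCK: 5}, seed=3)
        assert a == b

    def test_replicate_counts_respected(self):
        spots = make_array({SWEET: 11, MOCK: 5}, seed=0)
        assert sum(s.receptor == SWEET for s in spots) == 11

    def test_pixel_floor_excludes_qc_failures(self):
        spots = make_array({SWEET: 30}, seed=0, pixel_range=(20, 60))
        assert all(s.pixel_count >= 15 for s in spots)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ConfigError):
            make_array({SWEET: 0}, seed=0)

    def test_delays_bounded_by_max_delay(self):
        spots = make_array({SWEET: 10}, seed=0, max_delay=4.0)
        assert max(s.position_delay for s in spots) <= 4.0


def _ratio(trace):
    return trace.yfp / trace.cfp


class TestSimulateTraces:
    def test_bit_identical_for_fixed_seed(self):
        spots = make_array({SWEET: 5}, seed=1)
        kw = dict(
            receptor_models={SWEET: model()},
            flow_config=FLOW,
            schedule=schedule({"sucrose": 100.0}),
            noise=NoiseConfig(cv=0.01),
        )
        a = simulate_traces(spots, seed=7, **kw)
        b = simulate_traces(spots, seed=7, **kw)
        for sid in a.traces:
            assert np.array_equal(a.traces[sid].yfp, b.traces[sid].yfp)
            assert np.array_equal(a.traces[sid].cfp, b.traces[sid].cfp)

    def test_null_input_stays_at_baseline(self):
        spots = make_array({SWEET: 5}, seed=1)
        ts = simulate_traces(
            spots,
            {SWEET: model()},
            FLOW,
            schedule({"sucrose": 0.0}),
            NoiseConfig(cv=0.0),
            seed=0,
        )
        tr = ts.traces[spots[0].spot_id]
        assert np.allclose(tr.yfp, 1000.0)
        assert np.allclose(tr.cfp, 1000.0)

    def test_mock_spot_dips_under_high_osmolarity(self):
        spots = make_array({MOCK: 5}, seed=1)
        ts = simulate_traces(
            spots,
            {},
            FLOW,
            schedule({"sucrose": 500.0}),
            NoiseConfig(cv=0.0, dip_gain=0.05),
            seed=0,
        )
        r = _ratio(ts.traces[spots[0].spot_id])
        assert r.min() < r[0] - 1e-4

    def test_sensor_control_ratio_constant(self):
        spots = make_array({YC_CONTROL: 5}, seed=1)
        ts = simulate_traces(
            spots,
            {},
            FLOW,
            schedule({"sucrose": 500.0, FLUORESCEIN: 1.0}),
            NoiseConfig(cv=0.0, dip_gain=0.05),
            seed=0,
        )
        r = _ratio(ts.traces[spots[0].spot_id])
        assert np.allclose(r, r[0], atol=1e-9)

    def test_response_monotone_in_dose_without_noise(self):
        spots = make_array({SWEET: 5}, seed=1)
        doses = [1.0, 5.0, 20.0, 60.0]
        ts = simulate_traces(
            spots,
            {SWEET: model()},
            FLOW,
            schedule(*({"sucrose": d} for d in doses)),
            NoiseConfig(cv=0.0),
            seed=0,
        )
        tr = ts.traces[spots[0].spot_id]
        r = _ratio(tr)
        peaks = []
        for i in range(len(doses)):
            w = (tr.yfp_times >= 100.0 + i * 300.0) & (tr.yfp_times < 400.0 + i * 300.0)
            peaks.append(r[w].max() - r[w][0])
        assert all(b > a for a, b in zip(peaks, peaks[1:]))

    def test_desensitization_shrinks_repeated_saturating_peaks(self):
        m = model(desens_factor=0.6)
        sat = saturating_dose(m.agonists["sucrose"])
        spots = make_array({SWEET: 5}, seed=1)
        ts = simulate_traces(
            spots,
            {SWEET: m},
            FLOW,
            schedule({"sucrose": 2 * sat}, {"sucrose": 2 * sat}),
            NoiseConfig(cv=0.0),
            seed=0,
        )
        tr = ts.traces[spots[0].spot_id]
        r = _ratio(tr)
        w1 = (tr.yfp_times >= 100.0) & (tr.yfp_times < 400.0)
        w2 = (tr.yfp_times >= 400.0) & (tr.yfp_times < 700.0)
        p1 = r[w1].max() - r[w1][0]
        p2 = r[w2].max() - r[w2][0]
        assert p2 < p1 * 0.75

    def test_antagonist_at_ki_doubles_effective_ec50(self):
        # hill = 1: occupancy at dose = 2*EC50 with [I] = Ki equals
        # occupancy at dose = EC50 without antagonist (competitive shift)
        m = model(antagonists={"cyclamate": 10.0})
        spots = make_array({SWEET: 5}, seed=1)

        def peak(composition):
            ts = simulate_traces(
                spots, {SWEET: m}, FLOW, schedule(composition), NoiseConfig(cv=0.0),
                seed=0,
            )
            tr = ts.traces[spots[0].spot_id]
            r = _ratio(tr)
            return r.max() - r[0]

        with_antagonist = peak({"sucrose": 70.0, "cyclamate": 10.0})
        without = peak({"sucrose": 35.0})
        assert with_antagonist == pytest.approx(without, rel=1e-3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ConfigError):
            Injection(valve_time=0.0, sample_id="bad", composition={"sucrose": -1.0})

    def test_schedule_requires_increasing_valve_times(self):
        with pytest.raises(ConfigError):
            InjectionSchedule(
                (
                    Injection(valve_time=100.0, sample_id="a", composition={}),
                    Injection(valve_time=50.0, sample_id="b", composition={}),
                )
            )
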