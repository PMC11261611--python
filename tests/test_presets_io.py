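"""Preset contracts, file round-trips and the pipeline runner."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from tonguechip.array import SWEET, ConfigError
from tonguechip.io import RunConfig, SchemaError, read_traces, run_pipeline, write_traces
from tonguechip.presets import PRESET_NAMES, preset


class TestPresets:
    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            preset("no_such_preset")

    def test_sucrose_series_is_ascending_to_100(self):
        sc = preset("fig2_sucrose_series")
        doses = [inj.composition["sucrose"] for inj in sc.schedule]
        assert doses == sorted(doses)
        assert doses[-1] == 100.0
        assert sum(1 for s in sc.layout if s == SWEET) == 1
        assert sc.layout[SWEET] == 11

    def test_all_sweeteners_has_four_series(self):
        series = preset("fig2_all_sweeteners")
        assert set(series) == {"sucrose", "advantame", "saccharine", "aspartame"}
        assert series["advantame"].layout[SWEET] == 15

    def test_blocking_preset_sample_order(self):
        sc = preset("fig4_blocking")
        ids = [inj.sample_id for inj in sc.schedule]
        comps = [dict(inj.composition) for inj in sc.schedule]
        # injections 4..7: pure saccharine, mixture, saccharine again, cyclamate
        assert comps[3] == {"saccharine": 10.0}
        assert comps[4] == {"saccharine": 10.0, "cyclamate": 20.0}
        assert comps[5] == {"saccharine": 10.0}
        assert comps[6] == {"cyclamate": 20.0}
        assert len(ids) == 9

    def test_calibration_preset_has_no_receptor_spots(self):
        sc = preset("table1_calibration")
        assert sc.layout == {}
        ts = sc.simulate(seed=0)
        assert len(ts.spots) == 0

    def test_kinetics_presets_carry_dye_reference(self):
        scans = preset("table2_kinetics")
        for sc in scans.values():
            assert sc.schedule.injections[-1].sample_id == "fluorescein"


@pytest.fixture(scope="module")
def trace_set():
    sc = preset("table2_kinetics")["sucrose_high"]
    small = dataclasses.replace(sc, layout={SWEET: 5, "TAS1R1_R3": 5})
    return small.simulate(seed=2)


class TestIoRoundTrip:

    def test_round_trip_equality(self, tmp_path, trace_set):
        write_traces(trace_set, tmp_path)
        back = read_traces(tmp_path)
        assert back.spots == trace_set.spots
        assert len(back.schedule) == len(trace_set.schedule)
        for sid, tr in trace_set.traces.items():
            np.testing.assert_allclose(back.traces[sid].yfp, tr.yfp)
            np.testing.assert_allclose(back.traces[sid].cfp_times, tr.cfp_times)

    def test_missing_channel_column_named(self, tmp_path, trace_set):
        write_traces(trace_set, tmp_path)
        df = pd.read_csv(tmp_path / "traces.csv").drop(columns=["channel"])
        df.to_csv(tmp_path / "traces.csv", index=False)
        with pytest.raises(SchemaError, match="channel"):
            read_traces(tmp_path)

    def test_decreasing_valve_times_rejected(self, tmp_path, trace_set):
        write_traces(trace_set, tmp_path)
        with open(tmp_path / "schedule.json") as fh:
            sched = json.load(fh)
        sched["injections"] = sched["injections"][::-1]
        with open(tmp_path / "schedule.json", "w") as fh:
            json.dump(sched, fh)
        with pytest.raises((SchemaError, ConfigError)):
            read_traces(tmp_path)

    def test_orphan_spot_ids_rejected(self, tmp_path, trace_set):
        write_traces(trace_set, tmp_path)
        with open(tmp_path / "layout.json") as fh:
            layout = json.load(fh)
        with open(tmp_path / "layout.json", "w") as fh:
            json.dump(layout[:-1], fh)
        with pytest.raises(SchemaError, match="unknown spot"):
            read_traces(tmp_path)


class TestRunPipeline:
    def test_calibration_run_writes_16_condition_rows(self, tmp_path):
        cfg = RunConfig(preset="table1_calibration", out_dir=str(tmp_path))
        run_pipeline(cfg)
        df = pd.read_csv(tmp_path / "calibration.csv", comment="#")
        assert len(df) == 16
        assert set(df["flow_rate"]) == {100.0, 300.0, 600.0, 900.0}

    def test_same_seed_reproduces_byte_identical_tables(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            cfg = RunConfig(
                preset="fig2_sucrose_series", seed=5, out_dir=str(tmp_path / sub)
            )
            run_pipeline(cfg)
            outs.append((tmp_path / sub / "iratio.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_config_round_trips_through_yaml(self, tmp_path):
        cfg = RunConfig(preset="fig4_blocking", seed=3, smooth_window=5)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = RunConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg
        assert back.digest() == cfg.digest()


class TestCli:
    def test_calibrate_command_prints_metrics(self, tmp_path):
        from click.testing import CliRunner

        from tonguechip.cli import main

        runner = CliRunner()
        out = tmp_path / "table.csv"
        res = runner.invoke(
            main,
            ["calibrate", "--cell-volume", "50", "--injection-volume", "300",
             "--flow", "600", "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        assert "theoretical exposure 30 s" in res.output
        df = pd.read_csv(out)
        assert df["fwhm_s"].iloc[0] == pytest.approx(30.0, abs=0.5)

    def test_simulate_then_process(self, tmp_path):
        from click.testing import CliRunner

        from tonguechip.cli import main

        runner = CliRunner()
        res = runner.invoke(
            main,
            ["simulate", "--preset", "fig2_sucrose_series", "--seed", "1",
             "--out", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        out_csv = tmp_path / "iratio.csv"
        res = runner.invoke(
            main,
            ["process", "--traces", str(tmp_path / "fig2_sucrose_series"),
             "--out", str(out_csv)],
        )
        assert res.exit_code == 0, res.output
        df = pd.read_csv(out_csv)
        assert {"spot_id", "receptor", "sample_id", "iratio"} <= set(df.columns)
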