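"""File formats, run configuration and the end-to-end pipeline runner.

On-disk layout of a run directory (all text formats):

* ``traces.csv`` — long format, columns ``time_s, spot_id, channel,
  intensity`` with channel in {CFP, YFP};
* ``layout.json`` — list of spot records (spot_id, receptor, pixel_count,
  position_delay);
* ``schedule.json`` — the flow configuration plus the ordered injection
  list (valve_time, sample_id, composition in mM).

Times are seconds as floats; concentrations are mM.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .array import (
    ChannelTrace,
    Injection,
    InjectionSchedule,
    SpotRecord,
    TraceSet,
)
from .flowcell import FlowConfig

__all__ = [
    "SchemaError",
    "write_traces",
    "read_traces",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Raised when an input file does not match the documented dialect."""


def write_traces(trace_set: TraceSet, out_dir: str | Path) -> Path:
    """Write a trace set to ``traces.csv`` + ``layout.json`` + ``schedule.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for spot_id, tr in trace_set.traces.items():
        frames.append(
            pd.DataFrame(
                {"time_s": tr.cfp_times, "spot_id": spot_id, "channel": "CFP",
                 "intensity": tr.cfp}
            )
        )
        frames.append(
            pd.DataFrame(
                {"time_s": tr.yfp_times, "spot_id": spot_id, "channel": "YFP",
                 "intensity": tr.yfp}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(out / "traces.csv", index=False)
    with open(out / "layout.json", "w") as fh:
        json.dump([dataclasses.asdict(s) for s in trace_set.spots], fh, indent=1)
    with open(out / "schedule.json", "w") as fh:
        json.dump(
            {
                "flow_config": dataclasses.asdict(trace_set.flow_config),
                "injections": [
                    {
                        "valve_time": inj.valve_time,
                        "sample_id": inj.sample_id,
                        "composition": dict(inj.composition),
                    }
                    for inj in trace_set.schedule
                ],
            },
            fh,
            indent=1,
        )
    return out


def read_traces(path: str | Path) -> TraceSet:
    """Read a run directory back into validated in-memory objects.

    Unknown receptor names are preserved as opaque labels; schema
    violations raise :class:`SchemaError` naming the offending column or
    row.
    """
    path = Path(path)
    df = pd.read_csv(path / "traces.csv")
    required = {"time_s", "spot_id", "channel", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"traces.csv is missing column(s) {sorted(missing)}")
    bad_channel = ~df["channel"].isin(["CFP", "YFP"])
    if bad_channel.any():
        row = int(np.flatnonzero(bad_channel.to_numpy())[0]) + 2  # 1-based + header
        raise SchemaError(f"traces.csv row {row}: unknown channel {df['channel'][bad_channel.idxmax()]!r}")

    with open(path / "layout.json") as fh:
        layout_raw = json.load(fh)
    spots = []
    for i, rec in enumerate(layout_raw):
        try:
            spots.append(
                SpotRecord(
                    spot_id=rec["spot_id"],
                    receptor=rec["receptor"],
                    pixel_count=int(rec["pixel_count"]),
                    position_delay=float(rec.get("position_delay", 0.0)),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"layout.json entry {i}: missing field {exc}") from exc

    with open(path / "schedule.json") as fh:
        sched_raw = json.load(fh)
    flow = FlowConfig(**sched_raw["flow_config"])
    try:
        schedule = InjectionSchedule(
            tuple(
                Injection(
                    valve_time=float(inj["valve_time"]),
                    sample_id=inj["sample_id"],
                    composition={k: float(v) for k, v in inj["composition"].items()},
                )
                for inj in sched_raw["injections"]
            )
        )
    except ValueError as exc:
        raise SchemaError(f"schedule.json: {exc}") from exc

    known = {s.spot_id for s in spots}
    orphan = set(df["spot_id"].unique()) - known
    if orphan:
        raise SchemaError(f"traces.csv references unknown spot ids {sorted(orphan)[:5]}")

    traces = {}
    for spot in spots:
        sub = df[df["spot_id"] == spot.spot_id]
        c = sub[sub["channel"] == "CFP"].sort_values("time_s")
        y = sub[sub["channel"] == "YFP"].sort_values("time_s")
        for name, ch in (("CFP", c), ("YFP", y)):
            t = ch["time_s"].to_numpy(float)
            if t.size and np.any(np.diff(t) <= 0):
                raise SchemaError(f"{spot.spot_id}/{name}: non-monotone time_s")
        traces[spot.spot_id] = ChannelTrace(
            cfp_times=c["time_s"].to_numpy(float),
            cfp=c["intensity"].to_numpy(float),
            yfp_times=y["time_s"].to_numpy(float),
            yfp=y["intensity"].to_numpy(float),
        )
    return TraceSet(spots=tuple(spots), traces=traces, schedule=schedule, flow_config=flow)


@dataclasses.dataclass
class RunConfig:
    """Everything needed to (re)produce one analysis run."""

    preset: str | None = None          # generate input from this preset ...
    input_dir: str | None = None       # ... or load it from this directory
    seed: int = 0
    out_dir: str = "toc_run"
    # processing
    smooth_window: int = 3
    dt_out: float = 1.0
    min_pixels: int = 15
    min_replicates: int = 5
    window_extension: float = 120.0
    # kinetics
    sync_time: float = 50.0
    onset_mode: str = "peak_max"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        """Hash of every analysis-relevant field (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_with_hash(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> process -> preset-specific analyses.

    Writes all result tables plus ``run_log.json`` (parameters, seed,
    package version, config hash) into ``config.out_dir`` and returns the
    in-memory results keyed by stage.
    """
    from . import __version__
    from .flowcell import calibration_table
    from .pipeline import blocking_analysis, dose_response_fit, kinetics_run
    from .presets import preset as get_preset
    from .processing import iratio_table

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.digest()
    results: dict = {}
    proc_kwargs = dict(
        smooth_window=config.smooth_window,
        dt_out=config.dt_out,
        min_pixels=config.min_pixels,
        min_replicates=config.min_replicates,
        window_extension=config.window_extension,
    )

    stage = "setup"
    try:
        if config.preset == "table1_calibration":
            stage = "calibrate"
            table = calibration_table()
            _write_with_hash(table, out / "calibration.csv", chash)
            results["calibration"] = table
        elif config.preset is not None:
            scen = get_preset(config.preset)
            scenarios = scen if isinstance(scen, dict) else {config.preset: scen}
            fits, kin_rows, iratio_frames = {}, [], []
            for key, sc in scenarios.items():
                stage = f"simulate[{key}]"
                ts = sc.simulate(seed=config.seed)
                write_traces(ts, out / "traces" / key)
                stage = f"process[{key}]"
                table = iratio_table(
                    ts, reference_receptor=sc.reference_receptor, **proc_kwargs
                )
                table.insert(0, "scenario", key)
                iratio_frames.append(table)
                if sc.sample_doses and len(sc.sample_doses) >= 4:
                    stage = f"fit[{key}]"
                    fits[key] = dose_response_fit(
                        ts,
                        dict(sc.sample_doses),
                        aggregate="mean_trace",
                        smooth_window=config.smooth_window,
                        dt_out=config.dt_out,
                        window_extension=config.window_extension,
                    )
                if any(i.sample_id == "fluorescein" for i in sc.schedule):
                    stage = f"kinetics[{key}]"
                    agonist = next(
                        i.sample_id for i in sc.schedule if i.sample_id != "fluorescein"
                    )
                    m = kinetics_run(ts, agonist)
                    kin_rows.append(
                        {
                            "scenario": key,
                            "sample": agonist,
                            "onset_s": m.onset,
                            "fwhm_s": m.fwhm,
                            "delta_fwhm_s": (
                                m.delta_fwhm_lingering
                                if m.delta_fwhm_lingering is not None
                                else "none"
                            ),
                            "max_rise_pct_s": m.max_rise,
                            "max_fall_pct_s": m.max_fall,
                            "rel_rise_pct": m.rel_rise,
                            "rel_fall_pct": m.rel_fall,
                        }
                    )
                if config.preset == "fig4_blocking":
                    stage = f"contrasts[{key}]"
                    blk = blocking_analysis(ts, **proc_kwargs)
                    results["blocking"] = blk
                    cdf = pd.DataFrame([dataclasses.asdict(c) for c in blk.contrasts])
                    _write_with_hash(cdf, out / "contrasts.csv", chash)
                    bdf = pd.DataFrame(
                        [{"receptor": r, "blocking_pct": v} for r, v in blk.blocking.items()]
                    )
                    _write_with_hash(bdf, out / "blocking.csv", chash)
            if iratio_frames:
                _write_with_hash(
                    pd.concat(iratio_frames, ignore_index=True), out / "iratio.csv", chash
                )
            if fits:
                results["fits"] = fits
                with open(out / "fits.json", "w") as fh:
                    json.dump(
                        {k: dataclasses.asdict(f) for k, f in fits.items()}, fh, indent=1
                    )
            if kin_rows:
                kdf = pd.DataFrame(kin_rows)
                _write_with_hash(kdf, out / "kinetics.csv", chash)
                results["kinetics"] = kdf
        elif config.input_dir is not None:
            stage = "read"
            ts = read_traces(config.input_dir)
            stage = "process"
            table = iratio_table(ts, **proc_kwargs)
            _write_with_hash(table, out / "iratio.csv", chash)
            results["iratio"] = table
        else:
            raise ValueError("RunConfig needs either a preset or an input_dir")
    except Exception as exc:
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise

    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(config),
                "config_hash": chash,
                "version": __version__,
            },
            fh,
            indent=1,
        )
    return results
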