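"""From raw two-channel traces to QC-filtered ratio signals and iRatio peaks.

The ratio is acceptor/donor (YFP/CFP) so that a calcium rise produces an
upward peak.  Because the two channels are recorded on interleaved
timestamps, each channel is smoothed and linearly interpolated onto a
common uniform grid before dividing.  The response statistic per spot and
injection is the iRatio: the maximum ratio within the injection window
minus the ratio at the window start, floored at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array import ChannelTrace, InjectionSchedule, SpotRecord, TraceSet
from .flowcell import theoretical_exposure

__all__ = [
    "RatioTrace",
    "PeakResponse",
    "AllFilteredError",
    "DataError",
    "qc_filter",
    "compute_ratio",
    "iratio_response",
    "reference_correct",
    "mean_ratio_trace",
    "iratio_table",
]

log = logging.getLogger(__name__)


class AllFilteredError(ValueError):
    """Raised when quality control removes every spot."""


class DataError(ValueError):
    """Raised for invalid raw trace data."""


@dataclass(frozen=True)
class RatioTrace:
    spot_id: str
    times: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        r = np.asarray(self.ratio, float)
        if t.ndim != 1 or t.shape != r.shape:
            raise DataError(f"{self.spot_id}: malformed ratio trace")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ratio", r)


@dataclass(frozen=True)
class PeakResponse:
    spot_id: str
    injection_id: str
    iratio: float
    baseline: float
    window: tuple[float, float]


def qc_filter(
    spots: Sequence[SpotRecord],
    min_pixels: int = 15,
    min_replicates: int = 5,
) -> list[SpotRecord]:
    """Remove undersized spots, then underreplicated receptor groups.

    Spots with fewer than ``min_pixels`` fluorescent pixels are dropped
    first; any receptor type left with fewer than ``min_replicates``
    surviving spots is then dropped entirely.  Both thresholds are strict
    ("fewer than"), so a 15-pixel spot and a 5-replicate group survive.
    """
    sized = []
    for s in spots:
        if s.pixel_count < min_pixels:
            log.info("QC: dropping %s (%d px < %d)", s.spot_id, s.pixel_count, min_pixels)
        else:
            sized.append(s)
    counts: dict[str, int] = {}
    for s in sized:
        counts[s.receptor] = counts.get(s.receptor, 0) + 1
    kept = []
    for s in sized:
        if counts[s.receptor] < min_replicates:
            log.info(
                "QC: dropping %s (group %s has %d < %d replicates)",
                s.spot_id, s.receptor, counts[s.receptor], min_replicates,
            )
        else:
            kept.append(s)
    if not kept:
        raise AllFilteredError("quality control removed every spot")
    return kept


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(window - 1 - pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")


def compute_ratio(
    trace: ChannelTrace,
    spot_id: str,
    smooth_window: int = 3,
    dt_out: float = 1.0,
) -> RatioTrace:
    """Smooth, co-interpolate and divide the two channels of one spot.

    Each channel is smoothed with a short moving average and linearly
    interpolated onto a shared uniform grid (removing the interleaved
    sampling offset); the ratio is acceptor/donor.
    """
    for name, inten in (("CFP", trace.cfp), ("YFP", trace.yfp)):
        if len(inten) == 0:
            raise DataError(f"{spot_id}: empty {name} channel")
        if np.any(inten <= 0):
            t_bad = (trace.cfp_times if name == "CFP" else trace.yfp_times)[
                int(np.argmax(inten <= 0))
            ]
            raise DataError(f"{spot_id}: non-positive {name} intensity at t={t_bad:.1f} s")
    c_s = _smooth(np.asarray(trace.cfp, float), smooth_window)
    y_s = _smooth(np.asarray(trace.yfp, float), smooth_window)
    t0 = max(trace.cfp_times[0], trace.yfp_times[0])
    t1 = min(trace.cfp_times[-1], trace.yfp_times[-1])
    grid = np.arange(t0, t1 + dt_out / 2, dt_out)
    c_i = np.interp(grid, trace.cfp_times, c_s)
    y_i = np.interp(grid, trace.yfp_times, y_s)
    return RatioTrace(spot_id=spot_id, times=grid, ratio=y_i / c_i)


def iratio_response(
    ratio_trace: RatioTrace,
    schedule: InjectionSchedule,
    exposure_duration: float,
    window_extension: float = 120.0,
    baseline_window: float = 10.0,
    transit_offset: float = 0.0,
) -> list[PeakResponse]:
    """iRatio (window max minus window-start baseline, floored at 0).

    The window for each injection starts at the valve time plus the
    array-transit offset and spans the exposure duration plus
    ``window_extension``; it is truncated at the next injection's start.
    The baseline is the mean ratio over the ``baseline_window`` seconds
    preceding the window start.
    """
    t, r = ratio_trace.times, ratio_trace.ratio
    out = []
    starts = [inj.valve_time + transit_offset for inj in schedule]
    for j, inj in enumerate(schedule):
        w0 = starts[j]
        w1 = w0 + exposure_duration + window_extension
        if j + 1 < len(starts):
            w1 = min(w1, starts[j + 1])
        if w1 > t[-1]:
            log.warning("window for %s truncated at trace end", inj.sample_id)
            w1 = t[-1]
        base_mask = (t >= w0 - baseline_window) & (t < w0)
        baseline = float(r[base_mask].mean()) if base_mask.any() else float(
            np.interp(w0, t, r)
        )
        in_win = (t >= w0) & (t <= w1)
        peak = float(r[in_win].max()) if in_win.any() else baseline
        out.append(
            PeakResponse(
                spot_id=ratio_trace.spot_id,
                injection_id=inj.sample_id,
                iratio=max(peak - baseline, 0.0),
                baseline=baseline,
                window=(w0, w1),
            )
        )
    return out


def reference_correct(target: RatioTrace, reference: RatioTrace) -> RatioTrace:
    """Subtract a non-responding reference's deviation from its baseline.

    Removes non-specific shared artifacts (the osmotic dip) from the target
    while preserving the receptor-specific peak:
    ``corrected(t) = target(t) - (reference(t) - reference_baseline)``,
    where the reference baseline is its initial value.
    """
    if target.times.shape != reference.times.shape or not np.allclose(
        target.times, reference.times
    ):
        raise DataError("target and reference traces are on different grids")
    ref_baseline = float(reference.ratio[0])
    return RatioTrace(
        spot_id=target.spot_id,
        times=target.times,
        ratio=target.ratio - (reference.ratio - ref_baseline),
    )


def mean_ratio_trace(traces: Sequence[RatioTrace], spot_id: str = "mean") -> RatioTrace:
    """Pointwise mean of ratio traces sharing one grid."""
    if not traces:
        raise DataError("no traces to average")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise DataError("traces are on different grids")
    return RatioTrace(
        spot_id=spot_id,
        times=t0,
        ratio=np.mean([tr.ratio for tr in traces], axis=0),
    )


def iratio_table(
    trace_set: TraceSet,
    smooth_window: int = 3,
    dt_out: float = 1.0,
    min_pixels: int = 15,
    min_replicates: int = 5,
    window_extension: float = 120.0,
    reference_receptor: str | None = None,
) -> pd.DataFrame:
    """End-to-end processing of a trace set into a tidy iRatio table.

    Applies QC, computes per-spot ratio traces, optionally subtracts the
    mean trace of a non-responding reference receptor group (umami or
    mock) from every other spot, and extracts one iRatio per spot and
    injection.  Columns: spot_id, receptor, injection_id, sample_id, iratio.
    """
    kept = qc_filter(trace_set.spots, min_pixels=min_pixels, min_replicates=min_replicates)
    ratios = {
        s.spot_id: compute_ratio(
            trace_set.traces[s.spot_id], s.spot_id, smooth_window, dt_out
        )
        for s in kept
    }
    if reference_receptor is not None:
        ref_traces = [ratios[s.spot_id] for s in kept if s.receptor == reference_receptor]
        if ref_traces:
            ref_mean = mean_ratio_trace(ref_traces, spot_id=reference_receptor)
            ratios = {
                sid: (
                    reference_correct(tr, ref_mean)
                    if _receptor_of(kept, sid) != reference_receptor
                    else tr
                )
                for sid, tr in ratios.items()
            }
    exposure = theoretical_exposure(trace_set.flow_config)
    rows = []
    for s in kept:
        for i, resp in enumerate(
            iratio_response(
                ratios[s.spot_id],
                trace_set.schedule,
                exposure_duration=exposure,
                window_extension=window_extension,
            )
        ):
            rows.append(
                {
                    "spot_id": s.spot_id,
                    "receptor": s.receptor,
                    "injection_id": i + 1,
                    "sample_id": resp.injection_id,
                    "iratio": resp.iratio,
                }
            )
    return pd.DataFrame(rows)


def _receptor_of(spots: Sequence[SpotRecord], spot_id: str) -> str:
    for s in spots:
        if s.spot_id == spot_id:
            return s.receptor
    raise KeyError(spot_id)
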