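"""Sensory-analog kinetic metrics of a response peak.

All metrics are expressed relative to the fluorescein dye peak of the same
run, which traces the physical sample exposure.  Onset (the delay of the
response peak maximum behind the dye peak maximum) is the in vitro analog
of "time to peak sweetness"; Δfwhm (the excess full width at half maximum
of the response over the dye peak) is the analog of "lingering".  Curves
are first synchronized to a common valve time and normalized so baseline
is 0% and the peak maximum is 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flowcell import NoPeakError, peak_width_half_max

__all__ = [
    "PercentCurve",
    "KineticMetrics",
    "DegenerateCurveError",
    "normalize_and_sync",
    "peak_fwhm",
    "onset",
    "lingering",
    "slope_metrics",
    "kinetic_metrics",
]


class DegenerateCurveError(ValueError):
    """Raised when a curve has no dynamic range to normalize."""


@dataclass(frozen=True)
class PercentCurve:
    """A peak curve on a uniform grid, baseline 0 %, maximum 100 %."""

    times: np.ndarray
    values: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class KineticMetrics:
    """Table of peak kinetics relative to the dye reference.

    ``delta_fwhm_lingering`` is None when the response is no wider than
    the reference (no measurable lingering).
    """

    onset: float
    onset_uncertainty: float
    fwhm: float
    delta_fwhm_lingering: float | None
    max_rise: float        # %/s
    max_fall: float        # %/s, negative
    rel_rise: float        # % of reference max rise
    rel_fall: float        # % of reference max fall
    onset90: float | None = None


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(window - 1 - pad, y[-1])])
    return np.convolve(padded, np.ones(window) / window, mode="valid")


def normalize_and_sync(
    times: np.ndarray,
    values: np.ndarray,
    valve_time: float,
    sync_time: float = 50.0,
    baseline_window: float = 10.0,
    smooth_window: int = 5,
) -> PercentCurve:
    """Shift a curve so its valve event sits at ``sync_time`` and rescale
    to percent of peak.

    The baseline is the mean over ``baseline_window`` seconds before the
    valve event; the maximum maps to 100 %.  A short moving average
    (``smooth_window`` samples) stabilises the peak position against
    channel noise before normalization.
    """
    t = np.asarray(times, float)
    y = _moving_average(np.asarray(values, float), smooth_window)
    base_mask = (t >= valve_time - baseline_window) & (t < valve_time)
    baseline = float(y[base_mask].mean()) if base_mask.any() else float(y[0])
    peak = float(y.max())
    if peak <= baseline:
        raise DegenerateCurveError("curve has no dynamic range above baseline")
    pct = (y - baseline) / (peak - baseline) * 100.0
    return PercentCurve(times=t - valve_time + sync_time, values=pct)


def peak_fwhm(curve: PercentCurve, min_excursion: float = 0.0) -> float:
    """Width between the first upward and last downward 50 % crossing.

    Crossings are linearly interpolated against the fixed 50 % line.
    Optionally, excursions above 50 % shorter than ``min_excursion``
    seconds can be ignored (off by default: on genuinely shallow tails a
    debounce eats real crossings and underestimates the width).
    """
    t, y = curve.times, curve.values
    above = y >= 50.0
    if not above.any() or above.all():
        raise NoPeakError("curve does not cross 50% twice")
    idx = np.flatnonzero(above)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    runs = [r for r in runs if (t[r[-1]] - t[r[0]]) >= min_excursion]
    if not runs:
        raise NoPeakError("no half-maximum excursion longer than the debounce window")
    i0, i1 = runs[0][0], runs[-1][-1]
    if i0 == 0 or i1 == len(y) - 1:
        raise NoPeakError("peak is truncated at the grid boundary")

    def interp(a: int, b: int) -> float:
        return (
            float(t[a] + (50.0 - y[a]) / (y[b] - y[a]) * (t[b] - t[a]))
            if y[b] != y[a]
            else float(t[b])
        )

    return interp(i1, i1 + 1) - interp(i0 - 1, i0)


def _first_max_time(
    curve: PercentCurve, level: float | None = None, peak_band: float = 5.0
) -> float:
    """Peak time of a curve (or its first crossing of ``level``).

    The peak time is the centroid of the samples within ``peak_band`` % of
    the maximum.  A raw argmax is noise-selected on curves whose top is
    broad (a hazard of long sample exposures); the centroid treats the
    near-maximum band symmetrically, so measurement noise perturbs it
    without biasing it toward either flank, and a band of a few percent
    averages enough samples to keep the peak time stable.
    """
    if level is None:
        near = curve.values >= curve.values.max() - peak_band
        return float(curve.times[near].mean())
    idx = np.flatnonzero(curve.values >= level)
    if idx.size == 0:
        raise NoPeakError(f"curve never reaches {level}%")
    i = idx[0]
    if i == 0:
        return float(curve.times[0])
    t0, t1 = curve.times[i - 1], curve.times[i]
    y0, y1 = curve.values[i - 1], curve.values[i]
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0)) if y1 != y0 else float(t1)


def onset(
    response: PercentCurve,
    reference: PercentCurve,
    mode: str = "peak_max",
) -> tuple[float, float]:
    """Delay of the response maximum behind the reference maximum.

    ``mode='peak_max'`` locates each curve's peak as the centroid of its
    near-maximum band (see :func:`_first_max_time`); ``mode='p90'`` uses
    the first upward crossing of 90 % instead, an alternative that is
    robust when the exposure produces broad peak plateaus.  Returns
    (onset, uncertainty), the uncertainty being one interpolation grid
    step.
    """
    import warnings

    if mode == "peak_max":
        t_resp = _first_max_time(response)
        t_ref = _first_max_time(reference)
        fw = peak_fwhm(response)
        plateau = np.flatnonzero(response.values >= 100.0 - 1e-9)
        if plateau.size > 1 and (plateau[-1] - plateau[0]) * response.dt > 0.25 * fw:
            warnings.warn("broad response maximum; onset may be unreliable", stacklevel=2)
    elif mode == "p90":
        t_resp = _first_max_time(response, level=90.0)
        t_ref = _first_max_time(reference, level=90.0)
    else:
        raise ValueError(f"unknown onset mode {mode!r}")
    return t_resp - t_ref, max(response.dt, reference.dt)


def lingering(response: PercentCurve, reference: PercentCurve) -> float | None:
    """Δfwhm of the response over the reference; None when not positive."""
    delta = peak_fwhm(response) - peak_fwhm(reference)
    return delta if delta > 0 else None


def slope_metrics(
    response: PercentCurve,
    reference: PercentCurve,
) -> tuple[float, float, float, float]:
    """Extreme rise/fall rates (%/s) and their size relative to the reference.

    Returns (max_rise, max_fall, rel_rise_pct, rel_fall_pct); the relative
    values are response extremum over reference extremum, in percent.
    """
    def extrema(c: PercentCurve) -> tuple[float, float]:
        d = np.gradient(c.values, c.times)
        return float(d.max()), float(d.min())

    r_up, r_dn = extrema(response)
    f_up, f_dn = extrema(reference)
    rel_rise = 100.0 * r_up / f_up if f_up != 0 else float("nan")
    rel_fall = 100.0 * r_dn / f_dn if f_dn != 0 else float("nan")
    return r_up, r_dn, rel_rise, rel_fall


def kinetic_metrics(
    response: PercentCurve,
    reference: PercentCurve,
    onset_mode: str = "peak_max",
) -> KineticMetrics:
    """All Table-style kinetics of a response curve vs its dye reference."""
    on, unc = onset(response, reference, mode=onset_mode)
    on90 = None
    if onset_mode == "peak_max":
        try:
            on90, _ = onset(response, reference, mode="p90")
        except NoPeakError:
            on90 = None
    fw = peak_fwhm(response)
    rise, fall, rel_rise, rel_fall = slope_metrics(response, reference)
    return KineticMetrics(
        onset=on,
        onset_uncertainty=unc,
        fwhm=fw,
        delta_fwhm_lingering=lingering(response, reference),
        max_rise=rise,
        max_fall=fall,
        rel_rise=rel_rise,
        rel_fall=rel_fall,
        onset90=on90,
    )
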