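"""Hill-equation concentration-response fitting and threshold estimation.

The four-parameter logistic r(C) = bottom + (top - bottom) * C^h / (C^h +
EC50^h) is fitted by least squares in log10-dose space (which conditions
the problem well over the multi-decade dose ranges typical of tastants).
EC10, proposed as an in vitro taste-threshold analog, follows from the
closed-form inverse of the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["HillFit", "FitError", "fit_hill", "ec_fraction"]


class FitError(ValueError):
    """Raised for unusable dose-response input."""


@dataclass(frozen=True)
class HillFit:
    ec50: float
    hill: float
    top: float
    bottom: float
    se: dict  # parameter -> standard error (nan if unavailable)
    converged: bool
    n_points: int
    message: str = ""


def _logistic(logc: np.ndarray, bottom: float, top: float, log_ec50: float, h: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (h * (log_ec50 - logc)))


def fit_hill(doses, responses, top_cap: float | None = None) -> HillFit:
    """Least-squares Hill fit of per-spot (or per-dose mean) responses.

    Requires at least four distinct positive doses and a non-zero dynamic
    range.  Initialisation: bottom = min, top = max, EC50 = geometric mean
    of the doses, slope 1; bounds keep EC50 within a decade of the tested
    range and the slope in (0, 10].  ``top_cap`` optionally bounds the
    fitted maximum at ``top_cap * max(responses)``; with few dose points
    the top and the EC50 trade off along a ridge, and a mild cap (the
    assumption that the highest tested dose comes within ~1/top_cap of
    saturating the receptor) conditions the fit.  Non-convergence is
    reported on the returned object, never silently.
    """
    d = np.asarray(doses, float)
    r = np.asarray(responses, float)
    if d.shape != r.shape:
        raise FitError("doses and responses differ in length")
    if np.any(d <= 0):
        raise FitError("doses must be positive")
    distinct = np.unique(d)
    if distinct.size < 4:
        raise FitError(f"need >= 4 distinct doses, got {distinct.size}")
    if np.ptp(r) <= 0:
        raise FitError("responses have zero dynamic range")
    logc = np.log10(d)
    p0 = [r.min(), r.max(), float(np.mean(np.log10(distinct))), 1.0]
    lo = [-np.inf, -np.inf, np.log10(distinct.min() / 10.0), 1e-3]
    hi = [np.inf, np.inf, np.log10(distinct.max() * 10.0), 10.0]
    if top_cap is not None:
        hi[1] = top_cap * float(r.max())
        lo[1] = 0.0
        p0[1] = min(p0[1], 0.99 * hi[1])
    try:
        popt, pcov = curve_fit(
            _logistic, logc, r, p0=p0, bounds=(lo, hi), maxfev=20000
        )
        perr = np.sqrt(np.diag(pcov))
        converged, message = True, ""
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        popt, perr = p0, [np.nan] * 4
        converged, message = False, str(exc)
    bottom, top, log_ec50, h = popt
    ec50 = 10.0**log_ec50
    se = {
        "bottom": float(perr[0]),
        "top": float(perr[1]),
        "ec50": float(ec50 * np.log(10.0) * perr[2]),  # delta method
        "hill": float(perr[3]),
    }
    if converged and top <= bottom:
        converged, message = False, "fitted top <= bottom"
    return HillFit(
        ec50=float(ec50),
        hill=float(h),
        top=float(top),
        bottom=float(bottom),
        se=se,
        converged=converged,
        n_points=int(distinct.size),
        message=message,
    )


def ec_fraction(fit: HillFit, f: float) -> float:
    """Concentration producing fraction ``f`` of the maximal response.

    Closed form: EC50 * (f / (1 - f))^(1/h); EC10 (f = 0.1) is the
    proposed taste-threshold analog.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("f must be in (0, 1)")
    if not fit.converged:
        raise FitError("cannot invert a non-converged fit")
    return fit.ec50 * (f / (1.0 - f)) ** (1.0 / fit.hill)
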