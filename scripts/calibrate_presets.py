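"""One-off derivation of the preset kinetic and antagonism constants.

The synthetic presets must reproduce, on the noiseless end-to-end
pipeline, the platform's published response kinetics (onset and Δfwhm
lingering per sweetener) and the cyclamate blocking percentages of the
bitter receptors.  The raw traces behind those numbers are not published,
so the generator constants cannot be read off data; instead this script
searches for them:

* per sweetener, a coarse grid plus shrinking random search and a
  Nelder-Mead polish over (k_act, k_dec, linger_weight, linger_tau,
  adapt_weight, adapt_tau), minimising the squared error of
  (onset, Δfwhm) at the maximal dose against the published values, with
  secondary terms that keep the apparent EC50 of the dose series on the
  published midpoint, the peak response above the noise detection floor,
  and — among noiseless-correct candidates — the noisy-median estimate in
  agreement with the noiseless one (curve shapes whose metrics are only
  well-defined without noise are rejected);
* per bitter receptor, a bisection on the cyclamate Ki so that the
  noiseless blocking percentage matches the published reduction.

Run from the repository root:

    python scripts/calibrate_presets.py

and paste the printed constants into ``src/tonguechip/presets.py``
(SWEET_KINETICS and CYCLAMATE_KI).  The constants shipped there were
produced by this script.
"""

from __future__ import annotations

import dataclasses
import sys

import numpy as np
from scipy import optimize

from tonguechip.array import MOCK, SWEET, UMAMI, NoiseConfig, ReceptorModel
from tonguechip.pipeline import blocking_analysis, dose_response_fit, kinetics_run
from tonguechip.presets import (
    CYCLAMATE_KI,
    DOSE_SERIES,
    KINETICS_DOSES,
    SWEET_SITES,
    _dose_series_scenario,
    _fig4_scenario,
    _kinetics_scenario,
)

NOISELESS = NoiseConfig(cv=0.0, dip_gain=0.02)

#: published (onset s, Δfwhm lingering s) at the maximal dose
KINETIC_TARGETS = {
    "sucrose": (13.0, 6.0),
    "advantame": (5.0, 39.0),
    "aspartame": (18.0, 12.0),
    "saccharine": (16.0, 25.0),
}

#: published % signal reduction by 20 mM cyclamate
BLOCKING_TARGETS = {"TAS2R8": 33.0, "TAS2R31": 48.0, "TAS2R43": 92.0}


#: physiological bounds on the kinetic constants (rates 1/s, taus s)
KINETIC_BOUNDS = dict(k_act=(0.02, 5.0), k_dec=(0.02, 5.0), lw=(0.0, 0.9),
                      ltau=(2.0, 400.0), aw=(0.0, 0.9), atau=(5.0, 400.0))


def _out_of_bounds(kin: tuple) -> bool:
    k_act, k_dec, lw, ltau, aw, atau = kin
    b = KINETIC_BOUNDS
    return not (
        b["k_act"][0] <= k_act <= b["k_act"][1]
        and b["k_dec"][0] <= k_dec <= b["k_dec"][1]
        and lw <= b["lw"][1]
        and b["ltau"][0] <= ltau <= b["ltau"][1]
        and aw <= b["aw"][1]
        and b["atau"][0] <= atau <= b["atau"][1]
    )


def _model_for(ligand: str, kin: tuple) -> ReceptorModel:
    k_act, k_dec, lw, ltau, aw, atau = kin
    return ReceptorModel(
        agonists={ligand: SWEET_SITES[ligand]},
        k_act=k_act,
        k_dec=k_dec,
        linger_weight=lw,
        linger_tau=ltau,
        adapt_weight=aw,
        adapt_tau=atau,
    )


def _dose_scenario(ligand: str, kin: tuple):
    doses, _ = DOSE_SERIES[ligand]
    sc = _dose_series_scenario("cal", ligand, doses, 5)
    return dataclasses.replace(
        sc,
        layout={SWEET: 5, UMAMI: 5},
        models={SWEET: _model_for(ligand, kin)},
        noise=NOISELESS,
    )


def _full_scenario(ligand: str, kin: tuple, noise):
    """Kinetics scenario at the preset's real replication level."""
    from tonguechip.presets import STANDARD_NOISE  # noqa: F401

    dose = KINETICS_DOSES[ligand][1]
    sc = _kinetics_scenario(ligand, dose, "cal")
    return dataclasses.replace(sc, models={SWEET: _model_for(ligand, kin)}, noise=noise)


def ec50_recovery_error(kin: tuple, ligand: str) -> float:
    """Noiseless dose-series fit must recover the generator midpoint.

    Broad temporal filtering attenuates narrow (sub-saturating) occupancy
    peaks more than wide saturated ones, which drags the apparent EC50 off
    the published value; penalise that bias so the search prefers kinetic
    solutions under which the peak statistic is dose-faithful.  A soft
    amplitude floor keeps the peak response above the channel-noise
    detection floor.
    """
    sc = _dose_scenario(ligand, kin)
    ts = sc.simulate(seed=0)
    try:
        fit = dose_response_fit(ts, dict(sc.sample_doses), aggregate="mean_trace")
    except ValueError:
        return 1e6
    if not fit.converged:
        return 1e6
    err = float((np.log(fit.ec50 / SWEET_SITES[ligand].ec50) / 0.10) ** 2)
    from tonguechip.pipeline import mean_trace_responses

    top_dose_sample = max(sc.sample_doses, key=sc.sample_doses.get)
    peak = mean_trace_responses(ts)[top_dose_sample]
    if peak < 0.05:
        err += ((0.05 - peak) * 150.0) ** 2
    return err


def kinetic_error(kin: tuple, ligand: str) -> float:
    if _out_of_bounds(kin):
        return 1e6
    from tonguechip.presets import STANDARD_NOISE

    dose = KINETICS_DOSES[ligand][1]
    sid = f"{ligand}_{dose:g}mM"
    try:
        m0 = kinetics_run(_full_scenario(ligand, kin, NOISELESS).simulate(seed=0), sid)
    except ValueError:
        return 1e6
    onset_t, dfwhm_t = KINETIC_TARGETS[ligand]
    df0 = m0.delta_fwhm_lingering or 0.0
    # the published kinetic metrics are the primary calibration targets
    err = 16.0 * (m0.onset - onset_t) ** 2 + 8.0 * (df0 - dfwhm_t) ** 2
    if err < 200.0:
        # noise-consistency: among noiseless-correct candidates, prefer
        # curve shapes whose noisy median agrees with the noiseless value
        # (the noiseless value itself stays pinned to the published one)
        ons, dfs = [], []
        for seed in (11, 12, 13, 14, 15, 16):
            m = kinetics_run(
                _full_scenario(ligand, kin, STANDARD_NOISE).simulate(seed=seed), sid
            )
            ons.append(m.onset)
            dfs.append(m.delta_fwhm_lingering or 0.0)
        err += 8.0 * (np.median(ons) - m0.onset) ** 2
        err += 6.0 * (np.median(dfs) - df0) ** 2
        err += ec50_recovery_error(kin, ligand)
    return err


def _unpack(x: np.ndarray) -> tuple:
    k_act = np.exp(x[0])
    k_dec = np.exp(x[1])
    lw = 1.0 / (1.0 + np.exp(-x[2]))  # logit -> (0, 1)
    ltau = np.exp(x[3])
    aw = 1.0 / (1.0 + np.exp(-x[4]))
    atau = np.exp(x[5])
    return k_act, k_dec, float(lw), ltau, float(aw), atau


def _pack(kin: tuple) -> np.ndarray:
    k_act, k_dec, lw, ltau, aw, atau = kin
    logit = lambda p: np.log(np.clip(p, 1e-4, 1 - 1e-4) / (1 - np.clip(p, 1e-4, 1 - 1e-4)))
    return np.array([np.log(k_act), np.log(k_dec), logit(lw), np.log(ltau), logit(aw), np.log(atau)])


def calibrate_kinetics(ligand: str) -> tuple:
    # coarse grid to seed the simplex
    best, best_err = None, np.inf
    for k_dec in (0.05, 0.15, 0.5, 1.5):
        for lw in (0.05, 0.2, 0.4, 0.6, 0.8):
            for ltau in (20.0, 40.0, 80.0, 160.0):
                for aw in (0.0001, 0.2, 0.4, 0.6):
                    for atau in (20.0, 60.0, 150.0):
                        kin = (0.5, k_dec, lw, ltau, aw, atau)
                        err = kinetic_error(kin, ligand)
                        if err < best_err:
                            best, best_err = kin, err
    # shrinking random search around the incumbent (the objective is
    # piecewise constant in onset, which stalls a plain simplex)
    rng = np.random.default_rng(12345)
    for sigma in (0.8, 0.4, 0.2, 0.1):
        centre = _pack(best)
        for _ in range(300):
            kin = _unpack(centre + rng.normal(0.0, sigma, size=6))
            err = kinetic_error(kin, ligand)
            if err < best_err:
                best, best_err = kin, err
    res = optimize.minimize(
        lambda x: kinetic_error(_unpack(x), ligand),
        _pack(best),
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-3, "maxfev": 300},
    )
    if res.fun < best_err:
        best, best_err = _unpack(res.x), res.fun
    kin = best
    dose = KINETICS_DOSES[ligand][1]
    ts = _full_scenario(ligand, kin, NOISELESS).simulate(seed=0)
    m = kinetics_run(ts, f"{ligand}_{dose:g}mM")
    print(
        f"  {ligand}: k_act={kin[0]:.4f} k_dec={kin[1]:.4f} "
        f"lw={kin[2]:.4f} ltau={kin[3]:.2f} aw={kin[4]:.4f} atau={kin[5]:.2f}  (residual {best_err:.3f}; "
        f"onset {m.onset:.1f} vs {KINETIC_TARGETS[ligand][0]}, "
        f"dfwhm {m.delta_fwhm_lingering or 0:.1f} vs {KINETIC_TARGETS[ligand][1]})",
        file=sys.stderr,
    )
    return kin


def _blocking_with_ki(ki_values: dict) -> dict:
    import tonguechip.presets as presets

    sc = _fig4_scenario()
    models = dict(sc.models)
    for receptor, ki in ki_values.items():
        m = models[receptor]
        models[receptor] = dataclasses.replace(m, antagonists={"cyclamate": ki})
    layout = {r: 8 for r in sc.layout}
    sc = dataclasses.replace(sc, models=models, layout=layout, noise=NOISELESS)
    ts = sc.simulate(seed=0)
    return blocking_analysis(ts, require_significant=False).blocking


def calibrate_ki() -> dict:
    ki = dict(CYCLAMATE_KI)
    for receptor, target in BLOCKING_TARGETS.items():

        def f(log_ki: float) -> float:
            trial = dict(ki)
            trial[receptor] = float(np.exp(log_ki))
            return _blocking_with_ki(trial).get(receptor, 0.0) - target

        lo, hi = np.log(0.05), np.log(500.0)
        sol = optimize.brentq(f, lo, hi, xtol=1e-3)
        ki[receptor] = float(np.exp(sol))
        print(f"  {receptor}: Ki = {ki[receptor]:.4f} mM", file=sys.stderr)
    return ki


def main() -> None:
    print("calibrating sweet-receptor kinetics ...", file=sys.stderr)
    kinetics = {lig: calibrate_kinetics(lig) for lig in KINETIC_TARGETS}
    print("calibrating cyclamate Ki ...", file=sys.stderr)
    ki = calibrate_ki()

    print("\nSWEET_KINETICS = {")
    for lig, (ka, kd, lw, lt, aw, at) in kinetics.items():
        print(f'    "{lig}": ({ka:.4f}, {kd:.4f}, {lw:.4f}, {lt:.2f}, {aw:.4f}, {at:.2f}),')
    print("}")
    print("\nCYCLAMATE_KI = {")
    for rec, v in ki.items():
        print(f'    "{rec}": {v:.4f},')
    print("}")


if __name__ == "__main__":
    main()
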