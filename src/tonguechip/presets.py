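"""Self-contained study scenarios for the synthetic generator.

Each preset bundles an array layout, receptor models, a flow configuration
and an injection schedule emulating one of the platform's experiment
designs: the exposure-calibration grid, the sweetener dose-response
series, the onset/lingering kinetics runs (one agonist injection followed
by a fluorescein reference injection), and the saccharine/cyclamate
bitter-blocking series.

The per-sweetener calcium kinetic constants and the cyclamate inhibition
constants below are derived constants: they were fixed once by running
``scripts/calibrate_presets.py``, which grid-searches them so that the
noiseless end-to-end pipeline reproduces the platform's published kinetic
metrics and blocking percentages.  They are study conditions, not user
knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .array import (
    FLUORESCEIN,
    MOCK,
    SWEET,
    UMAMI,
    YC_CONTROL,
    AgonistSite,
    Injection,
    InjectionSchedule,
    NoiseConfig,
    ReceptorModel,
    TraceSet,
    make_array,
    simulate_traces,
)
from .flowcell import FlowConfig

__all__ = ["Scenario", "preset", "PRESET_NAMES"]

PRESET_NAMES = (
    "table1_calibration",
    "fig2_sucrose_series",
    "fig2_all_sweeteners",
    "table2_kinetics",
    "fig4_blocking",
)

# ---------------------------------------------------------------------------
# study conditions
# ---------------------------------------------------------------------------

#: standard receptomics flow settings (50 uL cell, 300 uL loop, 300 uL/min)
#: with a mild dead-zone tail so the dye peak falls more slowly than it
#: rises, as measured.
STANDARD_FLOW = FlowConfig(
    cell_volume=50.0,
    injection_volume=300.0,
    flow_rate=300.0,
    n_tanks=3,
    tailing_fraction=0.05,
    tailing_tau=30.0,
)

#: calibration runs use an empty flow cell without dead-zone tailing
CALIBRATION_FLOW = FlowConfig(
    cell_volume=50.0, injection_volume=300.0, flow_rate=300.0, n_tanks=3
)

STANDARD_NOISE = NoiseConfig(cv=0.01, dip_gain=0.02)

#: EC50s (mM) and per-ligand activation of the sweet receptor heterodimer
SWEET_SITES = {
    "sucrose": AgonistSite(ec50=35.0, hill=1.3, amplitude=0.8),
    "advantame": AgonistSite(ec50=0.0015, hill=1.3, amplitude=0.8),
    "aspartame": AgonistSite(ec50=0.625, hill=1.3, amplitude=0.8),
    "saccharine": AgonistSite(ec50=0.3, hill=1.3, amplitude=0.8),
    "cyclamate": AgonistSite(ec50=10.0, hill=1.3, amplitude=0.4),
}

#: calibrated calcium kinetics of the sweet receptor per sweetener
#: (k_act 1/s, k_dec 1/s, linger_weight, linger_tau s, adapt_weight,
#: adapt_tau s) — derived constants, see scripts/calibrate_presets.py
SWEET_KINETICS: Mapping[str, tuple[float, float, float, float, float, float]] = {
    "sucrose": (1.1082, 2.2438, 0.8099, 17.83, 0.2140, 172.94),
    "advantame": (0.6732, 1.1685, 0.8916, 66.27, 0.8336, 16.65),
    "aspartame": (0.7634, 0.0477, 0.0194, 64.07, 0.6526, 346.28),
    "saccharine": (4.3326, 1.2797, 0.8585, 41.41, 0.7457, 99.42),
}

#: calibrated cyclamate inhibition constants (mM) — derived constants
CYCLAMATE_KI: Mapping[str, float] = {
    "TAS2R8": 28.3329,
    "TAS2R31": 4.8909,
    "TAS2R43": 0.2921,
}

#: bitter receptor saccharine pharmacology (ec50 mM, amplitude);
#: TAS2R43 sits at the top of its curve at 10 mM, TAS2R8 is low-affinity.
#: Amplitudes put the strong responders ~5-10x above the blank-injection
#: response floor, so that a near-complete block of TAS2R43 leaves a
#: residual effect statistically indistinguishable from the blank, as the
#: platform reports for the saccharine/cyclamate mixture.
BITTER_SITES = {
    "TAS2R8": AgonistSite(ec50=8.0, hill=1.3, amplitude=0.45),
    "TAS2R31": AgonistSite(ec50=2.0, hill=1.3, amplitude=0.55),
    "TAS2R43": AgonistSite(ec50=0.5, hill=1.3, amplitude=0.25),
}

BITTER_KINETICS = dict(k_act=0.5, k_dec=0.15, linger_weight=0.15, linger_tau=40.0)

#: fractional response remaining after one saturating exposure
SWEET_DESENS = 0.7
TAS2R43_DESENS = 0.65

INJECTION_SPACING = 300.0  # s, ~5 min wash-out between injections


def _sweet_model(ligand: str, extra: Mapping[str, AgonistSite] | None = None,
                 desens: float = SWEET_DESENS) -> ReceptorModel:
    k_act, k_dec, lw, ltau, aw, atau = SWEET_KINETICS[ligand]
    sites = {ligand: SWEET_SITES[ligand]}
    if extra:
        sites.update(extra)
    return ReceptorModel(
        agonists=sites,
        k_act=k_act,
        k_dec=k_dec,
        linger_weight=lw,
        linger_tau=ltau,
        adapt_weight=aw,
        adapt_tau=atau,
        desens_factor=desens,
    )


def _bitter_model(receptor: str) -> ReceptorModel:
    sites = {}
    antagonists = {}
    if receptor in BITTER_SITES:
        sites["saccharine"] = BITTER_SITES[receptor]
        antagonists["cyclamate"] = CYCLAMATE_KI[receptor]
    return ReceptorModel(
        agonists=sites,
        antagonists=antagonists,
        desens_factor=TAS2R43_DESENS if receptor == "TAS2R43" else 1.0,
        **BITTER_KINETICS,
    )


@dataclass(frozen=True)
class Scenario:
    """A fully specified synthetic experiment."""

    name: str
    layout: Mapping[str, int]
    models: Mapping[str, ReceptorModel]
    flow_config: FlowConfig
    schedule: InjectionSchedule
    noise: NoiseConfig = STANDARD_NOISE
    reference_receptor: str | None = UMAMI
    sample_doses: Mapping[str, float] = field(default_factory=dict)  # sample -> mM
    dose_ligand: str | None = None

    def simulate(self, seed: int, dt: float = 0.5) -> TraceSet:
        spots = make_array(dict(self.layout), seed=seed)
        return simulate_traces(
            spots,
            dict(self.models),
            self.flow_config,
            self.schedule,
            self.noise,
            seed=seed + 1,
            dt=dt,
        )


def _dose_series_scenario(
    name: str,
    ligand: str,
    doses_mM: list[float],
    n_replicates: int,
) -> Scenario:
    injections = []
    sample_doses = {}
    for i, d in enumerate(doses_mM):
        sid = f"{ligand}_{d:g}mM"
        injections.append(
            Injection(
                valve_time=100.0 + i * INJECTION_SPACING,
                sample_id=sid,
                composition={ligand: d},
            )
        )
        sample_doses[sid] = d
    return Scenario(
        name=name,
        layout={SWEET: n_replicates, UMAMI: 8, MOCK: 8, YC_CONTROL: 5},
        models={SWEET: _sweet_model(ligand)},
        flow_config=STANDARD_FLOW,
        schedule=InjectionSchedule(tuple(injections)),
        sample_doses=sample_doses,
        dose_ligand=ligand,
    )


def _kinetics_scenario(ligand: str, dose_mM: float, label: str) -> Scenario:
    sid = f"{ligand}_{dose_mM:g}mM"
    sched = InjectionSchedule(
        (
            Injection(valve_time=100.0, sample_id=sid, composition={ligand: dose_mM}),
            Injection(
                valve_time=100.0 + INJECTION_SPACING,
                sample_id="fluorescein",
                composition={FLUORESCEIN: 1.0},
            ),
        )
    )
    # same replicate level as the ligand's dose-response arrays
    n_sweet = DOSE_SERIES[ligand][1]
    return Scenario(
        name=f"table2_{label}",
        layout={SWEET: n_sweet, UMAMI: 8, MOCK: 5, YC_CONTROL: 5},
        models={SWEET: _sweet_model(ligand)},
        flow_config=STANDARD_FLOW,
        schedule=sched,
        sample_doses={sid: dose_mM},
        dose_ligand=ligand,
    )


#: (ligand, EC50-level dose, maximal dose) of the kinetics runs, in mM
KINETICS_DOSES = {
    "sucrose": (30.0, 100.0),
    "advantame": (0.001, 0.015),
    "aspartame": (0.6, 5.0),
    "saccharine": (0.3, 5.0),
}

#: dose series of the four sweetener dose-response experiments (mM) and
#: their spot replication levels
DOSE_SERIES = {
    "sucrose": ([1.0, 3.0, 10.0, 30.0, 100.0], 11),
    "advantame": ([1.5e-4, 5e-4, 1.5e-3, 5e-3, 1.5e-2], 15),
    "saccharine": ([0.03, 0.1, 0.3, 1.0, 5.0], 11),
    "aspartame": ([0.06, 0.2, 0.625, 2.0, 5.0], 13),
}


def _fig4_scenario() -> Scenario:
    samples = [
        ("blank_1", {}),
        ("sucrose_100mM_a", {"sucrose": 100.0}),
        ("blank_2", {}),
        ("saccharine_10mM_a", {"saccharine": 10.0}),
        ("saccharine_cyclamate", {"saccharine": 10.0, "cyclamate": 20.0}),
        ("saccharine_10mM_b", {"saccharine": 10.0}),
        ("cyclamate_20mM", {"cyclamate": 20.0}),
        ("blank_3", {}),
        ("sucrose_100mM_b", {"sucrose": 100.0}),
    ]
    sched = InjectionSchedule(
        tuple(
            Injection(valve_time=100.0 + i * INJECTION_SPACING, sample_id=sid,
                      composition=comp)
            for i, (sid, comp) in enumerate(samples)
        )
    )
    models = {SWEET: _sweet_model("saccharine",
                                  extra={k: SWEET_SITES[k] for k in ("sucrose", "cyclamate")})}
    for r in ("TAS2R3", "TAS2R8", "TAS2R14", "TAS2R31", "TAS2R43", "TAS2R46"):
        models[r] = _bitter_model(r)
    return Scenario(
        name="fig4_blocking",
        layout={
            SWEET: 10,
            "TAS2R3": 10,
            "TAS2R8": 10,
            "TAS2R14": 10,
            "TAS2R31": 10,
            "TAS2R43": 10,
            "TAS2R46": 10,
            MOCK: 8,
            YC_CONTROL: 5,
        },
        models=models,
        flow_config=STANDARD_FLOW,
        schedule=sched,
        reference_receptor=None,
    )


def preset(name: str):
    """Return a named scenario (or mapping of scenarios for composites).

    ``table1_calibration`` and ``fig2_sucrose_series`` and
    ``fig4_blocking`` return a single :class:`Scenario`;
    ``fig2_all_sweeteners`` returns ``{ligand: Scenario}`` and
    ``table2_kinetics`` returns ``{"<ligand>_low"/"<ligand>_high":
    Scenario}``.
    """
    if name == "table1_calibration":
        # dye-only run in an empty flow cell: no receptor spots at all
        sched = InjectionSchedule(
            (Injection(valve_time=100.0, sample_id="fluorescein",
                       composition={FLUORESCEIN: 1.0}),)
        )
        return Scenario(
            name=name,
            layout={},
            models={},
            flow_config=CALIBRATION_FLOW,
            schedule=sched,
            reference_receptor=None,
        )
    if name == "fig2_sucrose_series":
        doses, n = DOSE_SERIES["sucrose"]
        return _dose_series_scenario(name, "sucrose", doses, n)
    if name == "fig2_all_sweeteners":
        return {
            ligand: _dose_series_scenario(f"fig2_{ligand}", ligand, doses, n)
            for ligand, (doses, n) in DOSE_SERIES.items()
        }
    if name == "table2_kinetics":
        out = {}
        for ligand, (low, high) in KINETICS_DOSES.items():
            out[f"{ligand}_low"] = _kinetics_scenario(ligand, low, f"{ligand}_low")
            out[f"{ligand}_high"] = _kinetics_scenario(ligand, high, f"{ligand}_high")
        return out
    if name == "fig4_blocking":
        return _fig4_scenario()
    raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
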