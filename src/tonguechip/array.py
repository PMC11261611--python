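"""Synthetic receptor-array FRET data generator.

Emulates a reverse-transfected taste-receptor array in a flow cell: spots
of cells expressing one receptor type each plus the Twitch2B ratiometric
calcium sensor, imaged in two interleaved fluorescence channels (CFP donor,
YFP acceptor) while tastant samples are loop-injected into a constant
buffer flow.

The cellular response model is deliberately phenomenological: receptor
occupancy follows a Hill function of the local ligand concentration (with
competitive antagonists shifting the midpoint), and the calcium signal is
the occupancy passed through a linear activation/decay filter with an
optional slow "lingering" component.  Repeated saturating exposures shrink
the response multiplicatively (desensitization).  High-osmolarity samples
add a non-specific negative "dip" to every cell-bearing spot, and a
fluorescein injection produces a purely optical acceptor-channel signal
used downstream as the exposure reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from .flowcell import FlowConfig, simulate_exposure

__all__ = [
    "RECEPTORS",
    "SWEET",
    "UMAMI",
    "MOCK",
    "YC_CONTROL",
    "FLUORESCEIN",
    "SpotRecord",
    "AgonistSite",
    "ReceptorModel",
    "Injection",
    "InjectionSchedule",
    "NoiseConfig",
    "ChannelTrace",
    "TraceSet",
    "ConfigError",
    "make_array",
    "simulate_traces",
    "saturating_dose",
]

SWEET = "TAS1R2_R3"
UMAMI = "TAS1R1_R3"
MOCK = "MOCK"
YC_CONTROL = "YC_CONTROL"
RECEPTORS = (
    SWEET,
    UMAMI,
    "TAS2R3",
    "TAS2R8",
    "TAS2R14",
    "TAS2R31",
    "TAS2R43",
    "TAS2R46",
    MOCK,
    YC_CONTROL,
)

#: pseudo-ligand name for the optical exposure reference dye
FLUORESCEIN = "fluorescein"


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass(frozen=True)
class SpotRecord:
    """One printed spot: receptor identity, size and arrival offset."""

    spot_id: str
    receptor: str
    pixel_count: int
    position_delay: float  # s, sample arrival offset at this spot

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ConfigError(f"{self.spot_id}: pixel_count must be positive")
        if self.position_delay < 0:
            raise ConfigError(f"{self.spot_id}: position_delay must be >= 0")


@dataclass(frozen=True)
class AgonistSite:
    """Hill-type activation parameters of one ligand at one receptor.

    ``ec50`` is in mM, ``hill`` is the slope, ``amplitude`` the maximal
    fractional calcium signal the ligand can evoke at this receptor.
    """

    ec50: float
    hill: float = 1.3
    amplitude: float = 0.8

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill <= 0 or not 0 < self.amplitude <= 1:
            raise ConfigError("invalid agonist parameters")


@dataclass(frozen=True)
class ReceptorModel:
    """Response parameters of one receptor type.

    Kinetics: ``k_act`` limits the activation rate (1/s); the decay kernel
    is a mixture of a fast exponential (rate ``k_dec``) and a slow
    lingering exponential (time constant ``linger_tau``, weight
    ``linger_weight``).  ``adapt_weight`` subtracts a low-passed copy of
    the occupancy (time constant ``adapt_tau``) before filtering, making
    the calcium response to a sustained stimulus transient, as IP3-driven
    calcium signals are; 0 disables adaptation.  ``desens_factor``
    multiplies the amplitude once per preceding near-saturating exposure.
    ``antagonists`` maps a ligand name to its competitive-inhibition
    constant Ki (mM).
    """

    agonists: Mapping[str, AgonistSite] = field(default_factory=dict)
    k_act: float = 0.5
    k_dec: float = 0.1
    linger_weight: float = 0.1
    linger_tau: float = 30.0
    adapt_weight: float = 0.0
    adapt_tau: float = 60.0
    desens_factor: float = 1.0
    antagonists: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.k_act, self.k_dec, self.linger_tau, self.adapt_tau) <= 0:
            raise ConfigError("rates and time constants must be positive")
        if not 0 <= self.linger_weight < 1:
            raise ConfigError("linger_weight must be in [0, 1)")
        if not 0 <= self.adapt_weight < 1:
            raise ConfigError("adapt_weight must be in [0, 1)")
        if not 0 < self.desens_factor <= 1:
            raise ConfigError("desens_factor must be in (0, 1]")
        if any(ki <= 0 for ki in self.antagonists.values()):
            raise ConfigError("Ki values must be positive")


def saturating_dose(site: AgonistSite, occupancy: float = 0.95) -> float:
    """Dose (mM) at which the site reaches the given fractional occupancy."""
    return site.ec50 * (occupancy / (1.0 - occupancy)) ** (1.0 / site.hill)


@dataclass(frozen=True)
class Injection:
    """One loop injection: valve switch time, label and sample composition.

    ``composition`` maps ligand name to concentration in mM (fluorescein
    concentration is in relative units; only its time course matters).
    """

    valve_time: float
    sample_id: str
    composition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.composition.values()):
            raise ConfigError(f"{self.sample_id}: negative concentration")

    @property
    def osmolarity(self) -> float:
        """Total tastant solute concentration (mM), dye excluded."""
        return sum(c for lig, c in self.composition.items() if lig != FLUORESCEIN)


@dataclass(frozen=True)
class InjectionSchedule:
    injections: tuple[Injection, ...]

    def __post_init__(self) -> None:
        inj = tuple(self.injections)
        times = [i.valve_time for i in inj]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError("valve_times must be strictly increasing")
        object.__setattr__(self, "injections", inj)

    def __iter__(self):
        return iter(self.injections)

    def __len__(self) -> int:
        return len(self.injections)


@dataclass(frozen=True)
class NoiseConfig:
    """Rendering parameters for the two fluorescence channels."""

    cv: float = 0.01              # multiplicative channel noise
    dip_gain: float = 0.0         # ratio dip per unit exposure at 100 mM osmolarity
    baseline_cfp: float = 1000.0  # a.u.
    baseline_yfp: float = 1000.0
    alpha: float = 0.15           # fractional YFP gain at full calcium signal
    beta: float = 0.15            # fractional CFP loss at full calcium signal
    fluorescein_gain: float = 0.3  # fractional YFP gain at undiluted dye
    sample_interval: float = 2.0  # s between CFP frames; YFP offset by half

    def __post_init__(self) -> None:
        if self.cv < 0 or self.sample_interval <= 0:
            raise ConfigError("invalid noise configuration")


@dataclass(frozen=True)
class ChannelTrace:
    """Interleaved two-channel fluorescence series of one spot."""

    cfp_times: np.ndarray
    cfp: np.ndarray
    yfp_times: np.ndarray
    yfp: np.ndarray


@dataclass(frozen=True)
class TraceSet:
    """Simulated (or loaded) raw data for a whole run."""

    spots: tuple[SpotRecord, ...]
    traces: Mapping[str, ChannelTrace]
    schedule: InjectionSchedule
    flow_config: FlowConfig


def make_array(
    layout: Mapping[str, int],
    seed: int,
    pixel_range: tuple[int, int] = (10, 60),
    max_delay: float = 4.0,
) -> list[SpotRecord]:
    """Lay out a replicated spotted array.

    ``layout`` maps receptor name to replicate count.  Pixel counts are
    drawn uniformly from ``pixel_range`` (so some spots can fail the
    15-pixel QC rule); arrival delays are spread linearly with spot index
    across ``max_delay`` seconds, mimicking the position-dependent exposure
    start across the array.
    """
    if any(n < 1 for n in layout.values()):
        bad = [r for r, n in layout.items() if n < 1]
        raise ConfigError(f"zero replicates requested for {bad}")
    rng = np.random.default_rng(seed)
    spots: list[SpotRecord] = []
    total = sum(layout.values())
    idx = 0
    for receptor, n in layout.items():
        for rep in range(n):
            delay = max_delay * idx / max(total - 1, 1)
            spots.append(
                SpotRecord(
                    spot_id=f"{receptor}_{rep + 1:02d}",
                    receptor=receptor,
                    pixel_count=int(rng.integers(pixel_range[0], pixel_range[1] + 1)),
                    position_delay=round(delay, 3),
                )
            )
            idx += 1
    return spots


def _first_order_lowpass(x: np.ndarray, rate: float, dt: float) -> np.ndarray:
    """Exact discretisation of dg/dt = rate*(x - g), g(0)=0."""
    phi = np.exp(-rate * dt)
    return _signal.lfilter([1.0 - phi], [1.0, -phi], x)


def _decay_kernel(model: ReceptorModel, dt: float, n: int) -> np.ndarray:
    t = (np.arange(n) + 0.5) * dt
    k = (1.0 - model.linger_weight) * model.k_dec * np.exp(-model.k_dec * t)
    if model.linger_weight > 0:
        k = k + model.linger_weight * np.exp(-t / model.linger_tau) / model.linger_tau
    return k / (k.sum() * dt)


def _occupancy(
    model: ReceptorModel,
    injection: Injection,
    exposure: np.ndarray,
    desens_count: int,
) -> np.ndarray:
    """Summed Hill occupancy evoked by one injection, scaled by amplitude
    and desensitization; antagonists shift each agonist's midpoint."""
    shift = 1.0
    for lig, ki in model.antagonists.items():
        conc_i = injection.composition.get(lig, 0.0)
        if conc_i > 0:
            shift += conc_i / ki
    o = np.zeros_like(exposure)
    for lig, site in model.agonists.items():
        dose = injection.composition.get(lig, 0.0)
        if dose <= 0:
            continue
        c = dose * exposure
        k_eff = site.ec50 * shift
        o = o + site.amplitude * c**site.hill / (c**site.hill + k_eff**site.hill)
    return np.clip(o, 0.0, 1.0) * model.desens_factor**desens_count


def _desens_counts(model: ReceptorModel, schedule: InjectionSchedule) -> list[int]:
    """Number of prior near-saturating exposures before each injection."""
    counts, seen = [], 0
    for inj in schedule:
        counts.append(seen)
        strong = any(
            inj.composition.get(lig, 0.0) > 0.8 * saturating_dose(site)
            for lig, site in model.agonists.items()
        )
        if strong:
            seen += 1
    return counts


def simulate_traces(
    spots: Sequence[SpotRecord],
    receptor_models: Mapping[str, ReceptorModel],
    flow_config: FlowConfig,
    schedule: InjectionSchedule,
    noise: NoiseConfig,
    seed: int,
    dt: float = 0.5,
    duration: float | None = None,
) -> TraceSet:
    """Render the full two-channel trace set for an array and schedule.

    Deterministic for fixed arguments and seed.  See the module docstring
    for the signal chain; the sensor-control (YC) spots ignore the calcium
    pathway entirely and receive the optical dye signal equally in both
    channels, so their ratio stays constant.
    """
    rng = np.random.default_rng(seed)
    schedule = (
        schedule
        if isinstance(schedule, InjectionSchedule)
        else InjectionSchedule(tuple(schedule))
    )
    valve_times = [inj.valve_time for inj in schedule]
    # one unit profile per injection on a common dense grid
    last = max(valve_times)
    if duration is None:
        from .flowcell import theoretical_exposure as _texp

        duration = (
            last
            + _texp(flow_config)
            + 5.0 * flow_config.mean_residence_time
            + 5.0 * flow_config.tailing_tau * (flow_config.tailing_fraction > 0)
            + 60.0
        )
    unit_profiles = []
    for v in valve_times:
        prof = simulate_exposure(flow_config, [v], dt=dt, duration=duration)
        unit_profiles.append(prof.concentration)
    times = np.arange(int(np.ceil(duration / dt)) + 1) * dt

    desens_by_receptor = {
        name: _desens_counts(model, schedule)
        for name, model in receptor_models.items()
    }

    # channel sampling grids (interleaved: YFP lags CFP by half a frame)
    si = noise.sample_interval
    cfp_times = np.arange(0.0, duration, si)
    yfp_times = cfp_times + si / 2.0

    traces: dict[str, ChannelTrace] = {}
    for spot in spots:
        shifted = [
            np.interp(times - spot.position_delay, times, u, left=0.0)
            for u in unit_profiles
        ]
        s_total = np.zeros_like(times)
        if spot.receptor not in (YC_CONTROL,):
            model = receptor_models.get(spot.receptor)
            if model is not None and model.agonists:
                occ = np.zeros_like(times)
                counts = desens_by_receptor[spot.receptor]
                for j, inj in enumerate(schedule):
                    occ += _occupancy(model, inj, shifted[j], counts[j])
                occ = np.clip(occ, 0.0, 1.0)
                if model.adapt_weight > 0:
                    occ = np.clip(
                        occ
                        - model.adapt_weight
                        * _first_order_lowpass(occ, 1.0 / model.adapt_tau, dt),
                        0.0,
                        None,
                    )
                g = _first_order_lowpass(occ, model.k_act, dt)
                kern = _decay_kernel(model, dt, len(times))
                s_total = np.convolve(g, kern)[: len(times)] * dt
            # non-specific osmotic dip on every cell-bearing spot
            if noise.dip_gain > 0:
                for j, inj in enumerate(schedule):
                    osmo = inj.osmolarity
                    if osmo > 0:
                        s_total = s_total - noise.dip_gain * (osmo / 100.0) * shifted[j]

        # optical dye signal (acceptor channel only, except YC: both)
        fluo = np.zeros_like(times)
        for j, inj in enumerate(schedule):
            cf = inj.composition.get(FLUORESCEIN, 0.0)
            if cf > 0:
                fluo = fluo + cf * shifted[j]

        s_c = np.interp(cfp_times, times, s_total)
        s_y = np.interp(yfp_times, times, s_total)
        f_c = np.interp(cfp_times, times, fluo)
        f_y = np.interp(yfp_times, times, fluo)

        if spot.receptor == YC_CONTROL:
            # fixed-ratio sensor: the optical artifact enters both channels
            # identically, so the raw ratio stays exactly constant
            yfp = noise.baseline_yfp * (1.0 + noise.fluorescein_gain * f_c)
            cfp = noise.baseline_cfp * (1.0 + noise.fluorescein_gain * f_c)
        else:
            yfp = noise.baseline_yfp * (
                1.0 + noise.alpha * s_y + noise.fluorescein_gain * f_y
            )
            cfp = noise.baseline_cfp * (1.0 - noise.beta * s_c)
        if noise.cv > 0:
            yfp = yfp * (1.0 + rng.normal(0.0, noise.cv, yfp.shape))
            cfp = cfp * (1.0 + rng.normal(0.0, noise.cv, cfp.shape))
        traces[spot.spot_id] = ChannelTrace(
            cfp_times=cfp_times.copy(),
            cfp=np.maximum(cfp, 1e-6),
            yfp_times=yfp_times.copy(),
            yfp=np.maximum(yfp, 1e-6),
        )
    return TraceSet(
        spots=tuple(spots),
        traces=traces,
        schedule=schedule,
        flow_config=flow_config,
    )
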