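"""Simulated instruments: turbidostat reactors and a plate-reader workflow.

The turbidostat holds a multi-strain yeast culture at an OD setpoint by
dilution (at steady state the dilution rate equals the culture's mean
growth rate) while tracking a shared limiting nutrient -- histidine for
his3 auxotrophs. Auxotroph growth is limited by saturable histidine
uptake: transport follows Monod kinetics in the external concentration
with the HIP1 transporter constant Km = 17 uM, and cells carry an excess
transport capacity ``uptake_capacity`` relative to their growth demand, so
growth is unaffected until the residual histidine falls low enough that
transport can no longer cover the requirement ``yield_q`` (uM consumed per
OD unit of growth). Prototrophs grow at a constant rate but import
available histidine in preference to synthesizing it, which couples the
residual concentration to total cell density -- the mechanism by which the
OD setpoint tunes the fitness of auxotrophs.

The plate-reader side reproduces the robot-assisted bacterial protocol:
evaporation-compensated dilutions (add 100 uL, remove 100 uL minus the
estimated evaporation since the last dilution), a forced feed after 10 h
without dilution, OD blank subtraction with an early-measurement artifact
filter, and antibiotic treatments by volume/mass conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cytometry import PopulationSpec, StrainPopulation

__all__ = [
    "Strain",
    "GrowthModel",
    "TurbidostatState",
    "TurbidostatStepResult",
    "turbidostat_step",
    "growth_rate",
    "steady_state_histidine",
    "delta_mu_curve",
    "run_competition",
    "sample_culture",
    "Well",
    "PlateState",
    "PlateAction",
    "evaporate",
    "plate_dilution_protocol",
    "treat_well",
    "CleanOdResult",
    "clean_od",
]


# ---------------------------------------------------------------------------
# Turbidostat with nutrient dynamics


@dataclass(frozen=True)
class Strain:
    """A strain in the consortium.

    ``fluorophores`` maps fluorophore names to mean constitutive
    expression in raw instrument units (used when sampling the culture
    into a synthetic cytometry run).
    """

    name: str
    mu_max: float = 0.4
    his_dependent: bool = False
    fluorophores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ValueError("mu_max must be > 0")
        object.__setattr__(self, "fluorophores", dict(self.fluorophores))


@dataclass(frozen=True)
class GrowthModel:
    """Growth and nutrient-coupling parameters.

    ``k_m``: Monod constant of the high-affinity histidine transporter
    (HIP1), uM. ``yield_q``: histidine consumed per OD unit of biomass
    produced, uM/OD. ``h_in``: feed histidine, uM (the experimental
    regimes are 4 and 20). ``uptake_capacity``: maximal transport flux as
    a multiple of the full-growth requirement; 1 recovers plain Monod
    growth, larger values give the sharp nutrient-limitation transition.
    """

    strains: tuple[Strain, ...]
    k_m: float = 17.0
    yield_q: float = 28.0
    h_in: float = 20.0
    uptake_capacity: float = 8.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.strains))
        if not self.strains:
            raise ValueError("model needs at least one strain")
        if self.k_m <= 0 or self.yield_q < 0 or self.uptake_capacity < 1:
            raise ValueError("require k_m > 0, yield_q >= 0, uptake_capacity >= 1")

    def strain(self, name: str) -> Strain:
        for s in self.strains:
            if s.name == name:
                return s
        raise KeyError(name)


def growth_rate(strain: Strain, histidine: float, model: GrowthModel) -> float:
    """Potential specific growth rate, h^-1, at external histidine level."""
    if not strain.his_dependent:
        return strain.mu_max
    h = max(histidine, 0.0)
    transport = model.uptake_capacity * h / (model.k_m + h)
    return strain.mu_max * min(1.0, transport)


@dataclass(frozen=True)
class TurbidostatState:
    """State of one 30 mL turbidostat reactor.

    OD is the sum of per-strain biomass densities; volume stays constant
    under the balanced in/out pumping contract.
    """

    densities: Mapping[str, float]
    histidine: float
    od_setpoint: float = 0.5
    volume: float = 30.0
    light_duty: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "densities", dict(self.densities))
        if any(x < 0 for x in self.densities.values()):
            raise ValueError("strain densities must be >= 0")
        if self.histidine < 0:
            raise ValueError("histidine must be >= 0")
        if not (0.0 <= self.light_duty <= 1.0):
            raise ValueError("light_duty must lie in [0, 1]")

    @property
    def od(self) -> float:
        return float(sum(self.densities.values()))

    def fractions(self) -> dict[str, float]:
        od = self.od
        if od <= 0:
            raise ValueError("cannot compute fractions of an empty culture")
        return {name: x / od for name, x in self.densities.items()}


@dataclass(frozen=True)
class TurbidostatStepResult:
    state: TurbidostatState
    growth: float  # integral of total growth over the step, OD units
    dilution: float  # integral of dilution removal, OD units
    realized_mu: dict[str, float]  # realized rates at the end of the step


def _allocate_histidine(
    model: GrowthModel,
    names: Sequence[str],
    X: np.ndarray,
    mu_pot: np.ndarray,
    is_aux: np.ndarray,
    h: float,
    dt: float,
    od_setpoint: float,
) -> tuple[np.ndarray, float, float]:
    """Realized growth rates, dilution, and histidine consumption flux.

    Consumption is ``yield_q`` per OD of growth for every strain
    (prototrophs import available histidine in preference to synthesis).
    When demand would drive the concentration negative within ``dt``, the
    incoming flux is allocated to prototrophs first -- they import only
    what is available, without slowing down -- and auxotroph growth is
    scaled to the residual flux (they are the ones that cannot grow
    without it).
    """
    od = float(X.sum())
    q = model.yield_q

    def dilution_rate(mu: np.ndarray) -> float:
        if od < od_setpoint or od <= 0:
            return 0.0
        # Ideal hold: choose D so the culture lands exactly on the setpoint.
        d = (float(mu @ X) - (od_setpoint - od) / dt) / od
        return max(d, 0.0)

    mu = mu_pot.copy()
    for _ in range(8):
        D = dilution_rate(mu)
        supply = D * (model.h_in - h)
        demand = q * float(mu @ X)
        if h + dt * (supply - demand) >= -1e-12 or q == 0:
            return mu, D, demand
        allowed = max(supply + h / dt, 0.0)  # consumption landing exactly on h = 0
        proto_demand = q * float(mu_pot[~is_aux] @ X[~is_aux])
        proto_consumption = min(proto_demand, allowed)
        residual = allowed - proto_consumption
        aux_demand = q * float(mu_pot[is_aux] @ X[is_aux])
        scale = min(residual / aux_demand, 1.0) if aux_demand > 0 else 1.0
        mu_new = mu_pot.copy()
        mu_new[is_aux] = scale * mu_pot[is_aux]
        consumption = proto_consumption + q * float(mu_new[is_aux] @ X[is_aux])
        if np.allclose(mu_new, mu, rtol=1e-12, atol=1e-15):
            return mu_new, dilution_rate(mu_new), consumption
        mu = mu_new
    return mu, dilution_rate(mu), consumption


def turbidostat_step(
    state: TurbidostatState,
    model: GrowthModel,
    dt: float,
    max_substep: float = 0.005,
) -> TurbidostatStepResult:
    """Advance the reactor by ``dt`` hours (internally sub-stepped).

    Dynamics per strain: dX_i/dt = (mu_i - D) X_i with the turbidostat law
    D = total specific growth rate once OD has reached the setpoint (ideal
    hold), D = 0 below it. Histidine: dh/dt = D (h_in - h) - q sum mu_i X_i,
    kept non-negative by the uptake allocation. The returned ``growth`` and
    ``dilution`` integrals satisfy the discrete mass balance
    delta(OD) = growth - dilution exactly.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    names = [s.name for s in model.strains]
    missing = set(state.densities) - set(names)
    if missing:
        raise ValueError(f"state contains strains unknown to the model: {sorted(missing)}")
    X = np.array([state.densities.get(n, 0.0) for n in names])
    is_aux = np.array([s.his_dependent for s in model.strains])
    h = state.histidine
    t = state.time
    growth_total = 0.0
    dilution_total = 0.0
    mu = np.zeros(len(names))

    n_sub = max(int(np.ceil(dt / max_substep)), 1) if dt > 0 else 0
    dt_sub = dt / n_sub if n_sub else 0.0
    for _ in range(n_sub):
        mu_pot = np.array(
            [growth_rate(s, h, model) for s in model.strains]
        )
        mu, D, consumption = _allocate_histidine(
            model, names, X, mu_pot, is_aux, h, dt_sub, state.od_setpoint
        )
        supply = D * (model.h_in - h)
        h_next = h + dt_sub * (supply - consumption)
        if h_next < -1e-9:
            raise RuntimeError("histidine went negative despite allocation")
        growth_total += dt_sub * float(mu @ X)
        dilution_total += dt_sub * D * float(X.sum())
        X = X * (1.0 + dt_sub * (mu - D))
        h = max(h_next, 0.0)
        t += dt_sub

    new_state = replace(
        state,
        densities={n: float(x) for n, x in zip(names, X)},
        histidine=float(h),
        time=float(t),
    )
    return TurbidostatStepResult(
        state=new_state,
        growth=float(growth_total),
        dilution=float(dilution_total),
        realized_mu={n: float(m) for n, m in zip(names, mu)},
    )


def steady_state_histidine(model: GrowthModel, od_setpoint: float) -> float:
    """Residual histidine at the held setpoint, uM.

    At steady state the dilution rate equals the mean growth rate and
    consumption is ``yield_q`` per OD of growth, so the flux balance
    D (h_in - h) = q D OD gives h = h_in - q OD, clamped at 0 in the
    depleted regime (where the auxotroph is growth-arrested).
    """
    return max(model.h_in - model.yield_q * od_setpoint, 0.0)


def run_competition(
    model: GrowthModel,
    od_setpoint: float,
    initial_aux_fraction: float = 5.0 / 6.0,
    duration_h: float = 24.0,
    sample_every_h: float = 2.0,
    inoculum_od: float | None = None,
) -> tuple[np.ndarray, np.ndarray, list[TurbidostatState]]:
    """Two-strain competition at a fixed OD setpoint.

    The culture starts at the setpoint (default) with the auxotroph at the
    5:1 mutant:WT inoculation ratio used in the competition assays, and
    fractions are recorded every ``sample_every_h`` (the 2 h automated
    cytometry cadence). Returns (times, auxotroph fractions, states).
    """
    aux = [s.name for s in model.strains if s.his_dependent]
    proto = [s.name for s in model.strains if not s.his_dependent]
    if len(aux) != 1 or len(proto) != 1:
        raise ValueError("competition needs exactly one auxotroph and one prototroph")
    od0 = od_setpoint if inoculum_od is None else inoculum_od
    state = TurbidostatState(
        densities={
            aux[0]: initial_aux_fraction * od0,
            proto[0]: (1.0 - initial_aux_fraction) * od0,
        },
        histidine=model.h_in,
        od_setpoint=od_setpoint,
    )
    times = [0.0]
    fracs = [state.fractions()[aux[0]]]
    states = [state]
    n = int(round(duration_h / sample_every_h))
    for _ in range(n):
        state = turbidostat_step(state, model, sample_every_h).state
        times.append(state.time)
        fracs.append(state.fractions()[aux[0]])
        states.append(state)
    return np.asarray(times), np.asarray(fracs), states


def delta_mu_curve(
    model: GrowthModel,
    od_setpoints: Sequence[float],
    settle_h: float = 20.0,
) -> np.ndarray:
    """Steady-state growth-rate difference (prototroph minus auxotroph).

    For each setpoint, the reactor is run to quasi-steady state from a
    50:50 inoculum and the realized specific growth rates are read off the
    simulator. Positive values mean the wild-type prototroph outgrows the
    his3 auxotroph at that density.
    """
    aux = [s.name for s in model.strains if s.his_dependent]
    proto = [s.name for s in model.strains if not s.his_dependent]
    if len(aux) != 1 or len(proto) != 1:
        raise ValueError("delta_mu_curve needs exactly one auxotroph and one prototroph")
    out = []
    for od in od_setpoints:
        state = TurbidostatState(
            densities={aux[0]: 0.5 * od, proto[0]: 0.5 * od},
            histidine=model.h_in,
            od_setpoint=od,
        )
        result = turbidostat_step(state, model, settle_h)
        mu = result.realized_mu
        out.append(mu[proto[0]] - mu[aux[0]])
    return np.asarray(out)


def sample_culture(
    state: TurbidostatState,
    model: GrowthModel,
    n_events: int,
    seed: int = 0,
    noise_sd: float = 0.1,
    fluor_overrides: Mapping[str, Mapping[str, float]] | None = None,
    doublet_fraction: float = 0.0,
    debris_fraction: float = 0.0,
) -> PopulationSpec:
    """Bridge the simulated culture to the synthetic cytometry generator.

    Strain fractions are proportional to biomass densities; per-strain
    fluorophore means come from each strain's constitutive levels, with
    ``fluor_overrides[strain][fluorophore]`` (raw instrument units)
    substituting dynamic levels such as the expression module's FP state
    for optogenetic reporters.
    """
    if n_events <= 0:
        raise ValueError("n_events must be > 0")
    if state.od <= 0:
        raise ValueError("cannot sample an empty culture")
    fractions = state.fractions()
    strains = []
    for strain in model.strains:
        frac = fractions.get(strain.name, 0.0)
        if frac <= 0:
            continue
        means = dict(strain.fluorophores)
        if fluor_overrides and strain.name in fluor_overrides:
            means.update(fluor_overrides[strain.name])
        strains.append(
            StrainPopulation(
                name=strain.name,
                fraction=frac,
                fluor_logmeans={f: float(np.log(v)) for f, v in means.items() if v > 0},
            )
        )
    total = sum(s.fraction for s in strains)
    strains = [replace(s, fraction=s.fraction / total) for s in strains]
    return PopulationSpec(
        strains=tuple(strains),
        n_events=n_events,
        doublet_fraction=doublet_fraction,
        debris_fraction=debris_fraction,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Plate reader with evaporation-compensated dilution


@dataclass(frozen=True)
class Well:
    """One microplate well: nominal 200 uL culture volume.

    ``media_antibiotic`` is the antibiotic concentration of this well's
    feed media (dilutions re-add drug at the configured concentration).
    """

    volume: float = 200.0
    od: float = 0.0
    antibiotic: float = 0.0
    media_antibiotic: float = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("well volume must be > 0")
        if self.od < 0 or self.antibiotic < 0 or self.media_antibiotic < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class PlateState:
    """A group of wells sharing one dilution protocol."""

    wells: tuple[Well, ...]
    blank_od: float = 0.0
    evaporation_rate: float = 10.0  # uL/h, the true physical rate
    nominal_volume: float = 200.0
    hours_since_dilution: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))


@dataclass(frozen=True)
class PlateAction:
    kind: str  # "dilute" | "feed" | "none"
    removed_volumes: tuple[float, ...] = ()
    warnings: tuple[str, ...] = ()


def evaporate(plate: PlateState, dt: float) -> PlateState:
    """Evaporation over ``dt`` hours: volume shrinks, solutes concentrate."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    loss = plate.evaporation_rate * dt
    wells = []
    for w in plate.wells:
        v_new = max(w.volume - loss, 1.0)
        factor = w.volume / v_new
        wells.append(replace(w, volume=v_new, od=w.od * factor, antibiotic=w.antibiotic * factor))
    return replace(
        plate,
        wells=tuple(wells),
        hours_since_dilution=plate.hours_since_dilution + dt,
        time=plate.time + dt,
    )


def _add_media(well: Well, volume: float, antibiotic: float) -> Well:
    v_new = well.volume + volume
    return replace(
        well,
        volume=v_new,
        od=well.od * well.volume / v_new,
        antibiotic=(well.antibiotic * well.volume + antibiotic * volume) / v_new,
    )


def plate_dilution_protocol(
    plate: PlateState,
    threshold: float,
    evaporation_estimate: float = 10.0,
    add_volume: float = 100.0,
    force_feed_after_h: float = 10.0,
) -> tuple[PlateAction, PlateState]:
    """One pass of the OD-triggered, evaporation-compensated dilution.

    If the median blank-subtracted OD exceeds ``threshold``: add
    ``add_volume`` uL of media (carrying each well's configured antibiotic
    concentration), mix, and remove ``add_volume - E`` uL where
    ``E = evaporation_estimate x hours since last dilution`` -- so volume
    returns exactly to nominal when the estimate matches the true rate.
    Otherwise, if ``force_feed_after_h`` hours have passed without a
    dilution, add ``add_volume`` uL with no removal (the well is assumed
    nearly dry). Removal is clamped at 0 (with a warning) if the estimated
    evaporation exceeds the added volume.
    """
    warnings: list[str] = []
    med = float(np.median([w.od for w in plate.wells])) - plate.blank_od
    if med > threshold:
        evap = evaporation_estimate * plate.hours_since_dilution
        removal = add_volume - evap
        if removal <= 0:
            warnings.append(
                f"estimated evaporation {evap:.1f} uL exceeds added volume; no removal"
            )
            removal = 0.0
        wells = []
        for w in plate.wells:
            w = _add_media(w, add_volume, w.media_antibiotic)
            wells.append(replace(w, volume=w.volume - removal))
        new = replace(plate, wells=tuple(wells), hours_since_dilution=0.0)
        return (
            PlateAction("dilute", tuple(removal for _ in wells), tuple(warnings)),
            new,
        )
    if plate.hours_since_dilution >= force_feed_after_h:
        wells = tuple(_add_media(w, add_volume, w.media_antibiotic) for w in plate.wells)
        new = replace(plate, wells=wells, hours_since_dilution=0.0)
        return PlateAction("feed", (), tuple(warnings)), new
    return PlateAction("none"), plate


def treat_well(
    plate: PlateState,
    index: int,
    dose: float,
    volume: float = 50.0,
) -> PlateState:
    """Add ``volume`` uL of antibiotic solution at concentration ``dose``
    (mg/L) to one well; cells are diluted and drug mixed by conservation."""
    if dose < 0 or volume <= 0:
        raise ValueError("dose must be >= 0 and volume > 0")
    wells = list(plate.wells)
    wells[index] = _add_media(wells[index], volume, dose)
    return replace(plate, wells=tuple(wells))


@dataclass(frozen=True)
class CleanOdResult:
    times: np.ndarray
    od: np.ndarray  # blank-subtracted, retained points only
    removed: np.ndarray  # mask over the input series
    n_removed: int


def clean_od(
    times: Sequence[float],
    od: Sequence[float],
    blank: float | Sequence[float],
    threshold: float = 3e-3,
    early_window_h: float = 2.0,
) -> CleanOdResult:
    """Blank-subtract an OD_600 series and drop early aberrant readings.

    The culture OD is the measured OD_600 minus the OD_600 of a control
    well without cells. Raw measurements exceeding ``threshold`` within
    the first ``early_window_h`` hours are instrument artifacts and are
    removed (the filter applies to the raw values and only to the early
    window).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    b = np.broadcast_to(np.asarray(blank, dtype=float), y.shape)
    if t.shape != y.shape:
        raise ValueError("times and od series must have matching lengths")
    removed = (t < early_window_h) & (y > threshold)
    keep = ~removed
    return CleanOdResult(
        times=t[keep],
        od=y[keep] - b[keep],
        removed=removed,
        n_removed=int(np.count_nonzero(removed)),
    )
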