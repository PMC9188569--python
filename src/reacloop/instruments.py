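"""Virtual instruments wired to the orchestrator's endpoint contract.

``OptoTurbidostat`` holds a yeast culture at its OD setpoint and carries
the light-driven expression circuit: ticks advance the expression ODE
exactly under the currently applied duty-cycle program, ``set_light``
replaces the program, ``read`` returns the (noise-free) FP median a
cytometry round would report. ``ConsortiumTurbidostat`` wraps the
two-strain nutrient-coupled turbidostat; its ``sample`` operation draws a
multinomial cytometry-sized sample of the composition with an explicit
seed, so every invocation is reproducible from the log.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any, Sequence

import numpy as np

from .control import LightMPCConfig, ODPlanConfig, RatioModelParams, plan_light, plan_od
from .expression import ExpressionParams, ExpressionState, LightProgram, estimate_state
from .orchestrator import ActionStep, Event, Experiment, InstrumentEndpoint, Periodic
from .virtual_lab import GrowthModel, TurbidostatState, turbidostat_step

__all__ = [
    "OptoTurbidostat",
    "ConsortiumTurbidostat",
    "build_light_mpc_loop",
    "build_ratio_control_loop",
]


class OptoTurbidostat(InstrumentEndpoint):
    """Virtual optogenetic turbidostat: OD held, expression ODE as plant."""

    def __init__(
        self,
        name: str,
        params: ExpressionParams,
        od_setpoint: float = 0.5,
        state: ExpressionState | None = None,
    ):
        self.params = params
        self.od_setpoint = od_setpoint
        self.state = state or ExpressionState(0.0, 0.0, t=0.0)
        self.program = LightProgram((), t_start=self.state.t)
        super().__init__(
            name,
            operations={
                "tick": self._tick,
                "read": self._read,
                "set_light": self._set_light,
                "set_od_setpoint": self._set_od_setpoint,
            },
        )

    def _tick(self, dt: float) -> dict[str, float]:
        from .expression import advance

        self.state = advance(self.params, self.state, self.program, dt)
        return {"t": self.state.t}

    def _read(self) -> dict[str, float]:
        return {"od": self.od_setpoint, "fp": self.state.fp, "t": self.state.t}

    def _set_light(self, duties: Sequence[float], period_min: float = 30.0) -> dict:
        self.program = LightProgram(tuple(duties), period_min=period_min, t_start=self.state.t)
        return {"n_cycles": len(self.program.duties), "t_start": self.program.t_start}

    def _set_od_setpoint(self, od: float) -> dict:
        self.od_setpoint = float(od)
        return {"od_setpoint": self.od_setpoint}

    def state_digest(self) -> dict[str, Any]:
        return {
            "od": self.od_setpoint,
            "fp": self.state.fp,
            "mrna": self.state.mrna,
            "t": self.state.t,
        }


class ConsortiumTurbidostat(InstrumentEndpoint):
    """Virtual two-strain turbidostat with nutrient-coupled fitness."""

    def __init__(self, name: str, model: GrowthModel, state: TurbidostatState):
        self.model = model
        self.state = state
        super().__init__(
            name,
            operations={
                "tick": self._tick,
                "read": self._read,
                "set_od_setpoint": self._set_od_setpoint,
                "sample": self._sample,
            },
        )

    def _tick(self, dt: float) -> dict[str, float]:
        self.state = turbidostat_step(self.state, self.model, dt).state
        return {"t": self.state.time, "od": self.state.od}

    def _read(self) -> dict[str, Any]:
        return {
            "od": self.state.od,
            "histidine": self.state.histidine,
            "fractions": self.state.fractions(),
            "t": self.state.time,
        }

    def _set_od_setpoint(self, od: float) -> dict:
        self.state = replace(self.state, od_setpoint=float(od))
        return {"od_setpoint": od}

    def _sample(self, n_events: int, seed: int) -> dict[str, Any]:
        """Cytometry-sized multinomial sample of the composition."""
        fracs = self.state.fractions()
        names = sorted(fracs)
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n_events, [fracs[n] for n in names])
        return {
            "counts": dict(zip(names, (int(c) for c in counts))),
            "fractions": dict(zip(names, (float(c) / n_events for c in counts))),
            "t": self.state.time,
        }

    def state_digest(self) -> dict[str, Any]:
        return {
            "od": self.state.od,
            "histidine": self.state.histidine,
            "t": self.state.time,
            **{f"x_{k}": v for k, v in self.state.densities.items()},
        }


# ---------------------------------------------------------------------------
# Canned closed loops expressed purely as events


def build_light_mpc_loop(
    reactor: OptoTurbidostat,
    target: float,
    config: LightMPCConfig = LightMPCConfig(),
) -> Event:
    """Hourly cytometry -> state estimate -> duty-cycle plan -> actuation.

    The controller closure keeps the applied light history (for the
    open-loop mRNA estimate) and the previous plan (warm start); the
    concrete duties it decides are logged by the ``set_light`` invocation,
    which is what makes the run replayable.
    """
    memory: dict[str, Any] = {"applied": [], "previous": None, "t_first": None}
    cycles_per_replan = int(round(config.replan_interval_h * 60.0 / config.period_min))

    def controller(exp: Experiment) -> dict[str, Any]:
        reading = exp.data["measurement"]
        if memory["t_first"] is None:
            memory["t_first"] = reading["t"]  # dark before the first actuation
        history = LightProgram(
            tuple(memory["applied"]),
            period_min=config.period_min,
            t_start=memory["t_first"],
        )
        est, _ = estimate_state(
            reading["fp"], history, reactor.params, t_sample=reading["t"]
        )
        plan = plan_light(est, target, reactor.params, config, previous=memory["previous"])
        memory["previous"] = plan.duties
        chunk = [float(u) for u in plan.duties[:cycles_per_replan]]
        memory["applied"].extend(chunk)
        return {"duties": chunk, "period_min": config.period_min}

    return Event(
        name="light-mpc",
        schedule=Periodic(config.replan_interval_h),
        action=[
            ActionStep(reactor.name, "read", store="measurement", publish="cytometry"),
            ActionStep(reactor.name, "set_light", params=controller),
        ],
    )


def build_ratio_control_loop(
    reactor: ConsortiumTurbidostat,
    target_ratio: float,
    ratio_model: RatioModelParams,
    numerator: str,
    config: ODPlanConfig = ODPlanConfig(),
    n_events: int = 10000,
    seed: int = 0,
    cadence_h: float = 2.0,
) -> Event:
    """Periodic cytometry sampling feeding the OD-setpoint planner."""
    memory: dict[str, Any] = {"previous": None, "round": 0}

    def sample_params(exp: Experiment) -> dict[str, Any]:
        memory["round"] += 1
        return {"n_events": n_events, "seed": seed + memory["round"]}

    def controller(exp: Experiment) -> dict[str, Any]:
        measured = exp.data["composition"]["fractions"][numerator]
        measured = min(max(measured, 1e-6), 1.0 - 1e-6)
        plan = plan_od(measured, target_ratio, ratio_model, config, previous=memory["previous"])
        memory["previous"] = plan.setpoints
        return {"od": float(plan.setpoints[0])}

    return Event(
        name="ratio-control",
        schedule=Periodic(cadence_h),
        action=[
            ActionStep(reactor.name, "sample", params=sample_params,
                       store="composition", publish="cytometry"),
            ActionStep(reactor.name, "set_od_setpoint", params=controller),
        ],
    )
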