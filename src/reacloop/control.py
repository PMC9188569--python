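"""Receding-horizon model-predictive controllers.

Two controllers mirror the platform's two closed loops:

* ``plan_light`` -- given the current expression-state estimate and an FP
  target, choose the next sequence of blue-light duty fractions (default
  10 cycles of 30 min, a 5 h horizon) minimizing the model-predicted mean
  squared deviation of FP from the target on a fine grid over the horizon.
* ``plan_od`` -- given the current consortium composition (auxotroph
  fraction) and a target, choose a vector of future OD setpoints (default
  5 blocks of 2 h, a 10 h horizon) so that the predicted ratio, driven by
  the fitted steady-state growth-rate difference curve, reaches the target.

Both are bounded, gradient-based searches with seeded multi-starts and a
receding-horizon warm start; on total optimizer failure the previous plan
is kept (fail-safe contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

from .expression import ExpressionParams, ExpressionState, LightProgram, simulate

__all__ = [
    "LightMPCConfig",
    "LightPlan",
    "plan_light",
    "RatioModelParams",
    "RatioFitResult",
    "fit_ratio_model",
    "ratio_dynamics",
    "ODPlanConfig",
    "ODPlan",
    "plan_od",
    "ClosedLoopResult",
    "closed_loop_light_control",
]

_BOUND_SNAP = 1e-10  # snap optimizer output this close to a bound onto it


# ---------------------------------------------------------------------------
# Light MPC


@dataclass(frozen=True)
class LightMPCConfig:
    """Settings for the duty-cycle planner.

    ``n_cycles`` 30-min cycles make the 5 h receding horizon; the objective
    is evaluated every ``eval_step_min`` minutes; re-planning happens every
    ``replan_interval_h`` (hourly cytometry cadence).
    """

    n_cycles: int = 10
    period_min: float = 30.0
    duty_bounds: tuple[float, float] = (0.0, 1.0)
    eval_step_min: float = 6.0
    replan_interval_h: float = 1.0
    n_random_starts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.period_min <= 0 or self.eval_step_min <= 0:
            raise ValueError("n_cycles, period_min, eval_step_min must be positive")
        lo, hi = self.duty_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("duty_bounds must satisfy 0 <= lo < hi <= 1")

    @property
    def horizon_h(self) -> float:
        return self.n_cycles * self.period_min / 60.0


@dataclass(frozen=True)
class LightPlan:
    duties: np.ndarray
    objective: float
    saturated: bool
    success: bool
    records: tuple[str, ...] = ()


def _light_objective(
    duties: np.ndarray,
    state: ExpressionState,
    target: float,
    params: ExpressionParams,
    config: LightMPCConfig,
    grid: np.ndarray,
) -> float:
    program = LightProgram(tuple(duties), period_min=config.period_min, t_start=state.t)
    traj = simulate(params, state, program, grid)
    dev = traj.fp - target
    return float(np.mean(dev * dev))


def _multistart_minimize(
    objective: Callable[[np.ndarray], float],
    starts: Sequence[np.ndarray],
    bounds: Sequence[tuple[float, float]],
) -> tuple[np.ndarray | None, float, list[str]]:
    """Bounded L-BFGS-B from several starts; best solution wins."""
    best_x, best_f = None, np.inf
    records: list[str] = []
    for x0 in starts:
        try:
            sol = minimize(
                objective,
                np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
            )
        except Exception as exc:  # noqa: BLE001 - fail-safe contract
            records.append(f"start failed: {exc}")
            continue
        if np.isfinite(sol.fun) and sol.fun < best_f - 1e-18:
            best_x, best_f = np.asarray(sol.x, dtype=float), float(sol.fun)
    return best_x, best_f, records


def plan_light(
    state: ExpressionState,
    target: float,
    params: ExpressionParams,
    config: LightMPCConfig = LightMPCConfig(),
    previous: Sequence[float] | None = None,
) -> LightPlan:
    """Optimal duty fractions for the next ``n_cycles`` light cycles.

    Minimizes the mean squared deviation of model-predicted FP from
    ``target`` on the evaluation grid over the horizon. Deterministic given
    the config seed; the start list is the shifted previous plan (warm
    start), three constant profiles, and seeded uniform draws. Unreachable
    targets saturate at the duty bounds and set the ``saturated`` flag.
    """
    if target < 0:
        raise ValueError("target must be >= 0")
    n = config.n_cycles
    step_h = config.eval_step_min / 60.0
    grid = state.t + np.arange(step_h, config.horizon_h + 1e-9, step_h)
    bounds = [config.duty_bounds] * n

    def objective(u: np.ndarray) -> float:
        return _light_objective(u, state, target, params, config, grid)

    rng = np.random.default_rng(config.seed)
    starts: list[np.ndarray] = []
    if previous is not None and len(previous) == n:
        warm = np.append(np.asarray(previous, dtype=float)[1:], previous[-1])
        starts.append(warm)
    starts += [np.full(n, c) for c in (0.0, 0.5, 1.0)]
    starts += [rng.uniform(*config.duty_bounds, size=n) for _ in range(config.n_random_starts)]

    best_x, best_f, records = _multistart_minimize(objective, starts, bounds)
    if best_x is None:
        fallback = (
            np.asarray(previous, dtype=float) if previous is not None else np.zeros(n)
        )
        records.append("all optimizer starts failed; keeping previous plan")
        return LightPlan(
            duties=fallback,
            objective=objective(fallback),
            saturated=False,
            success=False,
            records=tuple(records),
        )
    lo, hi = config.duty_bounds
    best_x[best_x < lo + _BOUND_SNAP] = lo
    best_x[best_x > hi - _BOUND_SNAP] = hi
    saturated = bool(
        np.all((best_x == lo) | (best_x == hi)) and best_f > 1e-10
    )
    return LightPlan(
        duties=best_x, objective=best_f, saturated=saturated, success=True,
        records=tuple(records),
    )


# ---------------------------------------------------------------------------
# Consortium ratio model and dynamics


@dataclass(frozen=True)
class RatioModelParams:
    """Sigmoidal steady-state growth-rate difference vs OD setpoint.

    delta_mu(OD) = c0 - c1 / (1 + exp(-(OD - c2) / c3))   [h^-1]

    The sign convention is auxotroph minus prototroph: positive means the
    auxotroph (numerator strain of the ratio) gains. For c1 > 0 the curve is
    monotone non-increasing in OD -- high OD depletes the shared nutrient
    and slows the auxotroph.
    """

    c0: float
    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        if self.c3 <= 0:
            raise ValueError("c3 (OD width) must be > 0")

    def delta_mu(self, od: float | np.ndarray) -> float | np.ndarray:
        z = -(np.asarray(od, dtype=float) - self.c2) / self.c3
        out = self.c0 - self.c1 / (1.0 + np.exp(z))
        return float(out) if np.isscalar(od) else out

    def as_array(self) -> np.ndarray:
        return np.array([self.c0, self.c1, self.c2, self.c3])


@dataclass(frozen=True)
class RatioFitResult:
    params: RatioModelParams
    residuals: np.ndarray
    cost: float


def fit_ratio_model(
    od: Sequence[float],
    delta_mu: Sequence[float],
    n_starts: int = 20,
    seed: int = 0,
    c3_bounds: tuple[float, float] = (1e-3, 1.0),
) -> RatioFitResult:
    """Least-squares sigmoid fit of measured growth-rate differences.

    Needs at least four distinct OD values (four parameters). Multi-start
    bounded least squares; the start list begins with the degenerate flat
    model (c1 = 0 at the mean) so constant data resolves deterministically
    to c1 -> 0.
    """
    od_arr = np.asarray(od, dtype=float)
    dmu_arr = np.asarray(delta_mu, dtype=float)
    if od_arr.shape != dmu_arr.shape or od_arr.ndim != 1:
        raise ValueError("od and delta_mu must be matching 1-d sequences")
    if np.unique(od_arr).size < 4:
        raise ValueError("need at least 4 distinct OD values to fit 4 parameters")

    span = float(od_arr.max() - od_arr.min()) or 1.0
    amp = float(dmu_arr.max() - dmu_arr.min())
    lo = np.array([-2.0, 0.0, od_arr.min() - span, c3_bounds[0]])
    hi = np.array([2.0, 2.0, od_arr.max() + span, c3_bounds[1]])

    def residuals(c: np.ndarray) -> np.ndarray:
        p = RatioModelParams(*c)
        return p.delta_mu(od_arr) - dmu_arr

    rng = np.random.default_rng(seed)
    mid = float(od_arr.mean())
    starts = [
        np.array([float(dmu_arr.mean()), 0.0, mid, span / 8.0]),
        np.array([float(dmu_arr.max()), max(amp, 1e-3), mid, span / 8.0]),
    ]
    for _ in range(max(n_starts - len(starts), 0)):
        starts.append(rng.uniform(np.maximum(lo, [-0.5, 0, od_arr.min(), c3_bounds[0]]),
                                  np.minimum(hi, [0.5, 1.0, od_arr.max(), 0.5])))

    best: tuple[float, np.ndarray] | None = None
    for x0 in starts:
        try:
            sol = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # noqa: BLE001
            continue
        if sol.success and (best is None or sol.cost < best[0] - 1e-15):
            best = (float(sol.cost), sol.x.copy())
    if best is None:
        raise RuntimeError("sigmoid fit failed from every start")
    params = RatioModelParams(*best[1])
    res = residuals(best[1])
    return RatioFitResult(params=params, residuals=res, cost=best[0])


def ratio_dynamics(
    r0: float,
    od_times: Sequence[float],
    od_values: Sequence[float],
    params: RatioModelParams,
    times: Sequence[float],
) -> np.ndarray:
    """Auxotroph-fraction trajectory under a piecewise-constant OD profile.

    At steady state the two-strain odds grow exponentially at the
    growth-rate difference, so the log-odds obey
    d/dt log(r / (1 - r)) = delta_mu(OD(t)), integrated exactly on each
    constant-OD segment. ``od_values[k]`` holds on
    [od_times[k], od_times[k+1]) and the last value extends indefinitely.
    r0 in {0, 1} is absorbing (constant trajectory).
    """
    t_grid = np.asarray(times, dtype=float)
    if not (0.0 <= r0 <= 1.0):
        raise ValueError("r0 must lie in [0, 1]")
    if r0 in (0.0, 1.0):
        return np.full_like(t_grid, r0)
    bt = np.asarray(od_times, dtype=float)
    vals = np.asarray(od_values, dtype=float)
    if bt.shape != vals.shape or bt.ndim != 1 or bt.size == 0:
        raise ValueError("od_times and od_values must be matching non-empty 1-d")
    if np.any(np.diff(bt) <= 0):
        raise ValueError("od_times must be strictly increasing")
    t0 = float(bt[0])
    if np.any(t_grid < t0 - 1e-12):
        raise ValueError("times must start at or after the OD profile start")

    dmu = np.asarray(params.delta_mu(vals), dtype=float)
    ends = np.append(bt[1:], np.inf)
    logit0 = np.log(r0 / (1.0 - r0))
    out = np.empty_like(t_grid)
    for i, t in enumerate(t_grid):
        overlap = np.clip(np.minimum(ends, t) - bt, 0.0, None)
        logit = logit0 + float(np.sum(dmu * overlap))
        out[i] = 1.0 / (1.0 + np.exp(-logit))
    return out


# ---------------------------------------------------------------------------
# OD-setpoint MPC


@dataclass(frozen=True)
class ODPlanConfig:
    """OD-setpoint planning: 5 blocks of 2 h (a 10 h horizon) by default,
    setpoints bounded to the explored range [0.1, 0.8]."""

    n_blocks: int = 5
    block_h: float = 2.0
    od_bounds: tuple[float, float] = (0.1, 0.8)
    n_random_starts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_h <= 0:
            raise ValueError("n_blocks and block_h must be positive")
        lo, hi = self.od_bounds
        if not (0 < lo < hi):
            raise ValueError("od_bounds must satisfy 0 < lo < hi")

    @property
    def horizon_h(self) -> float:
        return self.n_blocks * self.block_h


@dataclass(frozen=True)
class ODPlan:
    setpoints: np.ndarray
    objective: float
    saturated: bool
    success: bool
    records: tuple[str, ...] = ()


def plan_od(
    current_ratio: float,
    target_ratio: float,
    params: RatioModelParams,
    config: ODPlanConfig = ODPlanConfig(),
    previous: Sequence[float] | None = None,
) -> ODPlan:
    """Optimal OD setpoints steering the consortium ratio to the target.

    Minimizes the summed squared deviation of the predicted auxotroph
    fraction from ``target_ratio`` at the end of each 2-h block, using the
    exact odds-space dynamics under the fitted sigmoid. Bounded,
    gradient-based, seeded multi-start; fail-safe to the previous plan.
    """
    for name, r in (("current_ratio", current_ratio), ("target_ratio", target_ratio)):
        if not (0.0 < r < 1.0):
            raise ValueError(f"{name} must lie strictly in (0, 1)")
    n = config.n_blocks
    block_ends = config.block_h * np.arange(1, n + 1)
    block_starts = config.block_h * np.arange(n)

    def objective(ods: np.ndarray) -> float:
        r = ratio_dynamics(current_ratio, block_starts, ods, params, block_ends)
        dev = r - target_ratio
        return float(np.sum(dev * dev))

    lo, hi = config.od_bounds
    rng = np.random.default_rng(config.seed)
    starts: list[np.ndarray] = []
    if previous is not None and len(previous) == n:
        starts.append(np.append(np.asarray(previous, dtype=float)[1:], previous[-1]))
    starts += [np.full(n, c) for c in (lo, 0.5 * (lo + hi), hi)]
    starts += [rng.uniform(lo, hi, size=n) for _ in range(config.n_random_starts)]

    best_x, best_f, records = _multistart_minimize(objective, starts, [(lo, hi)] * n)
    if best_x is None:
        fallback = (
            np.asarray(previous, dtype=float)
            if previous is not None
            else np.full(n, 0.5 * (lo + hi))
        )
        records.append("all optimizer starts failed; keeping previous plan")
        return ODPlan(fallback, objective(fallback), False, False, tuple(records))
    best_x[best_x < lo + _BOUND_SNAP] = lo
    best_x[best_x > hi - _BOUND_SNAP] = hi
    saturated = bool(np.all((best_x == lo) | (best_x == hi)) and best_f > 1e-10)
    return ODPlan(best_x, best_f, saturated, True, tuple(records))


# ---------------------------------------------------------------------------
# Closed-loop light control on the (noise-free) model plant


@dataclass(frozen=True)
class ClosedLoopResult:
    times: np.ndarray
    fp: np.ndarray
    mrna: np.ndarray
    applied_duties: np.ndarray
    target: float

    @property
    def final_relative_error(self) -> float:
        return abs(self.fp[-1] - self.target) / max(self.target, 0.1)


def closed_loop_light_control(
    params: ExpressionParams,
    target: float,
    duration_h: float = 10.0,
    config: LightMPCConfig = LightMPCConfig(),
    delay_h: float = 0.0,
    measure: Callable[[float], float] | None = None,
) -> ClosedLoopResult:
    """Hourly re-planned light MPC against the expression model as plant.

    Every ``replan_interval_h`` the plant FP is measured (identity by
    default, or through ``measure`` to inject noise), the hybrid state
    estimate is formed (open-loop mRNA from the full light history, FP from
    the measurement, both advanced by ``delay_h``), a fresh duty plan is
    optimized warm-started from the previous one, and the first re-plan
    interval of the plan is applied to the plant.
    """
    from .expression import estimate_state  # local import keeps module API tidy

    cycles_per_replan = int(round(config.replan_interval_h * 60.0 / config.period_min))
    if cycles_per_replan < 1:
        raise ValueError("replan interval shorter than one light cycle")
    n_replans = int(round(duration_h / config.replan_interval_h))

    state = ExpressionState(0.0, 0.0, t=0.0)
    applied: list[float] = []
    previous: np.ndarray | None = None
    rec_t = [0.0]
    rec_fp = [0.0]
    rec_m = [0.0]
    for _ in range(n_replans):
        raw = state.fp if measure is None else measure(state.fp)
        history = LightProgram(tuple(applied), period_min=config.period_min, t_start=0.0)
        est, _ = estimate_state(
            raw, history, params, t_sample=state.t, delay=delay_h
        )
        plan = plan_light(est, target, params, config, previous=previous)
        previous = plan.duties
        chunk = plan.duties[:cycles_per_replan]
        program = LightProgram(tuple(chunk), period_min=config.period_min, t_start=state.t)
        grid = state.t + np.arange(1, cycles_per_replan + 1) * config.period_min / 60.0
        traj = simulate(params, state, program, grid)
        state = traj.final
        applied.extend(chunk)
        rec_t.extend(traj.times.tolist())
        rec_fp.extend(traj.fp.tolist())
        rec_m.extend(traj.mrna.tolist())
    return ClosedLoopResult(
        times=np.asarray(rec_t),
        fp=np.asarray(rec_fp),
        mrna=np.asarray(rec_m),
        applied_duties=np.asarray(applied),
        target=target,
    )
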