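"""Event-driven experiment orchestration over in-process instruments.

The architecture mirrors a reactive lab-automation stack: instruments
expose named operations through a uniform request/response contract
(status, payload, timestamp), an experiment loop advances virtual
instruments in discrete ticks, evaluates event conditions on the fresh
state, executes fired actions, and logs every instrument invocation and
event firing into a single append-only record sequence (JSON lines,
ISO-8601 timestamps).

The network layer of the original architecture is abstracted away: an
``InstrumentEndpoint`` is called in-process with the same semantics an
HTTP endpoint would have (every invocation returns a status; unavailable
endpoints reject rather than hang), which keeps the full control surface
testable without sockets.

Because every state-changing instrument call is logged with its concrete
parameters -- including parameters computed at fire time by controllers --
re-executing the logged invocation sequence against freshly initialized
instruments reproduces the final state bit-for-bit (``replay``).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Response",
    "InstrumentEndpoint",
    "OneShot",
    "Periodic",
    "OnData",
    "ActionStep",
    "Event",
    "EventHandle",
    "LogRecord",
    "ExperimentLog",
    "Experiment",
    "run_experiment",
    "replay",
    "format_notification",
]

_EPOCH = datetime.datetime(2021, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class Response:
    """Outcome of one instrument invocation."""

    status: str  # "ok" | "error" | "unavailable"
    payload: Any = None
    time: float = 0.0

    @property
    def ok(self) -> bool:
        return self.status == "ok"


class InstrumentEndpoint:
    """A named instrument exposing a set of operations.

    Operations are callables invoked with keyword parameters; whatever they
    return becomes the response payload. Exceptions become ``error``
    responses; an unavailable endpoint rejects with ``unavailable`` rather
    than hanging. Subclasses may override ``state_digest`` to expose their
    state for notifications and replay verification.
    """

    def __init__(
        self,
        name: str,
        operations: Mapping[str, Callable[..., Any]] | None = None,
        available: bool = True,
    ):
        self.name = name
        self.operations: dict[str, Callable[..., Any]] = dict(operations or {})
        self.available = available

    def invoke(self, operation: str, *, time: float = 0.0, **params: Any) -> Response:
        if not self.available:
            return Response("unavailable", f"{self.name} is unavailable", time)
        fn = self.operations.get(operation)
        if fn is None:
            return Response("error", f"unknown operation {operation!r}", time)
        try:
            return Response("ok", fn(**params), time)
        except Exception as exc:  # noqa: BLE001 - becomes an error response
            return Response("error", f"{type(exc).__name__}: {exc}", time)

    def state_digest(self) -> dict[str, Any]:
        return {}


# ---------------------------------------------------------------------------
# Events


@dataclass(frozen=True)
class OneShot:
    """Fires at most once, as soon as the condition holds."""


@dataclass(frozen=True)
class Periodic:
    """Fires at each completion of ``interval_h`` (never at t = 0)."""

    interval_h: float

    def __post_init__(self) -> None:
        if self.interval_h <= 0:
            raise ValueError("interval_h must be > 0")


@dataclass(frozen=True)
class OnData:
    """Fires once per new arrival on a named data topic."""

    topic: str


@dataclass(frozen=True)
class ActionStep:
    """One instrument invocation inside an event's action.

    ``params`` may be a concrete mapping or a callable evaluated on the
    experiment at fire time (e.g. a controller computing duty cycles from
    the latest measurement); the concrete values are what gets logged.
    ``publish`` posts the response payload on a data topic (triggering
    on-data events); ``store`` keeps it in the experiment data store for
    later steps.
    """

    instrument: str
    operation: str
    params: Mapping[str, Any] | Callable[["Experiment"], Mapping[str, Any]] = field(
        default_factory=dict
    )
    publish: str | None = None
    store: str | None = None


@dataclass
class Event:
    """If *this* happens, do *this*.

    ``condition`` is a side-effect-free predicate over the experiment;
    ``action`` is an ordered list of instrument invocations executed
    atomically in order with per-step logging (an error response aborts
    the remaining steps of this firing, and the loop continues).
    """

    name: str
    action: Sequence[ActionStep]
    schedule: OneShot | Periodic | OnData = field(default_factory=OneShot)
    condition: Callable[["Experiment"], bool] = lambda exp: True
    enabled: bool = True


class EventHandle:
    def __init__(self, event: Event):
        self._event = event

    def enable(self) -> None:
        self._event.enabled = True

    def disable(self) -> None:
        self._event.enabled = False

    @property
    def enabled(self) -> bool:
        return self._event.enabled


# ---------------------------------------------------------------------------
# Log


def _jsonable(value: Any) -> Any:
    """Round-trippable JSON form of invocation parameters."""
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def _digest(payload: Any) -> str:
    try:
        text = json.dumps(_jsonable(payload), sort_keys=True, default=repr)
    except TypeError:
        text = repr(payload)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class LogRecord:
    seq: int
    t: float  # simulated hours
    timestamp: str  # ISO-8601, derived from the simulated clock
    source: str  # "instrument" | "event"
    name: str  # endpoint or event name
    operation: str
    params: dict[str, Any]
    outcome: str
    payload_digest: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "seq": self.seq,
                "t": self.t,
                "timestamp": self.timestamp,
                "source": self.source,
                "name": self.name,
                "operation": self.operation,
                "params": self.params,
                "outcome": self.outcome,
                "payload_digest": self.payload_digest,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "LogRecord":
        d = json.loads(line)
        return cls(**d)


class ExperimentLog:
    """Append-only, totally ordered (time, then sequence) record list."""

    def __init__(self) -> None:
        self.records: list[LogRecord] = []

    def append(self, **kwargs: Any) -> LogRecord:
        stamp = (_EPOCH + datetime.timedelta(hours=kwargs["t"])).isoformat()
        rec = LogRecord(seq=len(self.records), timestamp=stamp, **kwargs)
        self.records.append(rec)
        return rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def instrument_records(self) -> list[LogRecord]:
        return [r for r in self.records if r.source == "instrument"]

    def event_records(self) -> list[LogRecord]:
        return [r for r in self.records if r.source == "event"]

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(rec.to_json() + "\n")

    @classmethod
    def from_jsonl(cls, path: str) -> "ExperimentLog":
        log = cls()
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    log.records.append(LogRecord.from_json(line))
        return log


# ---------------------------------------------------------------------------
# Experiment loop


class Experiment:
    """Discrete-time reactive experiment over registered instruments."""

    def __init__(self, instruments: Iterable[InstrumentEndpoint], tick_h: float = 1.0 / 60.0):
        if tick_h <= 0:
            raise ValueError("tick_h must be > 0")
        self.instruments: dict[str, InstrumentEndpoint] = {}
        for inst in instruments:
            if inst.name in self.instruments:
                raise ValueError(f"duplicate instrument name {inst.name!r}")
            self.instruments[inst.name] = inst
        self.tick_h = tick_h
        self.time = 0.0
        self.log = ExperimentLog()
        self.data: dict[str, Any] = {}
        self.last_event: str | None = None
        self._events: dict[str, Event] = {}
        self._fired_once: set[str] = set()
        self._next_due: dict[str, float] = {}
        self._arrivals: list[str] = []

    # -- events --------------------------------------------------------------
    def register_event(self, event: Event) -> EventHandle:
        if event.name in self._events:
            raise ValueError(f"duplicate event name {event.name!r}")
        self._events[event.name] = event
        if isinstance(event.schedule, Periodic):
            self._next_due[event.name] = event.schedule.interval_h
        return EventHandle(event)

    # -- instrument access ---------------------------------------------------
    def invoke(self, instrument: str, operation: str, **params: Any) -> Response:
        endpoint = self.instruments[instrument]
        clean = {k: _jsonable(v) for k, v in params.items()}
        response = endpoint.invoke(operation, time=self.time, **params)
        self.log.append(
            t=self.time,
            source="instrument",
            name=instrument,
            operation=operation,
            params=clean,
            outcome=response.status,
            payload_digest=_digest(response.payload),
        )
        return response

    def publish(self, topic: str, payload: Any) -> None:
        self.data[topic] = payload
        self._arrivals.append(topic)

    # -- main loop -----------------------------------------------------------
    def run(self, duration_h: float) -> ExperimentLog:
        n_ticks = int(round(duration_h / self.tick_h))
        for k in range(1, n_ticks + 1):
            for inst in self.instruments.values():
                if "tick" in inst.operations:
                    self.invoke(inst.name, "tick", dt=self.tick_h)
            self.time = k * self.tick_h
            self._process_events()
        return self.log

    def _due(self, event: Event) -> bool:
        sched = event.schedule
        if isinstance(sched, Periodic):
            return self.time >= self._next_due[event.name] - 1e-9
        if isinstance(sched, OnData):
            return sched.topic in self._arrivals
        return event.name not in self._fired_once

    def _process_events(self) -> None:
        # On-data cascades settle within the tick; each event fires at most
        # once per tick, ties broken by registration order.
        fired_this_tick: set[str] = set()
        for _ in range(len(self._events) + 1):
            progressed = False
            for event in list(self._events.values()):
                if not event.enabled or event.name in fired_this_tick:
                    continue
                if not self._due(event):
                    continue
                if not event.condition(self):
                    continue
                fired_this_tick.add(event.name)
                progressed = True
                if isinstance(event.schedule, Periodic):
                    self._next_due[event.name] += event.schedule.interval_h
                elif isinstance(event.schedule, OneShot):
                    self._fired_once.add(event.name)
                self._fire(event)
            self._arrivals = [
                t for t in self._arrivals
                if any(
                    isinstance(e.schedule, OnData)
                    and e.schedule.topic == t
                    and e.enabled
                    and e.name not in fired_this_tick
                    for e in self._events.values()
                )
            ]
            if not progressed:
                break

    def _fire(self, event: Event) -> None:
        self.last_event = event.name
        self.log.append(
            t=self.time,
            source="event",
            name=event.name,
            operation="fire",
            params={},
            outcome="ok",
            payload_digest=_digest(None),
        )
        for step in event.action:
            params = step.params(self) if callable(step.params) else dict(step.params)
            response = self.invoke(step.instrument, step.operation, **params)
            if not response.ok:
                break
            if step.store is not None:
                self.data[step.store] = response.payload
            if step.publish is not None:
                self.publish(step.publish, response.payload)

    # -- reporting -----------------------------------------------------------
    def state_digests(self) -> dict[str, dict[str, Any]]:
        return {name: inst.state_digest() for name, inst in self.instruments.items()}


def run_experiment(
    instruments: Iterable[InstrumentEndpoint],
    events: Iterable[Event],
    duration_h: float,
    tick_h: float = 1.0 / 60.0,
) -> tuple[ExperimentLog, Experiment]:
    """Build an experiment, register events, run it, return log and state."""
    exp = Experiment(instruments, tick_h=tick_h)
    for event in events:
        exp.register_event(event)
    exp.run(duration_h)
    return exp.log, exp


def replay(
    log: ExperimentLog,
    instruments: Iterable[InstrumentEndpoint],
) -> dict[str, dict[str, Any]]:
    """Re-execute the logged instrument invocations on fresh instruments.

    Event logic is not re-run: the log already contains every instrument
    invocation with concrete parameters, so determinism plus log
    completeness make the final instrument states reproduce bit-for-bit.
    Returns the final state digests.
    """
    by_name = {inst.name: inst for inst in instruments}
    for rec in log.instrument_records():
        by_name[rec.name].invoke(rec.operation, time=rec.t, **rec.params)
    return {name: inst.state_digest() for name, inst in by_name.items()}


def format_notification(experiment: Experiment) -> str:
    """Deterministic human-readable status digest (no network delivery).

    One header line with the experiment clock, one line per instrument
    with its numeric state formatted to 3 significant digits, and the last
    event fired.
    """

    def fmt(value: Any) -> str:
        if isinstance(value, (int, float, np.floating, np.integer)) and not isinstance(
            value, bool
        ):
            return f"{float(value):.3g}"
        return str(value)

    lines = [f"[reacloop] status at t = {experiment.time:.3g} h"]
    for name in sorted(experiment.instruments):
        digest = experiment.instruments[name].state_digest()
        if digest:
            body = ", ".join(f"{k}={fmt(v)}" for k, v in sorted(digest.items()))
            lines.append(f"  {name}: {body}")
        else:
            lines.append(f"  {name}: (no state)")
    if experiment.last_event is not None:
        lines.append(f"  last event: {experiment.last_event}")
    return "\n".join(lines)
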