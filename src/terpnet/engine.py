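"""Hybrid functional Petri net (HFPNe) representation and fixed-step simulation.

The net is bipartite: *places* hold state (continuous places carry nonnegative
real marks, generic places carry booleans or numbers used as switches and
parameter modulators), *transitions* move it. Continuous transitions fire at a
rate given by a speed expression; each normal arc then transfers
``weight * speed * dt`` units per step. Test arcs enable without consuming
(enzymes); inhibitory arcs disable a transition while the inhibitor place sits
at or above the arc threshold (strict inequality enables). Generic transitions
carry guarded assignment rules evaluated after the continuous update.

Integration is explicit fixed-step Euler: all speeds are evaluated
simultaneously from the pre-step marking, a one-pass starvation guard zeroes
any transition whose per-step demand would overdraw a source place, and the
marking is updated in one shot. This keeps firing deterministic and
order-independent, and guarantees nonnegative continuous marks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .expressions import CompiledExpression, ExpressionError, compile_expression

CONTINUOUS = "continuous"
GENERIC = "generic"

NORMAL = "normal"
TEST = "test"
INHIBITORY = "inhibitory"

#: Default divergence bound: simulation aborts if any marking exceeds this.
DEFAULT_OVERFLOW_BOUND = 1e9


class EngineError(RuntimeError):
    """Raised for structural faults discovered while simulating."""


class DivergenceError(EngineError):
    """A continuous marking exceeded the overflow bound."""

    def __init__(self, place: str, value: float, time: float, bound: float):
        super().__init__(
            f"marking of place {place!r} diverged to {value:g} at t={time:g} pt "
            f"(overflow bound {bound:g})"
        )
        self.place = place
        self.value = value
        self.time = time


# ---------------------------------------------------------------------------
# network specification types


@dataclass
class PlaceSpec:
    id: str
    kind: str = CONTINUOUS
    initial: Union[float, bool] = 0.0
    compartment: str = ""
    label: str = ""


@dataclass
class ArcSpec:
    """Arc between a place and a transition.

    ``threshold`` is an expression (or number): normal/test arcs enable their
    transition when the source marking is >= threshold, inhibitory arcs when
    the source marking is strictly below it. ``guard`` (optional boolean
    expression) makes the arc conditional: while false the arc neither gates
    nor consumes — used for the crosstalk substrate arcs that are live only
    when the corresponding pathway switch is on.
    """

    kind: str
    source: str
    target: str
    weight: float = 1.0
    threshold: Union[str, float] = 0.0
    guard: Optional[str] = None


@dataclass
class GenericUpdate:
    """Guarded assignment carried by a generic transition: when ``guard`` holds
    at the post-step time, ``target`` place is assigned the value expression."""

    guard: str
    target: str
    value: str


@dataclass
class TransitionSpec:
    id: str
    kind: str = CONTINUOUS
    speed: Optional[Union[str, float]] = None
    update: Optional[GenericUpdate] = None
    compartment: str = ""
    label: str = ""


@dataclass
class NetworkSpec:
    places: list[PlaceSpec] = field(default_factory=list)
    transitions: list[TransitionSpec] = field(default_factory=list)
    arcs: list[ArcSpec] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)
    overflow_bound: float = DEFAULT_OVERFLOW_BOUND

    def place(self, place_id: str) -> PlaceSpec:
        for p in self.places:
            if p.id == place_id:
                return p
        raise KeyError(place_id)

    def transition(self, transition_id: str) -> TransitionSpec:
        for t in self.transitions:
            if t.id == transition_id:
                return t
        raise KeyError(transition_id)

    def place_ids(self) -> list[str]:
        return [p.id for p in self.places]


@dataclass
class SimState:
    """Current Petri net time (pt) and the marking of every place."""

    time: float
    marking: dict[str, Union[float, bool]]

    def copy(self) -> "SimState":
        return SimState(self.time, dict(self.marking))


@dataclass
class Trace:
    """Time-indexed record of all place markings at a sampling interval."""

    times: np.ndarray
    series: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __contains__(self, species: str) -> bool:
        return species in self.series

    def __getitem__(self, species: str) -> np.ndarray:
        try:
            return self.series[species]
        except KeyError:
            raise KeyError(f"species {species!r} not in trace") from None

    def terminal(self, species: str) -> float:
        return float(self[species][-1])

    def to_dataframe(self):
        import pandas as pd

        data = {"time_pt": self.times}
        data.update({k: v for k, v in self.series.items()})
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok

    def raise_if_invalid(self) -> None:
        if self.violations:
            raise EngineError("invalid network:\n" + "\n".join(self.violations))


def validate_network(net: NetworkSpec) -> ValidationReport:
    """Check structural well-formedness; returns a report listing every violation."""
    report = ValidationReport()
    add = report.violations.append

    place_ids = set()
    for p in net.places:
        if p.id in place_ids:
            add(f"duplicate place id {p.id!r}")
        place_ids.add(p.id)
        if p.kind not in (CONTINUOUS, GENERIC):
            add(f"place {p.id!r}: unsupported kind {p.kind!r}")
        if p.kind == CONTINUOUS:
            if isinstance(p.initial, bool) or not isinstance(p.initial, (int, float)):
                add(f"place {p.id!r}: continuous initial must be a real number")
            elif p.initial < 0:
                add(f"place {p.id!r}: negative initial {p.initial!r}")

    transition_ids = set()
    for t in net.transitions:
        if t.id in transition_ids:
            add(f"duplicate transition id {t.id!r}")
        if t.id in place_ids:
            add(f"id {t.id!r} used for both a place and a transition")
        transition_ids.add(t.id)
        if t.kind == CONTINUOUS:
            if t.speed is None:
                add(f"continuous transition {t.id!r}: missing speed expression")
            if t.update is not None:
                add(f"continuous transition {t.id!r}: carries a generic update rule")
        elif t.kind == GENERIC:
            if t.speed is not None:
                add(f"generic transition {t.id!r}: speed on generic transition")
            if t.update is None:
                add(f"generic transition {t.id!r}: missing update rule")
            elif t.update.target not in place_ids:
                add(f"generic transition {t.id!r}: update target {t.update.target!r} unknown")
        else:
            add(f"transition {t.id!r}: unsupported kind {t.kind!r} "
                "(discrete entities are not part of this model)")

    known = place_ids | set(net.parameters) | {"time", "dt", "True", "False"}
    for i, a in enumerate(net.arcs):
        tag = f"arc #{i} ({a.source!r} -> {a.target!r})"
        if a.kind not in (NORMAL, TEST, INHIBITORY):
            add(f"{tag}: unsupported kind {a.kind!r}")
        src_place = a.source in place_ids
        src_trans = a.source in transition_ids
        tgt_place = a.target in place_ids
        tgt_trans = a.target in transition_ids
        if not (src_place or src_trans):
            add(f"{tag}: dangling source")
        if not (tgt_place or tgt_trans):
            add(f"{tag}: dangling target")
        if (src_place and tgt_place) or (src_trans and tgt_trans):
            add(f"{tag}: non-bipartite arc")
        if a.kind in (TEST, INHIBITORY) and not (src_place and tgt_trans):
            add(f"{tag}: {a.kind} arcs must run place -> transition")
        if a.weight < 0:
            add(f"{tag}: negative weight {a.weight!r}")
        if isinstance(a.threshold, (int, float)) and a.threshold < 0:
            add(f"{tag}: negative constant threshold {a.threshold!r}")

    # expressions must compile and reference only known symbols
    def check_expr(expr, where: str) -> None:
        try:
            compiled = compile_expression(expr)
        except ExpressionError as exc:
            add(f"{where}: {exc}")
            return
        for name in sorted(compiled.names - known):
            add(f"{where}: unknown symbol {name!r}")

    for t in net.transitions:
        if t.kind == CONTINUOUS and t.speed is not None:
            check_expr(t.speed, f"speed of {t.id!r}")
        if t.kind == GENERIC and t.update is not None:
            check_expr(t.update.guard, f"guard of {t.id!r}")
            check_expr(t.update.value, f"update value of {t.id!r}")
    for i, a in enumerate(net.arcs):
        check_expr(a.threshold, f"threshold of arc #{i}")
        if a.guard is not None:
            check_expr(a.guard, f"guard of arc #{i}")

    return report


# ---------------------------------------------------------------------------
# compiled simulator


class _CompiledArc:
    __slots__ = ("source", "kind", "threshold_const", "threshold_expr", "guard")

    def __init__(self, arc: ArcSpec):
        self.source = arc.source
        self.kind = arc.kind
        if isinstance(arc.threshold, (int, float)):
            self.threshold_const = float(arc.threshold)
            self.threshold_expr = None
        else:
            self.threshold_const = None
            self.threshold_expr = compile_expression(arc.threshold)
        self.guard = compile_expression(arc.guard) if arc.guard is not None else None


class _CompiledTransition:
    __slots__ = ("id", "speed", "in_arcs", "consume", "produce")

    def __init__(self, t: TransitionSpec):
        self.id = t.id
        self.speed: CompiledExpression = compile_expression(t.speed)
        self.in_arcs: list[_CompiledArc] = []
        # (place_id, weight, guard) pairs for mass transfer
        self.consume: list[tuple[str, float, Optional[CompiledExpression]]] = []
        self.produce: list[tuple[str, float, Optional[CompiledExpression]]] = []


class CompiledNetwork:
    """Pre-resolved arcs and compiled expressions for fast stepping."""

    def __init__(self, net: NetworkSpec):
        report = validate_network(net)
        report.raise_if_invalid()
        self.net = net
        self.place_ids = net.place_ids()
        self.continuous_places = [p.id for p in net.places if p.kind == CONTINUOUS]
        self.params = {k: float(v) for k, v in net.parameters.items()}
        self.overflow_bound = net.overflow_bound

        by_id = {}
        self.continuous: list[_CompiledTransition] = []
        for t in net.transitions:
            if t.kind == CONTINUOUS:
                ct = _CompiledTransition(t)
                by_id[t.id] = ct
                self.continuous.append(ct)
        self.generic = [
            (t.id, compile_expression(t.update.guard), t.update.target,
             compile_expression(t.update.value))
            for t in net.transitions
            if t.kind == GENERIC
        ]

        place_kinds = {p.id: p.kind for p in net.places}
        for arc in net.arcs:
            if arc.target in by_id:  # place -> continuous transition
                ct = by_id[arc.target]
                carc = _CompiledArc(arc)
                ct.in_arcs.append(carc)
                if arc.kind == NORMAL and place_kinds[arc.source] == CONTINUOUS:
                    ct.consume.append((arc.source, float(arc.weight), carc.guard))
            elif arc.source in by_id:  # continuous transition -> place
                ct = by_id[arc.source]
                guard = compile_expression(arc.guard) if arc.guard is not None else None
                if arc.kind == NORMAL and place_kinds[arc.target] == CONTINUOUS:
                    ct.produce.append((arc.target, float(arc.weight), guard))

    # -- semantics ---------------------------------------------------------

    def initial_state(self) -> SimState:
        marking = {}
        for p in self.net.places:
            marking[p.id] = p.initial if p.kind == GENERIC else float(p.initial)
        return SimState(0.0, marking)

    def _namespace(self, marking: dict, time: float, dt: float) -> dict:
        ns = dict(self.params)
        ns.update(marking)
        ns["time"] = time
        ns["dt"] = dt
        return ns

    def _arc_enabled(self, arc: _CompiledArc, marking: dict, ns: dict) -> bool:
        if arc.guard is not None and not arc.guard.evaluate(ns):
            return True  # inert arc imposes no condition
        thr = (arc.threshold_const if arc.threshold_const is not None
               else arc.threshold_expr.evaluate(ns))
        m = marking[arc.source]
        if arc.kind == INHIBITORY:
            return m < thr
        return m >= thr

    def transition_enabled(self, transition_id: str, state: SimState, dt: float = 0.0) -> bool:
        ct = self._find(transition_id)
        ns = self._namespace(state.marking, state.time, dt)
        return all(self._arc_enabled(a, state.marking, ns) for a in ct.in_arcs)

    def transition_speed(self, transition_id: str, state: SimState, dt: float = 0.0) -> float:
        ct = self._find(transition_id)
        ns = self._namespace(state.marking, state.time, dt)
        return self._speed(ct, state.marking, ns)

    def _find(self, transition_id: str) -> _CompiledTransition:
        for ct in self.continuous:
            if ct.id == transition_id:
                return ct
        raise KeyError(f"no continuous transition {transition_id!r}")

    def _speed(self, ct: _CompiledTransition, marking: dict, ns: dict) -> float:
        for arc in ct.in_arcs:
            if not self._arc_enabled(arc, marking, ns):
                return 0.0
        v = ct.speed.evaluate(ns)
        v = float(v)
        if v < 0:
            raise EngineError(f"speed of transition {ct.id!r} evaluated negative ({v:g})")
        if not math.isfinite(v):
            raise EngineError(f"speed of transition {ct.id!r} evaluated non-finite")
        return v

    def step(self, state: SimState, dt: float) -> SimState:
        """Advance the marking by one Euler step of size ``dt``."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        marking = state.marking
        ns = self._namespace(marking, state.time, dt)

        speeds = [self._speed(ct, marking, ns) for ct in self.continuous]

        # one-pass simultaneous starvation guard: find places whose total
        # demanded consumption this step exceeds their marking, then zero every
        # transition drawing on such a place.
        demand: dict[str, float] = {}
        for ct, v in zip(self.continuous, speeds):
            if v == 0.0:
                continue
            for pid, w, guard in ct.consume:
                if guard is not None and not guard.evaluate(ns):
                    continue
                demand[pid] = demand.get(pid, 0.0) + w * v * dt
        starved = {
            pid for pid, d in demand.items()
            if d > marking[pid] + 1e-12 * max(1.0, abs(marking[pid]))
        }
        if starved:
            for i, ct in enumerate(self.continuous):
                if speeds[i] == 0.0:
                    continue
                for pid, _, guard in ct.consume:
                    if pid in starved:
                        if guard is not None and not guard.evaluate(ns):
                            continue
                        speeds[i] = 0.0
                        break

        new_marking = dict(marking)
        for ct, v in zip(self.continuous, speeds):
            if v == 0.0:
                continue
            amount = v * dt
            for pid, w, guard in ct.consume:
                if guard is not None and not guard.evaluate(ns):
                    continue
                new_marking[pid] -= w * amount
            for pid, w, guard in ct.produce:
                if guard is not None and not guard.evaluate(ns):
                    continue
                new_marking[pid] += w * amount

        # clip float dust; true negatives cannot arise under the guard
        for pid in self.continuous_places:
            m = new_marking[pid]
            if m < 0.0:
                if m < -1e-9:
                    raise EngineError(
                        f"internal error: place {pid!r} went negative ({m:g})")
                new_marking[pid] = 0.0

        new_time = state.time + dt
        if self.generic:
            gns = self._namespace(new_marking, new_time, dt)
            for _, guard, target, value in self.generic:
                if guard.evaluate(gns):
                    val = value.evaluate(gns)
                    new_marking[target] = val
                    gns[target] = val

        return SimState(new_time, new_marking)

    def simulate(self, t_end: float, dt: float, sample_every: float = 1.0,
                 meta: dict | None = None) -> Trace:
        if t_end < 0:
            raise ValueError("t_end must be nonnegative")
        if t_end > 0 and not (0 < dt <= sample_every <= t_end):
            raise ValueError("require 0 < dt <= sample_every <= t_end")

        n_steps = int(round(t_end / dt)) if t_end > 0 else 0
        stride = max(1, int(round(sample_every / dt)))

        state = self.initial_state()
        times = [0.0]
        samples = [dict(state.marking)]
        for i in range(n_steps):
            state = self.step(state, dt)
            state = SimState((i + 1) * dt, state.marking)  # avoid float drift
            if (i + 1) % stride == 0 or (i + 1) == n_steps:
                for pid in self.continuous_places:
                    m = state.marking[pid]
                    if m > self.overflow_bound:
                        raise DivergenceError(pid, m, state.time, self.overflow_bound)
                if times[-1] != state.time:
                    times.append(state.time)
                    samples.append(dict(state.marking))

        series = {
            pid: np.array([float(s[pid]) for s in samples], dtype=float)
            for pid in self.place_ids
        }
        trace_meta = {"dt": dt, "sample_every": sample_every, "t_end": t_end}
        if meta:
            trace_meta.update(meta)
        return Trace(np.array(times, dtype=float), series, trace_meta)


# ---------------------------------------------------------------------------
# functional front-end (the module-level operations)


def is_enabled(transition: Union[str, TransitionSpec], state: SimState,
               net: NetworkSpec, dt: float = 0.0) -> bool:
    """True iff every normal/test input arc meets its threshold and every
    inhibitory input arc's source is strictly below its threshold."""
    tid = transition if isinstance(transition, str) else transition.id
    return CompiledNetwork(net).transition_enabled(tid, state, dt)


def effective_speed(transition: Union[str, TransitionSpec], state: SimState,
                    net: NetworkSpec, dt: float = 0.0) -> float:
    """Speed expression evaluated on the current marking; 0 when disabled."""
    tid = transition if isinstance(transition, str) else transition.id
    return CompiledNetwork(net).transition_speed(tid, state, dt)


def step(state: SimState, net: NetworkSpec, dt: float) -> SimState:
    """One fixed Euler step (see :meth:`CompiledNetwork.step`)."""
    return CompiledNetwork(net).step(state, dt)


def simulate(net: NetworkSpec, t_end: float, dt: float, sample_every: float = 1.0,
             meta: dict | None = None) -> Trace:
    """Simulate from the initial marking to ``t_end``, sampling every
    ``sample_every`` pt (always including t=0 and t_end)."""
    return CompiledNetwork(net).simulate(t_end, dt, sample_every, meta=meta)


__all__ = [
    "CONTINUOUS", "GENERIC", "NORMAL", "TEST", "INHIBITORY",
    "DEFAULT_OVERFLOW_BOUND",
    "PlaceSpec", "ArcSpec", "GenericUpdate", "TransitionSpec", "NetworkSpec",
    "SimState", "Trace", "ValidationReport",
    "EngineError", "DivergenceError",
    "CompiledNetwork", "validate_network",
    "is_enabled", "effective_speed", "step", "simulate",
]
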