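"""Reproducible stand-ins for kinetic constants that have no reference values.

Most rate constants of a dimensionless pathway model like this one cannot be
taken from the literature; they are normally tuned by hand until the known
qualitative behaviors emerge. This module substitutes a documented sampling
scheme for that hand-tuning: every free constant is drawn uniformly from a
stated range through a counter-based stream keyed by ``(seed, draw_index,
parameter name)``, so a parameter set is a pure function of those three values
and no global random state is touched. The model's fixed reference values (the
10 unit/pt ATP baseline, the 100-unit FPP -| MK threshold, the 150 pt
fosmidomycin activation) are pinned exactly.

Default ranges (units are the model's dimensionless unit / pt):

* reaction rate constants ``k_*``: [0.01, 0.05] /pt — keeps per-step
  bimolecular demand ``k * pool * dt`` safely below the source marking, so the
  engine's starvation guard stays a safety net (see docs/methods.md);
* degradation rates ``deg_*``: two kinetic classes — cofactors and small
  byproducts (ATP, NAD(P)H, CO2, ...) in [0.1, 0.2] /pt (turnover 5-10 pt,
  fast enough for the feedback loops to relax within the horizon), and
  carbon-skeleton intermediates in [0.005, 0.02] /pt (turnover 50-200 pt, so
  pools can accumulate to the 80/100-unit regulatory thresholds);
* source production rates ``prod_*``: [8, 15] unit/pt;
* free thresholds: ``theta_atp_pmk`` in [50, 80], ``theta_fos_dxr`` in
  [5, 50] units, so the fixed 80/100/10-unit thresholds are reachable by the
  trajectories.

End-product degradation (sesquiterpene, monoterpene) is pinned at 0: terminal
products accumulate monotonically.

The module also generates small random mass-action HFPNs used as engine test
fixtures, and runs parameter-ensemble robustness checks — an automated version
of the iterative simulate-and-revalidate loop by which such models are
developed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import model as _model
from .engine import (
    CONTINUOUS,
    NORMAL,
    ArcSpec,
    DivergenceError,
    NetworkSpec,
    PlaceSpec,
    TransitionSpec,
    validate_network,
)
from .model import ParameterSet

_REACTION_K_RANGE = (0.01, 0.05)
_FAST_DEGRADATION_RANGE = (0.1, 0.2)     # cofactors/byproducts: turnover 5-10 pt
_SLOW_DEGRADATION_RANGE = (0.005, 0.02)  # carbon intermediates: turnover 50-200 pt
_SOURCE_PRODUCTION_RANGE = (8.0, 15.0)
_THRESHOLD_RANGES = {"theta_atp_pmk": (50.0, 80.0), "theta_fos_dxr": (5.0, 50.0)}


@dataclass(frozen=True)
class ParameterRanges:
    """(low, high) bounds per parameter; pinned parameters have low == high."""

    ranges: dict[str, tuple[float, float]]
    seed: int

    def __post_init__(self):
        for name, (low, high) in self.ranges.items():
            if not (0 <= low <= high):
                raise ValueError(f"invalid range for {name!r}: ({low}, {high})")

    @classmethod
    def default(cls, seed: int = 0) -> "ParameterRanges":
        ranges: dict[str, tuple[float, float]] = {}
        for order in _model.MEV_REACTION_ORDERS + _model.MEP_REACTION_ORDERS:
            ranges[f"k_{order}"] = _REACTION_K_RANGE
        # terminal terpene synthases are slow enzymes relative to the upstream
        # kinases; a low rate constant lets the prenyl diphosphate pools (FPP,
        # GPP_2) rise into the regulatory range instead of being drained flat
        ranges["k_10"] = ranges["k_I"] = (0.01, 0.02)
        for m in _model.ALL_METABOLITES:
            if m == "fosmidomycin":
                continue
            if m != "ATP":  # ATP production is the pinned k_atp, via its modulator
                if m in _model.SOURCE_METABOLITES:
                    ranges[f"prod_{m}"] = _SOURCE_PRODUCTION_RANGE
                else:
                    ranges[f"prod_{m}"] = (0.0, 0.0)
            if m in _model.END_PRODUCTS:
                ranges[f"deg_{m}"] = (0.0, 0.0)
            elif m in _model.FAST_TURNOVER:
                ranges[f"deg_{m}"] = _FAST_DEGRADATION_RANGE
            else:
                ranges[f"deg_{m}"] = _SLOW_DEGRADATION_RANGE
        for name, value in _model.REFERENCE_PARAMETERS.items():
            ranges[name] = (value, value)
        for name, value in _model.SYNTHETIC_DEFAULTS.items():
            ranges[name] = (value, value)
        ranges.update(_THRESHOLD_RANGES)
        return cls(ranges=ranges, seed=seed)


def _stream(seed: int, draw_index: int, name: str) -> np.random.Generator:
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(draw_index), key]))


def sample_parameter_set(ranges: ParameterRanges, draw_index: int = 0) -> ParameterSet:
    """Draw one complete parameter set; pinned parameters come back exactly."""
    if draw_index < 0:
        raise ValueError("draw_index must be nonnegative")
    values: dict[str, float] = {}
    for name in sorted(ranges.ranges):
        low, high = ranges.ranges[name]
        if low == high:
            values[name] = float(low)
        else:
            u = float(_stream(ranges.seed, draw_index, name).random())
            values[name] = low + (high - low) * u
    return ParameterSet(values=values, seed=ranges.seed)


# ---------------------------------------------------------------------------
# random small HFPNs (engine oracle fixtures)


def random_hfpn(seed: int, n_places: int, n_transitions: int) -> NetworkSpec:
    """Well-formed random mass-action net: no thresholds, no inhibition.

    Each transition draws 1-2 input and 1-2 output places (inputs and outputs
    disjoint where possible), unit weights, speed ``k_t * product(inputs)``
    with k in [0.02, 0.2], and positive initial marks in [0.5, 2]. Such nets
    are smooth rate-equation systems, so an ODE integrator provides an
    independent reference trajectory.
    """
    if n_places < 1 or n_transitions < 1:
        raise ValueError("need at least one place and one transition")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), n_places, n_transitions]))
    place_ids = [f"p{i}" for i in range(n_places)]
    places = [
        PlaceSpec(pid, CONTINUOUS, float(0.5 + 1.5 * rng.random())) for pid in place_ids
    ]
    transitions, arcs, params = [], [], {}
    for j in range(n_transitions):
        tid = f"t{j}"
        k_name = f"k_{tid}"
        params[k_name] = float(0.02 + 0.18 * rng.random())
        n_in = int(rng.integers(1, min(2, n_places) + 1))
        inputs = list(rng.choice(n_places, size=n_in, replace=False))
        rest = [i for i in range(n_places) if i not in inputs]
        pool = rest if rest else list(range(n_places))
        n_out = int(rng.integers(1, min(2, len(pool)) + 1))
        outputs = list(rng.choice(pool, size=n_out, replace=False))
        speed = " * ".join([k_name] + [place_ids[i] for i in inputs])
        transitions.append(TransitionSpec(tid, CONTINUOUS, speed))
        for i in inputs:
            arcs.append(ArcSpec(NORMAL, place_ids[i], tid))
        for i in outputs:
            arcs.append(ArcSpec(NORMAL, tid, place_ids[i]))
    net = NetworkSpec(places=places, transitions=transitions, arcs=arcs, parameters=params)
    validate_network(net).raise_if_invalid()
    return net


# ---------------------------------------------------------------------------
# ensemble robustness


@dataclass(frozen=True)
class EnsembleResult:
    n_draws: int
    pass_fraction: dict[str, float]
    seeds: tuple[int, ...]
    n_diverged: int = 0
    meta: dict = field(default_factory=dict)


def behavior_registry() -> dict:
    """Named single-trace predicates for the scenarios' qualitative behaviors.
    Divergent draws count as failing every behavior."""
    from . import analysis

    def peaks(species, n=2, prominence=1.0):
        return lambda tr: analysis.count_peaks(tr, species, prominence) >= n

    def monotone(species):
        return lambda tr: analysis.is_monotone_nondecreasing(tr, species)

    return {
        "sesquiterpene_monotone": monotone("sesquiterpene"),
        "monoterpene_monotone": monotone("monoterpene"),
        "atp_oscillates": peaks("ATP"),
        "mevpp_oscillates": peaks("MEVPP"),
        "mevp_oscillates": peaks("MEVP"),
        "fpp_oscillates": peaks("FPP"),
        "monoterpene_decelerates": lambda tr: (
            analysis.deceleration_time(tr, "monoterpene") is not None
        ),
        "sesquiterpene_rises_late": lambda tr: (
            tr.terminal("sesquiterpene") > float(tr["sesquiterpene"][0]) + 1e-9
        ),
    }


def ensemble_robustness(scenario_id: int, ranges: ParameterRanges, n_draws: int,
                        behaviors: list[str], t_end: float = 300.0,
                        dt: float | None = None) -> EnsembleResult:
    """Run a scenario once per parameter draw and report per-behavior pass
    fractions. Fully reproducible from (ranges, seed, n_draws)."""
    from .scenarios import run_scenario

    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    registry = behavior_registry()
    unknown = [b for b in behaviors if b not in registry]
    if unknown:
        raise KeyError(f"unknown behaviors: {unknown}")

    passes = {b: 0 for b in behaviors}
    n_diverged = 0
    for draw in range(n_draws):
        params = sample_parameter_set(ranges, draw_index=draw)
        try:
            trace = run_scenario(scenario_id, params, t_end=t_end, dt=dt)
        except DivergenceError:
            n_diverged += 1
            continue
        for b in behaviors:
            if registry[b](trace):
                passes[b] += 1
    return EnsembleResult(
        n_draws=n_draws,
        pass_fraction={b: passes[b] / n_draws for b in behaviors},
        seeds=tuple([ranges.seed] * n_draws),
        n_diverged=n_diverged,
        meta={"scenario": scenario_id, "t_end": t_end},
    )
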