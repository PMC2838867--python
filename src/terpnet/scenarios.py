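"""The five simulation conditions of the terpenoid model.

1. Normal sesquiterpene production: MEV on, MEP off, all inhibition disabled.
2. Normal monoterpene production: MEP on, MEV off, all inhibition disabled.
3. ATP overproduction: MEV on; ATP production raised to 30 unit/pt (3-fold
   over the 10 unit/pt baseline); MEVP -| ATP-production threshold set to 80
   units and the ATP -| PMK arc live — the mutually antagonistic feedback pair
   that oscillates ATP/MEVP/MEVPP.
4. FPP overproduction: MEV on; the FPP -| MK threshold dropped to 10 units
   from its 100-unit default, closing the long negative feedback loop through
   the whole lower pathway.
5. Crosstalk: MEP on, MEV off; crossSwitch is scripted to flip at
   t >= 150 pt, which starts fosmidomycin injection (inhibiting DXR) and
   opens the arcs diverting plastidial IPP_2/DMAPP_2 into cytosolic GPP/FPP
   synthesis, so sesquiterpene rises despite the MEV switch being off.

"Inhibition disabled" sets the corresponding thresholds to the engine's
overflow bound rather than deleting arcs, so the structural census
(101 continuous transitions / 66 places) is identical across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import (
    GENERIC,
    DEFAULT_OVERFLOW_BOUND,
    GenericUpdate,
    NetworkSpec,
    Trace,
    TransitionSpec,
    simulate,
)
from .model import ParameterSet, build_model, default_parameters

#: threshold value that disables an inhibitory arc (never reachable: the
#: engine aborts with a divergence error before any marking attains it)
DISABLED_THRESHOLD = DEFAULT_OVERFLOW_BOUND

DEFAULT_T_END = 300.0
DEFAULT_DT = 0.02
DEFAULT_SAMPLE_EVERY = 1.0

_ALL_DISABLED = {
    "theta_mevp_atp": DISABLED_THRESHOLD,
    "theta_atp_pmk": DISABLED_THRESHOLD,
    "theta_fpp_mk": DISABLED_THRESHOLD,
    "theta_fos_dxr": DISABLED_THRESHOLD,
}


@dataclass(frozen=True)
class ScenarioConfig:
    id: int
    switch_states: dict[str, bool] = field(default_factory=dict)
    overrides: dict[str, float] = field(default_factory=dict)
    cross_scripted: bool = False
    t_end: float = DEFAULT_T_END
    dt: float = DEFAULT_DT
    sample_every: float = DEFAULT_SAMPLE_EVERY


def _scenario_settings(scenario_id: int, params: ParameterSet):
    base = dict(_ALL_DISABLED)
    if scenario_id == 1:
        return {"MEV_switch": True, "MEP_switch": False, "crossSwitch": False}, base, False
    if scenario_id == 2:
        return {"MEV_switch": False, "MEP_switch": True, "crossSwitch": False}, base, False
    if scenario_id == 3:
        base.update(k_atp=30.0, theta_mevp_atp=80.0,
                    theta_atp_pmk=params["theta_atp_pmk"])
        return {"MEV_switch": True, "MEP_switch": False, "crossSwitch": False}, base, False
    if scenario_id == 4:
        base.update(theta_fpp_mk=10.0)
        return {"MEV_switch": True, "MEP_switch": False, "crossSwitch": False}, base, False
    if scenario_id == 5:
        base.update(theta_fos_dxr=params["theta_fos_dxr"])
        return {"MEV_switch": False, "MEP_switch": True, "crossSwitch": False}, base, True
    raise ValueError(f"unknown scenario id {scenario_id!r} (expected 1..5)")


def configure_scenario(scenario_id: int, params: ParameterSet | None = None,
                       overrides: dict[str, float] | None = None,
                       cross_script: bool = True,
                       t_end: float = DEFAULT_T_END, dt: float = DEFAULT_DT,
                       sample_every: float = DEFAULT_SAMPLE_EVERY,
                       ) -> tuple[NetworkSpec, ScenarioConfig]:
    """Build the network and run configuration for one scenario.

    ``overrides`` (a partial parameter mapping) is applied after the scenario's
    own settings. ``cross_script=False`` suppresses scenario 5's crossSwitch
    script, giving the crosstalk-disabled control run.
    """
    params = params if params is not None else default_parameters(0)
    switches, scenario_overrides, scripted = _scenario_settings(scenario_id, params)
    scripted = scripted and cross_script
    merged = dict(scenario_overrides)
    if overrides:
        merged.update(overrides)
    full = params.override(**merged)
    net = build_model(full)
    for place in net.places:
        if place.id in switches:
            place.initial = switches[place.id]
    if scripted:
        net.transitions.append(TransitionSpec(
            "script_crossSwitch", GENERIC,
            update=GenericUpdate(guard="time >= t_fos", target="crossSwitch",
                                 value="True"),
        ))
    config = ScenarioConfig(
        id=scenario_id, switch_states=switches, overrides=merged,
        cross_scripted=scripted, t_end=t_end, dt=dt, sample_every=sample_every,
    )
    return net, config


def run_scenario(scenario_id: int, params: ParameterSet | None = None,
                 t_end: float | None = None, dt: float | None = None,
                 sample_every: float | None = None,
                 overrides: dict[str, float] | None = None,
                 cross_script: bool = True) -> Trace:
    """Deterministic trace of one scenario over ``[0, t_end]``."""
    net, config = configure_scenario(
        scenario_id, params, overrides=overrides, cross_script=cross_script,
        t_end=t_end if t_end is not None else DEFAULT_T_END,
        dt=dt if dt is not None else DEFAULT_DT,
        sample_every=sample_every if sample_every is not None else DEFAULT_SAMPLE_EVERY,
    )
    meta = {
        "scenario": scenario_id,
        "seed": params.seed if params is not None else 0,
        "switch_states": dict(config.switch_states),
        "cross_scripted": config.cross_scripted,
    }
    return simulate(net, config.t_end, config.dt, config.sample_every, meta=meta)
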