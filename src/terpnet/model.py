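"""The MEV + MEP terpenoid biosynthesis HFPNe model.

Two compartments mirror the subcellular split of isoprenoid precursor supply:
the mevalonate (MEV) route in the cytosol (acetyl-CoA -> ... -> FPP ->
sesquiterpenes, ten enzymatic reactions) and the methylerythritol-phosphate
(MEP) route in the plastid (G3P + pyruvate -> ... -> GPP -> monoterpenes, nine
reactions). Metabolites are continuous places; every metabolite except the
externally injected inhibitor fosmidomycin also carries one zeroth-order
production and one first-order degradation transition. Enzymes are continuous
places attached to their reaction through test arcs, so they are read but never
consumed. Three boolean switches (MEV_switch, MEP_switch, crossSwitch) gate the
reaction speeds multiplicatively and two numeric modulators retune the ATP
production rate and the FPP -| MK inhibition threshold without structural
change.

Census: 19 reaction transitions + 41 x (production + degradation)
= 101 continuous transitions; 42 + 19 metabolite/enzyme places = 61 continuous
places, + 3 switches + 2 modulators = 66 places.

Regulatory structure:

* MEVP -| ATP production (threshold ``theta_mevp_atp``; the scenario value is
  80 units) and ATP -| PMK (reaction 5, ``theta_atp_pmk``): the mutually
  antagonistic feedback pair behind the ATP/MEVPP oscillation.
* FPP -| MK (reaction 4): threshold read from the ``fpp_mk_threshold_mod``
  modulator place (100 units normally, 10 in the FPP-overproduction scenario).
* fosmidomycin -| DXR (reaction B, ``theta_fos_dxr``), with a generic
  transition injecting fosmidomycin once ``time >= t_fos`` and crossSwitch is
  on; crosstalk arcs then divert plastidial IPP_2/DMAPP_2 into the cytosolic
  GPP/FPP synthases (reactions 8-9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import (
    CONTINUOUS,
    GENERIC,
    INHIBITORY,
    NORMAL,
    TEST,
    ArcSpec,
    GenericUpdate,
    NetworkSpec,
    PlaceSpec,
    TransitionSpec,
)

CYTOSOL = "cytosol"
PLASTID = "plastid"

# -- canonical inventory ----------------------------------------------------

MEV_METABOLITES = [
    "acetyl_CoA", "acetoacetyl_CoA", "CoA", "H2O", "HMG_CoA", "NADPH", "NADP",
    "mevalonate", "ATP", "ADP", "MEVP", "MEVPP", "PO3", "CO2", "IPP", "DMAPP",
    "GPP", "FPP", "sesquiterpene",
]
MEV_ENZYMES = ["AACT", "HMGS", "HMGR", "MK", "PMK", "MVD", "IDI", "GPPS", "FPPS", "STPS"]
MEP_METABOLITES = [
    "G3P", "pyruvate", "DXP", "CO2_2", "NADPH_2", "NADP_2", "MEP", "CTP", "PPi",
    "CDP_ME", "ATP_2", "ADP_2", "pCDP_ME", "CMP", "MEcycPP", "protein_diol",
    "protein_disulfide", "HMBPP", "IPP_2", "DMAPP_2", "GPP_2", "monoterpene",
    "fosmidomycin",
]
MEP_ENZYMES = ["DXS", "DXR", "MCT", "CMK", "MDS", "HDS", "HDR", "GPPS_2", "MTPS"]

SWITCHES = ["MEV_switch", "MEP_switch", "crossSwitch"]
MODULATORS = ["atp_rate_mod", "fpp_mk_threshold_mod"]

#: pathway inputs fed by a nonzero zeroth-order production transition
SOURCE_METABOLITES = [
    "acetyl_CoA", "ATP", "NADPH", "H2O",
    "G3P", "pyruvate", "CTP", "ATP_2", "NADPH_2", "protein_diol",
]
#: terminal products accumulate: their degradation transitions idle at rate 0
END_PRODUCTS = ["sesquiterpene", "monoterpene"]

#: cofactors and small byproducts turn over fast (the cell recycles its energy
#: and redox currency); carbon-skeleton intermediates are chemically stable and
#: degrade slowly, letting pools accumulate to the regulatory thresholds
FAST_TURNOVER = [
    "ATP", "ADP", "NADPH", "NADP", "H2O", "CoA", "CO2", "PO3",
    "ATP_2", "ADP_2", "NADPH_2", "NADP_2", "CTP", "CMP", "PPi", "CO2_2",
    "protein_disulfide",
]

ALL_METABOLITES = MEV_METABOLITES + MEP_METABOLITES
CONTINUOUS_PLACES = MEV_METABOLITES + MEV_ENZYMES + MEP_METABOLITES + MEP_ENZYMES


@dataclass(frozen=True)
class ReactionDef:
    order: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    enzyme: str
    compartment: str


def reaction_table() -> list[ReactionDef]:
    """The 19 enzymatic reactions, transcribed in order of occurrence.

    Protons are omitted throughout; the water molecules produced on the MEP
    side (reactions F and G) are likewise omitted. Reaction 7 (IPP isomerase)
    is modeled forward-only.
    """

    def r(order, subs, prods, enzyme, compartment):
        return ReactionDef(order, tuple(subs), tuple(prods), enzyme, compartment)

    mev = [
        r("1", [("acetyl_CoA", 2)], [("acetoacetyl_CoA", 1), ("CoA", 1)], "AACT", CYTOSOL),
        r("2", [("acetoacetyl_CoA", 1), ("acetyl_CoA", 1), ("H2O", 1)],
          [("HMG_CoA", 1), ("CoA", 1)], "HMGS", CYTOSOL),
        r("3", [("HMG_CoA", 1), ("NADPH", 2)],
          [("mevalonate", 1), ("CoA", 1), ("NADP", 2)], "HMGR", CYTOSOL),
        r("4", [("mevalonate", 1), ("ATP", 1)], [("MEVP", 1), ("ADP", 1)], "MK", CYTOSOL),
        r("5", [("MEVP", 1), ("ATP", 1)], [("MEVPP", 1), ("ADP", 1)], "PMK", CYTOSOL),
        r("6", [("MEVPP", 1), ("ATP", 1)],
          [("IPP", 1), ("PO3", 1), ("CO2", 1), ("ADP", 1)], "MVD", CYTOSOL),
        r("7", [("IPP", 1)], [("DMAPP", 1)], "IDI", CYTOSOL),
        r("8", [("IPP", 1), ("DMAPP", 1)], [("GPP", 1)], "GPPS", CYTOSOL),
        r("9", [("IPP", 1), ("GPP", 1)], [("FPP", 1)], "FPPS", CYTOSOL),
        r("10", [("FPP", 1)], [("sesquiterpene", 1)], "STPS", CYTOSOL),
    ]
    mep = [
        r("A", [("G3P", 1), ("pyruvate", 1)], [("DXP", 1), ("CO2_2", 1)], "DXS", PLASTID),
        r("B", [("DXP", 1), ("NADPH_2", 1)], [("MEP", 1), ("NADP_2", 1)], "DXR", PLASTID),
        r("C", [("MEP", 1), ("CTP", 1)], [("CDP_ME", 1), ("PPi", 1)], "MCT", PLASTID),
        r("D", [("CDP_ME", 1), ("ATP_2", 1)], [("pCDP_ME", 1), ("ADP_2", 1)], "CMK", PLASTID),
        r("E", [("pCDP_ME", 1)], [("CMP", 1), ("MEcycPP", 1)], "MDS", PLASTID),
        r("F", [("MEcycPP", 1), ("protein_diol", 1)],
          [("HMBPP", 1), ("protein_disulfide", 1)], "HDS", PLASTID),
        r("G", [("HMBPP", 1), ("NADPH_2", 1)],
          [("IPP_2", 1), ("DMAPP_2", 1), ("NADP_2", 1)], "HDR", PLASTID),
        r("H", [("IPP_2", 1), ("DMAPP_2", 1)], [("GPP_2", 1)], "GPPS_2", PLASTID),
        r("I", [("GPP_2", 1)], [("monoterpene", 1)], "MTPS", PLASTID),
    ]
    return mev + mep


MEV_REACTION_ORDERS = [str(i) for i in range(1, 11)]
MEP_REACTION_ORDERS = list("ABCDEFGHI")

#: fixed reference parameter values (dimensionless unit / pt scale)
REFERENCE_PARAMETERS = {
    "k_atp": 10.0,          # baseline ATP production, unit/pt
    "theta_fpp_mk": 100.0,  # FPP -| MK threshold, units
    "t_fos": 150.0,         # fosmidomycin activation time, pt
}
#: stand-ins for constants that have no reference values
SYNTHETIC_DEFAULTS = {
    "theta_atp_pmk": 50.0,  # ATP -| PMK threshold, units
    "theta_fos_dxr": 20.0,  # fosmidomycin -| DXR threshold, units
    "theta_mevp_atp": 1e9,  # MEVP -| ATP production; disabled unless a scenario sets it
    "k_fos": 1.0,           # fosmidomycin injection rate once activated, unit/pt
}


@dataclass
class ParameterSet:
    """Named nonnegative rate constants and thresholds for the full model."""

    values: dict[str, float]
    seed: int | None = None

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def override(self, **changes: float) -> "ParameterSet":
        merged = dict(self.values)
        merged.update(changes)
        return ParameterSet(merged, seed=self.seed)


@dataclass(frozen=True)
class EntityInventory:
    continuous_places: tuple[str, ...]
    switches: tuple[str, ...]
    modulators: tuple[str, ...]
    continuous_transitions: tuple[str, ...]
    generic_transitions: tuple[str, ...]


def required_parameter_names() -> list[str]:
    names = [f"k_{o}" for o in MEV_REACTION_ORDERS + MEP_REACTION_ORDERS]
    names += [f"prod_{m}" for m in ALL_METABOLITES if m != "fosmidomycin" and m != "ATP"]
    names += [f"deg_{m}" for m in ALL_METABOLITES if m != "fosmidomycin"]
    names += list(REFERENCE_PARAMETERS) + list(SYNTHETIC_DEFAULTS)
    return names


def default_parameters(seed: int = 0) -> ParameterSet:
    """Reference values fixed exactly; all free constants drawn reproducibly
    from the documented ranges (see :mod:`terpnet.synthetic`) for ``seed``."""
    from .synthetic import ParameterRanges, sample_parameter_set

    return sample_parameter_set(ParameterRanges.default(seed), draw_index=0)


def inventory() -> EntityInventory:
    reactions = [f"r{r.order}" for r in reaction_table()]
    prod = [f"produce_{m}" for m in ALL_METABOLITES if m != "fosmidomycin"]
    deg = [f"degrade_{m}" for m in ALL_METABOLITES if m != "fosmidomycin"]
    return EntityInventory(
        continuous_places=tuple(CONTINUOUS_PLACES),
        switches=tuple(SWITCHES),
        modulators=tuple(MODULATORS),
        continuous_transitions=tuple(reactions + prod + deg),
        generic_transitions=("inject_fosmidomycin",),
    )


def _reaction_speed(rx: ReactionDef) -> str:
    """Mass-action speed, first order in each distinct substrate and the enzyme,
    gated multiplicatively by the pathway switch.

    Water is consumed stoichiometrically but excluded from the rate (solvent
    activity is constant and folded into k, as in any aqueous rate law).
    """
    subs = " * ".join(pid for pid, _ in rx.substrates if pid != "H2O")
    k = f"k_{rx.order}"
    if rx.compartment == PLASTID:
        return f"MEP_switch * {k} * {rx.enzyme} * {subs}"
    if rx.order == "8":
        return (f"{k} * GPPS"
                " * (MEV_switch * IPP + crossSwitch * IPP_2)"
                " * (MEV_switch * DMAPP + crossSwitch * DMAPP_2)")
    if rx.order == "9":
        return f"{k} * FPPS * (MEV_switch * IPP + crossSwitch * IPP_2) * GPP"
    if rx.order == "10":
        return f"(MEV_switch or crossSwitch) * {k} * STPS * FPP"
    return f"MEV_switch * {k} * {rx.enzyme} * {subs}"


def build_model(params: ParameterSet) -> NetworkSpec:
    """Assemble the full two-compartment network for a complete parameter set.

    Raises ``KeyError`` naming the first missing parameter.
    """
    values = params.values
    for name in required_parameter_names():
        if name not in values:
            raise KeyError(f"missing parameter {name!r}")

    places: list[PlaceSpec] = []
    for m in MEV_METABOLITES:
        places.append(PlaceSpec(m, CONTINUOUS, 0.0, CYTOSOL))
    for e in MEV_ENZYMES:
        places.append(PlaceSpec(e, CONTINUOUS, 1.0, CYTOSOL))
    for m in MEP_METABOLITES:
        places.append(PlaceSpec(m, CONTINUOUS, 0.0, PLASTID))
    for e in MEP_ENZYMES:
        places.append(PlaceSpec(e, CONTINUOUS, 1.0, PLASTID))
    places.append(PlaceSpec("MEV_switch", GENERIC, False, CYTOSOL, "MEV pathway switch"))
    places.append(PlaceSpec("MEP_switch", GENERIC, False, PLASTID, "MEP pathway switch"))
    places.append(PlaceSpec("crossSwitch", GENERIC, False, "", "crosstalk switch"))
    places.append(PlaceSpec("atp_rate_mod", GENERIC, values["k_atp"], CYTOSOL,
                            "ATP production rate modulator"))
    places.append(PlaceSpec("fpp_mk_threshold_mod", GENERIC, values["theta_fpp_mk"],
                            CYTOSOL, "FPP -| MK threshold modulator"))

    transitions: list[TransitionSpec] = []
    arcs: list[ArcSpec] = []

    for rx in reaction_table():
        tid = f"r{rx.order}"
        transitions.append(TransitionSpec(tid, CONTINUOUS, _reaction_speed(rx),
                                          compartment=rx.compartment))
        cross_subs = {"8": {"IPP", "DMAPP"}, "9": {"IPP"}}.get(rx.order, set())
        for pid, w in rx.substrates:
            guard = "MEV_switch" if pid in cross_subs else None
            arcs.append(ArcSpec(NORMAL, pid, tid, weight=float(w), guard=guard))
        for pid, w in rx.products:
            arcs.append(ArcSpec(NORMAL, tid, pid, weight=float(w)))
        arcs.append(ArcSpec(TEST, rx.enzyme, tid, threshold=0.5))

    # crosstalk: plastidial precursors feed the cytosolic prenyl synthases,
    # consumed only while crossSwitch is on
    arcs.append(ArcSpec(NORMAL, "IPP_2", "r8", guard="crossSwitch"))
    arcs.append(ArcSpec(NORMAL, "DMAPP_2", "r8", guard="crossSwitch"))
    arcs.append(ArcSpec(NORMAL, "IPP_2", "r9", guard="crossSwitch"))

    for m in ALL_METABOLITES:
        if m == "fosmidomycin":
            continue
        comp = CYTOSOL if m in MEV_METABOLITES else PLASTID
        speed = "atp_rate_mod" if m == "ATP" else f"prod_{m}"
        transitions.append(TransitionSpec(f"produce_{m}", CONTINUOUS, speed, compartment=comp))
        arcs.append(ArcSpec(NORMAL, f"produce_{m}", m))
        transitions.append(TransitionSpec(f"degrade_{m}", CONTINUOUS, f"deg_{m} * {m}",
                                          compartment=comp))
        arcs.append(ArcSpec(NORMAL, m, f"degrade_{m}"))

    transitions.append(TransitionSpec(
        "inject_fosmidomycin", GENERIC,
        update=GenericUpdate(guard="crossSwitch and (time >= t_fos)",
                             target="fosmidomycin",
                             value="fosmidomycin + k_fos * dt"),
        compartment=PLASTID,
    ))

    arcs.append(ArcSpec(INHIBITORY, "MEVP", "produce_ATP", threshold="theta_mevp_atp"))
    arcs.append(ArcSpec(INHIBITORY, "ATP", "r5", threshold="theta_atp_pmk"))
    arcs.append(ArcSpec(INHIBITORY, "FPP", "r4", threshold="fpp_mk_threshold_mod"))
    arcs.append(ArcSpec(INHIBITORY, "fosmidomycin", "rB", threshold="theta_fos_dxr"))

    net = NetworkSpec(places=places, transitions=transitions, arcs=arcs,
                      parameters=dict(values))
    return net


CROSSTALK_ARCS = (("IPP_2", "r8"), ("DMAPP_2", "r8"), ("IPP_2", "r9"))
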