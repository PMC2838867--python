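"""Readers and writers: JSON model exchange, CSV traces, DOT export.

The model format is a plain JSON document with top-level keys ``places``,
``transitions``, ``arcs`` and ``parameters``; expressions stay strings in the
restricted grammar. Floats serialise through Python's shortest round-trip
representation, so ``read_model(write_model(net))`` is structurally equal to
``net`` and repeated writes are byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np

from .engine import (
    ArcSpec,
    GenericUpdate,
    NetworkSpec,
    PlaceSpec,
    Trace,
    TransitionSpec,
    validate_network,
)

MODEL_FORMAT_KEYS = ("places", "transitions", "arcs", "parameters")


class ModelFormatError(ValueError):
    """Malformed or schema-violating model document."""


def _place_to_dict(p: PlaceSpec) -> dict:
    return {"id": p.id, "kind": p.kind, "initial": p.initial,
            "compartment": p.compartment, "label": p.label}


def _transition_to_dict(t: TransitionSpec) -> dict:
    d = {"id": t.id, "kind": t.kind, "compartment": t.compartment, "label": t.label}
    if t.speed is not None:
        d["speed"] = t.speed
    if t.update is not None:
        d["update"] = {"guard": t.update.guard, "target": t.update.target,
                       "value": t.update.value}
    return d


def _arc_to_dict(a: ArcSpec) -> dict:
    d = {"kind": a.kind, "source": a.source, "target": a.target,
         "weight": a.weight, "threshold": a.threshold}
    if a.guard is not None:
        d["guard"] = a.guard
    return d


def network_to_dict(net: NetworkSpec) -> dict:
    return {
        "places": [_place_to_dict(p) for p in net.places],
        "transitions": [_transition_to_dict(t) for t in net.transitions],
        "arcs": [_arc_to_dict(a) for a in net.arcs],
        "parameters": dict(net.parameters),
        "overflow_bound": net.overflow_bound,
    }


def network_from_dict(doc: dict) -> NetworkSpec:
    for key in MODEL_FORMAT_KEYS:
        if key not in doc:
            raise ModelFormatError(f"model document is missing key {key!r}")
    try:
        places = [PlaceSpec(**p) for p in doc["places"]]
        transitions = []
        for t in doc["transitions"]:
            t = dict(t)
            upd = t.pop("update", None)
            transitions.append(TransitionSpec(
                update=GenericUpdate(**upd) if upd else None, **t))
        arcs = [ArcSpec(**a) for a in doc["arcs"]]
    except TypeError as exc:
        raise ModelFormatError(f"malformed model entry: {exc}") from exc
    net = NetworkSpec(
        places=places, transitions=transitions, arcs=arcs,
        parameters={k: float(v) for k, v in doc["parameters"].items()},
        overflow_bound=float(doc.get("overflow_bound", NetworkSpec().overflow_bound)),
    )
    report = validate_network(net)
    if not report.ok:
        raise ModelFormatError("model document fails validation:\n"
                               + "\n".join(report.violations))
    return net


def write_model(net: NetworkSpec, path) -> None:
    Path(path).write_text(
        json.dumps(network_to_dict(net), indent=1) + "\n", encoding="utf-8")


def read_model(path) -> NetworkSpec:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"cannot parse {path}: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(doc, dict):
        raise ModelFormatError(f"{path}: expected a JSON object at top level")
    return network_from_dict(doc)


def model_fingerprint(net: NetworkSpec) -> str:
    """Stable hash of the canonical key-ordered serialisation."""
    canonical = json.dumps(network_to_dict(net), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


# ---------------------------------------------------------------------------
# traces


def _fmt(x: float) -> str:
    return repr(float(x))


def write_trace(trace: Trace, path) -> None:
    """CSV with a mandatory header: first column time_pt, then one column per
    place in declaration order. Values use shortest round-trip decimals, so a
    re-read reproduces the series exactly and rewrites are byte-identical."""
    if trace.times.size == 0:
        raise ValueError("refusing to write an empty trace")
    columns = list(trace.series)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["time_pt", *columns])
        for i, t in enumerate(trace.times):
            writer.writerow([_fmt(t)] + [_fmt(trace.series[c][i]) for c in columns])


def read_trace(path) -> Trace:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if not header or header[0] != "time_pt":
            raise ValueError(f"{path}: first column must be 'time_pt'")
        columns = header[1:]
        rows = [[float(x) for x in row] for row in reader]
    data = np.array(rows, dtype=float)
    if data.size == 0:
        raise ValueError(f"{path}: trace has no samples")
    return Trace(
        times=data[:, 0],
        series={c: data[:, i + 1] for i, c in enumerate(columns)},
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# DOT export


def _quote(s: str) -> str:
    return '"' + s.replace('"', '\\"') + '"'


def export_dot(net: NetworkSpec) -> str:
    """Graphviz DOT text: places as ellipses, transitions as boxes, inhibitory
    arcs with tee arrowheads, test arcs dashed, compartments as clusters."""
    lines = ["digraph hfpn {", "  rankdir=LR;", "  node [fontsize=10];"]
    compartments: dict[str, list[str]] = {}
    loose: list[str] = []
    for p in net.places:
        decl = (f"{_quote(p.id)} [shape=ellipse"
                + (", style=dashed" if p.kind == "generic" else "") + "];")
        (compartments.setdefault(p.compartment, []) if p.compartment else loose).append(decl)
    for t in net.transitions:
        decl = (f"{_quote(t.id)} [shape=box"
                + (", style=dashed" if t.kind == "generic" else "") + "];")
        (compartments.setdefault(t.compartment, []) if t.compartment else loose).append(decl)
    for i, (comp, decls) in enumerate(sorted(compartments.items())):
        lines.append(f"  subgraph cluster_{i} {{")
        lines.append(f"    label={_quote(comp)};")
        lines.extend(f"    {d}" for d in decls)
        lines.append("  }")
    lines.extend(f"  {d}" for d in loose)
    for a in net.arcs:
        attrs = []
        if a.kind == "inhibitory":
            attrs.append("arrowhead=tee")
        elif a.kind == "test":
            attrs.append("style=dashed, arrowhead=odot")
        if a.weight != 1.0:
            attrs.append(f'label="{a.weight:g}"')
        suffix = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(f"  {_quote(a.source)} -> {_quote(a.target)}{suffix};")
    lines.append("}")
    return "\n".join(lines) + "\n"
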