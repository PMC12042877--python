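"""Circuit serialization (YAML) with explicit concentration units.

The canonical on-disk form is YAML with strict key checking (unknown
keys are rejected to catch typos in placement fields).  Concentrations
are serialized with explicit units and parsed back to the internal
canonical unit, molar.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Any

import yaml

from .circuit import (
    ASEReactionSpec,
    CircuitSpec,
    FiringMode,
    InputDecl,
    Junction,
    Reporter,
    Site,
    SwitchPlacement,
)

__all__ = ["SchemaError", "read_circuit", "write_circuit", "circuit_to_dict", "circuit_from_dict"]

_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}
_CONC_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*([a-zµA-Z]+)\s*$")


class SchemaError(ValueError):
    """Schema violation, reported with the offending field path."""


def parse_concentration(value: Any, where: str) -> float:
    """Accept a bare number (molar) or a string with units like '50 nM'."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        m = _CONC_RE.match(value)
        if not m or m.group(2) not in _UNITS:
            raise SchemaError(f"{where}: cannot parse concentration {value!r}")
        return float(m.group(1)) * _UNITS[m.group(2)]
    raise SchemaError(f"{where}: concentration must be a number or '<value> <unit>' string")


def format_concentration(molar: float) -> str:
    return f"{molar * 1e9:g} nM"


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    if not isinstance(d, dict):
        raise SchemaError(f"{where}: expected a mapping")
    unknown = set(d) - allowed
    if unknown:
        raise SchemaError(f"{where}: unknown field(s) {sorted(unknown)}")


def circuit_to_dict(spec: CircuitSpec) -> dict:
    return {
        "standard_concentration": format_concentration(spec.standard_concentration),
        "inputs": [
            {"id": i.input_id, "on_multiple": i.on_multiple} for i in spec.inputs
        ],
        "outputs": list(spec.outputs),
        "reactions": [
            {
                "id": r.reaction_id,
                "mode": r.mode.value,
                "reporter": {
                    "label": r.reporter.label,
                    "fluorophore": r.reporter.fluorophore,
                    "quencher": r.reporter.quencher,
                },
                "concentration_s": format_concentration(r.concentration_s),
                "concentration_w": format_concentration(r.concentration_w),
                "placements": [
                    {
                        "switch_id": p.switch_id,
                        "input": p.input_id,
                        "junction": p.junction.value,
                        "site": p.site.value,
                        "stack_index": p.stack_index,
                    }
                    for p in r.placements
                ],
            }
            for r in spec.reactions
        ],
    }


def circuit_from_dict(data: dict) -> CircuitSpec:
    _check_keys(
        data, {"standard_concentration", "inputs", "outputs", "reactions"}, "circuit"
    )
    for req in ("inputs", "outputs", "reactions"):
        if req not in data:
            raise SchemaError(f"circuit: missing required field {req!r}")

    std = parse_concentration(
        data.get("standard_concentration", "50 nM"), "circuit.standard_concentration"
    )
    inputs = []
    for i, d in enumerate(data["inputs"]):
        where = f"inputs[{i}]"
        if isinstance(d, str):
            inputs.append(InputDecl(d))
            continue
        _check_keys(d, {"id", "on_multiple"}, where)
        if "id" not in d:
            raise SchemaError(f"{where}: missing required field 'id'")
        inputs.append(InputDecl(str(d["id"]), float(d.get("on_multiple", 5.0))))

    reactions = []
    for i, rd in enumerate(data["reactions"]):
        where = f"reactions[{i}]"
        _check_keys(
            rd,
            {"id", "mode", "reporter", "concentration_s", "concentration_w", "placements"},
            where,
        )
        for req in ("id", "mode", "reporter", "placements"):
            if req not in rd:
                raise SchemaError(f"{where}: missing required field {req!r}")
        rep = rd["reporter"]
        if isinstance(rep, str):
            reporter = Reporter(label=rep)
        else:
            _check_keys(rep, {"label", "fluorophore", "quencher"}, f"{where}.reporter")
            if "label" not in rep:
                raise SchemaError(f"{where}.reporter: missing required field 'label'")
            reporter = Reporter(
                label=rep["label"],
                fluorophore=rep.get("fluorophore", "FAM"),
                quencher=rep.get("quencher", "Dabcyl"),
            )
        try:
            mode = FiringMode(rd["mode"])
        except ValueError:
            raise SchemaError(f"{where}.mode: unknown mode {rd['mode']!r}") from None
        placements = []
        for j, pd_ in enumerate(rd["placements"]):
            pwhere = f"{where}.placements[{j}]"
            _check_keys(
                pd_, {"switch_id", "input", "junction", "site", "stack_index"}, pwhere
            )
            for req in ("switch_id", "input", "junction", "site"):
                if req not in pd_:
                    raise SchemaError(f"{pwhere}: missing required field {req!r}")
            try:
                junction = Junction(pd_["junction"])
                site = Site(pd_["site"])
            except ValueError as exc:
                raise SchemaError(f"{pwhere}: {exc}") from None
            placements.append(
                SwitchPlacement(
                    switch_id=pd_["switch_id"],
                    input_id=pd_["input"],
                    reaction_id=rd["id"],
                    junction=junction,
                    site=site,
                    stack_index=int(pd_.get("stack_index", 0)),
                )
            )
        reactions.append(
            ASEReactionSpec(
                reaction_id=rd["id"],
                placements=placements,
                mode=mode,
                reporter=reporter,
                concentration_s=parse_concentration(
                    rd.get("concentration_s", std), f"{where}.concentration_s"
                ),
                concentration_w=parse_concentration(
                    rd.get("concentration_w", std), f"{where}.concentration_w"
                ),
            )
        )

    return CircuitSpec(
        inputs=inputs,
        reactions=reactions,
        outputs=[str(o) for o in data["outputs"]],
        standard_concentration=std,
    )


def write_circuit(spec: CircuitSpec, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(circuit_to_dict(spec), sort_keys=False, default_flow_style=False)
    )


def read_circuit(path: str | Path) -> CircuitSpec:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"malformed YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError("circuit file must contain a mapping at top level")
    return circuit_from_dict(data)
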