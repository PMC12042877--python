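"""Core data model for allosteric strand-exchange (ASE) circuits.

An ASE reaction is a four-way strand exchange between a pair of
predominantly double-stranded gates (an S-gate and a W-gate).  Hairpin
molecular switches inserted between the toehold and recognition domains
of a gate hold the two domains apart; hybridisation of an input strand
to a switch triggers the conformational change that restores their
proximity.  Each gate pair has two toehold/recognition boundaries
(junctions J1 and J2); a junction is *open* when every switch placed on
it is activated, and a junction carrying no switch is constitutively
open.  Whether exchange needs one open junction or both is captured by
the reaction's firing mode (REQUIRE_ANY / REQUIRE_ALL), which is what
distinguishes OR-type from AND-type gate configurations.

This module also provides the Boolean reference semantics
(:func:`truth_table_oracle`) used as the ground truth against which the
kinetic simulator is checked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "DomainRole",
    "Domain",
    "Junction",
    "Site",
    "FiringMode",
    "SwitchPlacement",
    "Reporter",
    "ASEReactionSpec",
    "InputDecl",
    "CircuitSpec",
    "TruthTable",
    "ValidationIssue",
    "validate_circuit",
    "truth_table_oracle",
    "leak_configurations",
]

STANDARD_CONCENTRATION = 50e-9  # molar; the 1x reference concentration
DEFAULT_ON_MULTIPLE = 5.0  # inputs are delivered at 5x when logic-ON

DNA_ALPHABET = frozenset("ACGT")


class DomainRole(str, Enum):
    TOEHOLD = "toehold"
    RECOGNITION = "recognition"
    SPACER = "spacer"
    SWITCH = "switch"
    BLOCKER = "blocker"
    TARGET_SITE = "target-site"


@dataclass(frozen=True)
class Domain:
    """A named sequence domain, 5'->3'.

    ``two_prime_ome`` marks 2'-O-methyl RNA chemistry for intracellular
    use; it is an annotation only and does not change the letters
    (sequences are stored in DNA alphabet).
    """

    name: str
    sequence: str
    role: DomainRole
    two_prime_ome: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"domain {self.name!r}: characters {sorted(bad)} outside alphabet ACGT"
            )
        if not isinstance(self.role, DomainRole):
            object.__setattr__(self, "role", DomainRole(self.role))

    @property
    def length(self) -> int:
        return len(self.sequence)


class Junction(str, Enum):
    J1 = "J1"
    J2 = "J2"


class Site(str, Enum):
    TOP = "top-strand"
    BOTTOM = "bottom-strand"


class FiringMode(str, Enum):
    REQUIRE_ANY = "REQUIRE_ANY"
    REQUIRE_ALL = "REQUIRE_ALL"


@dataclass(frozen=True)
class SwitchPlacement:
    """One molecular switch inserted at a specific gate position.

    ``stack_index`` orders tandem switches stacked at the same site;
    values at one site must be contiguous from 0.  Tandem switches are
    conjunctive: an unopened inserted duplex still separates the toehold
    from the recognition domain, so a junction opens only when every
    switch on it is activated.
    """

    switch_id: str
    input_id: str
    reaction_id: str
    junction: Junction
    site: Site
    stack_index: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.junction, Junction):
            object.__setattr__(self, "junction", Junction(self.junction))
        if not isinstance(self.site, Site):
            object.__setattr__(self, "site", Site(self.site))
        if self.stack_index < 0:
            raise ValueError("stack_index must be nonnegative")

    @property
    def position(self) -> tuple[str, Junction, Site, int]:
        return (self.reaction_id, self.junction, self.site, self.stack_index)


@dataclass(frozen=True)
class Reporter:
    label: str
    fluorophore: str = "FAM"
    quencher: str = "Dabcyl"


@dataclass
class ASEReactionSpec:
    """One gate pair (S-gate + W-gate) and its switch placements."""

    reaction_id: str
    placements: list[SwitchPlacement]
    mode: FiringMode
    reporter: Reporter
    concentration_s: float = STANDARD_CONCENTRATION
    concentration_w: float = STANDARD_CONCENTRATION

    def __post_init__(self) -> None:
        if not isinstance(self.mode, FiringMode):
            self.mode = FiringMode(self.mode)

    def placements_on(self, junction: Junction) -> list[SwitchPlacement]:
        return [p for p in self.placements if p.junction is junction]

    def unswitched_junctions(self) -> list[Junction]:
        """Junctions with no switch; these are constitutively open."""
        return [j for j in Junction if not self.placements_on(j)]


@dataclass(frozen=True)
class InputDecl:
    input_id: str
    on_multiple: float = DEFAULT_ON_MULTIPLE  # multiple of 1x when logic-ON


@dataclass
class CircuitSpec:
    inputs: list[InputDecl]
    reactions: list[ASEReactionSpec]
    outputs: list[str]
    standard_concentration: float = STANDARD_CONCENTRATION

    @property
    def input_ids(self) -> list[str]:
        return [i.input_id for i in self.inputs]

    def reactions_for_output(self, label: str) -> list[ASEReactionSpec]:
        return [r for r in self.reactions if r.reporter.label == label]


@dataclass
class TruthTable:
    """Exhaustive Boolean behaviour: one row per input combination.

    Rows follow binary counting order with the first input as the most
    significant bit.
    """

    input_order: list[str]
    rows: list[tuple[tuple[int, ...], dict[str, bool]]]

    def to_frame(self):
        import pandas as pd

        records = []
        for combo, outs in self.rows:
            rec = dict(zip(self.input_order, combo))
            rec.update({k: int(v) for k, v in outs.items()})
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def output_vector(self, label: str) -> list[int]:
        return [int(outs[label]) for _, outs in self.rows]


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    location: str
    message: str


def validate_circuit(spec: CircuitSpec) -> list[ValidationIssue]:
    """Structural validation of a circuit specification.

    Returns an empty error list iff all invariants hold.  A REQUIRE_ANY
    reaction with an unswitched junction is flagged with a warning: that
    junction is constitutively open, so the reaction fires regardless of
    inputs (leak).
    """
    issues: list[ValidationIssue] = []

    seen_inputs: set[str] = set()
    for decl in spec.inputs:
        if decl.input_id in seen_inputs:
            issues.append(
                ValidationIssue("error", f"inputs[{decl.input_id}]", "duplicate input identifier")
            )
        seen_inputs.add(decl.input_id)

    seen_rxn: set[str] = set()
    seen_positions: set[tuple] = set()
    for rxn in spec.reactions:
        loc = f"reaction[{rxn.reaction_id}]"
        if rxn.reaction_id in seen_rxn:
            issues.append(ValidationIssue("error", loc, "duplicate reaction identifier"))
        seen_rxn.add(rxn.reaction_id)

        if rxn.reporter.label not in spec.outputs:
            issues.append(
                ValidationIssue(
                    "error", loc, f"reporter label {rxn.reporter.label!r} not in outputs"
                )
            )

        site_stacks: dict[tuple, list[int]] = {}
        for p in rxn.placements:
            ploc = f"{loc}.placement[{p.switch_id}@{p.junction.value}/{p.site.value}#{p.stack_index}]"
            if p.reaction_id != rxn.reaction_id:
                issues.append(
                    ValidationIssue(
                        "error", ploc, f"placement reaction_id {p.reaction_id!r} mismatch"
                    )
                )
            if p.input_id not in seen_inputs:
                issues.append(
                    ValidationIssue(
                        "error", ploc, f"placement references unknown input {p.input_id!r}"
                    )
                )
            if p.position in seen_positions:
                issues.append(ValidationIssue("error", ploc, "duplicate placement position"))
            seen_positions.add(p.position)
            site_stacks.setdefault((p.junction, p.site), []).append(p.stack_index)

        for (junction, site), idxs in site_stacks.items():
            if sorted(idxs) != list(range(len(idxs))):
                issues.append(
                    ValidationIssue(
                        "error",
                        f"{loc}.{junction.value}/{site.value}",
                        f"stack indices {sorted(idxs)} not contiguous from 0",
                    )
                )

        empty = rxn.unswitched_junctions()
        if rxn.mode is FiringMode.REQUIRE_ALL and empty:
            issues.append(
                ValidationIssue(
                    "error",
                    loc,
                    "REQUIRE_ALL with unswitched junction(s) "
                    f"{[j.value for j in empty]}: the mode demands a switch on each junction",
                )
            )
        if rxn.mode is FiringMode.REQUIRE_ANY and empty:
            issues.append(
                ValidationIssue(
                    "warning",
                    loc,
                    "constitutively-open junction "
                    f"{[j.value for j in empty]} => leak (reaction fires without input)",
                )
            )

    for label in spec.outputs:
        if not spec.reactions_for_output(label):
            issues.append(
                ValidationIssue("warning", f"outputs[{label}]", "no reaction carries this reporter")
            )

    return issues


def errors(issues: Iterable[ValidationIssue]) -> list[ValidationIssue]:
    return [i for i in issues if i.severity == "error"]


def _junction_open(
    rxn: ASEReactionSpec, junction: Junction, on_inputs: frozenset[str]
) -> bool:
    return all(p.input_id in on_inputs for p in rxn.placements_on(junction))


def reaction_fires(rxn: ASEReactionSpec, on_inputs: frozenset[str]) -> bool:
    """Boolean firing predicate for one gate pair.

    Junction J is open iff every switch placed on J has its input ON (a
    junction with no switches is open).  REQUIRE_ANY fires on >=1 open
    junction, REQUIRE_ALL needs both.
    """
    open_j = [_junction_open(rxn, j, on_inputs) for j in Junction]
    if rxn.mode is FiringMode.REQUIRE_ALL:
        return all(open_j)
    return any(open_j)


def input_combinations(input_order: list[str]):
    """All 2^N 0/1 assignments in binary counting order (first input = MSB)."""
    for combo in itertools.product((0, 1), repeat=len(input_order)):
        yield combo


def truth_table_oracle(spec: CircuitSpec) -> TruthTable:
    """Reference Boolean semantics of a circuit.

    An output label is ON iff at least one reaction carrying that
    reporter fires.  This is the ground truth the kinetic endpoint
    simulation is compared against.
    """
    errs = errors(validate_circuit(spec))
    if errs:
        raise ValueError(f"circuit does not validate: {errs[0].location}: {errs[0].message}")

    order = spec.input_ids
    rows = []
    for combo in input_combinations(order):
        on = frozenset(i for i, bit in zip(order, combo) if bit)
        outs = {
            label: any(reaction_fires(r, on) for r in spec.reactions_for_output(label))
            for label in spec.outputs
        }
        rows.append((combo, outs))
    return TruthTable(input_order=list(order), rows=rows)


def leak_configurations(spec: CircuitSpec) -> list[str]:
    """Reaction ids that are constitutively ON (fire for every input state).

    Exactly the REQUIRE_ANY reactions with at least one unswitched
    junction: a single bound toehold suffices to initiate the four-way
    branch migration, so an always-open junction fires the gate pair
    regardless of inputs.
    """
    errs = errors(validate_circuit(spec))
    if errs:
        raise ValueError(f"circuit does not validate: {errs[0].location}: {errs[0].message}")
    return [
        r.reaction_id
        for r in spec.reactions
        if r.mode is FiringMode.REQUIRE_ANY and r.unswitched_junctions()
    ]
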