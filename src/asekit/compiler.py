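"""Compile Boolean expressions into single-layer ASE circuits.

The architecture computes monotone Boolean functions (AND/OR, no
inverter) in a single layer: each disjunct of the DNF is mapped onto a
gate-pair junction, and wider disjunctions are spread over parallel
gate pairs sharing one fluorophore.  ``equivalent_gate_count`` reports
the size of the conventional cascade of two-input gates that the same
expression would need.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .circuit import (
    ASEReactionSpec,
    CircuitSpec,
    FiringMode,
    InputDecl,
    Junction,
    Reporter,
    Site,
    SwitchPlacement,
    STANDARD_CONCENTRATION,
    DEFAULT_ON_MULTIPLE,
)

__all__ = [
    "ExpressionTree",
    "DNFForm",
    "ExpressionError",
    "PackingError",
    "parse_expression",
    "to_dnf",
    "pack_reactions",
    "equivalent_gate_count",
    "compile_circuit",
    "PackingConfig",
]

# Reporters are assigned round-robin from the fluorophore/quencher pairs
# used for plate-reader readout of the circuits.
FLUOROPHORE_PAIRS = [("FAM", "Dabcyl"), ("Cy5", "BHQ3"), ("AF488", "BHQ1")]


class ExpressionError(ValueError):
    """Syntax or semantic error in a Boolean expression, with position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} at position {position}"
        super().__init__(message)


class PackingError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionTree:
    """AND/OR expression tree; leaves are input identifiers, no negation."""

    kind: str  # "AND" | "OR" | "literal"
    children: tuple["ExpressionTree", ...] = ()
    literal: str | None = None

    def leaves(self) -> Iterator[str]:
        if self.kind == "literal":
            yield self.literal
        else:
            for c in self.children:
                yield from c.leaves()

    def evaluate(self, assignment: Mapping[str, int]) -> bool:
        if self.kind == "literal":
            return bool(assignment[self.literal])
        if self.kind == "AND":
            return all(c.evaluate(assignment) for c in self.children)
        return any(c.evaluate(assignment) for c in self.children)

    def __str__(self) -> str:
        if self.kind == "literal":
            return self.literal
        op = f" {self.kind} "
        return "(" + op.join(str(c) for c in self.children) + ")"


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_]*)|(?P<amp>&&?)|(?P<pipe>\|\|?)"
    r"|(?P<lpar>\()|(?P<rpar>\))|(?P<bad>\S))"
)
_NEGATION_WORDS = {"NOT", "not", "Not"}
_NEGATION_SYMBOLS = {"!", "~", "¬"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    for m in _TOKEN_RE.finditer(text):
        pos = m.start(m.lastgroup)
        if m.lastgroup == "ident":
            word = m.group("ident")
            if word in _NEGATION_WORDS:
                raise ExpressionError("architecture has no NOT", pos)
            if word.upper() == "AND":
                tokens.append(("AND", word, pos))
            elif word.upper() == "OR":
                tokens.append(("OR", word, pos))
            else:
                tokens.append(("IDENT", word, pos))
        elif m.lastgroup == "amp":
            tokens.append(("AND", m.group(), pos))
        elif m.lastgroup == "pipe":
            tokens.append(("OR", m.group(), pos))
        elif m.lastgroup == "lpar":
            tokens.append(("LPAR", "(", pos))
        elif m.lastgroup == "rpar":
            tokens.append(("RPAR", ")", pos))
        else:
            ch = m.group("bad")
            if ch in _NEGATION_SYMBOLS:
                raise ExpressionError("architecture has no NOT", pos)
            raise ExpressionError(f"unexpected character {ch!r}", pos)
    tokens.append(("EOF", "", len(text)))
    return tokens


def parse_expression(text: str) -> ExpressionTree:
    """Parse an AND/OR expression with standard precedence (AND > OR).

    Identifiers are preserved verbatim; ``&`` / ``|`` are accepted as
    operator symbols; any negation operator is rejected because the
    architecture has no inverter.
    """
    tokens = _tokenize(text)
    idx = 0

    def peek() -> tuple[str, str, int]:
        return tokens[idx]

    def take(kind: str) -> tuple[str, str, int]:
        nonlocal idx
        tok = tokens[idx]
        if tok[0] != kind:
            raise ExpressionError(f"expected {kind}, found {tok[1] or 'end of input'!r}", tok[2])
        idx += 1
        return tok

    def parse_or() -> ExpressionTree:
        parts = [parse_and()]
        while peek()[0] == "OR":
            take("OR")
            parts.append(parse_and())
        if len(parts) == 1:
            return parts[0]
        return ExpressionTree("OR", tuple(parts))

    def parse_and() -> ExpressionTree:
        parts = [parse_atom()]
        while peek()[0] == "AND":
            take("AND")
            parts.append(parse_atom())
        if len(parts) == 1:
            return parts[0]
        return ExpressionTree("AND", tuple(parts))

    def parse_atom() -> ExpressionTree:
        kind, value, pos = peek()
        if kind == "IDENT":
            take("IDENT")
            return ExpressionTree("literal", literal=value)
        if kind == "LPAR":
            take("LPAR")
            node = parse_or()
            take("RPAR")
            return node
        raise ExpressionError(f"expected identifier or '(', found {value or 'end of input'!r}", pos)

    tree = parse_or()
    kind, value, pos = peek()
    if kind != "EOF":
        raise ExpressionError(f"unexpected {value!r}", pos)
    return tree


@dataclass(frozen=True)
class DNFForm:
    """Canonical disjunctive normal form: OR of AND terms.

    Terms are frozensets of literals, absorbed (no term is a superset of
    another) and ordered lexicographically by their sorted literals so
    compilation is deterministic.
    """

    terms: tuple[frozenset[str], ...]

    @property
    def literals(self) -> list[str]:
        out: list[str] = []
        for t in self.terms:
            for lit in sorted(t):
                if lit not in out:
                    out.append(lit)
        return out

    def evaluate(self, assignment: Mapping[str, int]) -> bool:
        return any(all(assignment[l] for l in t) for t in self.terms)


def to_dnf(tree: ExpressionTree) -> DNFForm:
    """Distribute AND over OR, then apply absorption and canonical ordering."""

    def expand(node: ExpressionTree) -> list[frozenset[str]]:
        if node.kind == "literal":
            return [frozenset([node.literal])]
        if node.kind == "OR":
            out: list[frozenset[str]] = []
            for c in node.children:
                out.extend(expand(c))
            return out
        # AND: cross product of children's term lists
        acc: list[frozenset[str]] = [frozenset()]
        for c in node.children:
            acc = [a | t for a in acc for t in expand(c)]
        return acc

    terms = set(expand(tree))
    # absorption: drop any term that is a proper superset of another
    absorbed = [t for t in terms if not any(o < t for o in terms)]
    ordered = tuple(sorted(set(absorbed), key=lambda t: (len(t), tuple(sorted(t)))))
    return DNFForm(terms=ordered)


def equivalent_gate_count(trees: ExpressionTree | Sequence[ExpressionTree]) -> int:
    """Number of two-input AND/OR gates in a cascaded realization of the DNF.

    A term of width w needs w-1 AND gates; t terms need t-1 OR gates; a
    bare literal needs none.  For a multi-output set of expressions the
    counts sum.
    """
    if isinstance(trees, ExpressionTree):
        trees = [trees]
    total = 0
    for tree in trees:
        dnf = to_dnf(tree)
        t = len(dnf.terms)
        total += sum(len(term) - 1 for term in dnf.terms) + (t - 1)
    return total


@dataclass(frozen=True)
class PackingConfig:
    max_switches_per_junction: int = 2  # deepest stack demonstrated
    standard_concentration: float = STANDARD_CONCENTRATION
    warn: bool = True


def _switch_id(input_id: str, reaction_id: str) -> str:
    return f"sw_{input_id}.{reaction_id}"


def _place_term(
    term: Sequence[str], junction: Junction, reaction_id: str
) -> list[SwitchPlacement]:
    """Assign a conjunction to one junction: J-top fills before J-bottom,
    stack_index ascending within a site."""
    placements = []
    sites = [Site.TOP, Site.BOTTOM]
    per_site = (len(term) + 1) // 2
    for i, lit in enumerate(sorted(term)):
        site = sites[i // per_site] if per_site else Site.TOP
        placements.append(
            SwitchPlacement(
                switch_id=_switch_id(lit, reaction_id),
                input_id=lit,
                reaction_id=reaction_id,
                junction=junction,
                site=site,
                stack_index=i % per_site,
            )
        )
    return placements


def pack_reactions(
    dnf: DNFForm, reporter: Reporter, config: PackingConfig | None = None
) -> list[ASEReactionSpec]:
    """Map DNF terms onto gate pairs.

    One term: a single REQUIRE_ALL reaction with the term split across
    J1/J2 as evenly as possible (a single literal is duplicated on both
    junctions so no junction is left constitutively open).  Two terms:
    one REQUIRE_ANY reaction, one term per junction.  More terms: pairs
    of terms are packed into parallel reactions sharing the reporter, in
    canonical term order, the odd last term duplicated across its
    reaction's junctions.
    """
    config = config or PackingConfig()
    if not dnf.terms:
        raise PackingError("empty DNF: nothing to pack")
    for term in dnf.terms:
        if len(term) > config.max_switches_per_junction:
            raise PackingError(
                f"term ({' AND '.join(sorted(term))}) is wider than "
                f"max_switches_per_junction={config.max_switches_per_junction}"
            )

    conc = config.standard_concentration
    reactions: list[ASEReactionSpec] = []
    terms = list(dnf.terms)

    def rxn_id(i: int) -> str:
        return f"{reporter.label}_r{i}"

    if len(terms) == 1:
        rid = rxn_id(0)
        term = sorted(terms[0])
        if len(term) == 1:
            # duplicate the lone switch on both junctions: an open junction
            # would make the reaction constitutively ON
            placements = _place_term(term, Junction.J1, rid) + _place_term(
                term, Junction.J2, rid
            )
        else:
            half = len(term) // 2
            placements = _place_term(term[: len(term) - half], Junction.J1, rid) + _place_term(
                term[len(term) - half :], Junction.J2, rid
            )
        reactions.append(
            ASEReactionSpec(
                reaction_id=rid,
                placements=placements,
                mode=FiringMode.REQUIRE_ALL,
                reporter=reporter,
                concentration_s=conc,
                concentration_w=conc,
            )
        )
        return reactions

    for i in range(0, len(terms), 2):
        rid = rxn_id(i // 2)
        if i + 1 < len(terms):
            placements = _place_term(sorted(terms[i]), Junction.J1, rid) + _place_term(
                sorted(terms[i + 1]), Junction.J2, rid
            )
            mode = FiringMode.REQUIRE_ANY
        else:
            # odd final term: duplicate it across both junctions
            placements = _place_term(sorted(terms[i]), Junction.J1, rid) + _place_term(
                sorted(terms[i]), Junction.J2, rid
            )
            mode = FiringMode.REQUIRE_ALL
        reactions.append(
            ASEReactionSpec(
                reaction_id=rid,
                placements=placements,
                mode=mode,
                reporter=reporter,
                concentration_s=conc,
                concentration_w=conc,
            )
        )
    return reactions


def compile_circuit(
    expressions: Mapping[str, str],
    config: PackingConfig | None = None,
    on_multiple: float = DEFAULT_ON_MULTIPLE,
) -> CircuitSpec:
    """Compile output-label -> expression mappings into a CircuitSpec.

    Input order is order of first appearance across expressions (left to
    right); compilation is deterministic, so identical arguments yield
    identical circuits.
    """
    config = config or PackingConfig()
    if len(set(expressions)) != len(expressions):
        raise ExpressionError("duplicate output labels")

    input_order: list[str] = []
    reactions: list[ASEReactionSpec] = []
    outputs: list[str] = []
    for idx, (label, text) in enumerate(expressions.items()):
        tree = parse_expression(text)
        for leaf in tree.leaves():
            if leaf not in input_order:
                input_order.append(leaf)
        fluor, quench = FLUOROPHORE_PAIRS[idx % len(FLUOROPHORE_PAIRS)]
        reporter = Reporter(label=label, fluorophore=fluor, quencher=quench)
        reactions.extend(pack_reactions(to_dnf(tree), reporter, config))
        outputs.append(label)

    return CircuitSpec(
        inputs=[InputDecl(i, on_multiple) for i in input_order],
        reactions=reactions,
        outputs=outputs,
        standard_concentration=config.standard_concentration,
    )
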