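"""Catalog of reference circuits.

Builders for every demonstrated circuit topology: the six single-input
gate-pair configurations used to characterise the exchange mechanism,
the two- to eight-input logic circuits, the eight-input mRNA classifier
(two sites on each of four biomarker mRNAs — Ck8/Sox17 for the
mesenchymal-epithelial transition readout, Alb/Cyp3a4 for the hepatic
readout; the mapping of mRNA pairs to reporters is illustrative), and
the sgRNA blocker-gate circuits.  Logic fixtures are verified against
their documented expression at build time.
"""

from __future__ import annotations

from typing import Callable

from .circuit import (
    ASEReactionSpec,
    CircuitSpec,
    FiringMode,
    InputDecl,
    Junction,
    Reporter,
    Site,
    SwitchPlacement,
    input_combinations,
    truth_table_oracle,
)
from .compiler import compile_circuit, parse_expression

__all__ = ["FIXTURE_EXPRESSIONS", "fixture_names", "make_fixture"]

#: documented Boolean function of each logic fixture (output -> expression)
FIXTURE_EXPRESSIONS: dict[str, dict[str, str]] = {
    "fig2_AND": {"Out": "a AND b"},
    "fig2_OR": {"Out": "a OR b"},
    "fig2_AND_OR": {"Out": "(a AND b) OR c"},
    "fig2_fourinput": {"Out": "(a AND b) OR (c AND d)"},
    "fig2_eightinput": {
        "Out_1": "(a AND b) OR (c AND d)",
        "Out_2": "(e AND f) OR (g AND h)",
    },
    "classifier_8input": {
        "MET": "(Ck8_s1 AND Ck8_s2) OR (Sox17_s1 AND Sox17_s2)",
        "hepatic": "(Alb_s1 AND Alb_s2) OR (Cyp3a4_s1 AND Cyp3a4_s2)",
    },
    "sgrna_YES": {"Cas9": "a"},
    "sgrna_OR": {"Cas9": "a OR b"},
    "sgrna_fourinput": {"Cas9": "(a AND b) OR (c AND d)"},
}

# the six single-input gate-pair configurations: (mode, occupied sites)
_FIG1_SITES: dict[int, tuple[FiringMode, list[tuple[Junction, Site]]]] = {
    1: (FiringMode.REQUIRE_ANY, [(Junction.J1, Site.TOP)]),
    2: (FiringMode.REQUIRE_ANY, [(Junction.J1, Site.TOP), (Junction.J1, Site.BOTTOM)]),
    3: (FiringMode.REQUIRE_ALL, [(Junction.J1, Site.TOP), (Junction.J2, Site.TOP)]),
    4: (
        FiringMode.REQUIRE_ALL,
        [(Junction.J1, Site.TOP), (Junction.J1, Site.BOTTOM), (Junction.J2, Site.TOP)],
    ),
    5: (
        FiringMode.REQUIRE_ALL,
        [(Junction.J1, Site.TOP), (Junction.J2, Site.TOP), (Junction.J2, Site.BOTTOM)],
    ),
    6: (
        FiringMode.REQUIRE_ALL,
        [
            (Junction.J1, Site.TOP),
            (Junction.J1, Site.BOTTOM),
            (Junction.J2, Site.TOP),
            (Junction.J2, Site.BOTTOM),
        ],
    ),
}


def _fig1_config(n: int) -> CircuitSpec:
    """Single-input gate pair with 1-4 switches (all driven by I1).

    Configurations 1-2 block only one junction: the other junction's
    free toehold suffices to initiate branch migration, so these leak.
    Configurations 3-6 block both junctions and fire only with input.
    """
    mode, sites = _FIG1_SITES[n]
    rid = f"fig1c{n}_r0"
    placements = [
        SwitchPlacement(
            switch_id=f"sw{i + 1}",
            input_id="I1",
            reaction_id=rid,
            junction=j,
            site=s,
            stack_index=0,
        )
        for i, (j, s) in enumerate(sites)
    ]
    return CircuitSpec(
        inputs=[InputDecl("I1")],
        reactions=[
            ASEReactionSpec(
                reaction_id=rid,
                placements=placements,
                mode=mode,
                reporter=Reporter("Out"),
            )
        ],
        outputs=["Out"],
    )


def _verified_compile(name: str) -> CircuitSpec:
    spec = compile_circuit(FIXTURE_EXPRESSIONS[name])
    table = truth_table_oracle(spec)
    trees = {label: parse_expression(expr) for label, expr in FIXTURE_EXPRESSIONS[name].items()}
    for combo, outs in table.rows:
        assignment = dict(zip(table.input_order, combo))
        for label, tree in trees.items():
            if outs[label] != tree.evaluate(assignment):
                raise AssertionError(
                    f"fixture {name}: oracle disagrees with its expression at {assignment}"
                )
    return spec


_BUILDERS: dict[str, Callable[[], CircuitSpec]] = {
    **{f"fig1_config_{n}": (lambda n=n: _fig1_config(n)) for n in range(1, 7)},
    **{name: (lambda name=name: _verified_compile(name)) for name in FIXTURE_EXPRESSIONS},
}


def fixture_names() -> list[str]:
    return list(_BUILDERS)


def make_fixture(name: str) -> CircuitSpec:
    """Build a named reference circuit (deterministic; logic verified)."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    return builder()
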