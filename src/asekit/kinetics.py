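"""Mass-action kinetics of allosteric strand-exchange reactions.

A circuit is expanded into a chemical reaction network whose species
are: free input strands, each gate in each of its switch-activation
states, bound-input bookkeeping sinks, and per-reaction exchanged
products and wastes.  Two reaction families are generated:

* activation — an input strand hybridises to one of its unactivated
  switches: ``I + G[state] -> G[state + switch] + I_bound`` at ``k_act``.
  Switch activation and hairpin refolding are lumped into this single
  irreversible step (inputs are delivered in 5x excess, so reverse
  binding is neglected and folding is fast relative to the bimolecular
  encounter).
* exchange — ``S[state_s] + W[state_w] -> product + waste``.  The rate is
  ``k_exchange * alpha^extra * spacer_factor`` when the firing predicate
  of the circuit model holds under the pair of states, and ``k_leak``
  otherwise.  ``extra = max(0, activated - 2)`` counts activated
  switches beyond the minimal two-switch both-blocked design; with
  ``alpha > 1`` this reproduces the observation that exchange kinetics
  speed up with the number of inserted switches.

The reporter signal of an output label is the summed product
concentration of the reactions carrying that reporter (the exchanged
duplex delocalises the quencher from the fluorophore).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import (
    ASEReactionSpec,
    CircuitSpec,
    FiringMode,
    Junction,
    SwitchPlacement,
    errors,
    input_combinations,
    truth_table_oracle,
    validate_circuit,
)

__all__ = ["KineticModel", "CRN", "TimeCourse", "build_crn", "simulate", "endpoint_signals"]

#: reference switch count of the minimal input-gated design (one switch
#: blocking each junction); alpha enhancement counts switches beyond it.
REFERENCE_SWITCH_COUNT = 2

MAX_SWITCHES_PER_GATE = 10  # state-explosion guard: 2^10 states per gate


@dataclass(frozen=True)
class KineticModel:
    """Rate constants (per molar per second for bimolecular steps).

    Absolute rates for this mechanism are not published; the defaults
    are order-of-magnitude values typical of toehold-mediated strand
    displacement and exchange, and the evaluation layer is deliberately
    threshold/qualitative so conclusions do not hinge on them.
    """

    k_act: float = 1e5  # input-switch hybridisation
    k_exchange: float = 2e4  # four-way exchange of a firing-eligible pair
    k_leak: float = 1.0  # residual exchange of a blocked pair
    enhancement_alpha: float = 1.5  # per-extra-activated-switch speedup
    spacer_factor: float = 1.0  # >1 models the TT-spacer rate enhancement
    t_end: float = 18000.0  # 5 h, the endpoint used for logic readout
    rtol: float = 1e-8
    atol: float = 1e-16  # molar; concentrations are O(1e-8)

    def __post_init__(self) -> None:
        if min(self.k_act, self.k_exchange, self.k_leak) < 0:
            raise ValueError("rates must be nonnegative")
        if self.enhancement_alpha < 1:
            raise ValueError("enhancement_alpha must be >= 1")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")


# A gate state is the frozenset of activated placement positions on that gate.
# Placements on J1 sit on the S-gate, placements on J2 on the W-gate: each
# junction is the toehold/recognition boundary controlled from one side of
# the gate pair.
GATE_OF_JUNCTION = {Junction.J1: "S", Junction.J2: "W"}


def _gate_placements(rxn: ASEReactionSpec, gate: str) -> list[SwitchPlacement]:
    return [p for p in rxn.placements if GATE_OF_JUNCTION[p.junction] == gate]


def _pair_fires(rxn: ASEReactionSpec, activated: frozenset) -> bool:
    """Firing predicate under a partial activation state of the gate pair."""
    open_j = {
        j: all(p.position in activated for p in rxn.placements_on(j)) for j in Junction
    }
    if rxn.mode is FiringMode.REQUIRE_ALL:
        return all(open_j.values())
    return any(open_j.values())


@dataclass
class Reaction:
    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate: float


@dataclass
class CRN:
    """Flattened mass-action network with named species."""

    species: list[str]
    reactions: list[Reaction]
    initial: np.ndarray
    reporter_species: dict[str, list[int]]  # output label -> product indices
    conservation_groups: dict[str, list[int]]  # group name -> species indices

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.species)}


def build_crn(
    circuit: CircuitSpec,
    model: KineticModel | None = None,
    input_state: dict[str, float] | None = None,
) -> CRN:
    """Expand a circuit into its activation-state reaction network.

    ``input_state`` maps input ids to concentration multiples of the
    standard 1x concentration (logic-ON is 5x, OFF is 0x; defaults to
    all OFF).  Gates start at 1x with no switch activated.
    """
    model = model or KineticModel()
    errs = errors(validate_circuit(circuit))
    if errs:
        raise ValueError(f"circuit does not validate: {errs[0].message}")
    input_state = input_state or {}

    c1 = circuit.standard_concentration
    species: list[str] = []
    initial: list[float] = []

    def add_species(name: str, conc: float) -> int:
        species.append(name)
        initial.append(conc)
        return len(species) - 1

    input_idx: dict[str, int] = {}
    sink_idx: dict[str, int] = {}
    for decl in circuit.inputs:
        mult = input_state.get(decl.input_id, 0.0)
        input_idx[decl.input_id] = add_species(f"I[{decl.input_id}]", mult * c1)
        sink_idx[decl.input_id] = add_species(f"Ibound[{decl.input_id}]", 0.0)

    reactions: list[Reaction] = []
    reporter_species: dict[str, list[int]] = {label: [] for label in circuit.outputs}
    conservation: dict[str, list[int]] = {}
    for decl in circuit.inputs:
        conservation[f"input[{decl.input_id}]"] = [
            input_idx[decl.input_id],
            sink_idx[decl.input_id],
        ]

    for rxn in circuit.reactions:
        gate_states: dict[str, dict[frozenset, int]] = {}
        gate_conc = {"S": rxn.concentration_s, "W": rxn.concentration_w}
        for gate in ("S", "W"):
            placements = _gate_placements(rxn, gate)
            if len(placements) > MAX_SWITCHES_PER_GATE:
                raise ValueError(
                    f"reaction {rxn.reaction_id}: {len(placements)} switches on "
                    f"gate {gate} exceeds the state-explosion guard "
                    f"({MAX_SWITCHES_PER_GATE})"
                )
            states: dict[frozenset, int] = {}
            for r in range(len(placements) + 1):
                for combo in itertools.combinations(placements, r):
                    state = frozenset(p.position for p in combo)
                    tag = "+".join(sorted(p.switch_id for p in combo)) or "0"
                    conc = gate_conc[gate] if not state else 0.0
                    states[state] = add_species(f"{gate}[{rxn.reaction_id}|{tag}]", conc)
            gate_states[gate] = states

        prod = add_species(f"P[{rxn.reaction_id}]", 0.0)
        waste = add_species(f"Q[{rxn.reaction_id}]", 0.0)
        reporter_species[rxn.reporter.label].append(prod)
        conservation[f"gateS[{rxn.reaction_id}]"] = list(gate_states["S"].values()) + [prod]
        conservation[f"gateW[{rxn.reaction_id}]"] = list(gate_states["W"].values()) + [waste]

        # activation: input + gate[state] -> gate[state+switch] + bound sink
        for gate in ("S", "W"):
            placements = _gate_placements(rxn, gate)
            for state, sidx in gate_states[gate].items():
                for p in placements:
                    if p.position in state:
                        continue
                    new_state = state | {p.position}
                    reactions.append(
                        Reaction(
                            reactants=(input_idx[p.input_id], sidx),
                            products=(gate_states[gate][new_state], sink_idx[p.input_id]),
                            rate=model.k_act,
                        )
                    )

        # exchange: S[state_s] + W[state_w] -> product + waste
        n_min = REFERENCE_SWITCH_COUNT
        for state_s, is_ in gate_states["S"].items():
            for state_w, iw in gate_states["W"].items():
                activated = state_s | state_w
                if _pair_fires(rxn, activated):
                    extra = max(0, len(activated) - n_min)
                    rate = model.k_exchange * model.enhancement_alpha**extra
                    rate *= model.spacer_factor
                else:
                    rate = model.k_leak
                reactions.append(
                    Reaction(reactants=(is_, iw), products=(prod, waste), rate=rate)
                )

    return CRN(
        species=species,
        reactions=reactions,
        initial=np.asarray(initial, dtype=float),
        reporter_species=reporter_species,
        conservation_groups=conservation,
    )


@dataclass
class TimeCourse:
    time: np.ndarray  # seconds
    concentrations: np.ndarray  # (n_species, n_times), molar
    species: list[str]
    reporter_signal: dict[str, np.ndarray]  # molar unquenched fluorophore

    def to_frame(self):
        import pandas as pd

        data = {"time_s": self.time}
        for label, sig in self.reporter_signal.items():
            data[label] = sig
        return pd.DataFrame(data)

    def species_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.concentrations.T, columns=self.species)
        df.insert(0, "time_s", self.time)
        return df


def _rhs_terms(crn: CRN):
    n_rxn = len(crn.reactions)
    n_sp = len(crn.species)
    rates = np.array([r.rate for r in crn.reactions])
    r0 = np.array([r.reactants[0] for r in crn.reactions])
    r1 = np.array([r.reactants[1] for r in crn.reactions])
    stoich = np.zeros((n_sp, n_rxn))
    for j, r in enumerate(crn.reactions):
        for idx in r.reactants:
            stoich[idx, j] -= 1
        for idx in r.products:
            stoich[idx, j] += 1
    return rates, r0, r1, stoich


def simulate(
    crn: CRN, model: KineticModel | None = None, n_points: int = 200
) -> TimeCourse:
    """Deterministic stiff-ODE integration of the network to ``t_end``.

    All generated reactions are bimolecular, so the flux vector is
    ``k * [A] * [B]`` per reaction; LSODA handles the stiffness from the
    well-separated activation/exchange/leak rates.
    """
    model = model or KineticModel()
    rates, r0, r1, stoich = _rhs_terms(crn)

    def rhs(_t, y):
        flux = rates * y[r0] * y[r1]
        return stoich @ flux

    t_eval = np.linspace(0.0, model.t_end, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, model.t_end),
        crn.initial,
        method="LSODA",
        t_eval=t_eval,
        rtol=model.rtol,
        atol=model.atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")

    conc = sol.y
    signals = {
        label: conc[idxs, :].sum(axis=0) if idxs else np.zeros_like(sol.t)
        for label, idxs in crn.reporter_species.items()
    }
    return TimeCourse(
        time=sol.t, concentrations=conc, species=list(crn.species), reporter_signal=signals
    )


def conservation_residuals(crn: CRN, tc: TimeCourse) -> dict[str, float]:
    """Max |group total - initial total| over the trajectory, per group."""
    out = {}
    for name, idxs in crn.conservation_groups.items():
        totals = tc.concentrations[idxs, :].sum(axis=0)
        out[name] = float(np.max(np.abs(totals - totals[0])))
    return out


def endpoint_signals(
    circuit: CircuitSpec,
    model: KineticModel | None = None,
    n_points: int = 2,
) -> np.ndarray:
    """Raw endpoint reporter signals for every input combination.

    Returns a ``(2^N, n_outputs)`` matrix in molar, rows in binary
    counting order (first input = most significant bit), columns in the
    circuit's output order.  One full kinetic simulation is run per
    combination.
    """
    model = model or KineticModel()
    order = circuit.input_ids
    if len(order) > 10:
        raise ValueError("endpoint sweep limited to 10 inputs (2^N simulations)")
    rows = []
    for combo in input_combinations(order):
        state = {
            i: (decl.on_multiple if bit else 0.0)
            for (i, bit), decl in zip(zip(order, combo), circuit.inputs)
        }
        crn = build_crn(circuit, model, state)
        tc = simulate(crn, model, n_points=n_points)
        rows.append([tc.reporter_signal[label][-1] for label in circuit.outputs])
    return np.asarray(rows)
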