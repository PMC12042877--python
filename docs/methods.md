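# Methods

## The circuit model

A circuit is a set of ASE reactions (gate pairs) read out by fluorophore/
quencher reporters. The semantic core is the junction predicate: a junction is
open iff every switch placed on it is activated, and a junction carrying no
switch is constitutively open. A reaction fires under REQUIRE_ANY when at
least one junction is open and under REQUIRE_ALL when both are. This
junction-plus-mode formalisation deliberately abstracts away the strand-level
geometry that distinguishes AND-type from OR-type switch placements: the two
firing modes capture the observable semantics (initiation by one or both
toeholds) without committing to a physical layout we do not model. Tandem
switches stacked at one site are conjunctive, because an unopened inserted
duplex still separates the toehold from the recognition domain regardless of
its neighbours.

Inputs are binary at the specification level: logic-ON delivers the input
strand at 5× the standard gate concentration (1× = 50 nM), logic-OFF at 0×.
The Boolean oracle (`truth_table_oracle`) evaluates the junction predicate
exactly and is the ground truth for every downstream check. Because the
architecture contains no inverter, the oracle is monotone — raising any input
can never turn an output off — and this is enforced as a property test.

## Compilation

Expressions are parsed with standard precedence (AND over OR, no negation),
converted to DNF by distribution, and canonicalised: duplicate terms removed,
absorption applied (no term a superset of another), terms ordered by (width,
sorted literals). Packing maps one term per junction; two terms share a gate
pair under REQUIRE_ANY; three or more terms use parallel gate pairs sharing
the reporter, packed pairwise in canonical order. A single-literal term is
duplicated on both junctions rather than leaving one open, since an open
junction fires constitutively. The per-junction width limit defaults to 2,
the deepest stack demonstrated experimentally; it can be raised, with a
warning that this is beyond demonstrated scale. Compilation is a pure
function of its arguments, so identical expressions yield byte-identical
serialisations.

The cascade-equivalent gate count of a DNF with t terms of widths w_i is
`Σ(w_i − 1) + (t − 1)` two-input gates (0 for a bare literal), summed over
outputs for multi-output circuits.

## Kinetics

The simulator expands a circuit into a mass-action network whose species are
free inputs, bound-input bookkeeping sinks, each gate in each subset of its
switch-activation states, and per-reaction product/waste species. Two
reaction families are generated:

* **Activation** `I + G[σ] → G[σ∪{s}] + I_bound` at `k_act` (default
  1e5 /M/s). Input binding is irreversible and stoichiometric — the 5× input
  excess justifies neglecting reversibility — and hairpin refolding is lumped
  into the binding step, treated as fast relative to the bimolecular
  encounter.
* **Exchange** `S[σ_S] + W[σ_W] → P + Q`. If the firing predicate holds under
  the combined activation state, the rate is
  `k_exchange · α^max(0, n_act − 2) · spacer_factor`; otherwise `k_leak`.

The α exponent counts activated switches beyond the minimal input-gated
design (one switch per junction, n = 2). This choice makes the fully
activated 2-, 3- and 4-switch configurations exchange at rate ratios
1 : α : α², reproducing the observed speed-up of exchange with switch count
while leaving the minimal configurations at `k_exchange` exactly; a
zero-switch (constitutive) pair also runs at `k_exchange`. `spacer_factor`
(default 1.0) exposes the spacer-length rate enhancement as a multiplier
without modelling its physics.

Absolute rate constants are not published for this mechanism; the defaults
(`k_exchange` 2e4 /M/s, `k_leak` 1 /M/s, α 1.5) are order-of-magnitude values
from the strand-displacement literature and are fully config-exposed. The
evaluation layer is threshold/qualitative by design, so the logic conclusions
are insensitive to them over wide ranges: at 50 nM gates and 5 h,
`k_exchange·S0·t ≈ 18` (near-complete conversion) while `k_leak·S0·t ≈ 9e-4`
(a ~0.1% leak floor), three orders of magnitude of margin around the 0.5
threshold.

Integration uses LSODA (`rtol` 1e-8, `atol` 1e-16 M) on the flattened
bimolecular flux vector. Every strand group (each gate's states plus its
product or waste; each input plus its bound sink) is conserved by
construction, and tests verify the residual stays below 1e-9 M over full
trajectories. A guard rejects gates with more than 10 switches (2^n states
per gate). Deterministic ODE integration only: the observable is bulk
fluorescence, so stochastic simulation would add cost without information.

## Evaluation metrics

Each reporter column of the endpoint matrix is normalised by its own maximum
over the 2^N input combinations (output = 1 at the highest signal), then
thresholded at 0.5 — strictly above is ON. The VP angle is
`arccos(s·e / (‖s‖‖e‖))` in degrees between the normalised signal vector and
the 0/1 truth vector. "Dynamic range" has no published formula; we adopt the
separation `min(ON) − max(OFF)` on normalised signals — the margin the 0.5
threshold line visually measures, standard in strand-displacement circuit
work — and provide the ratio variant `min(ON)/max(OFF)` behind a flag.
Neither variant is claimed to match any published numeric scale.

## Sequence design

Domains are rejection-sampled uniformly over {A,C,G,T} under four screens:
GC fraction within [0.40, 0.60], homopolymers ≤ 3 nt, self-complementary runs
≤ 6 nt, and longest complementary run against every previously accepted
non-cognate domain (and its complement) ≤ 6 nt. These heuristic screens stand
in for partition-function secondary-structure analysis; they are fast,
dependency-free, and their contracts (verified by exhaustive
complementary-run scans) are the guarantee the package makes. Candidates are
drawn from a single seeded generator, so a (circuit, config, seed) triple
always yields identical FASTA bytes.

Fixed lengths: 13-nt toehold, 14-nt recognition domain, literal "TT" spacer.
The switch module's internal architecture — 8-nt input toehold, 10-nt stem,
6-nt loop, giving a 34-nt inserted module (toehold + stem + loop + stem*) and
an 18-nt input-binding region (toehold + stem) — is a configurable default
chosen to put input binding in the range where toehold-mediated initiation is
strongly favoured; the true hairpin geometry is not modelled. Likewise the
strand-level convention (S-gate long strands carry the toehold/recognition
pair, W-gate strands their complements; J1 switches sit on the S-gate, J2 on
the W-gate; blockers append 3′ of the recognition domain) is a declared
convention, not an inferred geometry.

Target-site selection scans every window of the input-binding length on the
transcript and scores it by (uniqueness, accessibility): uniqueness counts
window 12-mers present anywhere in the background sequence set — a desk-scale
surrogate for a BLAST off-target screen; k = 12 is the shortest k-mer with a
low random-match probability at transcriptome scale (4^12 ≈ 1.7e7) that still
catches near-exact off-targets — and accessibility is the longest
complementary run between the window and its ±50-nt flanks, penalising
windows buried in local secondary structure. The two non-overlapping windows
minimising the score lexicographically win, ties broken 5′-most. Coordinates
are 0-based half-open on the given strand; mRNA inputs are single-stranded so
no reverse-strand search is done. If no zero-uniqueness window exists the
best-effort result is returned flagged.

sgRNA blocker gates choose one 18-nt engineered region of the guide (default
the 5′-most 18 nt; position configurable) and give each gate pair a 9-nt
blocker complementary to a sub-window of it. Sub-window offsets cycle over
(0, 9) so parallel gate pairs address disjoint halves of the region rather
than competing for the same bases. The predicted sgRNA activation logic is
exactly the circuit's Boolean oracle.

## Synthetic data and what passing means

All fixtures are generated in-package: the six single-input gate
configurations (switch occupancy of the four junction sites), the two- to
eight-input logic circuits, the eight-input mRNA classifier, and the sgRNA
circuits. The classifier's mapping of mRNA pairs to reporters
(Ck8/Sox17 → MET, Alb/Cyp3a4 → hepatic) is illustrative of the topology.
Simulated inputs are clean 0×/5× concentration steps in a well-mixed dilute
solution. Real operation differs in ways the model does not capture:
cellular delivery and degradation, off-target binding beyond the heuristic
screens, folding thermodynamics of real sequences, crowding, and
fluorophore-specific readout artifacts. Passing tests therefore certify the
logic architecture, compiler correctness, and the internal consistency of the
kinetic model — not cell-derived performance numbers, which are outside the
package's scope.

## Problem sizes and numerical choices

Endpoint sweeps run one ODE integration per input combination (2^N, capped at
N = 10); the eight-input circuits integrate 256 networks of ~36 species in
about a second. Time-to-half-max measurements use 600-point grids; endpoint
calls use 2-point grids (LSODA's internal stepping is unaffected by the
output grid). Ties in target-site selection break 5′-most; DNF term order
breaks ties lexicographically; degenerate inputs (all-zero signal columns,
all-ON truth vectors, zero-norm vectors) raise informative errors rather than
returning NaN.

## Known limitations

No inverter, hence only monotone functions; no multi-level ASE→ASE cascading
in the compiler; no thermodynamic folding or free-energy computation; no
fitting of rate constants to experimental traces; reporter cross-talk between
fluorophores is not modelled.
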