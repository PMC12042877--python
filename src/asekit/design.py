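"""Sequence design for ASE circuits.

Generates orthogonal DNA domains for compiled circuits, assembles the
gate strands, selects mRNA target sites, and designs sgRNA blocker
gates.  Orthogonality is enforced with heuristic screens — GC-content
and homopolymer filters plus an exhaustive longest-complementary-run
scan between every non-cognate domain pair — rather than a
partition-function fold; the screens' contracts are themselves the
design guarantee.

Domain architecture of one gate pair (all 5'->3'):

    long strand  =  toehold(13) -- "TT" spacer -- [switch modules] -- recognition(14)
    switch module = input-toehold(8) + stem(10) + loop(6) + stem*(10)
    short strand  = exact complement of the recognition region

The S-gate long strands carry the (toehold, recognition) pair; the
W-gate long strands carry their complements so the two gates can
exchange strands.  The input-binding region of a switch is its input
toehold plus stem (18 nt), which is also the length of an mRNA target
site and of the engineered sgRNA region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from io import StringIO
from typing import Iterable, Sequence

import numpy as np

from .circuit import (
    ASEReactionSpec,
    CircuitSpec,
    Domain,
    DomainRole,
    Junction,
    Site,
    errors,
    truth_table_oracle,
    validate_circuit,
)

__all__ = [
    "DesignConfig",
    "DomainLibrary",
    "Strand",
    "StrandSet",
    "TargetSite",
    "DesignError",
    "generate_domains",
    "crosstalk_matrix",
    "longest_complementary_run",
    "assemble_gate_strands",
    "select_target_sites",
    "design_sgrna_gate",
    "SgRNAGateDesign",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DesignError(RuntimeError):
    pass


@dataclass(frozen=True)
class DesignConfig:
    """Tunable sequence-design rules.

    Lengths follow the gate architecture: 13-nt toehold, 14-nt
    recognition domain, a literal "TT" spacer between them, and 9-nt
    sgRNA blockers addressing an 18-nt engineered region.  The switch
    module internals (8-nt input toehold, 10-nt stem, 6-nt loop) are a
    configurable default.
    """

    toehold_length: int = 13
    recognition_length: int = 14
    spacer: str = "TT"
    switch_toehold_length: int = 8
    switch_stem_length: int = 10
    switch_loop_length: int = 6
    gc_range: tuple[float, float] = (0.40, 0.60)
    max_homopolymer: int = 3
    max_crosstalk_run: int = 6
    two_prime_ome: bool = False
    rng_seed: int = 0
    attempt_budget: int = 5000
    # target-site selection
    uniqueness_k: int = 12
    accessibility_flank: int = 50
    # sgRNA gate engineering
    engineered_region_start: int = 0
    engineered_region_length: int = 18
    blocker_length: int = 9
    blocker_offsets: tuple[int, ...] = (0, 9)  # cycled over reactions

    def __post_init__(self) -> None:
        for name in (
            "toehold_length",
            "recognition_length",
            "switch_toehold_length",
            "switch_stem_length",
            "switch_loop_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.gc_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("gc_range must be an ordered pair within [0, 1]")

    @property
    def input_binding_length(self) -> int:
        """Length of the switch region an input (or mRNA site) hybridises to."""
        return self.switch_toehold_length + self.switch_stem_length

    @property
    def switch_module_length(self) -> int:
        return self.switch_toehold_length + 2 * self.switch_stem_length + self.switch_loop_length


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def longest_complementary_run(x: str, y: str) -> int:
    """Longest contiguous exact Watson-Crick duplex between strands x and y.

    Equivalent to the longest common substring of x and the reverse
    complement of y (both read 5'->3').
    """
    ry = reverse_complement(y)
    n, m = len(x), len(ry)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        xi = x[i - 1]
        for j in range(1, m + 1):
            if xi == ry[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


@dataclass
class DomainLibrary:
    """Named domains for one circuit, with provenance.

    ``cognates`` records pairs that are exact reverse complements by
    construction (excluded from the cross-talk screen).
    """

    domains: dict[str, Domain]
    cognates: list[tuple[str, str]]
    config: DesignConfig
    seed: int

    def __getitem__(self, name: str) -> Domain:
        return self.domains[name]

    @property
    def primary_names(self) -> list[str]:
        return list(self.domains)

    def max_noncognate_crosstalk(self) -> int:
        df = crosstalk_matrix(self)
        return int(df.values.max()) if df.size else 0

    def to_fasta(self) -> str:
        buf = StringIO()
        for name, dom in self.domains.items():
            buf.write(
                f">{name} role={dom.role.value} length={dom.length} "
                f"seed={self.seed} chemistry={'2OMe-RNA' if dom.two_prime_ome else 'DNA'}\n"
                f"{dom.sequence}\n"
            )
        return buf.getvalue()


def _required_domains(circuit: CircuitSpec, config: DesignConfig) -> list[tuple[str, DomainRole, int]]:
    """Deterministic list of (name, role, length) the circuit needs."""
    needs: list[tuple[str, DomainRole, int]] = []
    seen_switches: set[str] = set()
    for rxn in circuit.reactions:
        needs.append((f"t.{rxn.reaction_id}", DomainRole.TOEHOLD, config.toehold_length))
        needs.append((f"m.{rxn.reaction_id}", DomainRole.RECOGNITION, config.recognition_length))
        for p in rxn.placements:
            if p.switch_id in seen_switches:
                continue
            seen_switches.add(p.switch_id)
            needs.append((f"{p.switch_id}.t", DomainRole.SWITCH, config.switch_toehold_length))
            needs.append((f"{p.switch_id}.stem", DomainRole.SWITCH, config.switch_stem_length))
            needs.append((f"{p.switch_id}.loop", DomainRole.SWITCH, config.switch_loop_length))
    return needs


def generate_domains(circuit: CircuitSpec, config: DesignConfig | None = None) -> DomainLibrary:
    """Rejection-sample an orthogonal domain set for a circuit.

    Each candidate must satisfy the GC window and homopolymer cap, avoid
    self-complementary runs longer than ``max_crosstalk_run``, and keep
    every complementary run against already-accepted non-cognate domains
    within the same cap.  Deterministic given ``config.rng_seed``.
    """
    config = config or DesignConfig()
    errs = errors(validate_circuit(circuit))
    if errs:
        raise ValueError(f"circuit does not validate: {errs[0].message}")

    rng = np.random.default_rng(config.rng_seed)
    bases = np.array(list("ACGT"))
    accepted: dict[str, Domain] = {}
    lo, hi = config.gc_range

    for name, role, length in _required_domains(circuit, config):
        for _ in range(config.attempt_budget):
            seq = "".join(rng.choice(bases, size=length))
            if not (lo <= _gc_fraction(seq) <= hi):
                continue
            if _max_homopolymer(seq) > config.max_homopolymer:
                continue
            if longest_complementary_run(seq, seq) > config.max_crosstalk_run:
                continue
            if any(
                longest_complementary_run(seq, d.sequence) > config.max_crosstalk_run
                or longest_complementary_run(seq, reverse_complement(d.sequence))
                > config.max_crosstalk_run
                for d in accepted.values()
            ):
                continue
            accepted[name] = Domain(name, seq, role, config.two_prime_ome)
            break
        else:
            raise DesignError(
                f"could not satisfy binding constraints for domain {name!r} "
                f"({role.value}, {length} nt) within {config.attempt_budget} attempts: "
                f"GC in [{lo}, {hi}], homopolymer <= {config.max_homopolymer}, "
                f"cross-talk run <= {config.max_crosstalk_run}"
            )

    return DomainLibrary(domains=accepted, cognates=[], config=config, seed=config.rng_seed)


def crosstalk_matrix(library: DomainLibrary):
    """Symmetric matrix of longest complementary run between non-cognate pairs.

    The diagonal reports each domain against itself (self-dimer); a
    domain equal to its own reverse complement is palindromic and is
    flagged in ``matrix.attrs['palindromic']``.  Cognate pairs are
    excluded (set to -1) and listed in ``matrix.attrs['cognates']`` at
    full length.
    """
    import pandas as pd

    names = library.primary_names
    if len(names) < 2:
        raise ValueError("crosstalk matrix needs at least 2 domains")
    cognate_set = {frozenset(p) for p in library.cognates}
    n = len(names)
    mat = np.zeros((n, n), dtype=int)
    for i, a in enumerate(names):
        for j in range(i, n):
            b = names[j]
            if frozenset((a, b)) in cognate_set:
                mat[i, j] = mat[j, i] = -1
                continue
            run = longest_complementary_run(
                library[a].sequence, library[b].sequence
            )
            mat[i, j] = mat[j, i] = run
    df = pd.DataFrame(mat, index=names, columns=names)
    df.attrs["palindromic"] = [
        nm
        for nm in names
        if library[nm].sequence == reverse_complement(library[nm].sequence)
    ]
    df.attrs["cognates"] = [
        (a, b, len(library[a].sequence)) for a, b in library.cognates
    ]
    return df


@dataclass(frozen=True)
class Strand:
    name: str
    sequence: str
    parts: tuple[tuple[str, str], ...]  # (domain name, subsequence) in 5'->3' order
    annotations: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fasta_description(self) -> str:
        breakdown = "|".join(f"{n}[{len(s)}]" for n, s in self.parts)
        ann = (" " + " ".join(self.annotations)) if self.annotations else ""
        return f"domains={breakdown}{ann}"


@dataclass
class StrandSet:
    strands: list[Strand]
    circuit_outputs: list[str]

    def __iter__(self):
        return iter(self.strands)

    def __getitem__(self, name: str) -> Strand:
        for s in self.strands:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_fasta(self) -> str:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(s.sequence), id=s.name, description=s.fasta_description())
            for s in self.strands
        ]
        buf = StringIO()
        seqio_write(records, buf, "fasta")
        return buf.getvalue()

    def breakdown_table(self):
        import pandas as pd

        rows = []
        for s in self.strands:
            pos = 0
            for dom, sub in s.parts:
                rows.append(
                    {
                        "strand": s.name,
                        "domain": dom,
                        "start": pos,
                        "end": pos + len(sub),
                        "sequence": sub,
                    }
                )
                pos += len(sub)
        return pd.DataFrame(rows)


# strand positions: placements on (junction, site) map onto the four long
# strands of the pair; J1 is controlled from the S-gate, J2 from the W-gate
_STRAND_OF = {
    (Junction.J1, Site.TOP): ("S", "A"),
    (Junction.J1, Site.BOTTOM): ("S", "C"),
    (Junction.J2, Site.TOP): ("W", "A"),
    (Junction.J2, Site.BOTTOM): ("W", "C"),
}


def _switch_module_parts(switch_id: str, library: DomainLibrary) -> list[tuple[str, str]]:
    t = library[f"{switch_id}.t"].sequence
    stem = library[f"{switch_id}.stem"].sequence
    loop = library[f"{switch_id}.loop"].sequence
    return [
        (f"{switch_id}.t", t),
        (f"{switch_id}.stem", stem),
        (f"{switch_id}.loop", loop),
        (f"{switch_id}.stem*", reverse_complement(stem)),
    ]


def assemble_gate_strands(
    circuit: CircuitSpec,
    library: DomainLibrary,
    config: DesignConfig | None = None,
    blockers: dict[str, str] | None = None,
) -> StrandSet:
    """Concatenate domains into the physical strands of every gate pair.

    Per reaction: four long strands (A/C on each of the S- and W-gates),
    each toehold -- "TT" spacer -- switch modules (stack order) --
    recognition, plus the two short complementary strands (B).  The
    W-gate carries the complementary toehold/recognition so the pair can
    exchange.  Fluorophore/quencher labels are attached as annotations,
    not bases.  ``blockers`` optionally appends a named 9-nt blocker
    domain (3' of the recognition domain) to every long strand of the
    given reactions.
    """
    config = config or library.config
    strands: list[Strand] = []
    for rxn in circuit.reactions:
        try:
            t = library[f"t.{rxn.reaction_id}"].sequence
            m = library[f"m.{rxn.reaction_id}"].sequence
        except KeyError as exc:
            raise DesignError(f"library is missing domain {exc.args[0]!r}") from exc

        seqs = {
            "S": {"toehold": t, "recognition": m},
            "W": {"toehold": reverse_complement(t), "recognition": reverse_complement(m)},
        }
        by_strand: dict[tuple[str, str], list] = {
            key: [] for key in (("S", "A"), ("S", "C"), ("W", "A"), ("W", "C"))
        }
        for p in sorted(rxn.placements, key=lambda p: (p.junction.value, p.site.value, p.stack_index)):
            by_strand[_STRAND_OF[(p.junction, p.site)]].append(p)

        for (gate, arm), placements in by_strand.items():
            star = "" if gate == "S" else "*"
            parts: list[tuple[str, str]] = [
                (f"t.{rxn.reaction_id}{star}", seqs[gate]["toehold"]),
                ("spacer", config.spacer),
            ]
            for p in sorted(placements, key=lambda p: p.stack_index):
                try:
                    parts.extend(_switch_module_parts(p.switch_id, library))
                except KeyError as exc:
                    raise DesignError(f"library is missing domain {exc.args[0]!r}") from exc
            parts.append((f"m.{rxn.reaction_id}{star}", seqs[gate]["recognition"]))
            if blockers and rxn.reaction_id in blockers:
                parts.append((f"blocker.{rxn.reaction_id}", blockers[rxn.reaction_id]))
            annotations: tuple[str, ...] = ()
            if gate == "S" and arm == "A":
                annotations = (
                    f"fluorophore={rxn.reporter.fluorophore}",
                    f"quencher={rxn.reporter.quencher}",
                    f"reporter={rxn.reporter.label}",
                )
            strands.append(
                Strand(
                    name=f"{rxn.reaction_id}.{arm}_{gate}",
                    sequence="".join(s for _, s in parts),
                    parts=tuple(parts),
                    annotations=annotations,
                )
            )

        # short strands complementary to the recognition regions
        strands.append(
            Strand(
                name=f"{rxn.reaction_id}.B_S",
                sequence=reverse_complement(m),
                parts=((f"m.{rxn.reaction_id}*", reverse_complement(m)),),
            )
        )
        strands.append(
            Strand(
                name=f"{rxn.reaction_id}.B_W",
                sequence=m,
                parts=((f"m.{rxn.reaction_id}", m),),
            )
        )
    return StrandSet(strands=strands, circuit_outputs=list(circuit.outputs))


@dataclass(frozen=True)
class TargetSite:
    """A candidate input window on a transcript (0-based half-open, 5'->3')."""

    transcript_id: str
    start: int
    end: int
    sequence: str
    uniqueness: int  # window k-mers shared with the background
    accessibility: int  # longest self-complementary run vs local flanks
    flagged: bool = False


def _normalise_seq(seq) -> tuple[str, str]:
    """Accept str or Bio SeqRecord; return (id, uppercase DNA sequence)."""
    if hasattr(seq, "seq"):
        return (getattr(seq, "id", "seq") or "seq", str(seq.seq).upper().replace("U", "T"))
    return ("seq", str(seq).upper().replace("U", "T"))


def select_target_sites(
    transcript,
    background: Sequence = (),
    config: DesignConfig | None = None,
) -> tuple[tuple[TargetSite, TargetSite], list[str]]:
    """Pick the two best non-overlapping input windows on a transcript.

    Every window of the switch input-binding length is scored by
    (uniqueness, accessibility): uniqueness counts window k-mers present
    anywhere in the background set (a desk-scale stand-in for a BLAST
    off-target screen), accessibility is the longest complementary run
    between the window and its +/-50-nt flanks (windows buried in local
    secondary structure score high).  The lexicographically minimal pair
    wins, ties broken by 5'-most position.  Returns the two sites plus a
    list of warnings; if no window reaches uniqueness 0 the result is
    flagged best-effort.
    """
    config = config or DesignConfig()
    tid, seq = _normalise_seq(transcript)
    L = config.input_binding_length
    if len(seq) < 2 * L:
        raise ValueError(
            f"transcript {tid!r} ({len(seq)} nt) shorter than two site lengths (2x{L} nt)"
        )

    k = config.uniqueness_k
    bg_kmers: set[str] = set()
    for b in background:
        _, bseq = _normalise_seq(b)
        for i in range(len(bseq) - k + 1):
            bg_kmers.add(bseq[i : i + k])

    flank = config.accessibility_flank
    scored: list[tuple[int, int, int]] = []  # (uniqueness, accessibility, start)
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        uniq = sum(1 for i in range(L - k + 1) if window[i : i + k] in bg_kmers)
        flanks = seq[max(0, start - flank) : start] + seq[start + L : start + L + flank]
        access = longest_complementary_run(window, flanks) if flanks else 0
        scored.append((uniq, access, start))
    scored.sort()

    first = scored[0]
    second = next(
        (s for s in scored if s[2] >= first[2] + L or s[2] + L <= first[2]), None
    )
    if second is None:  # transcript length guarantees one exists
        raise AssertionError("no non-overlapping second window")

    warnings: list[str] = []
    flagged = False
    if first[0] > 0 or second[0] > 0:
        flagged = True
        warnings.append(
            "no window (pair) with zero shared background k-mers; "
            "returning best-effort sites flagged for manual review"
        )

    def mk(site: tuple[int, int, int]) -> TargetSite:
        uniq, access, start = site
        return TargetSite(
            transcript_id=tid,
            start=start,
            end=start + L,
            sequence=seq[start : start + L],
            uniqueness=uniq,
            accessibility=access,
            flagged=flagged,
        )

    pair = tuple(sorted((mk(first), mk(second)), key=lambda s: s.start))
    return pair, warnings


@dataclass
class SgRNAGateDesign:
    """Blocker-gated sgRNA circuit: strands, duplex map, and predicted logic."""

    circuit: CircuitSpec
    strands: StrandSet
    engineered_region: tuple[int, int]  # 0-based half-open on the sgRNA
    blockers: dict[str, tuple[int, int, str]]  # rxn -> (start, end, blocker seq)
    predicted_logic: "object"  # TruthTable


def design_sgrna_gate(
    sgrna: str,
    circuit: CircuitSpec,
    config: DesignConfig | None = None,
    library: DomainLibrary | None = None,
) -> SgRNAGateDesign:
    """Reprogram a circuit's gates to sequester an sgRNA.

    A single engineered region (default 18 nt) of the sgRNA is chosen;
    each gate pair receives a 9-nt blocker domain complementary to a
    sub-window of that region (sub-window offsets cycle over the
    configured list so parallel gates address disjoint halves).  The
    blocker holds the sgRNA in an inactive conformation until the
    circuit's inputs open the gates, so the predicted sgRNA activation
    logic is exactly the circuit's Boolean oracle.
    """
    config = config or DesignConfig()
    _, seq = _normalise_seq(sgrna)
    r0 = config.engineered_region_start
    r1 = r0 + config.engineered_region_length
    if len(seq) < r1:
        raise ValueError(
            f"sgRNA ({len(seq)} nt) shorter than the engineered region "
            f"[{r0}, {r1}) ({config.engineered_region_length} nt)"
        )
    region = seq[r0:r1]

    blockers: dict[str, tuple[int, int, str]] = {}
    blocker_seqs: dict[str, str] = {}
    offsets = config.blocker_offsets or (0,)
    for i, rxn in enumerate(circuit.reactions):
        off = offsets[i % len(offsets)]
        if off < 0 or off + config.blocker_length > config.engineered_region_length:
            raise ValueError(
                f"blocker window offset {off} (+{config.blocker_length} nt) falls "
                f"outside the {config.engineered_region_length}-nt engineered region"
            )
        window = region[off : off + config.blocker_length]
        blocker = reverse_complement(window)
        blockers[rxn.reaction_id] = (r0 + off, r0 + off + config.blocker_length, blocker)
        blocker_seqs[rxn.reaction_id] = blocker

    if library is None:
        library = generate_domains(circuit, config)
    strands = assemble_gate_strands(circuit, library, config, blockers=blocker_seqs)

    return SgRNAGateDesign(
        circuit=circuit,
        strands=strands,
        engineered_region=(r0, r1),
        blockers=blockers,
        predicted_logic=truth_table_oracle(circuit),
    )
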