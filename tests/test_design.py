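"""Sequence design: orthogonal domains, strand assembly, target sites, sgRNA gates."""

import numpy as np
import pytest

from asekit import make_fixture
from asekit.design import (
    DesignConfig,
    DesignError,
    assemble_gate_strands,
    crosstalk_matrix,
    design_sgrna_gate,
    generate_domains,
    longest_complementary_run,
    reverse_complement,
    select_target_sites,
)


@pytest.fixture(scope="module")
def and_library():
    circuit = make_fixture("fig2_AND")
    config = DesignConfig(rng_seed=7)
    return circuit, config, generate_domains(circuit, config)


class TestComplementaryRun:
    def test_exact_complement_scores_full_length(self):
        seq = "ACGTTGCACGTAA"
        assert longest_complementary_run(seq, reverse_complement(seq)) == 13

    def test_known_partial_duplex(self):
        # GCCA (in x) pairs with TGGC (in y): a 4-bp duplex
        assert longest_complementary_run("AAGCCATT", "CTTGGCAC") == 4

    def test_symmetric(self):
        x, y = "ACGTACGTACGT", "TTGCATGCAA"
        assert longest_complementary_run(x, y) == longest_complementary_run(y, x)


class TestGenerateDomains:
    def test_design_rule_lengths(self, and_library):
        _, config, lib = and_library
        for name, d in lib.domains.items():
            if d.role.value == "toehold":
                assert d.length == 13
            elif d.role.value == "recognition":
                assert d.length == 14

    def test_gc_and_homopolymer_constraints(self, and_library):
        _, config, lib = and_library
        lo, hi = config.gc_range
        for d in lib.domains.values():
            gc = (d.sequence.count("G") + d.sequence.count("C")) / d.length
            assert lo <= gc <= hi
            for base in "ACGT":
                assert base * (config.max_homopolymer + 1) not in d.sequence

    def test_crosstalk_bounded_by_exhaustive_scan(self, and_library):
        _, config, lib = and_library
        mat = crosstalk_matrix(lib)
        off_diag = mat.values[~np.eye(len(mat), dtype=bool)]
        assert (off_diag[off_diag >= 0] <= config.max_crosstalk_run).all()

    def test_deterministic_fasta_bytes(self):
        circuit = make_fixture("fig2_OR")
        runs = [
            assemble_gate_strands(circuit, generate_domains(circuit, DesignConfig(rng_seed=11)))
            .to_fasta()
            .encode()
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_unsatisfiable_config_raises_with_constraint(self):
        circuit = make_fixture("fig2_AND")
        with pytest.raises(DesignError, match="cross-talk|GC"):
            generate_domains(
                circuit, DesignConfig(rng_seed=1, gc_range=(0.0, 0.0), attempt_budget=200)
            )


class TestAssembly:
    def test_unswitched_long_strand_is_29_nt(self, and_library):
        circuit, config, lib = and_library
        strands = assemble_gate_strands(circuit, lib, config)
        # the AND circuit has one switch per gate: the unswitched arms are bare
        assert strands["Out_r0.C_S"].length == 13 + 2 + 14
        assert strands["Out_r0.C_W"].length == 29

    def test_switched_strand_adds_one_module_length(self, and_library):
        circuit, config, lib = and_library
        strands = assemble_gate_strands(circuit, lib, config)
        assert strands["Out_r0.A_S"].length == 29 + config.switch_module_length
        assert config.switch_module_length == 8 + 10 + 10 + 6

    def test_spacer_is_literally_TT_in_every_long_strand(self, and_library):
        circuit, config, lib = and_library
        for s in assemble_gate_strands(circuit, lib, config):
            parts = dict(s.parts)
            if "spacer" in parts:
                assert parts["spacer"] == "TT"

    def test_short_strands_complement_recognition(self, and_library):
        circuit, config, lib = and_library
        strands = assemble_gate_strands(circuit, lib, config)
        m = lib["m.Out_r0"].sequence
        assert strands["Out_r0.B_S"].sequence == reverse_complement(m)
        assert strands["Out_r0.B_W"].sequence == m

    def test_lengths_sum_over_declared_parts(self, and_library):
        circuit, config, lib = and_library
        for s in assemble_gate_strands(circuit, lib, config):
            assert s.length == sum(len(sub) for _, sub in s.parts)

    def test_missing_domain_is_named(self, and_library):
        circuit, config, lib = and_library
        broken = dict(lib.domains)
        broken.pop("m.Out_r0")
        from asekit.design import DomainLibrary

        with pytest.raises(DesignError, match="m.Out_r0"):
            assemble_gate_strands(
                circuit, DomainLibrary(broken, [], config, config.rng_seed), config
            )

    def test_reporter_annotation_on_fluorophore_strand(self, and_library):
        circuit, config, lib = and_library
        ann = assemble_gate_strands(circuit, lib, config)["Out_r0.A_S"].annotations
        assert any(a.startswith("fluorophore=") for a in ann)


def _brute_force_sites(seq, background, config):
    """Independent window scoring used as the oracle for site selection."""
    L = config.input_binding_length
    k = config.uniqueness_k
    bg = set()
    for b in background:
        bg |= {b[i : i + k] for i in range(len(b) - k + 1)}
    scored = []
    for start in range(len(seq) - L + 1):
        w = seq[start : start + L]
        uniq = sum(w[i : i + k] in bg for i in range(L - k + 1))
        flanks = seq[max(0, start - 50) : start] + seq[start + L : start + L + 50]
        acc = longest_complementary_run(w, flanks)
        scored.append((uniq, acc, start))
    scored.sort()
    first = scored[0]
    second = next(s for s in scored if abs(s[2] - first[2]) >= L)
    return tuple(sorted([first[2], second[2]]))


class TestTargetSites:
    def test_unique_insert_attracts_both_sites(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        common = "".join(rng.choice(bases, 200))
        insert = "".join(rng.choice(bases, 40))
        transcript = common[:100] + insert + common[100:]
        config = DesignConfig()
        (s1, s2), warnings = select_target_sites(transcript, [common], config)
        assert warnings == []
        assert (s1.uniqueness, s2.uniqueness) == (0, 0)
        assert (s1.start, s2.start) == _brute_force_sites(transcript, [common], config)
        # zero-uniqueness windows must overlap the insert: only there do all
        # 12-mers avoid the background
        for s in (s1, s2):
            assert s.end > 100 - config.uniqueness_k and s.start < 140 + config.uniqueness_k

    def test_empty_background_gives_five_prime_most_pair(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(np.array(list("ACGT")), 120))
        config = DesignConfig()
        (s1, s2), _ = select_target_sites(seq, [], config)
        assert {s1.uniqueness, s2.uniqueness} == {0}
        expected = _brute_force_sites(seq, [], config)
        assert (s1.start, s2.start) == expected

    def test_short_transcript_rejected(self):
        with pytest.raises(ValueError, match="shorter than two site lengths"):
            select_target_sites("ACGT" * 8, [], DesignConfig())  # 32 nt < 36

    def test_nonzero_uniqueness_everywhere_is_flagged(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(np.array(list("ACGT")), 80))
        (s1, s2), warnings = select_target_sites(seq, [seq], DesignConfig())
        assert warnings and s1.flagged and s2.flagged

    def test_sites_do_not_overlap(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(np.array(list("ACGT")), 150))
        (s1, s2), _ = select_target_sites(seq, [], DesignConfig())
        assert s1.end <= s2.start


@pytest.fixture(scope="module")
def sgrna():
    rng = np.random.default_rng(21)
    return "".join(rng.choice(np.array(list("ACGT")), 100))


class TestSgRNAGate:
    def test_yes_circuit_single_gate_blocker_length_9(self, sgrna):
        design = design_sgrna_gate(sgrna, make_fixture("sgrna_YES"), DesignConfig(rng_seed=2))
        assert len(design.blockers) == 1
        ((start, end, blocker),) = design.blockers.values()
        assert end - start == 9 and len(blocker) == 9
        assert design.engineered_region == (0, 18)

    def test_blocker_is_revcomp_of_its_window(self, sgrna):
        design = design_sgrna_gate(
            sgrna, make_fixture("sgrna_fourinput"), DesignConfig(rng_seed=2)
        )
        for start, end, blocker in design.blockers.values():
            assert blocker == reverse_complement(sgrna[start:end])
            assert design.engineered_region[0] <= start < end <= design.engineered_region[1]

    def test_or_circuit_activation_logic(self, sgrna):
        design = design_sgrna_gate(sgrna, make_fixture("sgrna_OR"), DesignConfig(rng_seed=2))
        assert design.predicted_logic.output_vector("Cas9") == [0, 1, 1, 1]

    def test_long_strands_carry_blocker_domain(self, sgrna):
        design = design_sgrna_gate(sgrna, make_fixture("sgrna_YES"), DesignConfig(rng_seed=2))
        long_strands = [s for s in design.strands if ".A_" in s.name or ".C_" in s.name]
        assert long_strands
        for s in long_strands:
            names = [n for n, _ in s.parts]
            assert any(n.startswith("blocker.") for n in names)

    def test_sgrna_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter than the engineered region"):
            design_sgrna_gate("ACGTACGTACGT", make_fixture("sgrna_YES"), DesignConfig())

    def test_blocker_window_out_of_range_rejected(self, sgrna):
        with pytest.raises(ValueError, match="outside"):
            design_sgrna_gate(
                sgrna, make_fixture("sgrna_YES"), DesignConfig(blocker_offsets=(15,))
            )
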