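"""Sequence alphabet, pair rules, parameters, loops, stacking, energies."""

import math

import numpy as np
import pytest

from tubefold.errors import ModelError, ParameterError, SequenceError
from tubefold.model import (
    decompose_loops,
    all_stacking_state_energies,
    enumerate_stacking_states,
    load_parameters,
    loop_energy,
    min_stacking_energy,
    parameters_at_temperature,
    parse_sequence,
    save_parameters,
    sequence_to_text,
    stacking_bonus,
    structure_free_energy,
    valid_pair,
    wc_complement,
)
from tubefold.structures import Structure, parse_structure
from tubefold.toyparams import toy_parameter_set


class TestSequences:
    def test_mixed_material_prefixes(self):
        assert parse_sequence("rACGdAT") == ("rA", "rC", "rG", "dA", "dT")

    def test_default_material(self):
        assert parse_sequence("ACGUU", "r") == ("rA", "rC", "rG", "rU", "rU")
        assert parse_sequence("ACGTT", "d") == ("dA", "dC", "dG", "dT", "dT")

    def test_ut_interconversion(self):
        assert parse_sequence("ACGTT", "r") == ("rA", "rC", "rG", "rU", "rU")
        assert parse_sequence("U", "d") == ("dT",)

    def test_illegal_letter_positioned(self):
        with pytest.raises(SequenceError, match="position 5"):
            parse_sequence("ACGTX", "d")

    def test_dangling_material_prefix(self):
        with pytest.raises(SequenceError):
            parse_sequence("ACGr")

    def test_text_round_trip(self):
        for text in ("rACGdAT", "ACGUU"):
            assert sequence_to_text(parse_sequence(text)) == text


class TestPairRules:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("rA", "rU", True), ("rC", "rG", True), ("rG", "rU", True),
            ("dA", "dT", True), ("dG", "dT", False),
            ("mG", "mU", True), ("rG", "mU", True), ("mG", "rU", True),
            ("rG", "dT", True), ("dG", "rU", False),
            ("rA", "dT", True), ("dA", "rU", True), ("rG", "dC", True),
            ("rA", "rA", False), ("rA", "rG", False),
        ],
    )
    def test_pair_table(self, a, b, expected):
        assert valid_pair(a, b) is expected
        assert valid_pair(b, a) is expected

    def test_dna_merna_unsupported(self):
        with pytest.raises(ModelError):
            valid_pair("dG", "mC")

    def test_wc_complement(self):
        assert wc_complement("rA") == "rU"
        assert wc_complement("dA") == "dT"
        assert wc_complement("dG") == "dC"


class TestParameters:
    def test_round_trip(self, params, tmp_path):
        path = tmp_path / "toy.json"
        save_parameters(params, path)
        loaded = load_parameters(path)
        assert loaded.tables == params.tables
        assert loaded.scalars == params.scalars
        assert loaded.T_ref == params.T_ref

    def test_missing_table_rejected(self, params, tmp_path):
        import json

        raw = params.to_json()
        del raw["tables"]["coaxial"]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(raw))
        with pytest.raises(ParameterError, match="coaxial"):
            load_parameters(path)

    def test_temperature_identity_at_reference(self, params):
        v_ref = parameters_at_temperature(params, params.T_ref)
        key = sorted(params.tables["stack"])[0]
        dg_ref, _dh = params.tables["stack"][key]
        assert v_ref._table("stack", key) == pytest.approx(dg_ref, abs=1e-12)

    def test_two_point_extrapolation(self):
        # dG37 = -1.0, dH = -8.0 at T = 320.15 K, by hand:
        # dG(T) = dH - T (dH - dG_ref)/T_ref
        T, T_ref, dg, dh = 320.15, 310.15, -1.0, -8.0
        expected = dh - T * (dh - dg) / T_ref
        p = toy_parameter_set()
        p.tables["stack"]["probe"] = (dg, dh)
        v = parameters_at_temperature(p, T)
        assert v._table("stack", "probe") == pytest.approx(expected, rel=1e-12)
        del p.tables["stack"]["probe"]

    def test_zero_entropy_entry_constant_in_t(self):
        p = toy_parameter_set()
        p.tables["stack"]["probe"] = (-2.0, -2.0)
        for T in (280.0, 310.15, 350.0):
            v = parameters_at_temperature(p, T)
            assert v._table("stack", "probe") == pytest.approx(-2.0)
        del p.tables["stack"]["probe"]

    def test_temperature_out_of_range(self, params):
        with pytest.raises(ValueError):
            parameters_at_temperature(params, 100.0)

    def test_missing_context_is_error_not_zero(self, view):
        with pytest.raises(ModelError, match="no parameter"):
            view._table("stack", "bogus")


class TestLoopDecomposition:
    def test_stem_loop(self):
        loops = decompose_loops(parse_structure("(((...)))"))
        kinds = sorted(l.kind for l in loops)
        assert kinds == ["exterior", "hairpin", "interior", "interior"]

    def test_duplex_faces(self):
        # 2-pair duplex: p+1 = 3 faces; both nick-containing faces exterior
        loops = decompose_loops(parse_structure("((+))"))
        kinds = sorted(l.kind for l in loops)
        assert kinds == ["exterior", "exterior", "interior"]
        ext = [l for l in loops if l.kind == "exterior"]
        assert sorted(l.n_nicks for l in ext) == [1, 1]

    def test_three_strand_complex(self):
        # Y-junction: A pairs B and C around a multiloop-like exterior face
        s = parse_structure("((..((+))..((+))))")
        loops = decompose_loops(s)
        assert len(loops) == len(s.pairs) + 1
        # every nucleotide belongs to at least one face; pairs close 2 faces
        counted = set()
        for l in loops:
            counted.update(l.unpaired)
            for i, j in l.closing_pairs:
                counted.update((i, j))
        assert counted == set(range(s.length))

    def test_pseudoknot_rejected(self):
        with pytest.raises(ModelError):
            decompose_loops(Structure({(0, 4), (2, 6)}, (8,)))

    def test_multiloop_detected(self):
        # outer pair + two hairpins: the outer pair's inner face closes three
        # pairs with no nick, i.e. a multiloop
        loops = decompose_loops(parse_structure("((...)(...))"))
        assert "multiloop" in [l.kind for l in loops]


class TestStackingStates:
    def test_single_pair_no_neighbors(self):
        loops = decompose_loops(parse_structure("((+))"))
        ext = [l for l in loops if l.kind == "exterior"]
        for l in ext:
            assert len(enumerate_stacking_states(l)) == 1

    def test_pair_with_base_each_side_four_states(self):
        # exterior top face: . (pair) . -> none, 5' dangle, 3' dangle, both
        loops = decompose_loops(parse_structure(".((...))."))
        top = [l for l in loops if l.kind == "exterior"][0]
        states = enumerate_stacking_states(top)
        assert len(states) == 4
        sizes = sorted(sum(len(b) for _, b in st.dangles) for st in states)
        assert sizes == [0, 1, 1, 2]

    def test_adjacent_pairs_include_coax(self):
        # two hairpins abutting on the exterior face
        loops = decompose_loops(parse_structure("(...)(...)"))
        top = [l for l in loops if l.kind == "exterior"][0]
        states = enumerate_stacking_states(top)
        coax_states = [st for st in states if st.coax]
        assert len(coax_states) == 1

    def test_exhaustive_assignment_oracle(self):
        # multiloop with 3 pairs and 2 unpaired: compare against a direct
        # product-with-filter enumeration over per-element choices
        s = parse_structure("((...).(...).)")
        loops = decompose_loops(s)
        ml = [l for l in loops if l.kind == "multiloop"][0]
        states = enumerate_stacking_states(ml)
        # oracle: pairs p0,p1,p2 arranged with unpaired between p1-p2, p2-p0;
        # adjacency: p0-p1 coax; each unpaired base may dangle on a flanking
        # pair; a coax-stacked pair takes no dangles
        import itertools as it

        elems = ml.elements
        pair_idx = [k for k, e in enumerate(elems) if e[0] == "p"]
        base_idx = [k for k, e in enumerate(elems) if e[0] == "u"]
        m = len(elems)
        adj = [(k, (k + 1) % m) for k in range(m)]
        coax_edges = {
            tuple(sorted(e))
            for e in adj
            if elems[e[0]][0] == "p" and elems[e[1]][0] == "p"
        }
        count = 0
        seen = set()
        for coax_choice in it.chain([()], [(e,) for e in coax_edges]):
            stacked = {k for e in coax_choice for k in e}
            opts = []
            for b in base_idx:
                o = [None]
                for k, k2 in adj:
                    if k == b and elems[k2][0] == "p" and k2 not in stacked:
                        o.append((k2, "5"))
                    if k2 == b and elems[k][0] == "p" and k not in stacked:
                        o.append((k, "3"))
                opts.append(o)
            for combo in it.product(*opts):
                key = (tuple(sorted(coax_choice)), tuple(sorted(c for c in combo if c)))
                if key not in seen:
                    seen.add(key)
                    count += 1
        assert len(states) == count

    def test_bonus_nonpositive_and_monotone(self, view):
        s = parse_structure(".((...)).((...))..")
        for l in decompose_loops(s):
            if l.kind not in ("multiloop", "exterior"):
                continue
            phi = parse_sequence("A" * s.length)
            phi = _pairable_sequence(s)
            b_all = stacking_bonus(l, phi, view, "all")
            b_dangle = stacking_bonus(l, phi, view, "dangle")
            b_none = stacking_bonus(l, phi, view, "none")
            assert b_all <= b_dangle + 1e-12 <= 1e-12
            assert b_none == 0.0

    def test_single_dangle_closed_form(self, view):
        # one pair with exactly one adjacent unpaired base:
        # bonus = -kT log(1 + exp(-dG_dangle/kT))
        s = parse_structure("((...)).")
        phi = _pairable_sequence(s)
        top = [l for l in decompose_loops(s) if l.kind == "exterior"][0]
        states = enumerate_stacking_states(top)
        assert len(states) == 2
        (i, j) = top.closing_pairs[0]
        dg = view.dangle((phi[i], phi[j]), phi[s.length - 1], "3")
        kT = view.kT
        expected = -kT * math.log(1 + math.exp(-dg / kT))
        assert stacking_bonus(top, phi, view) == pytest.approx(expected, abs=1e-12)


def _pairable_sequence(s):
    """Concrete RNA sequence in which every pair of s is G-C."""
    nts = ["rA"] * s.length
    for a, b in s.pairs:
        nts[a], nts[b] = "rG", "rC"
    return tuple(nts)


class TestEnergies:
    def test_unpaired_strand_zero(self, view):
        s = parse_structure("......")
        phi = parse_sequence("AAAAAA")
        assert structure_free_energy(phi, s, view) == (0.0, 0.0)

    def test_multiloop_hand_sum_no_stacking(self, view):
        s = parse_structure("((...).(...).)")
        phi = _pairable_sequence(s)
        loops = decompose_loops(s)
        ml = [l for l in loops if l.kind == "multiloop"][0]
        expected = (
            view.scalar("multiloop_init")
            + 3 * view.scalar("multiloop_bp")
            + 2 * view.scalar("multiloop_nt")
            + sum(view.terminalbp(phi[i], phi[j]) for i, j in ml.closing_pairs)
        )
        assert loop_energy(ml, phi, view, "none") == pytest.approx(expected)

    def test_stack_loop_is_table_lookup(self, view):
        s = parse_structure("((...))")
        phi = _pairable_sequence(s)
        stacks = [l for l in decompose_loops(s) if l.kind == "interior"]
        st = stacks[0]
        (i, j), (d, e) = st.closing_pairs
        assert loop_energy(st, phi, view) == pytest.approx(
            view.stack((phi[i], phi[j]), (phi[d], phi[e]))
        )

    def test_association_penalty_per_extra_strand(self, view):
        s = parse_structure("((((+))))")
        phi = parse_sequence("GGGG") + parse_sequence("CCCC")
        dg_bar, _ = structure_free_energy(phi, s, view, "none")
        loops = decompose_loops(s)
        loop_sum = sum(loop_energy(l, phi, view, "none") for l in loops)
        assert dg_bar == pytest.approx(loop_sum + view.scalar("assoc"))

    def test_symmetry_correction_kt_log2(self, view):
        s = parse_structure("((((+))))")
        phi = parse_sequence("GGCC") + parse_sequence("GGCC")
        dg_bar, dg = structure_free_energy(phi, s, view, species=["A", "A"])
        assert dg - dg_bar == pytest.approx(view.kT * math.log(2))
        dg_bar2, dg2 = structure_free_energy(phi, s, view, species=["A", "B"])
        assert dg2 == dg_bar2

    def test_invalid_pair_rejected(self, view):
        s = parse_structure("(...)")
        phi = parse_sequence("GAAAG")
        with pytest.raises(ModelError):
            structure_free_energy(phi, s, view)

    def test_energy_invariant_under_species_relabeling(self, view):
        s = parse_structure("((((+))))")
        phi = parse_sequence("GGCC") + parse_sequence("GGCC")
        _, dg_aa = structure_free_energy(phi, s, view, species=["A", "A"])
        _, dg_xx = structure_free_energy(phi, s, view, species=["X", "X"])
        assert dg_aa == dg_xx


class TestStackingConsistency:
    def test_logsumexp_over_states_reproduces_structure_energy(self, view, corpus):
        """The Boltzmann sum over enumerated stacking-state energies equals
        the loop model with per-loop stacking bonuses, to 1e-9."""
        kT = view.kT
        checked = 0
        for _name, spec, s in corpus:
            if spec.length > 12:
                continue
            phi = spec.phi
            energies = all_stacking_state_energies(phi, s, view, "all")
            m = min(energies)
            lse = m - kT * math.log(
                sum(math.exp(-(e - m) / kT) for e in energies)
            )
            dg_bar, _ = structure_free_energy(phi, s, view, "all")
            assert lse == pytest.approx(dg_bar, abs=1e-9)
            checked += 1
        assert checked >= 5

    def test_min_state_bounds_logsumexp(self, view, corpus):
        for _name, spec, s in corpus[:8]:
            dg_bar, _ = structure_free_energy(spec.phi, s, view)
            assert min_stacking_energy(spec.phi, s, view) >= dg_bar - 1e-12
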