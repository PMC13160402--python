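"""Complex-ensemble enumeration and physical quantities."""

import math

import numpy as np
import pytest

from tubefold.ensemble import (
    ComplexSpec,
    analyze_complex,
    complex_ensemble_defect,
    complex_free_energy,
    ensemble_sizes,
    enumerate_ensemble,
    mfe_proxy,
    pair_probability_matrix,
    partition_function,
    sample_structures,
    structure_probability,
    suboptimal_structures,
)
from tubefold.errors import EnsembleCapError
from tubefold.model import min_stacking_energy, parse_sequence, structure_free_energy
from tubefold.structures import Structure, is_connected, parse_structure, structure_matrix


def spec_of(*texts, names=None):
    seqs = tuple(parse_sequence(t) for t in texts)
    names = tuple(names or [chr(ord("A") + k) for k in range(len(seqs))])
    return ComplexSpec(names, seqs)


class TestEnumeration:
    def test_unpairable_strand_single_structure(self):
        gamma = enumerate_ensemble(spec_of("AAAA"))
        assert len(gamma) == 1
        assert gamma[0].pairs == frozenset()

    def test_one_admissible_hairpin_two_structures(self):
        # G...C: the only admissible pair is (0,4)
        gamma = enumerate_ensemble(spec_of("GAAAC"))
        assert len(gamma) == 2
        assert {frozenset(), frozenset({(0, 4)})} == {s.pairs for s in gamma}

    def test_min_hairpin_enforced(self):
        # G..C: loop of 2 < 3 is inadmissible on one strand
        gamma = enumerate_ensemble(spec_of("GAAC"))
        assert len(gamma) == 1

    def test_disconnected_structures_excluded(self):
        for s in enumerate_ensemble(spec_of("GGG", "CCC")):
            assert is_connected(s)
            assert any(
                s.strand_of(a) != s.strand_of(b) for a, b in s.pairs
            )

    def test_cap_exceeded(self):
        spec = ComplexSpec(("A",), (parse_sequence("A" * 31),))
        with pytest.raises(EnsembleCapError):
            enumerate_ensemble(spec)

    def test_indistinguishable_dedup(self):
        # A·A homodimer: rotation classes collapse
        spec = ComplexSpec(
            ("A", "A"), (parse_sequence("GGCC"), parse_sequence("GGCC"))
        )
        bar = enumerate_ensemble(spec, distinct_only=False)
        dedup = enumerate_ensemble(spec, distinct_only=True)
        assert len(dedup) < len(bar)

    def test_distinct_species_no_dedup(self):
        spec = spec_of("GGG", "CCC")
        assert enumerate_ensemble(spec, False) == enumerate_ensemble(spec, True)


class TestPartitionFunction:
    def test_unpairable_q_is_one(self, view):
        assert partition_function(spec_of("AAAA"), view) == 1.0

    def test_two_term_hand_sum(self, view, params):
        # Q = 1 + exp(-dG_h/kT) with dG_h assembled by hand from raw tables
        spec = spec_of("GAAAC")
        dg_hairpin = params.tables["hairpin_size"]["3"][0]
        dg_term = params.tables["terminalbp"]["rGrC"][0]
        # the lone pair closes a hairpin face and an exterior face, each
        # charging the terminal-pair penalty; no stacks are available
        dg = dg_hairpin + 2 * dg_term
        expected = 1 + math.exp(-dg / view.kT)
        assert partition_function(spec, view) == pytest.approx(expected, rel=1e-12)

    def test_q_over_states_equals_q_over_structures(self, view, corpus):
        """Summing Boltzmann factors of individual stacking states equals
        summing structure free energies (Eq 4 folded into Eq 7)."""
        from tubefold.model import all_stacking_state_energies

        kT = view.kT
        for _name, spec, _s in corpus[:6]:
            if len(spec.names) > 1:
                continue  # single strands: Gamma == Gamma_bar, R == 1
            q_structures = partition_function(spec, view)
            q_states = sum(
                math.exp(-e / kT)
                for s in enumerate_ensemble(spec)
                for e in all_stacking_state_energies(spec.phi, s, view)
            )
            assert q_states == pytest.approx(q_structures, rel=1e-9)

    def test_complex_free_energy(self, view):
        assert complex_free_energy(1.0, view.kT) == 0.0
        assert complex_free_energy(math.e, view.kT) == pytest.approx(-view.kT)
        with pytest.raises(ValueError):
            complex_free_energy(0.0, view.kT)


class TestStructureProbability:
    def test_single_structure_probability_one(self, view):
        spec = spec_of("AAAA")
        s = enumerate_ensemble(spec)[0]
        assert structure_probability(spec, s, view) == 1.0

    def test_probabilities_sum_to_one(self, view, corpus):
        for _name, spec, _s in corpus[:6]:
            total = sum(
                structure_probability(spec, s, view)
                for s in enumerate_ensemble(spec, distinct_only=True)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_not_in_ensemble_rejected(self, view):
        spec = spec_of("AAAA")
        with pytest.raises(ValueError):
            structure_probability(spec, parse_structure("(..)"), view)


class TestPairProbabilities:
    def test_unpairable_identity(self, view):
        P = pair_probability_matrix(spec_of("AAAA"), view)
        assert np.allclose(P, np.eye(4))

    def test_hairpin_ratio(self, view):
        # two-structure ensemble: P[0,4] = w/(1+w)
        spec = spec_of("GAAAC")
        s_h = [s for s in enumerate_ensemble(spec) if s.pairs][0]
        dg, _ = structure_free_energy(spec.phi, s_h, view)
        w = math.exp(-dg / view.kT)
        P = pair_probability_matrix(spec, view)
        assert P[0, 4] == pytest.approx(w / (1 + w), rel=1e-12)
        assert P[0, 0] == pytest.approx(1 / (1 + w), rel=1e-12)

    def test_row_col_sums_one_on_corpus(self, view, corpus):
        for _name, spec, _s in corpus:
            P = pair_probability_matrix(spec, view)
            assert np.abs(P.sum(axis=0) - 1).max() < 1e-9
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-9
            assert np.allclose(P, P.T)


class TestMfeAndSuboptimal:
    def test_single_structure_ensemble(self, view):
        spec = spec_of("AAAA")
        s, dg = mfe_proxy(spec, view)
        assert s.pairs == frozenset()
        assert dg == 0.0

    def test_mfe_equals_exhaustive_argmin(self, view, corpus):
        from tubefold.model import all_stacking_state_energies

        for _name, spec, _s in corpus[:8]:
            s_mfe, _ = mfe_proxy(spec, view)
            best = min(
                min(all_stacking_state_energies(spec.phi, s, view))
                for s in enumerate_ensemble(spec)
            )
            assert min_stacking_energy(spec.phi, s_mfe, view) == pytest.approx(
                best, abs=1e-12
            )

    def test_mfe_bounded_below_by_complex_free_energy(self, view, corpus):
        for _name, spec, _s in corpus:
            _, dg_mfe = mfe_proxy(spec, view)
            dg_complex = complex_free_energy(
                partition_function(spec, view), view.kT
            )
            assert dg_mfe >= dg_complex - 1e-12

    def test_suboptimal_gap_zero_and_monotone(self, view):
        spec = spec_of("GGGAAAACCC")
        subs0 = suboptimal_structures(spec, view, dG_gap=0.0)
        s_mfe, _ = mfe_proxy(spec, view)
        assert s_mfe in subs0
        sub1 = suboptimal_structures(spec, view, dG_gap=1.0)
        sub2 = suboptimal_structures(spec, view, dG_gap=2.0)
        assert set(map(lambda s: s.pairs, sub1)) <= set(map(lambda s: s.pairs, sub2))
        everything = suboptimal_structures(spec, view, dG_gap=1e9)
        assert len(everything) == len(enumerate_ensemble(spec))
        with pytest.raises(ValueError):
            suboptimal_structures(spec, view, dG_gap=-1.0)

    def test_oracle_filter(self, view):
        spec = spec_of("GGGAAAACCC")
        gap = 1.5
        subs = suboptimal_structures(spec, view, dG_gap=gap)
        mfe_e = min(
            min_stacking_energy(spec.phi, s, view)
            for s in enumerate_ensemble(spec)
        )
        expected = {
            s.pairs
            for s in enumerate_ensemble(spec)
            if min_stacking_energy(spec.phi, s, view) <= mfe_e + gap + 1e-12
        }
        assert {s.pairs for s in subs} == expected


class TestSampling:
    def test_single_structure_all_identical(self, view):
        spec = spec_of("AAAA")
        samples = sample_structures(spec, view, J=5, seed=1)
        assert all(s.pairs == frozenset() for s in samples)

    def test_seed_reproducibility(self, view):
        spec = spec_of("GGGAAAACCC")
        a = sample_structures(spec, view, J=50, seed=42)
        b = sample_structures(spec, view, J=50, seed=42)
        assert a == b

    def test_frequencies_match_probabilities(self, view):
        spec = spec_of("GAAAC")
        J = 10_000
        samples = sample_structures(spec, view, J=J, seed=7)
        n_paired = sum(1 for s in samples if s.pairs)
        gamma = enumerate_ensemble(spec, distinct_only=True)
        s_h = [s for s in gamma if s.pairs][0]
        p = structure_probability(spec, s_h, view)
        sigma = math.sqrt(J * p * (1 - p))
        assert abs(n_paired - J * p) < 3 * sigma


class TestSizesAndDefect:
    def test_unpairable_sizes(self, view):
        assert ensemble_sizes(spec_of("AAAA"), view) == (1, 1)

    def test_hairpin_sizes_no_stack_options(self, view):
        # lone hairpin pair spanning the whole strand: no dangles available
        assert ensemble_sizes(spec_of("GAAAC"), view) == (2, 2)

    def test_states_at_least_structures(self, view, corpus):
        for _name, spec, _s in corpus[:10]:
            n_s, n_ss = ensemble_sizes(spec, view)
            assert n_ss >= n_s

    def test_defect_zero_for_dominant_target(self, view):
        spec = spec_of("AAAA")
        n, N = complex_ensemble_defect(spec, parse_structure("...."), view)
        assert n == pytest.approx(0.0, abs=1e-12)
        assert N == 0.0

    def test_defect_hand_inner_product(self, view):
        # two-structure toy: n = |phi| - sum P.S(target)
        spec = spec_of("GAAAC")
        target = [s for s in enumerate_ensemble(spec) if s.pairs][0]
        P = pair_probability_matrix(spec, view)
        S = structure_matrix(target)
        expected = 5 - float((P * S).sum())
        n, N = complex_ensemble_defect(spec, target, view)
        assert n == pytest.approx(expected, abs=1e-12)
        # with p = probability of the open structure, the paired bases 0 and
        # 4 and no others are wrong in the open chain: n = 2p
        p_open = structure_probability(
            spec, [s for s in enumerate_ensemble(spec) if not s.pairs][0], view
        )
        assert n == pytest.approx(2 * p_open, abs=1e-12)

    def test_defect_bounds(self, view, corpus):
        for _name, spec, s in corpus[:10]:
            n, N = complex_ensemble_defect(spec, s, view)
            assert -1e-12 <= n <= spec.length + 1e-12
            assert -1e-12 <= N <= 1 + 1e-12

    def test_analyze_complex_bundle(self, view):
        res = analyze_complex(spec_of("GGGAAAACCC"), view)
        assert res.Q > 1
        assert res.n_structures >= 2
        assert res.mfe_energy >= res.dG_complex
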