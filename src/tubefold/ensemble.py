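"""Exact complex-ensemble analysis by exhaustive enumeration.

The complex ensemble of a strand ordering contains every connected,
unpseudoknotted, pair-admissible secondary structure of the concatenation.
Two views are maintained: the ensemble treating all strands as distinct
(used for pair probabilities, the MFE proxy search, and suboptimal
structures) and the ensemble treating strands of the same species as
indistinguishable (one representative per rotational equivalence class,
with symmetry-corrected free energies; used for the partition function,
structure probabilities, and Boltzmann sampling).

Enumeration is the normative engine at desk scale; the total complex length
is capped (default 30 nt) and exceeding the cap is an error, never a silent
truncation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import EnsembleCapError, ModelError
from .model import (
    ParamView,
    count_stacking_states,
    min_stacking_energy,
    structure_free_energy,
    valid_pair,
)
from .structures import (
    MIN_HAIRPIN,
    Structure,
    rotate_structure,
    is_connected,
    structure_matrix,
)

DEFAULT_CAP = 30


@dataclass(frozen=True)
class ComplexSpec:
    """A strand ordering around the polymer circle.

    ``names`` are the species labels (equal labels mean indistinguishable
    strands); ``seqs`` are the per-strand annotated-nucleotide tuples.
    """

    names: tuple
    seqs: tuple
    cap: int = DEFAULT_CAP

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "seqs", tuple(tuple(q) for q in self.seqs))
        if len(self.names) != len(self.seqs) or not self.names:
            raise ValueError("need one species name per strand sequence")

    @property
    def phi(self) -> tuple:
        return tuple(nt for q in self.seqs for nt in q)

    @property
    def strand_lengths(self) -> tuple:
        return tuple(len(q) for q in self.seqs)

    @property
    def length(self) -> int:
        return sum(self.strand_lengths)

    def label(self) -> str:
        return "·".join(self.names)


def _strand_index(lengths) -> list:
    out = []
    for k, n in enumerate(lengths):
        out.extend([k] * n)
    return out


@lru_cache(maxsize=2048)
def enumerate_ensemble(spec: ComplexSpec, distinct_only: bool = False) -> tuple:
    """All structures of the complex ensemble for this strand ordering.

    With ``distinct_only=False`` this is the ensemble treating all strands as
    distinct; with ``distinct_only=True`` one representative is kept per
    class of structures related by a species-preserving rotation of the
    polymer graph (strands of the same species indistinguishable).
    """
    if spec.length > spec.cap:
        raise EnsembleCapError(
            f"complex of {spec.length} nt exceeds the enumeration cap "
            f"({spec.cap} nt)"
        )
    phi = spec.phi
    lengths = spec.strand_lengths
    strand_of = _strand_index(lengths)

    def admissible(a: int, b: int) -> bool:
        if strand_of[a] == strand_of[b] and b - a - 1 < MIN_HAIRPIN:
            return False
        try:
            return valid_pair(phi[a], phi[b])
        except ModelError:
            return False

    n = spec.length
    memo = {}

    def gen(lo: int, hi: int) -> list:
        if lo >= hi:
            return [()]
        key = (lo, hi)
        if key in memo:
            return memo[key]
        out = list(gen(lo + 1, hi))  # lo unpaired
        for b in range(lo + 1, hi):
            if admissible(lo, b):
                for left in gen(lo + 1, b):
                    for right in gen(b + 1, hi):
                        out.append(((lo, b),) + left + right)
        memo[key] = out
        return out

    structures = []
    for pairs in gen(0, n):
        s = Structure(frozenset(pairs), lengths)
        if is_connected(s):
            structures.append(s)
    structures.sort(key=lambda s: tuple(sorted(s.pairs)))

    if not distinct_only:
        return tuple(structures)

    # canonical representative per species-preserving rotation class
    L = len(lengths)
    valid_rots = [
        t
        for t in range(L)
        if all(spec.names[k] == spec.names[(k + t) % L] for k in range(L))
        and all(lengths[k] == lengths[(k + t) % L] for k in range(L))
    ]
    seen, reps = set(), []
    for s in structures:
        key = min(
            tuple(sorted(rotate_structure(s, t).pairs)) for t in valid_rots
        )
        if key not in seen:
            seen.add(key)
            reps.append(s)
    return tuple(reps)


# ---------------------------------------------------------------------------
# physical quantities


def partition_function(spec: ComplexSpec, view: ParamView, opt: str = "all") -> float:
    """Q = sum over the indistinguishable-strand ensemble of
    exp(-dG(phi,s)/kT) with symmetry-corrected structure free energies."""
    kT = view.kT
    total = 0.0
    for s in enumerate_ensemble(spec, distinct_only=True):
        _, dg = structure_free_energy(spec.phi, s, view, opt, species=spec.names)
        total += math.exp(-dg / kT)
    return total


def complex_free_energy(Q: float, kT: float) -> float:
    """dG = -kT log Q."""
    if Q <= 0:
        raise ValueError("partition function must be positive")
    return -kT * math.log(Q)


def structure_probability(
    spec: ComplexSpec, s: Structure, view: ParamView, opt: str = "all"
) -> float:
    """Equilibrium probability of s in the indistinguishable-strand ensemble."""
    gamma = enumerate_ensemble(spec, distinct_only=True)
    if s not in gamma:
        # accept any member of the rotation class
        matches = [g for g in gamma if _same_class(spec, s, g)]
        if not matches:
            raise ValueError("structure not in the complex ensemble")
        s = matches[0]
    _, dg = structure_free_energy(spec.phi, s, view, opt, species=spec.names)
    return math.exp(-dg / view.kT) / partition_function(spec, view, opt)


def _same_class(spec: ComplexSpec, a: Structure, b: Structure) -> bool:
    L = len(spec.names)
    for t in range(L):
        if all(spec.names[k] == spec.names[(k + t) % L] for k in range(L)):
            try:
                if rotate_structure(a, t).pairs == b.pairs:
                    return True
            except ValueError:
                continue
    return False


def pair_probability_matrix(
    spec: ComplexSpec, view: ParamView, opt: str = "all"
) -> np.ndarray:
    """Equilibrium base-pairing probability matrix over the ensemble treating
    all strands as distinct; diagonal entries are unpaired probabilities.
    Symmetric with unit row and column sums."""
    kT = view.kT
    structs = enumerate_ensemble(spec, distinct_only=False)
    energies = np.array(
        [structure_free_energy(spec.phi, s, view, opt)[0] for s in structs]
    )
    w = np.exp(-(energies - energies.min()) / kT)
    w /= w.sum()
    n = spec.length
    P = np.zeros((n, n))
    for s, p in zip(structs, w):
        P += p * structure_matrix(s)
    return P


def mfe_proxy(
    spec: ComplexSpec, view: ParamView, opt: str = "all"
) -> tuple:
    """(structure, dG) for the MFE proxy: the secondary structure whose
    subensemble contains the minimum-free-energy stacking state over the
    distinct-strand stacking ensemble.  Ties break toward the
    lexicographically smallest structure matrix.  The reported free energy is
    the symmetry-corrected structure free energy."""
    best = None
    for s in enumerate_ensemble(spec, distinct_only=False):
        e = min_stacking_energy(spec.phi, s, view, opt)
        key = (e, structure_matrix(s).ravel().tobytes())
        if best is None or key < best[0]:
            best = (key, s)
    s = best[1]
    _, dg = structure_free_energy(spec.phi, s, view, opt, species=spec.names)
    return s, dg


def suboptimal_structures(
    spec: ComplexSpec, view: ParamView, opt: str = "all", dG_gap: float = 0.0
) -> list:
    """Structures containing a stacking state within ``dG_gap`` of the MFE
    stacking state (distinct-strand ensemble), sorted by that energy."""
    if dG_gap < 0:
        raise ValueError("dG_gap must be nonnegative")
    scored = [
        (min_stacking_energy(spec.phi, s, view, opt), s)
        for s in enumerate_ensemble(spec, distinct_only=False)
    ]
    mfe = min(e for e, _ in scored)
    keep = [(e, s) for e, s in scored if e <= mfe + dG_gap + 1e-12]
    keep.sort(key=lambda es: (es[0], tuple(sorted(es[1].pairs))))
    return [s for _, s in keep]


def sample_structures(
    spec: ComplexSpec,
    view: ParamView,
    opt: str = "all",
    J: int = 1,
    seed: int = 0,
) -> list:
    """J i.i.d. Boltzmann samples from the indistinguishable-strand ensemble,
    by cumulative-probability inversion; reproducible for a given seed."""
    if J < 1:
        raise ValueError("J must be >= 1")
    gamma = enumerate_ensemble(spec, distinct_only=True)
    kT = view.kT
    energies = np.array(
        [
            structure_free_energy(spec.phi, s, view, opt, species=spec.names)[1]
            for s in gamma
        ]
    )
    w = np.exp(-(energies - energies.min()) / kT)
    w /= w.sum()
    cdf = np.cumsum(w)
    rng = np.random.default_rng(seed)
    idx = np.searchsorted(cdf, rng.random(J), side="right")
    idx = np.minimum(idx, len(gamma) - 1)
    return [gamma[i] for i in idx]


def ensemble_sizes(spec: ComplexSpec, view: ParamView, opt: str = "all") -> tuple:
    """(number of secondary structures, number of stacking states) in the
    distinct-strand ensemble."""
    structs = enumerate_ensemble(spec, distinct_only=False)
    n_states = sum(
        count_stacking_states(spec.phi, s, view, opt) for s in structs
    )
    return len(structs), n_states


def complex_ensemble_defect(
    spec: ComplexSpec,
    s_target: Structure,
    view: ParamView,
    opt: str = "all",
) -> tuple:
    """(n, N): expected number and fraction of nucleotides in an incorrect
    base-pairing state relative to the target structure, over the
    distinct-strand ensemble (diagonal unpaired agreement included)."""
    if s_target.length != spec.length:
        raise ValueError("target structure length does not match complex")
    P = pair_probability_matrix(spec, view, opt)
    S = structure_matrix(s_target)
    n = spec.length - float((P * S).sum())
    return n, n / spec.length


@dataclass
class ComplexEnsembleResult:
    """Bundle of the complex-level observables for one strand ordering."""

    spec: ComplexSpec
    Q: float
    dG_complex: float
    pair_probabilities: np.ndarray
    mfe_structure: Structure
    mfe_energy: float
    n_structures: int
    n_stacking_states: int


def analyze_complex(
    spec: ComplexSpec, view: ParamView, opt: str = "all"
) -> ComplexEnsembleResult:
    Q = partition_function(spec, view, opt)
    s_mfe, dg_mfe = mfe_proxy(spec, view, opt)
    n_s, n_ss = ensemble_sizes(spec, view, opt)
    return ComplexEnsembleResult(
        spec=spec,
        Q=Q,
        dG_complex=complex_free_energy(Q, view.kT),
        pair_probabilities=pair_probability_matrix(spec, view, opt),
        mfe_structure=s_mfe,
        mfe_energy=dg_mfe,
        n_structures=n_s,
        n_stacking_states=n_ss,
    )
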