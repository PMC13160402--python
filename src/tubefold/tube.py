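"""Dilute test-tube equilibrium: concentrations and tube-level observables.

Strand species introduced at given total concentrations partition among a set
of complex species at equilibrium.  The equilibrium mole fractions are the
unique solution of the strictly convex program

    min  sum_j x_j (log x_j - log Q_j - 1)
    s.t. sum_j A_ij x_j = x_i^0  for every strand species i

where A_ij counts strands of species i in complex j.  The program is solved
in its dual form (one chemical potential per strand species) with a damped
Newton iteration.  Inputs and outputs are molar; internally mole fractions
are used, converted through the molarity of water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError
from .ensemble import ComplexSpec, DEFAULT_CAP
from .structures import enumerate_strand_orderings, canonical_rotation

#: molarity of water at 310.15 K (mol/L)
RHO_H2O_37C = 55.14

_MW_WATER = 18.01528


def water_molarity(T: float) -> float:
    """Molarity of water (mol/L) at temperature T in kelvin, from the Kell
    atmospheric-pressure density rational polynomial (0-100 C)."""
    t = T - 273.15
    num = (
        999.83952
        + 16.945176 * t
        - 7.9870401e-3 * t**2
        - 46.170461e-6 * t**3
        + 105.56302e-9 * t**4
        - 280.54253e-12 * t**5
    )
    density = num / (1 + 16.879850e-3 * t) / 1000.0  # g/mL
    return 1000.0 * density / _MW_WATER


@dataclass
class TubeSpec:
    """One test tube: strand species with molar totals and its complex set.

    ``complexes`` hold the necklace-distinct strand orderings in the tube's
    ensemble; generate them with :func:`generate_complexes` or list them
    explicitly.
    """

    strands: dict  # species name -> annotated-nucleotide tuple
    totals: dict  # species name -> molar concentration
    complexes: list  # list of ComplexSpec
    name: str = "tube"

    def __post_init__(self):
        for sp, c in self.totals.items():
            if c <= 0:
                raise ValueError(f"strand total for {sp!r} must be positive")
            if sp not in self.strands:
                raise ValueError(f"total given for unknown strand {sp!r}")
        for c in self.complexes:
            for nm in c.names:
                if nm not in self.strands:
                    raise ValueError(f"complex uses unknown strand {nm!r}")


def generate_complexes(
    strands: dict,
    L_max: int = 1,
    include: list | None = None,
    exclude: list | None = None,
    cap: int = DEFAULT_CAP,
) -> list:
    """All necklace-distinct complexes of up to ``L_max`` strands, plus
    explicit inclusions, minus exclusions.  Orderings are given as tuples of
    species names; exclusion matches up to cyclic rotation."""
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    species = sorted(strands)
    orderings = []
    seen = set()
    import itertools

    for L in range(1, L_max + 1):
        for multiset in itertools.combinations_with_replacement(species, L):
            for ordering in enumerate_strand_orderings(list(multiset)):
                if ordering not in seen:
                    seen.add(ordering)
                    orderings.append(ordering)
    for inc in include or []:
        inc = canonical_rotation(tuple(inc))
        for nm in inc:
            if nm not in strands:
                raise ValueError(f"include names unknown species {nm!r}")
        if inc not in seen:
            seen.add(inc)
            orderings.append(inc)
    excluded = {canonical_rotation(tuple(e)) for e in exclude or []}
    orderings = [o for o in orderings if canonical_rotation(o) not in excluded]
    orderings.sort(key=lambda o: (len(o), o))
    return [
        ComplexSpec(o, tuple(strands[nm] for nm in o), cap=cap) for o in orderings
    ]


def stoichiometry_matrix(tube: TubeSpec) -> tuple:
    """(species list, A) with A[i, j] = copies of strand species i in
    complex j (counting occurrences in the ordering)."""
    species = sorted(tube.totals)
    A = np.zeros((len(species), len(tube.complexes)))
    for j, c in enumerate(tube.complexes):
        for nm in c.names:
            A[species.index(nm), j] += 1
    return species, A


@dataclass
class ConcentrationSolution:
    """Equilibrium concentrations of every complex in a tube."""

    species: list
    complexes: list  # ComplexSpec, aligned with x / molar
    x: np.ndarray  # mole fractions
    molar: np.ndarray
    duals: np.ndarray  # chemical potentials (log-mole-fraction units)
    A: np.ndarray
    residual: float
    iterations: int
    rho: float

    def concentration(self, ordering) -> float:
        key = canonical_rotation(tuple(ordering))
        for c, m in zip(self.complexes, self.molar):
            if canonical_rotation(c.names) == key:
                return float(m)
        raise KeyError(ordering)


def solve_concentrations(
    tube: TubeSpec,
    Q: dict,
    T: float = 310.15,
    tol: float = 1e-12,
    max_iter: int = 200,
    rho: float | None = None,
) -> ConcentrationSolution:
    """Solve the convex equilibrium program in dual form.

    ``Q`` maps each complex's canonical ordering (tuple of species names) to
    its partition function.  Damped Newton on the strand chemical potentials,
    initialized from the ideal monomer distribution, with backtracking line
    search; converges when the mass-conservation residual (relative to the
    largest strand total) drops below ``tol``.
    """
    species, A_full = stoichiometry_matrix(tube)
    if rho is None:
        rho = water_molarity(T)
    x0 = np.array([tube.totals[sp] / rho for sp in species])
    # a complex whose ensemble is empty (no connected structure can form)
    # has Q = 0 and exists at zero concentration; drop it from the program
    active = []
    for j, c in enumerate(tube.complexes):
        q = Q[canonical_rotation(c.names)]
        if q < 0:
            raise ValueError(f"partition function for {c.label()} must be nonnegative")
        if len(c.names) == 1 and q <= 0:
            raise ValueError(f"monomer {c.label()} must have positive Q")
        if q > 0:
            active.append(j)
    A = A_full[:, active]
    logQ = np.array(
        [
            math.log(Q[canonical_rotation(tube.complexes[j].names)])
            for j in active
        ]
    )
    active_complexes = [tube.complexes[j] for j in active]

    # lam[i]: dual variable of strand i; x_j = exp(logQ_j + sum_i A_ij lam_i)
    monomer_col = {
        sp: next(
            j for j, c in enumerate(active_complexes) if c.names == (sp,)
        )
        for sp in species
        if any(c.names == (sp,) for c in active_complexes)
    }
    lam = np.zeros(len(species))
    for i, sp in enumerate(species):
        j = monomer_col.get(sp)
        lam[i] = math.log(x0[i]) - (logQ[j] if j is not None else 0.0)

    scale = x0.max()

    def compute(lam):
        logx = logQ + A.T @ lam
        logx = np.clip(logx, -700, 700)
        x = np.exp(logx)
        F = A @ x - x0
        return x, F

    x, F = compute(lam)
    it = 0
    while np.abs(F).max() / scale > tol and it < max_iter:
        J = (A * x) @ A.T
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -F, rcond=None)[0]
        # backtracking on the residual norm
        t = 1.0
        f_old = np.linalg.norm(F)
        for _ in range(60):
            x_new, F_new = compute(lam + t * step)
            if np.linalg.norm(F_new) < f_old * (1 - 1e-4 * t) or t < 1e-12:
                break
            t *= 0.5
        lam = lam + t * step
        x, F = x_new, F_new
        it += 1

    residual = float(np.abs(F).max() / scale)
    if residual > tol:
        raise ConvergenceError(
            f"concentration solver stalled at relative residual {residual:.3e}",
            residual=residual,
        )
    x_full = np.zeros(len(tube.complexes))
    x_full[active] = x
    return ConcentrationSolution(
        species=species,
        complexes=list(tube.complexes),
        x=x_full,
        molar=x_full * rho,
        duals=lam,
        A=A_full,
        residual=residual,
        iterations=it,
        rho=rho,
    )


# ---------------------------------------------------------------------------
# tube-level base-pairing observables


def fraction_unpaired(tube: TubeSpec, sol: ConcentrationSolution, P: dict) -> float:
    """Concentration-weighted fraction of all bases unpaired at equilibrium.

    ``P`` maps canonical orderings to pair-probability matrices.  The
    numerator sums x_j times the unpaired diagonal over each complex's bases;
    the denominator is the total base concentration.
    """
    num = den = 0.0
    for c, xj in zip(sol.complexes, sol.x):
        if xj == 0.0 and canonical_rotation(c.names) not in P:
            continue  # unformable complex (empty ensemble)
        Pj = P[canonical_rotation(c.names)]
        num += xj * float(np.trace(Pj))
        den += xj * c.length
    return num / den if den > 0 else 1.0


def distinct_base_index(tube: TubeSpec) -> list:
    """(species, offset) label for each distinct base, species sorted."""
    out = []
    for sp in sorted(tube.totals):
        for a in range(len(tube.strands[sp])):
            out.append((sp, a))
    return out


def ensemble_pair_fractions(
    tube: TubeSpec, sol: ConcentrationSolution, P: dict
) -> np.ndarray:
    """Matrix of test-tube ensemble pair fractions over distinct bases.

    Entry [(i,a), (k,b)] is the fraction of i-species strands whose base a is
    paired to base b of a k-species strand at equilibrium; the diagonal holds
    unpaired fractions.  Rows are normalized by the row species' total strand
    concentration and always sum to 1; the matrix is asymmetric in general.
    """
    labels = distinct_base_index(tube)
    index = {lab: k for k, lab in enumerate(labels)}
    N = len(labels)
    M = np.zeros((N, N))
    for c, xj in zip(sol.complexes, sol.x):
        if xj == 0.0 and canonical_rotation(c.names) not in P:
            continue
        Pj = P[canonical_rotation(c.names)]
        # map concatenated positions to (species, offset)
        pos_labels = []
        for nm in c.names:
            for a in range(len(tube.strands[nm])):
                pos_labels.append((nm, a))
        n = c.length
        for u in range(n):
            iu = index[pos_labels[u]]
            M[iu, iu] += xj * Pj[u, u]
            for v in range(n):
                if v == u:
                    continue
                M[iu, index[pos_labels[v]]] += xj * Pj[u, v]
    totals_x = {sp: tube.totals[sp] / sol.rho for sp in tube.totals}
    for k, (sp, _a) in enumerate(labels):
        M[k, :] /= totals_x[sp]
    return M


# ---------------------------------------------------------------------------
# tube ensemble defect


@dataclass
class TubeDefectReport:
    """Decomposition of the test-tube ensemble defect (Molar·nt units)."""

    structural: dict  # on-target ordering -> M·nt
    concentration: dict  # on-target ordering -> M·nt
    total: float  # C
    normalized: float  # M_h in [0, 1]
    y_nt: float  # total nucleotide concentration of the targets


def tube_ensemble_defect(
    on_targets: list,
    sol: ConcentrationSolution,
    defects: dict,
) -> TubeDefectReport:
    """Test-tube ensemble defect from on-target specifications.

    ``on_targets`` is a list of (ordering, |phi|, y_molar); ``defects`` maps
    canonical orderings to the complex ensemble defect n (nucleotides).
    Per on-target: structural defect n_j min(x_j, y_j) plus concentration
    defect |phi_j| max(y_j - x_j, 0); off-targets contribute only through
    mass conservation.
    """
    structural, concentration = {}, {}
    y_nt = 0.0
    rho = sol.rho
    for ordering, size, y_molar in on_targets:
        key = canonical_rotation(tuple(ordering))
        y = y_molar  # work in molar throughout (scale cancels in M_h)
        xj = sol.concentration(ordering)
        nj = defects[key]
        structural[key] = nj * min(xj, y)
        concentration[key] = size * max(y - xj, 0.0)
        y_nt += size * y
    C = sum(structural.values()) + sum(concentration.values())
    return TubeDefectReport(
        structural=structural,
        concentration=concentration,
        total=C,
        normalized=C / y_nt if y_nt > 0 else 0.0,
        y_nt=y_nt,
    )
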