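"""Loop-based free-energy model for multistranded nucleic-acid structures.

The free energy of an unpseudoknotted connected secondary structure is the sum
of the free energies of its constituent loops (the faces of the polymer graph)
plus a strand-association penalty applied L-1 times for an L-strand complex;
an unpaired strand is the zero reference state.  Multiloops and exterior loops
carry a Boltzmann-weighted subensemble of coaxial and dangle stacking states:
within such a loop a base pair may form one coaxial stack with an adjacent
pair or a dangle stack with at most two adjacent unpaired bases, and an
unpaired base may dangle on at most one adjacent pair.  Structures with an
R-fold rotational symmetry receive a +kT log R correction when strands of the
same species are treated as indistinguishable.

Parameters live in JSON files holding free energies and enthalpies at a
reference temperature; values at other temperatures follow the two-point
extrapolation dG(T) = dH - T (dH - dG_ref)/T_ref.  Free energies are in
kcal/mol, temperatures in kelvin.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from .errors import ModelError, ParameterError, SequenceError
from .structures import Structure, rotational_symmetry

logger = logging.getLogger(__name__)

#: Boltzmann constant in kcal/(mol K)
KB = 0.0019872041

MATERIALS = {"r": "RNA", "d": "DNA", "m": "2OMe-RNA"}
_BASES = {"r": "ACGU", "d": "ACGT", "m": "ACGU"}

ENSEMBLE_OPTIONS = ("all", "coaxial", "dangle", "none")


def normalize_ensemble_option(opt: str) -> str:
    alias = {
        "all": "all", "all-stacking": "all", "all_stacking": "all",
        "stacking": "all", "coaxial": "coaxial", "dangle": "dangle",
        "none": "none", "no-stacking": "none", "nostacking": "none",
    }
    try:
        return alias[opt.lower()]
    except KeyError:
        raise ValueError(f"unknown ensemble option {opt!r}") from None


# ---------------------------------------------------------------------------
# sequences


def parse_sequence(text: str, default_material: str = "r") -> tuple:
    """Parse one strand into a tuple of material-annotated nucleotides.

    Material prefixes (r/d/m) are sticky: they apply until the next prefix.
    U and T are interconverted to match the active material ("ACGUU" with
    DNA default becomes dA dC dG dT dT).
    """
    if default_material not in MATERIALS:
        raise SequenceError(f"unknown material {default_material!r}")
    mat = default_material
    out = []
    i = 0
    text = text.strip()
    if not text:
        raise SequenceError("empty sequence")
    while i < len(text):
        ch = text[i]
        if ch in "rdm":
            mat = ch
            i += 1
            if i >= len(text):
                raise SequenceError("material prefix with no following base")
            continue
        base = ch.upper()
        if base == "T" and mat in ("r", "m"):
            base = "U"
        elif base == "U" and mat == "d":
            base = "T"
        if base not in _BASES[mat]:
            raise SequenceError(
                f"illegal letter {ch!r} for material {MATERIALS[mat]} "
                f"at position {i + 1}"
            )
        out.append(mat + base)
        i += 1
    return tuple(out)


def sequence_to_text(nts, collapse: bool = True) -> str:
    """Render annotated nucleotides; with ``collapse`` the material prefix is
    emitted only on changes (and omitted entirely for single-material)."""
    if not collapse:
        return "".join(nts)
    mats = {nt[0] for nt in nts}
    out, cur = [], None
    single = len(mats) == 1
    for nt in nts:
        if not single and nt[0] != cur:
            out.append(nt[0])
        cur = nt[0]
        out.append(nt[1])
    return "".join(out)


def _canon_ut(letter: str) -> str:
    return "U" if letter == "T" else letter


def valid_pair(a: str, b: str) -> bool:
    """Whether two annotated nucleotides may pair (Watson-Crick or wobble).

    Wobble pairs: rG·rU, mG·mU, rG·mU, mG·rU, and rG·dT; the mismatches
    dG×dT and dG×rU do not pair.  DNA with 2'OMe-RNA is an unsupported
    material combination and raises :class:`ModelError`.
    """
    ma, mb = a[0], b[0]
    if {ma, mb} == {"d", "m"}:
        raise ModelError("DNA/2'OMe-RNA pairing is not a supported material combination")
    la, lb = _canon_ut(a[1]), _canon_ut(b[1])
    if {la, lb} in ({"A", "U"}, {"C", "G"}):
        return True
    if {la, lb} == {"G", "U"}:
        g_mat = ma if la == "G" else mb
        u_mat = mb if la == "G" else ma
        if g_mat == "d":
            return False  # dG x dT and dG x rU are mismatches
        if u_mat == "d":
            return g_mat == "r"  # rG·dT wobble
        return True
    return False


_WC = {"A": "U", "U": "A", "C": "G", "G": "C", "T": "A"}


def wc_complement(nt: str) -> str:
    """Watson-Crick partner within the same material."""
    mat, base = nt[0], nt[1]
    comp = _WC[base]
    if mat == "d" and comp == "U":
        comp = "T"
    return mat + comp


# ---------------------------------------------------------------------------
# parameter sets

_REQUIRED_TABLES = (
    "stack", "terminalbp", "coaxial", "dangle5", "dangle3",
    "hairpin_size", "interior_size", "bulge_size",
)
_REQUIRED_SCALARS = (
    "multiloop_init", "multiloop_bp", "multiloop_nt",
    "interior_asym_per_nt", "interior_asym_max", "assoc",
)
_OPTIONAL_TABLES = ("terminal_mismatch", "hairpin_special", "salt_correction")


@dataclass
class ParameterSet:
    """Free energies (kcal/mol at ``T_ref``) and enthalpies for every model
    context, per material scope.

    ``tables`` maps table name -> {context key -> (dG, dH)}; ``scalars`` maps
    scalar name -> (dG, dH).  Missing contexts raise at lookup, never default
    to zero.
    """

    name: str
    materials: tuple
    T_ref: float
    salt: dict
    tables: dict
    scalars: dict

    def __post_init__(self):
        self.materials = tuple(self.materials)
        for m in self.materials:
            if m not in MATERIALS:
                raise ParameterError(f"unknown material tag {m!r}")
        for t in _REQUIRED_TABLES:
            if t not in self.tables:
                raise ParameterError(f"parameter set missing table {t!r}")
        for sname in _REQUIRED_SCALARS:
            if sname not in self.scalars:
                raise ParameterError(f"parameter set missing scalar {sname!r}")
        for t, entries in self.tables.items():
            for key, val in entries.items():
                if len(val) != 2 or not all(
                    isinstance(v, (int, float)) for v in val
                ):
                    raise ParameterError(
                        f"table {t!r} entry {key!r} must be [dG, dH]"
                    )
        self._check_complete()
        for name in _OPTIONAL_TABLES:
            if name not in self.tables and name != "salt_correction":
                logger.warning(
                    "parameter set %s has no %s table; it contributes 0",
                    self.name, name,
                )

    def alphabet(self) -> list:
        return [m + b for m in self.materials for b in _BASES[m]]

    def valid_pairs(self) -> list:
        out = []
        for a, b in itertools.product(self.alphabet(), repeat=2):
            try:
                if valid_pair(a, b):
                    out.append((a, b))
            except ModelError:
                continue
        return out

    def _check_complete(self):
        """Referential completeness: every pair/stack/dangle context over the
        declared materials must be present."""
        pairs = self.valid_pairs()
        for a, b in pairs:
            if f"{a}{b}" not in self.tables["terminalbp"]:
                raise ParameterError(f"terminalbp missing context {a}{b}")
        for (a, b), (c, d) in itertools.product(pairs, repeat=2):
            if f"{a}{c}/{d}{b}" not in self.tables["stack"]:
                raise ParameterError(f"stack missing context {a}{c}/{d}{b}")
            if _coax_key(f"{a}{b}", f"{c}{d}") not in self.tables["coaxial"]:
                raise ParameterError(f"coaxial missing context {a}{b}|{c}{d}")
        for (a, b), x in itertools.product(pairs, self.alphabet()):
            for tname in ("dangle5", "dangle3"):
                if f"{a}{b}:{x}" not in self.tables[tname]:
                    raise ParameterError(f"{tname} missing context {a}{b}:{x}")
        for n in range(3, 31):
            if str(n) not in self.tables["hairpin_size"]:
                raise ParameterError(f"hairpin_size missing size {n}")
        for n in range(2, 31):
            if str(n) not in self.tables["interior_size"]:
                raise ParameterError(f"interior_size missing size {n}")
        for n in range(1, 31):
            if str(n) not in self.tables["bulge_size"]:
                raise ParameterError(f"bulge_size missing size {n}")

    def to_json(self) -> dict:
        return {
            "schema": 1,
            "name": self.name,
            "materials": list(self.materials),
            "T_ref": self.T_ref,
            "salt": dict(self.salt),
            "tables": {
                t: {k: list(v) for k, v in sorted(entries.items())}
                for t, entries in sorted(self.tables.items())
            },
            "scalars": {k: list(v) for k, v in sorted(self.scalars.items())},
        }


def _coax_key(pair1: str, pair2: str) -> str:
    return "|".join(sorted((pair1, pair2)))


def load_parameters(path) -> ParameterSet:
    """Load and validate a JSON parameter file."""
    raw = json.loads(Path(path).read_text())
    return parameters_from_dict(raw)


def parameters_from_dict(raw: dict) -> ParameterSet:
    try:
        return ParameterSet(
            name=raw["name"],
            materials=tuple(raw["materials"]),
            T_ref=float(raw["T_ref"]),
            salt=dict(raw.get("salt", {})),
            tables={
                t: {k: (float(v[0]), float(v[1])) for k, v in entries.items()}
                for t, entries in raw["tables"].items()
            },
            scalars={
                k: (float(v[0]), float(v[1]))
                for k, v in raw["scalars"].items()
            },
        )
    except KeyError as exc:
        raise ParameterError(f"parameter file missing field {exc}") from None


def save_parameters(p: ParameterSet, path) -> None:
    Path(path).write_text(json.dumps(p.to_json(), indent=1, sort_keys=True))


class ParamView:
    """Parameter set evaluated at a working temperature.

    Every lookup returns dG(T) = dH - T (dH - dG_ref)/T_ref.  Missing
    contexts raise :class:`ModelError` naming the table and key.
    """

    def __init__(self, params: ParameterSet, T: float):
        if not (273.0 <= T <= 373.0):
            raise ValueError(f"temperature {T} K outside supported 273-373 K")
        self.params = params
        self.T = T
        self.kT = KB * T

    def _dg(self, entry) -> float:
        dg_ref, dh = entry
        return dh - self.T * (dh - dg_ref) / self.params.T_ref

    def _table(self, table: str, key: str) -> float:
        try:
            return self._dg(self.params.tables[table][key])
        except KeyError:
            raise ModelError(f"no parameter for {table}[{key}]") from None

    def scalar(self, name: str) -> float:
        try:
            return self._dg(self.params.scalars[name])
        except KeyError:
            raise ModelError(f"no scalar parameter {name!r}") from None

    def stack(self, outer: tuple, inner: tuple) -> float:
        a, b = outer
        c, d = inner
        return self._table("stack", f"{a}{c}/{d}{b}")

    def terminalbp(self, a: str, b: str) -> float:
        tab = self.params.tables["terminalbp"]
        for key in (f"{a}{b}", f"{b}{a}"):
            if key in tab:
                return self._dg(tab[key])
        raise ModelError(f"no parameter for terminalbp[{a}{b}]")

    def coaxial(self, pair1: tuple, pair2: tuple) -> float:
        return self._table("coaxial", _coax_key("".join(pair1), "".join(pair2)))

    def dangle(self, pair: tuple, base: str, side: str) -> float:
        return self._table(f"dangle{side}", f"{pair[0]}{pair[1]}:{base}")

    def terminal_mismatch(self, pair: tuple, b5: str, b3: str) -> float | None:
        tab = self.params.tables.get("terminal_mismatch")
        if tab is None:
            return None
        key = f"{pair[0]}{pair[1]}:{b5}{b3}"
        if key not in tab:
            return None
        return self._dg(tab[key])

    def _size(self, table: str, n: int) -> float:
        tab = self.params.tables[table]
        if str(n) in tab:
            return self._dg(tab[str(n)])
        # outside the tabulated size range, clamp to the nearest entry
        sizes = sorted(int(k) for k in tab)
        n = min(max(n, sizes[0]), sizes[-1])
        return self._dg(tab[str(n)])

    def hairpin_size(self, n: int) -> float:
        return self._size("hairpin_size", n)

    def interior_size(self, n: int) -> float:
        return self._size("interior_size", n)

    def bulge_size(self, n: int) -> float:
        return self._size("bulge_size", n)

    def interior_asymmetry(self, n1: int, n2: int) -> float:
        per = self.scalar("interior_asym_per_nt")
        cap = self.scalar("interior_asym_max")
        return min(per * abs(n1 - n2), cap)


def parameters_at_temperature(params: ParameterSet, T: float) -> ParamView:
    return ParamView(params, T)


# ---------------------------------------------------------------------------
# loop decomposition (polymer-graph faces)


@dataclass(frozen=True)
class Loop:
    """One face of the polymer graph.

    ``elements`` walk the face in order; each is ``('p', (i, j))`` for a
    closing pair or ``('u', a)`` for an unpaired base.  ``gaps[k]`` is True if
    the backbone segment between element k and element k+1 (circularly)
    carries a nick.  For inner faces element 0 is the enclosing pair.
    """

    kind: str  # hairpin | interior | multiloop | exterior
    elements: tuple
    gaps: tuple

    @property
    def closing_pairs(self) -> tuple:
        return tuple(e[1] for e in self.elements if e[0] == "p")

    @property
    def unpaired(self) -> tuple:
        return tuple(e[1] for e in self.elements if e[0] == "u")

    @property
    def n_nicks(self) -> int:
        return sum(self.gaps)


def _classify(elements, gaps) -> str:
    n_nicks = sum(gaps)
    n_pairs = sum(1 for e in elements if e[0] == "p")
    if n_nicks > 0:
        return "exterior"
    if n_pairs == 1:
        return "hairpin"
    if n_pairs == 2:
        return "interior"
    return "multiloop"


def decompose_loops(s: Structure) -> list:
    """Faces of the polymer graph for the structure's strand ordering.

    Raises :class:`ModelError` on pseudoknotted input.  A structure with p
    pairs yields p + 1 loops (the top-level face, which always contains the
    wrap nick of the circle, is an exterior loop).
    """
    from .structures import is_unpseudoknotted

    if not is_unpseudoknotted(s):
        raise ModelError("pseudoknotted structure has no loop decomposition")
    pm = s.pair_map()
    nick_after = set(s.nicks)  # includes the wrap nick after the final strand
    loops = []

    for i, j in sorted(s.pairs):
        elements = [("p", (i, j))]
        gaps = []
        cur = i
        while True:
            gaps.append(cur in nick_after)
            nxt = cur + 1
            if nxt == j:
                break
            if nxt in pm and pm[nxt] > nxt:
                elements.append(("p", (nxt, pm[nxt])))
                cur = pm[nxt]
            else:
                elements.append(("u", nxt))
                cur = nxt
        loops.append(Loop(_classify(elements, gaps), tuple(elements), tuple(gaps)))

    # top-level face around the circle
    elements, gaps = [], []
    k = 0
    while k < s.length:
        if k in pm and pm[k] > k:
            elements.append(("p", (k, pm[k])))
            end = pm[k]
        else:
            elements.append(("u", k))
            end = k
        gaps.append(end in nick_after)
        k = end + 1
    loops.append(Loop(_classify(elements, gaps), tuple(elements), tuple(gaps)))
    return loops


# ---------------------------------------------------------------------------
# stacking subensembles


def _adjacencies(loop: Loop):
    """Consecutive-element adjacencies around the face.

    Returns (coax_edges, dangle_opts): coax_edges is a list of unordered
    element-index pairs of adjacent closing pairs (a nick does not block a
    coaxial stack); dangle_opts maps an unpaired element index to the list of
    (pair_element_index, side) it may dangle on, where side '5' means the base
    sits immediately 5' of the pair's helix end (no nick in between).
    """
    m = len(loop.elements)
    coax, dangle = set(), {}
    for k in range(m):
        k2 = (k + 1) % m
        if k == k2:
            continue  # a face with a single element has no adjacencies
        e1, e2 = loop.elements[k], loop.elements[k2]
        nicked = loop.gaps[k]
        if e1[0] == "p" and e2[0] == "p":
            # a nick does not block coaxial stacking of adjacent pairs
            coax.add(tuple(sorted((k, k2))))
        elif not nicked:
            if e1[0] == "u" and e2[0] == "p":
                # base exits at u, pair entry end follows: base is 5' of it
                dangle.setdefault(k, []).append((k2, "5"))
            elif e1[0] == "p" and e2[0] == "u":
                dangle.setdefault(k2, []).append((k, "3"))
    return sorted(coax), dangle


@dataclass(frozen=True)
class StackingState:
    """One consistent assignment of coaxial and dangle stacks within a loop.

    ``coax`` holds (pair, pair) index pairs; ``dangles`` maps a pair to the
    tuple of (base_index, side) stacked on it (at most two bases).
    """

    coax: tuple
    dangles: tuple  # ((pair, ((base, side), ...)), ...)

    @property
    def n_stacks(self) -> int:
        return len(self.coax) + len(self.dangles)


def enumerate_stacking_states(loop: Loop, opt: str = "all") -> list:
    """All consistent stacking assignments of a multiloop or exterior loop,
    including the empty state; deduplicated and deterministic."""
    opt = normalize_ensemble_option(opt)
    if loop.kind not in ("multiloop", "exterior"):
        raise ValueError("stacking states exist only for multiloops/exterior loops")
    if opt == "none":
        return [StackingState((), ())]
    coax_edges, dangle_opts = _adjacencies(loop)
    if opt == "dangle":
        coax_edges = []
    if opt == "coaxial":
        dangle_opts = {}

    # matchings over coax edges
    def matchings(edges):
        if not edges:
            yield []
            return
        first, rest = edges[0], edges[1:]
        # skip first
        yield from matchings(rest)
        # take first, drop conflicting
        ok = [e for e in rest if not (set(e) & set(first))]
        for m in matchings(ok):
            yield [first] + m

    elems = loop.elements
    states = set()
    for coax_set in matchings(coax_edges):
        stacked = {k for e in coax_set for k in e}
        base_elems = sorted(dangle_opts)
        per_base = []
        for b in base_elems:
            opts = [None] + [
                (pk, side) for pk, side in dangle_opts[b] if pk not in stacked
            ]
            per_base.append(opts)
        for choice in itertools.product(*per_base):
            per_pair = {}
            for b, ch in zip(base_elems, choice):
                if ch is None:
                    continue
                pk, side = ch
                per_pair.setdefault(pk, []).append((elems[b][1], side))
            coax_pairs = tuple(
                sorted(
                    tuple(sorted((elems[a][1], elems[b][1])))
                    for a, b in coax_set
                )
            )
            dangles = tuple(
                sorted(
                    (elems[pk][1], tuple(sorted(bases)))
                    for pk, bases in per_pair.items()
                )
            )
            states.add(StackingState(coax_pairs, dangles))
    return sorted(states, key=lambda st: (st.coax, st.dangles))


def stack_energy(state: StackingState, phi, view: ParamView) -> float:
    """Sum of the per-stack free energies of one stacking state."""
    total = 0.0
    for p1, p2 in state.coax:
        total += view.coaxial((phi[p1[0]], phi[p1[1]]), (phi[p2[0]], phi[p2[1]]))
    for pair, bases in state.dangles:
        pnts = (phi[pair[0]], phi[pair[1]])
        if len(bases) == 2:
            b5 = next(b for b, side in bases if side == "5")
            b3 = next(b for b, side in bases if side == "3")
            tm = view.terminal_mismatch(pnts, phi[b5], phi[b3])
            if tm is not None:
                total += tm
                continue
        for b, side in bases:
            total += view.dangle(pnts, phi[b], side)
    return total


def stacking_state_energies(loop: Loop, phi, view: ParamView, opt: str) -> list:
    """Free energies of every stacking state of the loop (0.0 for the empty
    state), sorted ascending."""
    return sorted(
        stack_energy(st, phi, view) for st in enumerate_stacking_states(loop, opt)
    )


def stacking_bonus(loop: Loop, phi, view: ParamView, opt: str = "all") -> float:
    """-kT log sum over stacking states of exp(-dG_state/kT); always <= 0
    because the empty state contributes a term of 1."""
    energies = stacking_state_energies(loop, phi, view, opt)
    kT = view.kT
    m = min(energies)
    total = sum(math.exp(-(e - m) / kT) for e in energies)
    return min(0.0, m - kT * math.log(total))


# ---------------------------------------------------------------------------
# loop and structure free energies


def loop_base_energy(loop: Loop, phi, view: ParamView) -> float:
    """Loop free energy without any stacking bonus (the fixed part shared by
    every stacking state of the loop)."""
    kind = loop.kind
    if kind == "hairpin":
        (i, j), = loop.closing_pairs
        return view.hairpin_size(j - i - 1) + view.terminalbp(phi[i], phi[j])
    if kind == "interior":
        (i, j), (d, e) = loop.closing_pairs
        n1, n2 = d - i - 1, j - e - 1
        if n1 == 0 and n2 == 0:
            return view.stack((phi[i], phi[j]), (phi[d], phi[e]))
        terms = view.terminalbp(phi[i], phi[j]) + view.terminalbp(phi[d], phi[e])
        if n1 == 0 or n2 == 0:
            return view.bulge_size(n1 + n2) + terms
        return (
            view.interior_size(n1 + n2)
            + view.interior_asymmetry(n1, n2)
            + terms
        )
    if kind == "multiloop":
        total = (
            view.scalar("multiloop_init")
            + view.scalar("multiloop_bp") * len(loop.closing_pairs)
            + view.scalar("multiloop_nt") * len(loop.unpaired)
        )
        for i, j in loop.closing_pairs:
            total += view.terminalbp(phi[i], phi[j])
        return total
    if kind == "exterior":
        total = 0.0
        for i, j in loop.closing_pairs:
            total += view.terminalbp(phi[i], phi[j])
        return total
    raise ValueError(kind)


def loop_energy(loop: Loop, phi, view: ParamView, opt: str = "all") -> float:
    """Loop free energy including the stacking bonus for multiloops and
    exterior loops."""
    e = loop_base_energy(loop, phi, view)
    if loop.kind in ("multiloop", "exterior"):
        e += stacking_bonus(loop, phi, view, opt)
    return e


def _check_pairs_valid(phi, s: Structure):
    for a, b in s.pairs:
        if not valid_pair(phi[a], phi[b]):
            raise ModelError(
                f"invalid base pair {phi[a]}·{phi[b]} at ({a},{b})"
            )


@lru_cache(maxsize=500_000)
def _energy_terms_cached(phi, s, view, opt):
    _check_pairs_valid(phi, s)
    loops = decompose_loops(s)
    base = (s.n_strands - 1) * view.scalar("assoc")
    stack_lists = []
    for lp in loops:
        base += loop_base_energy(lp, phi, view)
        if lp.kind in ("multiloop", "exterior"):
            stack_lists.append(
                tuple(stacking_state_energies(lp, phi, view, opt))
            )
    return base, tuple(loops), tuple(stack_lists)


def structure_energy_terms(
    phi, s: Structure, view: ParamView, opt: str = "all"
):
    """(base, loops, stack_lists): fixed energy (association penalty plus all
    non-stacking loop terms), the loop list, and per-stacking-loop sorted
    stacking-state energy lists.  The structure free energy without symmetry
    correction is base + sum over stacking loops of -kT logsumexp.

    Results are memoized on (phi, structure, parameter view, option); the
    view participates by identity, so reuse the same view object across
    calls for cache hits.
    """
    return _energy_terms_cached(tuple(phi), s, view, normalize_ensemble_option(opt))


def _logsumexp_neg(energies, kT: float) -> float:
    m = min(energies)
    return m - kT * math.log(sum(math.exp(-(e - m) / kT) for e in energies))


def structure_free_energy(
    phi,
    s: Structure,
    view: ParamView,
    opt: str = "all",
    species=None,
) -> tuple:
    """(dG_bar, dG): structure free energy treating strands as distinct, and
    with the +kT log R rotational-symmetry correction for indistinguishable
    strands of the same species.

    ``phi`` is the concatenated annotated-nucleotide tuple; ``species`` gives
    one label per strand (default: all distinct, so R = 1 and dG == dG_bar).
    """
    base, _loops, stack_lists = structure_energy_terms(phi, s, view, opt)
    dg_bar = base
    for lst in stack_lists:
        dg_bar += min(0.0, _logsumexp_neg(lst, view.kT))
    if species is None:
        species = [str(k) for k in range(s.n_strands)]
    R = rotational_symmetry(s, list(species))
    return dg_bar, dg_bar + view.kT * math.log(R)


def min_stacking_energy(phi, s: Structure, view: ParamView, opt: str = "all") -> float:
    """Free energy of the minimum-energy stacking state of structure s
    (strands distinct): base terms plus the per-loop minimum stack energy."""
    base, _loops, stack_lists = structure_energy_terms(phi, s, view, opt)
    return base + sum(min(lst) for lst in stack_lists)


def count_stacking_states(phi, s: Structure, view: ParamView, opt: str = "all") -> int:
    """Number of stacking states in the subensemble of structure s."""
    _check_pairs_valid(phi, s)
    n = 1
    for lp in decompose_loops(s):
        if lp.kind in ("multiloop", "exterior"):
            n *= len(enumerate_stacking_states(lp, opt))
    return n


def all_stacking_state_energies(
    phi, s: Structure, view: ParamView, opt: str = "all"
) -> list:
    """Free energies of every stacking state of s (strands distinct), by
    explicit product over the per-loop subensembles; the Boltzmann logsumexp
    over this list reproduces the structure free energy."""
    base, _loops, stack_lists = structure_energy_terms(phi, s, view, opt)
    out = [base]
    for lst in stack_lists:
        out = [e + x for e in out for x in lst]
    return sorted(out)
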