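"""Multitube ensemble-defect sequence design.

A design problem is a set of target test tubes sharing sequence domains.
Each tube holds on-target complexes (target structure + target concentration)
and off-target complexes (no structure, vanishing target concentration).  The
objective is the multitube ensemble defect M: the average over tubes of the
normalized test-tube ensemble defect, augmented by weighted soft-constraint
penalties.  Candidate sequences must satisfy hard constraints; optimization
is a seeded stochastic descent over single-class mutations (a mutation of a
base mutates its Watson-Crick partner classes in lockstep), accepting steps
that lower the augmented objective, until it drops below the stop condition.

Exact objective evaluation: every tube is analyzed with the enumeration
engine and the convex concentration solver; nothing is estimated.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np

from .errors import ConstraintError
from .ensemble import (
    ComplexSpec,
    complex_ensemble_defect,
    pair_probability_matrix,
    partition_function,
)
from .model import (
    ParamView,
    _BASES,
    structure_free_energy,
    valid_pair,
    wc_complement,
)
from .structures import Structure, canonical_rotation
from .tube import (
    TubeSpec,
    generate_complexes,
    solve_concentrations,
    tube_ensemble_defect,
)

# ---------------------------------------------------------------------------
# degenerate nucleotide codes

_CODE_SETS = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "T",
    "M": "AC", "R": "AG", "W": "AU", "S": "CG", "Y": "CU", "K": "GU",
    "V": "ACG", "H": "ACU", "D": "AGU", "B": "CGU", "N": "ACGU",
}


def expand_degenerate(code: str, job_materials: tuple = ("r",)) -> frozenset:
    """Concrete annotated nucleotides denoted by a degenerate code.

    ``code`` is a material prefix (r/d/m, or the wildcard w for mixed jobs)
    followed by a code letter; a bare letter uses the job's first material.
    """
    if not code:
        raise ConstraintError("empty degenerate code")
    if code[0] in "rdmw":
        mats = tuple(job_materials) if code[0] == "w" else (code[0],)
        letter = code[1:]
    else:
        mats = (job_materials[0],)
        letter = code
    letter = letter.upper()
    if letter == "T":
        letter = "U"
    if letter not in _CODE_SETS:
        raise ConstraintError(f"unknown degenerate code {code!r}")
    out = set()
    for m in mats:
        if m not in _BASES:
            raise ConstraintError(f"unknown material in code {code!r}")
        for b in _CODE_SETS[letter]:
            b = "T" if (b == "U" and m == "d") else b
            if b in _BASES[m]:
                out.add(m + b)
    return frozenset(out)


def parse_degenerate_sequence(text: str, job_materials: tuple = ("r",)) -> tuple:
    """Per-position sets of allowed annotated nucleotides, with sticky
    material prefixes as in concrete sequence parsing."""
    mat = job_materials[0]
    out = []
    i = 0
    text = text.strip()
    if not text:
        raise ConstraintError("empty domain sequence")
    while i < len(text):
        ch = text[i]
        if ch in "rdmw":
            mat = ch
            i += 1
            if i >= len(text):
                raise ConstraintError("material prefix with no following code")
            continue
        out.append(expand_degenerate(mat + text[i], job_materials))
        i += 1
    return tuple(out)


# ---------------------------------------------------------------------------
# design specification


@dataclass
class Domain:
    """Named run of consecutive designable nucleotides; its degenerate code
    string is an implicit hard assignment constraint."""

    name: str
    codes: str  # degenerate code string (with optional material prefixes)

    def __post_init__(self):
        if not self.name or self.name.endswith("*"):
            raise ConstraintError("domain names must be nonempty and not end in '*'")


@dataclass
class TargetComplex:
    name: str
    strand_names: tuple  # ordering around the polymer circle
    structure: Structure | None = None  # required where used as an on-target


@dataclass
class DesignTube:
    name: str
    on_targets: dict  # complex name -> target concentration (molar)
    off_targets: tuple = ()  # explicit complex names
    L_max: int = 1  # auto-generate off-targets up to this size
    exclude: tuple = ()  # orderings (tuples of strand names) to exclude


# hard constraints ----------------------------------------------------------


@dataclass
class PatternConstraint:
    patterns: tuple  # plain base-letter strings, e.g. "GGGG"
    domains: tuple | None = None  # None = global (every strand)


@dataclass
class DiversityConstraint:
    word: int
    min_types: int
    domains: tuple | None = None


@dataclass
class MatchConstraint:
    domains_a: tuple
    domains_b: tuple


@dataclass
class ComplementarityConstraint:
    domains_a: tuple
    domains_b: tuple
    wobble: bool = False


@dataclass
class SimilarityConstraint:
    domains: tuple
    reference: str  # degenerate codes, e.g. poly-S for GC content
    lo: float = 0.0
    hi: float = 1.0


@dataclass
class WindowConstraint:
    domains: tuple
    sources: tuple  # concrete source sequences (text)


@dataclass
class LibraryConstraint:
    domains: tuple
    libraries: tuple  # each a tuple of equal-length concrete alternatives


# soft constraints ----------------------------------------------------------


@dataclass
class SoftPattern:
    patterns: tuple
    domains: tuple | None = None
    weight: float = 1.0


@dataclass
class SoftSimilarity:
    domains: tuple
    reference: str
    lo: float = 0.0
    hi: float = 1.0
    weight: float = 1.0


@dataclass
class SoftSymmetry:
    word: int
    weight: float = 1.0


@dataclass
class SoftEnergyMatch:
    """Penalize duplexes whose free energies deviate from each other (or a
    reference).  Each duplex is (domains_top, domains_bottom) assumed to form
    a full helix."""

    duplexes: tuple
    reference: float | None = None
    weight: float = 1.0


@dataclass
class DesignSpec:
    domains: list
    strands: dict  # strand name -> tuple of domain names ('x*' = complement)
    complexes: dict  # name -> TargetComplex
    tubes: list  # DesignTube
    hard: list = field(default_factory=list)
    soft: list = field(default_factory=list)
    weights: dict = field(default_factory=dict)  # {"tube:NAME": w, "complex:NAME": w, "strand:NAME": w, "domain:NAME": w}
    f_stop: float = 0.02
    materials: tuple = ("r",)
    wobble_mutations: bool = False

    def __post_init__(self):
        if not (0 < self.f_stop < 1):
            raise ConstraintError("f_stop must lie in (0, 1)")
        self.domain_map = {d.name: d for d in self.domains}
        for tube in self.tubes:
            for cname in tube.on_targets:
                c = self.complexes.get(cname)
                if c is None:
                    raise ConstraintError(f"tube {tube.name}: unknown complex {cname!r}")
                if c.structure is None:
                    raise ConstraintError(
                        f"on-target {cname!r} needs a target structure"
                    )


# ---------------------------------------------------------------------------
# variable model: union-find with complement parity over domain positions


class _UnionFind:
    def __init__(self):
        self.parent = {}
        self.rel = {}  # parity to parent: 0 same, 1 complement

    def add(self, v):
        if v not in self.parent:
            self.parent[v] = v
            self.rel[v] = 0

    def find(self, v):
        self.add(v)
        if self.parent[v] == v:
            return v, 0
        root, r = self.find(self.parent[v])
        self.parent[v] = root
        self.rel[v] = (self.rel[v] + r) % 2
        return root, self.rel[v]

    def union(self, u, v, rel):
        ru, pu = self.find(u)
        rv, pv = self.find(v)
        if ru == rv:
            if (pu + pv) % 2 != rel:
                raise ConstraintError(
                    f"inconsistent complementarity/match cycle at {u} ~ {v}"
                )
            return
        self.parent[ru] = rv
        self.rel[ru] = (pu + pv + rel) % 2


def _domain_positions(spec: DesignSpec, dname: str) -> list:
    """Slots of a (possibly starred) domain reference, 5'->3', each as
    (base_domain, index, parity)."""
    if dname.endswith("*"):
        base = dname[:-1]
        n = len(parse_degenerate_sequence(spec.domain_map[base].codes, spec.materials))
        return [(base, n - 1 - k, 1) for k in range(n)]
    n = len(parse_degenerate_sequence(spec.domain_map[dname].codes, spec.materials))
    return [(dname, k, 0) for k in range(n)]


def _concat_positions(spec: DesignSpec, dnames) -> list:
    out = []
    for d in dnames:
        out.extend(_domain_positions(spec, d))
    return out


def _strand_positions(spec: DesignSpec, strand: str) -> list:
    return _concat_positions(spec, spec.strands[strand])


class SequenceVariables:
    """Designable positions reduced to independent classes.

    Match and complementarity constraints, and target-structure base pairs,
    merge domain positions into classes with a complement parity; each class
    carries the intersection of the allowed nucleotide sets of its members.
    """

    def __init__(self, spec: DesignSpec):
        self.spec = spec
        self.uf = _UnionFind()
        self.pos_sets = {}
        for d in spec.domains:
            sets = parse_degenerate_sequence(d.codes, spec.materials)
            for k, s in enumerate(sets):
                self.pos_sets[(d.name, k)] = s
                self.uf.add((d.name, k))
        self._apply_structural_links()
        self._apply_hard_links()
        self._build_classes()

    def _apply_structural_links(self):
        # base pairs in on-target structures imply complementarity
        spec = self.spec
        for tube in spec.tubes:
            for cname in tube.on_targets:
                c = spec.complexes[cname]
                pos = []
                for sname in c.strand_names:
                    pos.extend(_strand_positions(spec, sname))
                if c.structure.length != len(pos):
                    raise ConstraintError(
                        f"target structure of {cname!r} has length "
                        f"{c.structure.length}, strands give {len(pos)}"
                    )
                for a, b in c.structure.pairs:
                    da, ka, pa = pos[a]
                    db, kb, pb = pos[b]
                    self.uf.union((da, ka), (db, kb), (pa + pb + 1) % 2)

    def _apply_hard_links(self):
        for hc in self.spec.hard:
            if isinstance(hc, MatchConstraint):
                rel = 0
            elif isinstance(hc, ComplementarityConstraint):
                rel = 1
            else:
                continue
            pa = _concat_positions(self.spec, hc.domains_a)
            pb = _concat_positions(self.spec, hc.domains_b)
            if len(pa) != len(pb):
                raise ConstraintError("linked concatenations differ in length")
            if rel == 1:
                pb = pb[::-1]
            for (da, ka, qa), (db, kb, qb) in zip(pa, pb):
                self.uf.union((da, ka), (db, kb), (qa + qb + rel) % 2)

    def _comp_set(self, s: frozenset) -> frozenset:
        return frozenset(wc_complement(nt) for nt in s)

    def _build_classes(self):
        groups = {}
        for v in self.pos_sets:
            root, parity = self.uf.find(v)
            groups.setdefault(root, []).append((v, parity))
        self.classes = []  # list of (members, allowed-set in root orientation)
        self.class_of = {}
        for root, members in sorted(groups.items()):
            allowed = None
            for v, parity in members:
                s = self.pos_sets[v]
                s = self._comp_set(s) if parity else s
                allowed = s if allowed is None else (allowed & s)
            if not allowed:
                raise ConstraintError(
                    f"no nucleotide satisfies the constraints on class of {root}"
                )
            idx = len(self.classes)
            self.classes.append((tuple(v for v, _ in members), frozenset(allowed)))
            for v, parity in members:
                self.class_of[v] = (idx, parity)

    def assignment_to_domains(self, assignment) -> dict:
        """Class assignment (one nt per class, root orientation) -> concrete
        domain sequences (tuples of annotated nucleotides)."""
        out = {}
        for d in self.spec.domains:
            n = len(parse_degenerate_sequence(d.codes, self.spec.materials))
            seq = []
            for k in range(n):
                idx, parity = self.class_of[(d.name, k)]
                nt = assignment[idx]
                seq.append(wc_complement(nt) if parity else nt)
            out[d.name] = tuple(seq)
        return out

    def random_assignment(self, rng) -> list:
        return [
            sorted(allowed)[rng.integers(len(allowed))]
            for _, allowed in self.classes
        ]


def domain_sequence(spec: DesignSpec, domains_concrete: dict, dname: str) -> tuple:
    """Concrete sequence of a (possibly starred) domain reference."""
    if dname.endswith("*"):
        return tuple(
            wc_complement(nt) for nt in reversed(domains_concrete[dname[:-1]])
        )
    return tuple(domains_concrete[dname])


def strand_sequence(spec: DesignSpec, domains_concrete: dict, strand: str) -> tuple:
    out = []
    for d in spec.strands[strand]:
        out.extend(domain_sequence(spec, domains_concrete, d))
    return tuple(out)


# ---------------------------------------------------------------------------
# hard-constraint evaluation


def _letters(seq) -> str:
    return "".join(nt[1] for nt in seq)


def _scope_text(spec, domains_concrete, domains) -> list:
    """Texts to scan: each strand (global scope) or the one concatenation."""
    if domains is None:
        return [
            _letters(strand_sequence(spec, domains_concrete, s))
            for s in sorted(spec.strands)
        ]
    return [
        _letters(
            tuple(
                nt
                for d in domains
                for nt in domain_sequence(spec, domains_concrete, d)
            )
        )
    ]


def check_hard_constraints(spec: DesignSpec, domains_concrete: dict) -> list:
    """Evaluate every hard constraint; returns a list of violation strings
    (empty = pass).  Match/complementarity are re-validated post hoc even
    though the variable model enforces them by construction."""
    violations = []
    for hc in spec.hard:
        if isinstance(hc, PatternConstraint):
            for text in _scope_text(spec, domains_concrete, hc.domains):
                for pat in hc.patterns:
                    p = pat.upper().replace("T", "U")
                    t = text.replace("T", "U")
                    at = t.find(p)
                    if at >= 0:
                        violations.append(
                            f"pattern {pat} occurs at position {at + 1}"
                        )
        elif isinstance(hc, DiversityConstraint):
            for text in _scope_text(spec, domains_concrete, hc.domains):
                for i in range(len(text) - hc.word + 1):
                    if len(set(text[i : i + hc.word])) < hc.min_types:
                        violations.append(
                            f"diversity: window at {i + 1} has fewer than "
                            f"{hc.min_types} nucleotide types"
                        )
                        break
        elif isinstance(hc, MatchConstraint):
            a = [
                nt
                for d in hc.domains_a
                for nt in domain_sequence(spec, domains_concrete, d)
            ]
            b = [
                nt
                for d in hc.domains_b
                for nt in domain_sequence(spec, domains_concrete, d)
            ]
            if a != b:
                violations.append("match constraint violated")
        elif isinstance(hc, ComplementarityConstraint):
            a = [
                nt
                for d in hc.domains_a
                for nt in domain_sequence(spec, domains_concrete, d)
            ]
            b = [
                nt
                for d in hc.domains_b
                for nt in domain_sequence(spec, domains_concrete, d)
            ]
            if len(a) != len(b):
                violations.append("complementarity lengths differ")
                continue
            for x, y in zip(a, reversed(b)):
                ok = valid_pair(x, y) if hc.wobble else (wc_complement(x) == y)
                if not ok:
                    violations.append(f"complementarity violated at {x}·{y}")
                    break
        elif isinstance(hc, SimilarityConstraint):
            seq = [
                nt
                for d in hc.domains
                for nt in domain_sequence(spec, domains_concrete, d)
            ]
            ref = parse_degenerate_sequence(hc.reference, spec.materials)
            if len(ref) != len(seq):
                violations.append("similarity reference length mismatch")
                continue
            frac = sum(nt in r for nt, r in zip(seq, ref)) / len(seq)
            if not (hc.lo - 1e-12 <= frac <= hc.hi + 1e-12):
                violations.append(
                    f"similarity {frac:.2f} outside [{hc.lo}, {hc.hi}]"
                )
        elif isinstance(hc, WindowConstraint):
            text = _scope_text(spec, domains_concrete, hc.domains)[0]
            if not any(text in src.upper().replace("T", "U") for src in hc.sources):
                violations.append("window: not a subsequence of any source")
        elif isinstance(hc, LibraryConstraint):
            text = _scope_text(spec, domains_concrete, hc.domains)[0]
            ok = False
            for combo in itertools.product(*hc.libraries):
                if "".join(combo).upper().replace("T", "U") == text:
                    ok = True
                    break
            if not ok:
                violations.append("library: no alternative combination matches")
        else:
            raise ConstraintError(f"unknown hard constraint {hc!r}")
    return violations


# ---------------------------------------------------------------------------
# soft-constraint penalties


def soft_penalties(
    spec: DesignSpec,
    domains_concrete: dict,
    view: ParamView | None = None,
    variables: SequenceVariables | None = None,
) -> list:
    """Per-soft-constraint (name, f_k, w_k f_k) with f_k in [0, 1].

    Normalizations (artifact conventions): pattern counts over scanned
    windows; similarity deviation over its maximum attainable value;
    symmetry violations over the number of scanned words; energy-match
    deviation over max(1 kcal/mol, mean |dG|).
    """
    out = []
    for sc in spec.soft:
        if isinstance(sc, SoftPattern):
            hits = windows = 0
            for text in _scope_text(spec, domains_concrete, sc.domains):
                t = text.replace("T", "U")
                for pat in sc.patterns:
                    p = pat.upper().replace("T", "U")
                    w = max(0, len(t) - len(p) + 1)
                    windows += w
                    hits += sum(
                        1 for i in range(w) if t[i : i + len(p)] == p
                    )
            f = hits / windows if windows else 0.0
            out.append(("pattern", f, sc.weight * f))
        elif isinstance(sc, SoftSimilarity):
            seq = [
                nt
                for d in sc.domains
                for nt in domain_sequence(spec, domains_concrete, d)
            ]
            ref = parse_degenerate_sequence(sc.reference, spec.materials)
            frac = sum(nt in r for nt, r in zip(seq, ref)) / len(seq)
            dev = max(0.0, sc.lo - frac, frac - sc.hi)
            norm = max(sc.lo, 1.0 - sc.hi, 1e-12)
            f = min(1.0, dev / norm)
            out.append(("similarity", f, sc.weight * f))
        elif isinstance(sc, SoftSymmetry):
            f = _symmetry_penalty(spec, domains_concrete, sc.word, variables)
            out.append(("symmetry", f, sc.weight * f))
        elif isinstance(sc, SoftEnergyMatch):
            f = _energy_match_penalty(spec, domains_concrete, sc, view)
            out.append(("energy_match", f, sc.weight * f))
        else:
            raise ConstraintError(f"unknown soft constraint {sc!r}")
    return out


def _strand_words(spec, domains_concrete, w):
    words = []
    for sname in sorted(spec.strands):
        seq = strand_sequence(spec, domains_concrete, sname)
        pos = _strand_positions(spec, sname)
        for i in range(len(seq) - w + 1):
            words.append((sname, i, seq[i : i + w], pos[i : i + w]))
    return words


def _symmetry_penalty(spec, domains_concrete, w, variables):
    """Fraction of length-w words that repeat, meet an unintended reverse
    complement, or are self-complementary.  'Intended' duplex positions are
    those whose variable classes are complement-linked."""
    words = _strand_words(spec, domains_concrete, w)
    if not words:
        return 0.0
    letter = {i: _letters(word) for i, (_, _, word, _) in enumerate(words)}
    rc = {
        i: _letters([wc_complement(nt) for nt in reversed(word)])
        for i, (_, _, word, _) in enumerate(words)
    }

    def intended(i, j):
        if variables is None:
            return False
        pi = words[i][3]
        pj = words[j][3]
        for (da, ka, qa), (db, kb, qb) in zip(pi, reversed(pj)):
            ca, pa = variables.class_of[(da, ka)]
            cb, pb = variables.class_of[(db, kb)]
            if ca != cb or (pa + qa + pb + qb) % 2 != 1:
                return False
        return True

    bad = 0
    n = len(words)
    for i in range(n):
        viol = letter[i] == rc[i]  # self-complementary
        if not viol:
            for j in range(n):
                if j != i and letter[j] == letter[i]:
                    viol = True
                    break
                if letter[j] == rc[i] and not intended(i, j):
                    viol = True
                    break
        bad += viol
    return bad / n


def _energy_match_penalty(spec, domains_concrete, sc: SoftEnergyMatch, view):
    if view is None:
        raise ConstraintError("energy-match soft constraint needs parameters")
    energies = []
    for top, bottom in sc.duplexes:
        a = tuple(
            nt for d in top for nt in domain_sequence(spec, domains_concrete, d)
        )
        b = tuple(
            nt
            for d in bottom
            for nt in domain_sequence(spec, domains_concrete, d)
        )
        n = len(a)
        if len(b) != n:
            raise ConstraintError("energy-match duplex arms differ in length")
        s = Structure(
            frozenset((k, 2 * n - 1 - k) for k in range(n)), (n, n)
        )
        energies.append(structure_free_energy(a + b, s, view)[0])
    if not energies:
        return 0.0
    ref = sc.reference if sc.reference is not None else float(np.mean(energies))
    dev = max(abs(e - ref) for e in energies)
    scale = max(1.0, abs(ref))
    return min(1.0, dev / scale)


# ---------------------------------------------------------------------------
# objective evaluation


@dataclass
class ObjectiveReport:
    """Exact decomposition of the augmented design objective."""

    M: float  # multitube ensemble defect
    M_weighted: float
    soft_terms: list  # (name, f_k, w_k f_k)
    augmented: float
    per_tube: dict  # tube name -> dict(M_h, structural, concentration)


def _resolve_weight(spec: DesignSpec, tube: str, cname: str) -> float:
    w = spec.weights.get(f"tube:{tube}", 1.0)
    w *= spec.weights.get(f"complex:{cname}", 1.0)
    return w


def _tube_complexes(spec: DesignSpec, tube: DesignTube, domains_concrete, cap):
    """(strands dict, complexes list, on-target list) for a design tube."""
    strands = {}
    for cname in list(tube.on_targets) + list(tube.off_targets):
        for sname in spec.complexes[cname].strand_names:
            strands[sname] = strand_sequence(spec, domains_concrete, sname)
    on_specs = {}
    for cname in tube.on_targets:
        c = spec.complexes[cname]
        on_specs[canonical_rotation(c.strand_names)] = cname
    exclude = list(tube.exclude)
    gen = generate_complexes(strands, tube.L_max, cap=cap)
    complexes = [
        g for g in gen if canonical_rotation(g.names) not in {
            canonical_rotation(tuple(e)) for e in exclude
        }
    ]
    seen = {canonical_rotation(c.names) for c in complexes}
    for cname in list(tube.on_targets) + list(tube.off_targets):
        c = spec.complexes[cname]
        key = canonical_rotation(c.strand_names)
        if key not in seen:
            seen.add(key)
            complexes.append(
                ComplexSpec(key, tuple(strands[nm] for nm in key), cap=cap)
            )
    return strands, complexes, on_specs


class _QuantityCache:
    """Q and pair-probability cache keyed by the concrete complex."""

    def __init__(self, view: ParamView, opt: str):
        self.view = view
        self.opt = opt
        self.store = {}

    def get(self, c: ComplexSpec):
        key = (c.names, c.seqs)
        if key not in self.store:
            Q = partition_function(c, self.view, self.opt)
            P = (
                pair_probability_matrix(c, self.view, self.opt)
                if Q > 0
                else None
            )
            self.store[key] = (Q, P)
        return self.store[key]


def evaluate_objective(
    spec: DesignSpec,
    domains_concrete: dict,
    view: ParamView,
    opt: str = "all",
    cap: int = 30,
    cache: _QuantityCache | None = None,
    variables: SequenceVariables | None = None,
) -> ObjectiveReport:
    """Exact multitube objective for a concrete candidate."""
    if cache is None or cache.view is not view or cache.opt != opt:
        cache = _QuantityCache(view, opt)
    per_tube = {}
    M_sum = Mw_sum = 0.0
    for tube in spec.tubes:
        strands, complexes, on_specs = _tube_complexes(
            spec, tube, domains_concrete, cap
        )
        totals = _tube_totals(spec, tube)
        tspec = TubeSpec(strands, totals, complexes, name=tube.name)
        Qmap, Pmap = {}, {}
        for c in complexes:
            Q, P = cache.get(c)
            Qmap[canonical_rotation(c.names)] = Q
            if P is not None:
                Pmap[canonical_rotation(c.names)] = P
        sol = solve_concentrations(tspec, Qmap, T=view.T)
        on_list, defects = [], {}
        w_struct = {}
        for cname, y in tube.on_targets.items():
            c = spec.complexes[cname]
            key = canonical_rotation(c.strand_names)
            cspec = ComplexSpec(
                key, tuple(strands[nm] for nm in key), cap=cap
            )
            target = _rotate_target(c, key)
            n, _N = complex_ensemble_defect(cspec, target, view, opt)
            defects[key] = n
            on_list.append((key, cspec.length, y))
            w_struct[key] = _resolve_weight(spec, tube.name, cname)
        rep = tube_ensemble_defect(on_list, sol, defects)
        Mh = rep.normalized
        Ch_w = sum(
            w_struct[k] * (rep.structural[k] + rep.concentration[k])
            for k in rep.structural
        )
        Mh_w = Ch_w / rep.y_nt if rep.y_nt > 0 else 0.0
        per_tube[tube.name] = {
            "M_h": Mh,
            "structural": sum(rep.structural.values()) / rep.y_nt
            if rep.y_nt
            else 0.0,
            "concentration": sum(rep.concentration.values()) / rep.y_nt
            if rep.y_nt
            else 0.0,
        }
        M_sum += Mh
        Mw_sum += Mh_w
    n_tubes = max(1, len(spec.tubes))
    M = M_sum / n_tubes
    Mw = Mw_sum / n_tubes
    soft = soft_penalties(spec, domains_concrete, view, variables)
    augmented = Mw + sum(t[2] for t in soft)
    return ObjectiveReport(
        M=M, M_weighted=Mw, soft_terms=soft, augmented=augmented, per_tube=per_tube
    )


def _tube_totals(spec: DesignSpec, tube: DesignTube) -> dict:
    """Strand totals implied by the on-target target concentrations."""
    totals = {}
    for cname, y in tube.on_targets.items():
        for sname in spec.complexes[cname].strand_names:
            totals[sname] = totals.get(sname, 0.0) + y
    for cname in tube.off_targets:
        for sname in spec.complexes[cname].strand_names:
            totals.setdefault(sname, 0.0)
    return {k: v if v > 0 else 1e-9 for k, v in totals.items()}


def _rotate_target(c: TargetComplex, key: tuple) -> Structure:
    """Target structure expressed on the canonical rotation of the ordering."""
    from .structures import rotate_structure

    names = tuple(c.strand_names)
    if names == key:
        return c.structure
    L = len(names)
    for t in range(L):
        if tuple(names[t:] + names[:t]) == key:
            return rotate_structure(c.structure, t)
    raise ConstraintError(f"cannot rotate target of {c.name} onto {key}")


# ---------------------------------------------------------------------------
# stochastic design


@dataclass
class DesignResult:
    domains: dict  # domain name -> concrete tuple
    strands: dict  # strand name -> concrete tuple
    report: ObjectiveReport
    trace: list  # (evaluation index, augmented objective) at accepted steps
    success: bool
    evaluations: int
    seed: int


def _initial_assignment(variables: SequenceVariables, spec, rng, max_tries=2000):
    for _ in range(max_tries):
        assignment = variables.random_assignment(rng)
        dom = variables.assignment_to_domains(assignment)
        if not check_hard_constraints(spec, dom):
            return assignment
    raise ConstraintError(
        "no feasible initial assignment found under the hard constraints"
    )


def design_sequences(
    spec: DesignSpec,
    view: ParamView,
    opt: str = "all",
    seed: int = 1,
    trials: int = 1,
    cap: int = 30,
    max_evals: int = 100_000,
    max_time: float = 600.0,
) -> list:
    """Seeded stochastic descent on the augmented objective.

    Per trial: random feasible initialization, single-class mutations (each
    mutates a base and all its matched/complement partners), acceptance on
    strict decrease of the augmented objective, stop when it reaches
    ``spec.f_stop`` or the evaluation/time budget runs out.  The accepted
    trace is monotone nonincreasing; identical seeds give identical runs.
    """
    variables = SequenceVariables(spec)
    results = []
    for trial in range(trials):
        rng = np.random.default_rng((seed + 7919 * trial) % (2**31 - 1))
        cache = _QuantityCache(view, opt)
        assignment = _initial_assignment(variables, spec, rng)
        dom = variables.assignment_to_domains(assignment)
        report = evaluate_objective(
            spec, dom, view, opt, cap, cache, variables
        )
        best = (assignment, dom, report)
        evals = 1
        trace = [(evals, report.augmented)]
        t0 = time.monotonic()
        stall = 0
        mutable = [
            i
            for i, (_, allowed) in enumerate(variables.classes)
            if len(allowed) > 1
        ]
        while (
            best[2].augmented > spec.f_stop
            and evals < max_evals
            and time.monotonic() - t0 < max_time
            and mutable
        ):
            i = mutable[rng.integers(len(mutable))]
            allowed = sorted(variables.classes[i][1])
            cur = best[0][i]
            choices = [nt for nt in allowed if nt != cur]
            nt = choices[rng.integers(len(choices))]
            cand = list(best[0])
            cand[i] = nt
            cand_dom = variables.assignment_to_domains(cand)
            if check_hard_constraints(spec, cand_dom):
                continue
            cand_report = evaluate_objective(
                spec, cand_dom, view, opt, cap, cache, variables
            )
            evals += 1
            if cand_report.augmented < best[2].augmented - 1e-15:
                best = (cand, cand_dom, cand_report)
                trace.append((evals, cand_report.augmented))
                stall = 0
            else:
                stall += 1
                if stall > 50 * max(1, len(mutable)):
                    break  # converged short of the stop condition
        results.append(
            DesignResult(
                domains=best[1],
                strands={
                    s: strand_sequence(spec, best[1], s) for s in spec.strands
                },
                report=best[2],
                trace=trace,
                success=best[2].augmented <= spec.f_stop,
                evaluations=evals,
                seed=seed,
            )
        )
    return results
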