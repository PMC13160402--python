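"""Secondary structures of one or more interacting strands.

A secondary structure is a set of base pairs over the concatenated sequence of
a complex, together with the strand breaks (nicks).  Structures can be written
in three equivalent notations:

* dot-parens-plus: one character per base (``.`` unpaired, matched ``()`` for
  a pair) with ``+`` marking the nick between successive strands;
* run-length-encoded dot-parens-plus: any run of identical characters may be
  abbreviated as the character followed by its count;
* DU+: a duplex of ``n`` stacked pairs is ``Dn`` followed by the enclosed
  substructure (parenthesised when it has several elements), an unpaired run
  of ``n`` bases is ``Un``, and ``+`` is a nick.

Indices are 0-based over the concatenation; rendered output is 1-based only
where explicitly noted.  The polymer-graph view puts the strands around a
circle with a nick after the 3' end of every strand (so a single strand still
carries one nick); a structure is unpseudoknotted for a strand ordering when
no two pair chords cross on that circle.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Sequence as TSequence

import numpy as np

from .errors import StructureParseError

#: minimum number of unpaired nucleotides between the two partners of a pair
#: on the same strand (standard nearest-neighbor hairpin convention).  This is
#: enforced when *ensembles* are enumerated; the notation parsers accept any
#: geometrically consistent structure so that hand-written examples with
#: shorter hairpins remain representable.
MIN_HAIRPIN = 3


@dataclass(frozen=True)
class Structure:
    """A set of base pairs plus the strand partition of the concatenation.

    Parameters
    ----------
    pairs:
        frozenset of ``(a, b)`` index pairs with ``a < b``, 0-based over the
        concatenated sequence.
    strand_lengths:
        length of each strand in concatenation order.
    """

    pairs: frozenset
    strand_lengths: tuple

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        object.__setattr__(self, "strand_lengths", tuple(self.strand_lengths))
        if not self.strand_lengths or any(n <= 0 for n in self.strand_lengths):
            raise ValueError("strand lengths must be positive and nonempty")
        n = self.length
        seen = set()
        for a, b in self.pairs:
            if not (0 <= a < b < n):
                raise ValueError(f"pair ({a},{b}) out of range or not ordered")
            if a in seen or b in seen:
                raise ValueError(f"index in more than one pair: ({a},{b})")
            seen.add(a)
            seen.add(b)

    # -- geometry ---------------------------------------------------------

    @property
    def length(self) -> int:
        return sum(self.strand_lengths)

    @property
    def n_strands(self) -> int:
        return len(self.strand_lengths)

    @property
    def nicks(self) -> tuple:
        """Ascending indices of the last nucleotide of each strand."""
        out, tot = [], 0
        for n in self.strand_lengths:
            tot += n
            out.append(tot - 1)
        return tuple(out)

    def strand_of(self, a: int) -> int:
        tot = 0
        for k, n in enumerate(self.strand_lengths):
            tot += n
            if a < tot:
                return k
        raise IndexError(a)

    def partner(self, a: int) -> int | None:
        for x, y in self.pairs:
            if x == a:
                return y
            if y == a:
                return x
        return None

    def pair_map(self) -> dict:
        m = {}
        for a, b in self.pairs:
            m[a] = b
            m[b] = a
        return m

    def __str__(self):
        return write_structure(self, "dpp")


# ---------------------------------------------------------------------------
# parsing


def _parse_dpp(text: str) -> Structure:
    pairs, stack = [], []
    strand_lengths, cur = [], 0
    idx = 0
    for pos, ch in enumerate(text):
        if ch == ".":
            idx += 1
            cur += 1
        elif ch == "(":
            stack.append(idx)
            idx += 1
            cur += 1
        elif ch == ")":
            if not stack:
                raise StructureParseError("unbalanced ')'", pos)
            pairs.append((stack.pop(), idx))
            idx += 1
            cur += 1
        elif ch == "+":
            if cur == 0:
                raise StructureParseError("empty strand before '+'", pos)
            strand_lengths.append(cur)
            cur = 0
        else:
            raise StructureParseError(f"illegal character {ch!r}", pos)
    if stack:
        raise StructureParseError("unbalanced '('", len(text))
    if cur == 0:
        raise StructureParseError(
            "trailing '+' (empty final strand)" if text else "empty structure",
            len(text),
        )
    strand_lengths.append(cur)
    return Structure(frozenset(pairs), tuple(strand_lengths))


_RLE_TOKEN = re.compile(r"([.()+])(\d*)")


def _expand_rle(text: str) -> str:
    out, pos = [], 0
    for m in _RLE_TOKEN.finditer(text):
        if m.start() != pos:
            raise StructureParseError(f"illegal character {text[pos]!r}", pos)
        ch, count = m.group(1), m.group(2)
        n = int(count) if count else 1
        if n <= 0:
            raise StructureParseError("run count must be positive", m.start(2))
        out.append(ch * n)
        pos = m.end()
    if pos != len(text):
        raise StructureParseError(f"illegal character {text[pos]!r}", pos)
    return "".join(out)


_DU_TOKEN = re.compile(r"\s*(?:([DU])(\d+)|([+()]))")


def _du_to_dpp(text: str) -> str:
    tokens = []  # (kind, value, position)
    pos = 0
    while pos < len(text):
        m = _DU_TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise StructureParseError(
                f"illegal DU+ token at {text[pos:pos + 4]!r}", pos
            )
        if m.group(1):
            tokens.append((m.group(1), int(m.group(2)), m.start()))
        else:
            tokens.append((m.group(3), 0, m.start()))
        pos = m.end()

    def parse_one(i: int) -> tuple[str, int]:
        kind, val, tpos = tokens[i]
        if kind == "U":
            if val <= 0:
                raise StructureParseError("unpaired count must be positive", tpos)
            return "." * val, i + 1
        if kind == "+":
            return "+", i + 1
        if kind == "D":
            if val <= 0:
                raise StructureParseError("duplex count must be positive", tpos)
            # enclosed substructure: a parenthesised group or a single element
            if i + 1 < len(tokens) and tokens[i + 1][0] == "(":
                inner, j = parse_many(i + 2)
                if j >= len(tokens) or tokens[j][0] != ")":
                    raise StructureParseError("unclosed '(' in DU+ scope", tpos)
                j += 1
            elif i + 1 < len(tokens) and tokens[i + 1][0] not in ")":
                inner, j = parse_one(i + 1)
            else:
                inner, j = "", i + 1
            return "(" * val + inner + ")" * val, j
        raise StructureParseError("unexpected token", tpos)

    def parse_many(i: int) -> tuple[str, int]:
        parts = []
        while i < len(tokens) and tokens[i][0] != ")":
            part, i = parse_one(i)
            parts.append(part)
        return "".join(parts), i

    dpp, i = parse_many(0)
    if i != len(tokens):
        raise StructureParseError("unexpected ')'", tokens[i][2])
    return dpp


def _infer_notation(text: str) -> str:
    stripped = text.strip()
    if re.search(r"[DU]\d", stripped):
        return "du"
    if re.search(r"[.()+]\d", stripped):
        return "rle"
    return "dpp"


def parse_structure(text: str, notation: str = "auto") -> Structure:
    """Parse a structure from dot-parens-plus, RLE, or DU+ notation.

    ``notation='auto'`` infers the dialect: leading ``D``/``U`` tokens mean
    DU+, digits following symbols mean RLE, otherwise plain dot-parens-plus.
    """
    if not text or not text.strip():
        raise StructureParseError("empty structure text", 0)
    if notation == "auto":
        notation = _infer_notation(text)
    if notation == "dpp":
        return _parse_dpp(text.strip())
    if notation == "rle":
        return _parse_dpp(_expand_rle(text.strip()))
    if notation == "du":
        return _parse_dpp(_du_to_dpp(text))
    raise ValueError(f"unknown notation {notation!r}")


# ---------------------------------------------------------------------------
# writing


def _to_dpp(s: Structure) -> str:
    chars = ["."] * s.length
    for a, b in s.pairs:
        chars[a] = "("
        chars[b] = ")"
    out, idx = [], 0
    for n in s.strand_lengths:
        out.append("".join(chars[idx : idx + n]))
        idx += n
    return "+".join(out)


def _to_rle(s: Structure) -> str:
    dpp = _to_dpp(s)
    out = []
    for ch, grp in itertools.groupby(dpp):
        n = len(list(grp))
        out.append(ch if n == 1 else f"{ch}{n}")
    return "".join(out)


def _to_du(s: Structure) -> str:
    pm = s.pair_map()
    nick_after = set(s.nicks[:-1])  # internal nicks only; wrap nick is implicit

    def nick_between(a: int, b: int) -> bool:
        """True if a strand break separates adjacent indices a and b = a+1."""
        return a in nick_after

    def render(lo: int, hi: int) -> list:
        toks = []
        i = lo
        while i < hi:
            if i > lo and nick_between(i - 1, i):
                toks.append("+")
            j = pm.get(i)
            if j is None:
                run, i = 1, i + 1
                while i < hi and pm.get(i) is None and not nick_between(i - 1, i):
                    run += 1
                    i += 1
                toks.append(f"U{run}")
                continue
            # duplex: count consecutively stacked pairs with no intervening nick
            d = 1
            while (
                pm.get(i + d) == j - d
                and j - d > i + d
                and not nick_between(i + d - 1, i + d)
                and not nick_between(j - d, j - d + 1)
            ):
                d += 1
            inner = render(i + d, j - d + 1)
            # nicks sitting exactly at the enclosed region's boundaries are
            # not visible to the recursive call; emit them here
            if nick_between(i + d - 1, i + d):
                inner.insert(0, "+")
            if j - d >= i + d and nick_between(j - d, j - d + 1):
                inner.append("+")
            if not inner:
                # empty enclosed substructure needs an explicit scope so the
                # following element is not swallowed on re-parse
                toks.append(f"D{d} ()")
            elif len(inner) == 1:
                toks.append(f"D{d} {inner[0]}")
            else:
                toks.append(f"D{d} (" + " ".join(inner) + ")")
            i = j + 1
        return toks

    return " ".join(render(0, s.length))


def write_structure(s: Structure, notation: str = "dpp") -> str:
    """Render a structure in the requested notation; round-trips with
    :func:`parse_structure` for all three dialects."""
    if notation == "dpp":
        return _to_dpp(s)
    if notation == "rle":
        return _to_rle(s)
    if notation == "du":
        return _to_du(s)
    raise ValueError(f"unknown notation {notation!r}")


# ---------------------------------------------------------------------------
# matrix and polymer-graph predicates


def structure_matrix(s: Structure) -> np.ndarray:
    """0/1 structure matrix: S[a,b]=1 iff a·b paired, S[a,a]=1 iff a unpaired.

    Symmetric with unit row and column sums.
    """
    n = s.length
    S = np.zeros((n, n), dtype=np.int8)
    paired = set()
    for a, b in s.pairs:
        S[a, b] = S[b, a] = 1
        paired.add(a)
        paired.add(b)
    for a in range(n):
        if a not in paired:
            S[a, a] = 1
    return S


def is_unpseudoknotted(s: Structure) -> bool:
    """True iff no two pairs interleave (a < c < b < d) for the structure's
    strand ordering; equivalently the polymer graph has no crossing chords."""
    ps = sorted(s.pairs)
    for (a, b), (c, d) in itertools.combinations(ps, 2):
        if a < c < b < d:
            return False
    return True


def is_connected(s: Structure) -> bool:
    """True iff no subset of strands is unpaired to the rest (graph with
    strands as nodes and inter-strand pairs as edges is connected)."""
    L = s.n_strands
    if L == 1:
        return True
    adj = {k: set() for k in range(L)}
    for a, b in s.pairs:
        sa, sb = s.strand_of(a), s.strand_of(b)
        if sa != sb:
            adj[sa].add(sb)
            adj[sb].add(sa)
    seen, stack = {0}, [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == L


def rotate_structure(s: Structure, t: int) -> Structure:
    """Rotate the strand ordering by ``t`` strands (strand k becomes strand
    k - t mod L), remapping pair indices accordingly."""
    L = s.n_strands
    t %= L
    if t == 0:
        return s
    lengths = s.strand_lengths[t:] + s.strand_lengths[:t]
    starts_old = np.concatenate([[0], np.cumsum(s.strand_lengths)[:-1]])
    starts_new = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    idx_map = {}
    for k_old in range(L):
        k_new = (k_old - t) % L
        for o in range(s.strand_lengths[k_old]):
            idx_map[starts_old[k_old] + o] = starts_new[k_new] + o
    pairs = frozenset(
        tuple(sorted((idx_map[a], idx_map[b]))) for a, b in s.pairs
    )
    return Structure(pairs, tuple(lengths))


def rotational_symmetry(s: Structure, species: TSequence[str]) -> int:
    """Largest R such that rotating the polymer graph by L/R strands maps
    every strand onto a strand of the same species and pairs onto pairs.

    R divides L and is 1 whenever all species are distinct.
    """
    L = s.n_strands
    if len(species) != L:
        raise ValueError("one species label per strand required")
    best_t = L  # rotation by L = identity
    for t in range(1, L):
        if any(species[k] != species[(k + t) % L] for k in range(L)):
            continue
        if any(
            s.strand_lengths[k] != s.strand_lengths[(k + t) % L]
            for k in range(L)
        ):
            continue
        if rotate_structure(s, t).pairs == s.pairs:
            best_t = t
            break
    return L // best_t


def canonical_rotation(ordering: TSequence[str]) -> tuple:
    """Lexicographically smallest rotation of a strand ordering (the
    deterministic necklace representative)."""
    word = tuple(ordering)
    return min(word[i:] + word[:i] for i in range(len(word)))


def enumerate_strand_orderings(
    species_multiset: TSequence[str], distinct_only: bool = True
) -> list:
    """Strand orderings of a multiset of species around the polymer circle.

    With ``distinct_only`` (the physical convention for complex species), one
    representative per cyclic-rotation equivalence class is returned, each the
    lexicographically smallest rotation; otherwise all distinct linear
    arrangements.  Output is sorted for determinism.
    """
    if not species_multiset:
        raise ValueError("empty species multiset")
    perms = set(itertools.permutations(species_multiset))
    if not distinct_only:
        return sorted(perms)
    return sorted({canonical_rotation(p) for p in perms})
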