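"""Toy free-energy parameter sets.

These are artifact-defined parameter sets with physically plausible magnitudes
(stacks of roughly -1 to -2.5 kcal/mol at 37 C, GC-rich contexts stronger than
AU-rich ones, positive loop-initiation penalties that grow logarithmically
with loop size).  They are complete over their declared material scope so that
every lookup the model can make succeeds, and they are deterministic functions
of the seed.  They do not reproduce any published nearest-neighbor set; users
with transcribed published tables can load them through the same JSON dialect.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .model import ParameterSet, _coax_key, valid_pair, _BASES, MATERIALS


def _gc_count(pair: tuple) -> int:
    return sum(1 for nt in pair if nt[1] in "GC")


def toy_parameter_set(
    materials: tuple = ("r",), seed: int = 0, name: str | None = None
) -> ParameterSet:
    """Build a complete toy parameter set over the given material scope.

    Values at T_ref = 310.15 K; enthalpies are chosen so that duplexes melt
    with temperature (dH roughly 5x the stack free energy).
    """
    rng = np.random.default_rng(seed)
    alphabet = [m + b for m in materials for b in _BASES[m]]
    pairs = []
    for a, b in itertools.product(alphabet, repeat=2):
        try:
            if valid_pair(a, b):
                pairs.append((a, b))
        except Exception:
            continue

    def jitter(scale=0.15):
        return float(rng.uniform(-scale, scale))

    tables: dict = {}

    stack = {}
    for (a, b), (c, d) in itertools.product(pairs, repeat=2):
        dg = -(0.6 + 0.65 * _gc_count((a, b)) + 0.65 * _gc_count((c, d))) + jitter()
        stack[f"{a}{c}/{d}{b}"] = (round(dg, 3), round(5.0 * dg, 3))
    tables["stack"] = stack

    terminalbp = {}
    for a, b in pairs:
        dg = 0.1 if _gc_count((a, b)) == 2 else 0.45
        terminalbp[f"{a}{b}"] = (round(dg + jitter(0.05), 3), 3.0)
    tables["terminalbp"] = terminalbp

    coaxial = {}
    for (a, b), (c, d) in itertools.product(pairs, repeat=2):
        key = _coax_key(f"{a}{b}", f"{c}{d}")
        if key in coaxial:
            continue
        dg = -(1.0 + 0.45 * _gc_count((a, b)) + 0.45 * _gc_count((c, d))) + jitter()
        coaxial[key] = (round(dg, 3), round(5.0 * dg, 3))
    tables["coaxial"] = coaxial

    for side, strength in (("dangle5", 0.35), ("dangle3", 0.5)):
        tab = {}
        for (a, b), x in itertools.product(pairs, alphabet):
            dg = -(strength + 0.15 * _gc_count((a, b)) + (0.1 if x[1] in "GC" else 0.0))
            tab[f"{a}{b}:{x}"] = (round(dg + jitter(0.05), 3), round(4.0 * dg, 3))
        tables[side] = tab

    tables["hairpin_size"] = {
        str(n): (round(4.6 + 1.6 * math.log(n / 3.0), 3), 0.5)
        for n in range(3, 31)
    }
    tables["interior_size"] = {
        str(n): (round(3.4 + 1.5 * math.log(n / 2.0), 3), 0.0)
        for n in range(2, 31)
    }
    tables["bulge_size"] = {
        str(n): (round(3.6 + 1.5 * math.log(n), 3), 0.0) for n in range(1, 31)
    }

    scalars = {
        "multiloop_init": (3.2, 0.0),
        "multiloop_bp": (0.4, 0.0),
        "multiloop_nt": (0.25, 0.0),
        "interior_asym_per_nt": (0.45, 0.0),
        "interior_asym_max": (3.0, 0.0),
        "assoc": (1.96, 0.0),
    }

    salt = {"sodium": 1.0, "magnesium": 0.0}
    if name is None:
        name = "toy-" + "".join(MATERIALS[m][0].lower() for m in materials) + f"-{seed}"
    return ParameterSet(
        name=name,
        materials=tuple(materials),
        T_ref=310.15,
        salt=salt,
        tables=tables,
        scalars=scalars,
    )
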