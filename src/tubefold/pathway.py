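"""Reaction-pathway to multitube design-ensemble construction.

A reaction pathway lists elementary steps (step 0 being formation of the
initial reactants); each step names its reactant and product complexes.  For
N orthogonal systems of an M-step pathway the builder emits one elementary
step tube per (system, step) pair plus a single global crosstalk tube:
|Omega| = N (M + 1) + 1 target test tubes.

Elementary step tube (n, m): on-targets are the step's products at the target
concentration; off-targets are every complex of the tube's strands up to
L_max, excluding other on-pathway multi-strand complexes that are neither
products nor reactants of the step (so reactants remain as off-targets and
the tube designs for full conversion, while cognate products of other steps
are omitted entirely).

Global crosstalk tube: on-targets are the reactive species - every step
product except complexes formed by association of two or more reactants of
their step (those cognate products are omitted from the ensemble entirely);
off-targets are all remaining complexes of the reactive strands up to L_max.
Any species can then either stay unreacted (on-target) or undergo crosstalk
(off-target).
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import DesignSpec, DesignTube, Domain, TargetComplex
from .errors import ConstraintError


@dataclass
class PathwayStep:
    """One elementary step: reactants -> products (complex names).  Step 0
    has no reactants (it forms the initial species)."""

    products: tuple
    reactants: tuple = ()

    def __post_init__(self):
        if not self.products:
            raise ConstraintError("an elementary step must name products")


def on_pathway_complexes(steps) -> list:
    """Distinct on-pathway complexes, in first-appearance order."""
    seen, out = set(), []
    for step in steps:
        for name in step.products:
            if name not in seen:
                seen.add(name)
                out.append(name)
    return out


def _association_products(steps, complexes) -> set:
    """Products formed by association of >= 2 reactants of their step: the
    cognate products omitted from the global crosstalk tube."""
    omitted = set()
    for step in steps:
        if not step.reactants:
            continue
        reactant_strands = [
            set(complexes[r].strand_names) for r in step.reactants
        ]
        for pname in step.products:
            strands = set(complexes[pname].strand_names)
            if not any(strands <= rs for rs in reactant_strands):
                omitted.add(pname)
    return omitted


def _suffix(name: str, n: int, N: int) -> str:
    return name if N == 1 else f"{name}~{n}"


def build_multitube_spec(
    domains: list,
    strands: dict,
    complexes: dict,
    steps: list,
    N: int = 1,
    L_max_offtargets: int = 2,
    y_target: float = 1e-8,
    f_stop: float = 0.02,
    materials: tuple = ("r",),
    hard=None,
    soft=None,
) -> DesignSpec:
    """Assemble the multitube design ensemble for N orthogonal systems.

    ``steps[0]`` is Step 0 (initial reactants); every product complex must
    carry a target structure.  Returns a DesignSpec with
    N*(len(steps)) elementary-step tubes (steps includes step 0) plus one
    global crosstalk tube.
    """
    for step in steps:
        for name in list(step.products) + list(step.reactants):
            if name not in complexes:
                raise ConstraintError(f"unknown complex {name!r} in pathway")
    for name in on_pathway_complexes(steps):
        if complexes[name].structure is None:
            raise ConstraintError(
                f"on-pathway complex {name!r} needs a target structure"
            )

    on_pathway = on_pathway_complexes(steps)
    omitted_global = _association_products(steps, complexes)

    all_domains, all_strands, all_complexes = [], {}, {}
    for n in range(1, N + 1):
        for d in domains:
            all_domains.append(Domain(_suffix(d.name, n, N), d.codes))
        for sname, doms in strands.items():
            all_strands[_suffix(sname, n, N)] = tuple(
                _suffix(d[:-1], n, N) + "*" if d.endswith("*") else _suffix(d, n, N)
                for d in doms
            )
        for cname, c in complexes.items():
            all_complexes[_suffix(cname, n, N)] = TargetComplex(
                _suffix(cname, n, N),
                tuple(_suffix(s, n, N) for s in c.strand_names),
                c.structure,
            )

    tubes = []
    for n in range(1, N + 1):
        for m, step in enumerate(steps):
            on = {
                _suffix(p, n, N): y_target for p in step.products
            }
            allowed = set(step.products) | set(step.reactants)
            exclude = [
                all_complexes[_suffix(c, n, N)].strand_names
                for c in on_pathway
                if c not in allowed
                and len(complexes[c].strand_names) > 1
            ]
            tubes.append(
                DesignTube(
                    name=_suffix(f"step{m}", n, N),
                    on_targets=on,
                    L_max=L_max_offtargets,
                    exclude=tuple(tuple(e) for e in exclude),
                )
            )

    # global crosstalk tube over all systems
    global_on = {}
    global_exclude = []
    for n in range(1, N + 1):
        for c in on_pathway:
            if c in omitted_global:
                global_exclude.append(
                    all_complexes[_suffix(c, n, N)].strand_names
                )
            else:
                global_on[_suffix(c, n, N)] = y_target
    tubes.append(
        DesignTube(
            name="crosstalk",
            on_targets=global_on,
            L_max=L_max_offtargets,
            exclude=tuple(tuple(e) for e in global_exclude),
        )
    )

    return DesignSpec(
        domains=all_domains,
        strands=all_strands,
        complexes=all_complexes,
        tubes=tubes,
        hard=list(hard or []),
        soft=list(soft or []),
        f_stop=f_stop,
        materials=tuple(materials),
    )
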