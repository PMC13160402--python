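"""Deterministic fixture generation.

Produces, from a single seed: two toy parameter sets (RNA-only and mixed
RNA/DNA), a corpus of random sequences with random member structures of
their enumerated ensembles, and the worked two-step conditional-RNA pathway
specification (shape transduction: input X displaces A from A·B, releasing B
to assemble with C) with small toy domains so every on-pathway complex stays
within the enumeration cap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .design import DesignSpec, Domain, TargetComplex
from .ensemble import ComplexSpec, enumerate_ensemble
from .model import ParameterSet, sequence_to_text
from .pathway import PathwayStep, build_multitube_spec
from .structures import Structure, parse_structure, write_structure
from .toyparams import toy_parameter_set

_BASES = "ACGU"


@dataclass
class FixtureBundle:
    params_rna: ParameterSet
    params_mixed: ParameterSet
    corpus: list  # (name, ComplexSpec, Structure)
    pathway_spec: DesignSpec
    seed: int


def random_complex(rng, n_strands: int = 1, length_range=(5, 12)) -> ComplexSpec:
    """Random RNA complex spec with the given strand count."""
    seqs, names = [], []
    for k in range(n_strands):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seqs.append(tuple("r" + _BASES[i] for i in rng.integers(0, 4, n)))
        names.append(chr(ord("A") + k))
    return ComplexSpec(tuple(names), tuple(seqs))


def random_structures(rng, spec: ComplexSpec, count: int = 1) -> list:
    """Uniformly random members of the complex's enumerated ensemble."""
    gamma = enumerate_ensemble(spec)
    if not gamma:
        return []
    idx = rng.integers(0, len(gamma), count)
    return [gamma[i] for i in idx]


def scrna_pathway_steps():
    """Two-step conditional-RNA pathway: Step 1: X + A·B -> X·A + B;
    Step 2: B + C -> B·C; Step 0 forms the initial reactants X, A·B, C."""
    return [
        PathwayStep(products=("X", "AB", "C")),
        PathwayStep(products=("XA", "B"), reactants=("X", "AB")),
        PathwayStep(products=("BC",), reactants=("B", "C")),
    ]


def scrna_design_spec(N: int = 1, f_stop: float = 0.05) -> DesignSpec:
    """The conditional-RNA pathway with 4-nt toy domains a, b, c, w.

    X = a-b-c detects the input; A = c*-b*-a* with A·B presenting toehold
    a*; displacement yields fully paired X·A and free B = b-c-w, which then
    assembles with C = w*-c* into the output duplex B·C.
    """
    domains = [
        Domain("a", "NNNN"),
        Domain("b", "NNNN"),
        Domain("c", "NNNN"),
        Domain("w", "NNNN"),
    ]
    strands = {
        "X": ("a", "b", "c"),
        "A": ("c*", "b*", "a*"),
        "B": ("b", "c", "w"),
        "C": ("w*", "c*"),
    }
    complexes = {
        "X": TargetComplex("X", ("X",), parse_structure("............")),
        "AB": TargetComplex(
            "AB", ("A", "B"), parse_structure("((((((((....+))))))))....")
        ),
        "C": TargetComplex("C", ("C",), parse_structure("........")),
        "XA": TargetComplex(
            "XA", ("X", "A"), parse_structure("((((((((((((+))))))))))))")
        ),
        "B": TargetComplex("B", ("B",), parse_structure("............")),
        "BC": TargetComplex(
            "BC", ("B", "C"), parse_structure("....((((((((+))))))))")
        ),
    }
    return build_multitube_spec(
        domains, strands, complexes, scrna_pathway_steps(), N=N,
        L_max_offtargets=2, y_target=1e-8, f_stop=f_stop,
    )


def generate_fixtures(seed: int = 0) -> FixtureBundle:
    """Deterministic fixture bundle for a seed."""
    rng = np.random.default_rng(seed)
    corpus = []
    k = 0
    while len(corpus) < 20:
        n_strands = 1 if k % 3 else 2
        spec = random_complex(rng, n_strands, (4, 9) if n_strands == 2 else (5, 12))
        structs = random_structures(rng, spec, 1)
        k += 1
        if structs:
            corpus.append((f"fix{len(corpus)}", spec, structs[0]))
    return FixtureBundle(
        params_rna=toy_parameter_set(("r",), seed=seed),
        params_mixed=toy_parameter_set(("r", "d"), seed=seed),
        corpus=corpus,
        pathway_spec=scrna_design_spec(),
        seed=seed,
    )


def write_fixtures(bundle: FixtureBundle, out_dir) -> None:
    """Write the bundle as plain-text files that re-read through the public
    readers."""
    from .model import save_parameters

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_parameters(bundle.params_rna, out / "toy_rna.json")
    save_parameters(bundle.params_mixed, out / "toy_rna_dna.json")
    with open(out / "corpus.tsv", "w") as fh:
        fh.write("name\tstrands\tsequences\tstructure\n")
        for name, spec, s in bundle.corpus:
            fh.write(
                f"{name}\t{','.join(spec.names)}\t"
                f"{','.join(sequence_to_text(q) for q in spec.seqs)}\t"
                f"{write_structure(s, 'dpp')}\n"
            )
    spec = bundle.pathway_spec
    payload = {
        "domains": {d.name: d.codes for d in spec.domains},
        "strands": {k: list(v) for k, v in spec.strands.items()},
        "complexes": {
            k: {
                "strands": list(c.strand_names),
                "structure": write_structure(c.structure, "dpp")
                if c.structure
                else None,
            }
            for k, c in spec.complexes.items()
        },
        "tubes": [
            {
                "name": t.name,
                "on_targets": t.on_targets,
                "L_max": t.L_max,
                "exclude": [list(e) for e in t.exclude],
            }
            for t in spec.tubes
        ],
        "f_stop": spec.f_stop,
    }
    (out / "scrna_pathway.json").write_text(json.dumps(payload, indent=1))
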