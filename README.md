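# tubefold

Exact thermodynamic analysis and ensemble-defect sequence design for
multistranded nucleic-acid systems at desk scale.

`tubefold` is for researchers in nucleic-acid nanotechnology, molecular
programming, and synthetic biology who need to reason about what a set of
interacting DNA/RNA strands does at equilibrium: which complexes form, at
what concentrations, with what base-pairing — and, in the inverse direction,
which sequences make an intended structure and reaction pathway dominate.
Everything is computed by **exhaustive enumeration** of the complex ensemble
(within a configurable length cap, default 30 nt), so every reported number
is exact for the loop-based free-energy model in use.  That makes the
package a reference implementation for validating faster dynamic-programming
engines, for teaching, and for small-system design studies.

## The model

A secondary structure `s` of strands ordered around a polymer-graph circle
is a set of base pairs; its free energy is a sum over the faces (loops) of
the graph plus a strand-association penalty,

    ΔḠ(φ, s) = (L − 1) ΔG_assoc + Σ_loop ΔG(loop),

with hairpin, interior, multiloop, and exterior (nick-containing) loop types.
Multiloops and exterior loops carry a Boltzmann-weighted subensemble of
coaxial and dangle stacking states:

    ΔG_stacking = −kT log Σ_ω Π_{x∈ω} e^(−ΔG_x / kT).

Structures with an R-fold rotational symmetry get ΔG = ΔḠ + kT log R when
strands of a species are treated as indistinguishable.  On top of the energy
model the package computes, per complex,

    Q(φ)  = Σ_{s∈Γ} e^(−ΔG(φ,s)/kT)          partition function
    ΔG(φ) = −kT log Q(φ)                      complex free energy
    P̄_ab  = Σ_s p̄(s) S_ab(s)                  pair-probability matrix
    n(φ, s_target) = |φ| − ⟨P̄, S(s_target)⟩   complex ensemble defect

plus the MFE proxy structure (the structure containing the minimum-energy
stacking state), suboptimal structures within an energy gap, and Boltzmann
samples.  For a dilute test tube, equilibrium complex concentrations solve
the strictly convex program `min Σ_j x_j (log x_j − log Q_j − 1)` subject to
strand conservation `A x = x⁰`, solved here by damped Newton in the dual.
Sequence design minimizes the multitube ensemble defect
`M = (1/|Ω|) Σ_h C_h / y_h^nt` — the average fraction of wrongly paired
nucleotides over a set of target test tubes — under hard sequence
constraints, with optional weighted soft-constraint penalties.

Free energies are in kcal/mol (k = 0.0019872041 kcal/mol/K), temperatures in
kelvin internally, concentrations in molar.  Parameter sets are JSON files
of (ΔG at T_ref, ΔH) entries; two complete toy sets ship with the package
(see `docs/methods.md` — published nearest-neighbor tables can be
transcribed into the same dialect).

## Worked example

```python
from tubefold import (ComplexSpec, analyze_complex, parameters_at_temperature,
                      parse_sequence, toy_parameter_set, write_structure)

view = parameters_at_temperature(toy_parameter_set(), 310.15)   # 37 C
spec = ComplexSpec(("A",), (parse_sequence("GGGAAAACCC"),))
res = analyze_complex(spec, view)
print(round(res.Q, 4), round(res.dG_complex, 4))
print(write_structure(res.mfe_structure), round(res.mfe_energy, 4))
print(res.n_structures, res.n_stacking_states)
```

prints

```
6.2225 -1.1268
(((....))) -0.916
20 43
```

Q = 6.2225 is the Boltzmann-weighted size of the 20-structure ensemble
(43 stacking states); the complex free energy −1.1268 kcal/mol is below the
MFE proxy's −0.916 kcal/mol, as it must be — the whole ensemble is always at
least as stable as its best single structure.  The hairpin closing pair
forms with probability `res.pair_probabilities[0, 9] ≈ 0.712`.

The `examples/` directory holds one short script per capability: structure
notations (dot-parens-plus, run-length-encoded, DU+), complex analysis,
test-tube concentrations with a melt profile, stem-loop design under
pattern/diversity constraints, and multitube construction for a two-step
strand-displacement cascade (`|Ω| = N(M+1)+1` tubes).  A thin CLI mirrors
the library: `tubefold struct`, `tubefold analyze complex`,
`tubefold analyze tube` (with `--melt`), `tubefold design`,
`tubefold fixtures`.

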