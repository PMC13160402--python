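"""Multitube design ensemble for a two-step hybridization cascade.

Input X (= a-b-c) displaces A from the scRNA-style duplex A·B (step 1),
releasing B to assemble with C into the output duplex B·C (step 2).  The
builder emits one tube per elementary step (step 0 = formation of the
initial reactants) plus a global crosstalk tube: |Omega| = N(M+1)+1.
"""

from tubefold.fixtures import scrna_design_spec, scrna_pathway_steps
from tubefold.pathway import on_pathway_complexes

steps = scrna_pathway_steps()
print("on-pathway complexes:", on_pathway_complexes(steps))

for N in (1, 8):
    spec = scrna_design_spec(N=N)
    print(f"\nN = {N} orthogonal systems -> |Omega| = {len(spec.tubes)} tubes")
    if N == 1:
        for tube in spec.tubes:
            print(f"  {tube.name:10s} on-targets: {sorted(tube.on_targets)}"
                  f"  excluded: {[ '·'.join(e) for e in tube.exclude ]}")
# the step-0 tube excludes the cognate product of step 1 (X·A) so that X,
# A·B and C are forced to either stay well-formed or reveal crosstalk; the
# global crosstalk tube omits both association products (X·A and B·C)
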