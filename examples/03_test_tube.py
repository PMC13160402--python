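"""Equilibrium concentrations in a dilute test tube, plus a melt profile.

Two complementary strands at 1 uM partition among monomers and dimers; the
convex concentration program is solved in its dual form.  Raising the
temperature melts the duplex, which shows up as a growing fraction of
unpaired bases.
"""

from tubefold import (
    fraction_unpaired,
    generate_complexes,
    pair_probability_matrix,
    parameters_at_temperature,
    parse_sequence,
    partition_function,
    solve_concentrations,
    toy_parameter_set,
    TubeSpec,
)
from tubefold.structures import canonical_rotation

params = toy_parameter_set()
strands = {"B": parse_sequence("GGGGG"), "C": parse_sequence("CCCCC")}
tube = TubeSpec(strands, {"B": 1e-6, "C": 1e-6}, generate_complexes(strands, 2))

for T_c in (25, 37, 55, 70):
    view = parameters_at_temperature(params, T_c + 273.15)
    Q = {canonical_rotation(c.names): partition_function(c, view)
         for c in tube.complexes}
    sol = solve_concentrations(tube, Q, T=view.T)
    P = {key: pair_probability_matrix(c, view)
         for c in tube.complexes
         for key in [canonical_rotation(c.names)] if Q[key] > 0}
    fu = fraction_unpaired(tube, sol, P)
    duplex = sol.concentration(("B", "C"))
    print(f"T = {T_c:2d} C: [B·C] = {duplex:.3e} M, "
          f"fraction unpaired = {fu:.3f}")
# the duplex concentration falls and the unpaired fraction rises with T:
# a melt curve computed point by point from exact ensemble quantities
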