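# Methods

## Ensembles and the enumeration engine

For a strand ordering π around the polymer-graph circle, the complex
ensemble contains every connected, unpseudoknotted, pair-admissible
secondary structure of the concatenation.  `tubefold` enumerates this set
exhaustively by recursive generation of non-crossing matchings, then filters
for connectivity.  Two views are kept:

* **Γ̄** — all strands distinct.  Used for pair probabilities, the MFE proxy
  search, suboptimal structures, and the complex ensemble defect.
* **Γ** — strands of the same species indistinguishable: one representative
  per class of structures related by a species-preserving rotation, with the
  symmetry correction +kT log R added to each structure's free energy.  Used
  for the partition function, structure probabilities, and Boltzmann
  sampling.

The two views intentionally answer different questions (a pair probability
is a per-position observable of labeled strands; a partition function is a
property of the physical, label-free complex), so quantities computed over
Γ̄ and Γ are not interconverted.

Enumeration is capped at 30 nt total per complex by default (configurable);
exceeding the cap raises an error rather than truncating.  Pair
admissibility requires a valid Watson–Crick/wobble pair for the two
materials and at least 3 unpaired nucleotides between partners on the same
strand.  The minimum-hairpin rule is enforced at enumeration (and therefore
everywhere physical quantities are computed), while the notation parsers
accept any geometrically consistent pair set, so textbook examples with
shorter hairpins remain representable; size tables clamp to their tabulated
range if such a structure is evaluated directly.

## Loop model conventions

Loops are the faces of the polymer graph: a structure with p pairs has
p + 1 faces.  The circle carries one nick per strand (a single strand has
one, between its 3' and 5' ends), so the top-level face is always an
exterior loop.  A consequence worth stating explicitly: a two-strand duplex
such as `((+))` decomposes into one stack loop and **two** exterior loops,
each charging its closing pair's terminal penalty — the standard
nearest-neighbor treatment of a duplex with two helix ends.

Loop energies: hairpins use a size table plus the terminal-pair penalty;
interior loops use a size table plus an asymmetry penalty (linear per
unpaired-count difference, capped) plus both terminal penalties, with stack
loops a pure nearest-neighbor table lookup and bulges a separate size table;
multiloops use init/per-pair/per-nucleotide penalties plus terminal
penalties; exterior loops sum terminal penalties.  An unpaired strand is
the zero reference state.

### Stacking subensembles

Within each multiloop and exterior loop, stacking states are enumerated
exactly: a pair may coaxially stack with one adjacent pair (adjacency =
consecutive elements on the face walk; **a nick does not block a coaxial
stack**) or carry a dangle stack with at most two adjacent unpaired bases;
an unpaired base dangles on at most one pair, and requires direct backbone
adjacency (no intervening nick).  A two-sided dangle on one pair is a single
stacking state; its energy is the terminal-mismatch table entry when that
optional table is present, otherwise the sum of the 5' and 3' dangle terms.
The loop's stacking bonus is −kT log Σ_states exp(−ΔG_state/kT), which is
≤ 0 because the no-stack state contributes 1.  Four ensemble options select
which stack kinds are enumerable: `all` (default), `coaxial`, `dangle`,
`none`.  The per-structure Boltzmann sum over enumerated stacking states
reproduces the per-loop-bonus energy to ≤ 1e−9 kcal/mol (tested), and the
MFE proxy is found as the structure whose cheapest stacking state (fixed
loop terms + per-loop minima) is globally minimal, with ties broken toward
the lexicographically smallest structure matrix.

## Parameters and temperature

Parameter files are JSON: tables of `context -> [ΔG(T_ref), ΔH]` plus
scalars, validated for referential completeness at load (every valid pair,
stack, coaxial, and dangle context over the declared materials must be
present; a missing context at lookup is an error, never a silent zero).
Values at temperature T follow the two-point extrapolation
ΔG(T) = ΔH − T(ΔH − ΔG_ref)/T_ref.  Supported range 273–373 K.

The shipped toy sets (deterministic functions of a seed; defaults fixed
once) use physically plausible magnitudes: stacks −0.45 to −2 kcal/mol
biased stronger for GC-containing pairs with ΔH = 5·ΔG so duplexes melt
with temperature; positive logarithmic loop-size penalties; a +1.96
kcal/mol strand-association penalty; coaxial stacks somewhat stronger than
dangles.  They reproduce no published parameter set; transcribed published
tables load through the same dialect.  Salt concentrations are metadata
validated against per-material ranges; no salt correction is applied unless
a parameter file supplies a correction table.

## Test-tube equilibrium

Complex concentrations minimize Σ_j x_j(log x_j − log Q_j − 1) subject to
A x = x⁰ (mole fractions).  The solver runs damped Newton on the strand
chemical potentials λ (x_j = exp(log Q_j + Σ_i A_ij λ_i)), initialized from
the ideal monomer distribution, with backtracking on the residual norm;
convergence at max-norm mass-conservation residual ≤ 1e−12 relative to the
largest strand total (typically 4–8 iterations).  Molar inputs/outputs are
converted through the molarity of water from the Kell density polynomial
(55.138 M at 310.15 K).  Complexes whose ensemble is empty (no connected
structure can form, Q = 0) are carried at zero concentration.  Re-solving
for new strand totals reuses cached partition functions.

Tube observables: the fraction of unpaired bases is the concentration
weighted average of the pair-probability diagonals over all bases of all
complexes (numerator and denominator both in base concentration).  The
ensemble pair-fraction matrix over distinct bases is **row-species
normalized**: entry [(A,a),(B,b)] is the fraction of A strands whose base a
pairs b of B.  Rows always sum to 1; columns sum to 1 only when strand
totals are equal (with unequal totals, the same physical pair is a larger
fraction of the scarcer species, and no single normalization can make both
sums unity — the package keeps the physically interpretable row convention
and documents it here).

The tube ensemble defect is Σ over on-targets of
n_j·min(x_j, y_j) + |φ_j|·max(y_j − x_j, 0) (structural + concentration
parts), normalized by y^nt = Σ |φ_j| y_j; off-targets contribute through
mass conservation only.

## Design

The multitube objective is M = (1/|Ω|) Σ_h M_h, augmented with weighted
soft-constraint penalties; the optimizer is a seeded greedy descent:

* Variables: every domain position, merged by match/complementarity
  constraints and by on-target base pairs (which imply Watson–Crick
  complementarity) into classes via union–find with complement parity,
  each class carrying the intersection of its members' degenerate-code
  sets.  An empty intersection or an inconsistent parity cycle is reported
  as infeasible at construction.
* Initialization: rejection sampling of random class assignments against
  the full hard-constraint set.
* Moves: mutate one class (so a base and all its matched/complement
  partners change together) to another allowed nucleotide; reject hard
  constraint violations; accept on strict decrease of the augmented
  objective.  The accepted trace is therefore monotone nonincreasing, and
  runs are reproducible per seed.  Termination: objective ≤ f_stop, an
  evaluation/time budget, or a stall heuristic.
* Evaluation is exact: each tube's complexes are enumerated, partition
  functions and pair probabilities computed, concentrations solved, and
  defects assembled; per-complex quantities are cached on the concrete
  sequences so mutations that do not touch a complex cost nothing.

Wobble mutations: the flag is accepted, and complementarity *checking* can
allow wobble pairs, but mutation proposals keep Watson–Crick lockstep
between paired classes; designs that should exploit G·U wobble must encode
it in the degenerate codes.  This is a known simplification.

Soft-constraint normalizations (each f_k ∈ [0,1]): pattern — occurrences
over scanned windows; similarity — deviation from the allowed fractional
band over its maximum attainable value; symmetry — fraction of length-w
words that repeat, meet an unintended reverse complement (aligned positions
not complement-linked in the variable model), or are self-complementary;
energy match — maximum duplex ΔG deviation from the reference (or mutual
mean) over max(1 kcal/mol, |reference|), clamped to 1.  Defect weights
compose multiplicatively tube × complex (strand/domain weights are accepted
in the schema but currently applied at complex granularity); with unit
weights the weighted objective equals M exactly.

### Pathway tubes

For an M-step pathway replicated over N systems the builder emits
N(M+1) elementary-step tubes plus one global crosstalk tube.  Step tubes
keep their own reactants in the ensemble as off-targets (designing for full
conversion) and exclude every other multi-strand on-pathway complex (the
worked two-step cascade's step-0 tube excludes X·A).  The global crosstalk
tube's on-targets are the reactive species — step products not formed by
association of two or more reactants of their step — and it omits the
association products (X·A, B·C) entirely, so every species either stays
unreacted or reveals crosstalk.  The general construction rule is not fully
specified by the worked example; the convention above (association-product
detection via reactant strand-set coverage) is this package's choice and is
exercised by the tests.

## Problem sizes and what the tests show

The shipped studies run at desk scale: complexes ≤ 30 nt, random fixture
corpora of 20–100 complexes at 4–12 nt (1–2 strands), a 16-nt stem-loop
design, and the 4-domain × 4-nt cascade.  The toy parameter sets are
complete and plausible but synthetic, so passing tests demonstrate the
correctness of the machinery (enumeration, energies, convex solving,
design descent) — not agreement with experimental melting data, which
would require transcribing a published parameter set into the JSON dialect.
Known limitations: no pseudoknot energetics, no dynamic-programming fast
path (enumeration is the engine and the spec of correctness), no salt
correction formulas, historical approximate-dangle modes not implemented.
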