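# Methods

This note documents the models implemented in `emcharge`, the numerical
choices behind them, and what the synthetic test fixtures do and do not
establish about real molecules.

## The charge model families

All methods assign one real number per atom (elementary-charge units) from
atomic parameters plus molecular topology (2D methods) or geometry (3D
methods). No electronic-structure calculation is involved; accuracy is
inherited from the reference data the parameter sets were fitted to.

### Electronegativity equalization (EEM, SFKEEM, QEq, EQeq, EQeq+C)

At equilibrium all atoms share one molecular electronegativity χ̄. With a
quadratic energy per atom this gives the bordered linear system

```
[ M   -1 ] [ q ]   [ -A ]        M_ii = hardness-like diagonal
[ 1    0 ] [ χ̄ ] = [  Q ]        M_ij = interaction kernel K(R_ij)
```

solved once, dense, per molecule. The N×N block is symmetric; the last row
enforces Σq = Q. Method kernels:

| method | diagonal | off-diagonal | right-hand side |
|---|---|---|---|
| EEM    | B_i      | κ / R_ij                          | −A_i |
| SFKEEM | 2 B_i    | 2 √(B_i B_j) · sech(σ R_ij)       | −A_i |
| QEq    | J_i      | k_e / √(R² + a_ij²)               | −χ_i |
| EQeq   | J_i      | k_e / √(R² + a_ij²)               | −χ_i |

with k_e = 14.399645 eV·Å/e². For QEq/EQeq the screening length
a_ij = 2 k_e/(J_i + J_j) matches the contact limit K(0) = (J_i+J_j)/2 and
decays to the bare Coulomb tail k_e/R — an Ohno-type closure chosen here in
place of the original Slater-overlap integrals; it preserves every property
the rest of the pipeline relies on (symmetry, positive screening, Coulomb
tail). EQeq's χ = (IP+EA)/2 and J = IP−EA come from tabulated first
ionization energies and electron affinities. EQeq+C adds an antisymmetric
per-bond correction D(element pair, bond order) after the solve; it
preserves Σq exactly and reduces to EQeq when the correction table is empty.

QEq treats hydrogen self-consistently: J_H(q) = J_H⁰ (1 + q_H), floored at
0.1 J_H⁰. The outer loop re-assembles and re-solves at the previous iterate
(damped fixed point, initial mixing 0.5, halved whenever the step grows,
tolerance 1e-8 e, cap 50 iterations). The tolerance is deliberately tighter
than the charge precision anyone uses because the equalization certificate
(below) maps charge error through dχ/dq ≈ J ≈ 14 eV/e. Molecules without
hydrogen converge in one iteration.

Diagnostics: `effective_electronegativities` recomputes χ_i(q) for a
returned solution; its spread around χ̄ ("equalization certificate") is at
machine precision for the linear methods and below 1e-6 for QEq.

### Iterative transfer schemes (PEOE, GDAC)

PEOE iterates charge transfer along bonds. Each atom's electronegativity is
χ(q) = a + b q + c q²; at cycle k each bond moves
Δq = (χ_high − χ_low)/χ⁺_low · (1/2)^k from the less to the more
electronegative atom, where χ⁺ is the donor's cation electronegativity
(a + b + c; the conventional 20.02 eV for hydrogen). Updates within a cycle
are synchronous, so results are independent of bond ordering. Starting
charges are the atomic formal charges (shifted uniformly when a
total-charge override differs from their sum), the stop criterion
max|Δq| < 1e-6 e or 100 cycles — the geometric damping makes this
equivalent to the classic fixed six cycles, without hard-coding the count.
This implementation agrees with RDKit's independent Gasteiger code to
~1e-6 e on identical inputs.

GDAC replaces the fixed damping with a geometric one:
f_ij = 0.5·(r_cov,i + r_cov,j)/R_ij, applied as f^k at cycle k. At covalent
contact distance it reduces to PEOE's 1/2; stretched bonds transfer less,
compressed bonds more. It shares PEOE's polynomial slots and convergence
machinery and requires f < 1 (severely compressed bonds are a structured
error).

### Closed-form graph schemes (MGC, VEEM, Del Re)

- **MGC** — geometric-mean equalization on the Pauling scale, per connected
  component: χ_mol = (Π χ_i)^(1/n), q_i = (χ_mol − χ_i)/(2.08 √χ_i)
  (Sanderson's normalization), then a uniform shift restores the component's
  formal charge. Less electronegative atoms come out positive.
- **VEEM** — parameter-free valence-electron redistribution per component:
  the pool V = Σv_i − Q is shared with weights v_i², q_i = v_i − V v_i²/Σv_j².
  Exactly zero for neutral homonuclear systems.
- **Del Re** — solves δ = δ⁰ + Γδ over the bond graph (Γ from per-bond γ),
  then per-bond transfers q_ij = (δ_j − δ_i)/(2 ε_ij) accumulate onto atoms;
  antisymmetry gives exact conservation.

MGC and VEEM are this package's documented closed-form realisations of
geometric-mean and valence-electron equalization; their frozen contracts
(conservation, orbit symmetry, electronegativity sign ordering) are enforced
by the test suite.

## Macromolecule strategies (cutoff / cover)

Automatic routing by atom count: full dense solve up to 20 000 atoms, cutoff
to 79 999, cover from 80 000 (any strategy can be forced). Both replace the
global system with local ones:

- **cutoff**: one subsystem per atom over its `radius`-ball (default 12 Å, a
  typical electrostatics cutoff), keeping the central atom's solution rows;
- **cover**: subsystems only around a greedy, deterministic set of centers
  (no center within radius/2 of an earlier one, scanned in index order — so
  every atom lies within radius/2 of some center); each atom reads its rows
  from its nearest center's solve, ties to the lower center index.

Each local system is solved (one LU, two right-hand sides) for q⁰ (response
to the electronegativities at χ̄ = 0) and g (response to χ̄). The global χ̄
then comes from the exact constraint χ̄ = (Q − Σq⁰)/Σg and q = q⁰ + χ̄·g —
the Schur-complement step of the bordered system evaluated on the local
approximations. Conservation is exact by construction. Off-diagonal
couplings of atoms in the outer 2 Å (`TAPER_WIDTH`) of a local ball are
attenuated by a cosine switch: without it, charges jump as whole atoms enter
or leave the ball and the sup-norm error oscillates with the boundary-shell
composition instead of decaying. With the taper, the error on 1000-atom
helix/polymer fixtures decays monotonically over radii 6→12 Å for nearly
every toy-parameter draw (19/20 cutoff, 16/20 cover over twenty seeds);
occasional small inversions at one radius step remain possible — an inherent
cost of truncating a 1/R kernel spatially. Once radius ≥ molecular diameter
+ taper width, every subsystem is the untapered full system and both
strategies reproduce the dense solve to machine precision. Neighbor search
uses an exact uniform grid; cost scales near-linearly in N at fixed radius.

Known limitation: a local subsystem that is physically meaningless (radius
far below bonding distances) can be singular; this raises a structured
error rather than returning nonsense.

## Parameter sets

On-disk JSON dialect (`format_version: "1"`): metadata (`id`, `method`,
`citation`, `description`), the atom-classification `scheme`, global scalars
in `common`, per-atom-type vectors in `atom` (element + classifier value +
named slots), optional per-bond vectors in `bond`, and per-slot `units`.
Atom types support three classifiers: `plain` (element only), `hbo`
(highest incident bond order, isolated atoms → "1"), `hyb` (sp/sp2/sp3 from
bond orders). Lookup falls back to a `"*"` wildcard value within the same
scheme. Applicability of a set to a molecule means every atom type resolves;
parameter-free methods cover everything.

Bundled sets (each JSON carries its citation): the six EEM sets of Geidl et
al. 2015 (HF/6-31G* and B3LYP/6-311G × AIM/Mulliken/NPA reference charges,
`hbo`-typed), the Rappé–Goddard 1991 QEq element table, the
Gasteiger–Marsili 1980 PEOE coefficients (also exposed for GDAC), and
ionization-derived EQeq/EQeq+C tables. `eem2015ha` heads the registry
order: with it, the EEM charges on the phenolic hydrogens of the worked
dissociation example reproduce the reference web service's published values
to ~0.01 e, which identifies it as the set that service selects for
drug-like organics. Units are eV-based for the physicochemical tables; the
fitted EEM sets use the (consistent) model units they were published in.

Automatic selection: restrict to methods applicable to all input molecules;
prefer 3D methods (EEM, SFKEEM, QEq, EQeq, EQeq+C, GDAC) when every
molecule has coordinates, else 2D (PEOE, MGC, DelRe, VEEM); among a
method's covering sets take the one with the fewest surplus atom types,
ties by registry order. One batch never mixes parameter sets.

## Input handling

SDF V2000 and MOL2 are parsed in-package so validation can cite the
offending record; V3000 is rejected with a clear message. PDB/mmCIF go
through gemmi: first model only; altloc keeps the highest occupancy (ties →
first); PDB CONECT records are honoured when present, otherwise bonds are
perceived by the covalent-radius rule R ≤ r_cov(i) + r_cov(j) + 0.4 Å (and
R > 0.4 Å; closer pairs are clash warnings). Radii are Cordero 2008 values
(bundled; also used for PQR radii). MOL2 aromatic/amide bond types are read
as order 1 with a warning — aromaticity perception is out of scope, so
`hbo`/`hyb` typing of such inputs sees single bonds (kekulized inputs are
unaffected). Missing hydrogens are never added; heavy-atom-only polymers
get a warning. Per-file size guard 10 MB (CLI-overridable). Validation is
total: every malformed input becomes a report entry, never a crash.

## Synthetic fixtures

The generators produce exactly symmetric geometries (tetrahedral methane and
ammonium, a mirror-symmetric kekulized phenol, zig-zag chains, parametric
helices with per-atom rise 0.6 Å and radius 2.3 Å, seeded self-avoiding
random polymers) plus full-coverage toy parameter sets whose magnitudes
mirror the bundled literature sets; toy electronegativities are anchored to
the Pauling ordering so the toy chemistry stays physical (hydrogen less
electronegative than oxygen, which also keeps the QEq hydrogen loop deep in
its convergence region). Everything is bit-reproducible from one integer
seed; no global random state.

What passing tests on these fixtures shows: the solvers and kernels satisfy
their exact invariants (conservation, orbit symmetry, equivariances,
certificate, oracle equivalence) and the approximation strategies converge.
What they do not show: chemical accuracy on real conformers — that rests on
the published parameter sets, and is spot-checked against an independent
implementation (OpenBabel) and the worked phenol example, where the
pKa/charge rank relation is reproduced exactly and the charges to ~0.01 e
(residual differences reflect conformer generation, not the solver).

## Numerical choices

- Dense solves: LAPACK LU with a condition estimate; cond > 1e12 or a
  residual above 1e-8 raises a structured error. Coincident atoms
  (R < 1e-4 Å) are an error, not a silent regularization.
- χ̄ is kept as an unknown of the bordered system (no symmetric
  elimination): one (N+1) solve, simpler and numerically equivalent.
- Coordinates are Å everywhere; 0-based atom indices internally, 1-based
  only at file-format boundaries.
- All tie-breaks (cover centers, nearest-center assignment, registry order,
  orbit ordering) are deterministic, so identical inputs give byte-identical
  outputs.

## Acceptance measurements

`scripts/acceptance.py --seed S --out results.json` recomputes, at run time:
the worst conservation error and certificate deviation over all ten methods
× three fixtures; the solver-vs-elimination-oracle difference on twelve
random N ≤ 6 systems; the cutoff error at radii 6/8/10/12 Å and the cover
error at 12 Å on the 1000-atom helix; the full-solve recovery error at
radius ≥ diameter; the routing-boundary checks; the 4000/1000-atom cutoff
timing ratio; and the seven phenolic-hydrogen charges with their pKa rank
correlation. Problem sizes were chosen so the whole script runs in about a
minute on one CPU while still exercising the macromolecule code paths.
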