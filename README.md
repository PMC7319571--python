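# emcharge

Empirical partial atomic charges for small molecules and biomacromolecules.

Partial atomic charges model the distribution of charge density over the
atoms of a molecule. They are not observables, but they drive electrostatics
in docking, molecular dynamics, QSAR descriptors and pKa estimation, so fast
non-quantum ("empirical") charge schemes remain everyday tools. `emcharge`
implements the two main families behind one interface:

- **Conformationally independent (2D) methods** that use only the bond
  graph: Gasteiger–Marsili **PEOE**, geometric-mean (Sanderson-type)
  equalization **MGC**, **Del Re**'s inductive scheme, and the
  parameter-free valence-electron scheme **VEEM**.
- **Conformationally dependent (3D) methods** built on electronegativity
  equalization: **EEM**, **SFKEEM**, **QEq**, **EQeq**, **EQeq+C**, and the
  geometry-damped iterative scheme **GDAC**.

The equalization family solves one bordered linear system: at equilibrium
every atom's effective electronegativity equals the molecular value χ̄,

    B_i q_i + Σ_{j≠i} K(R_ij) q_j − χ̄ = −A_i ,   Σ_i q_i = Q ,

where `A_i`/`B_i` are electronegativity/hardness parameters, `K` the
method's interaction kernel (κ/R for EEM, a screened Coulomb for QEq/EQeq,
2√(B_iB_j)·sech(σR) for SFKEEM) and `Q` the total molecular charge. A dense
solve is O(N³); for macromolecules `emcharge` provides **cutoff** and
**cover** strategies that solve smoothly tapered local subsystems and
recover the global χ̄ from the exact charge constraint — with automatic
routing (full ≤ 20 000 atoms < cutoff < 80 000 ≤ cover).

Also included: SDF (V2000), MOL2, PDB and mmCIF readers (plus zip/tar.gz
archives) with total validation and covalent-radius bond perception; PQR,
MOL2 and plaintext writers; a registry of literature parameter sets (with
citations) plus per-molecule applicability checking and automatic
method/parameter selection; and deterministic synthetic fixtures for
testing at any size.

## Worked example

```python
import emcharge as ec

mols, report = ec.read_structures("phenol.sdf")
desc, ps = ec.select_automatic(mols)         # -> EEM + a covering set
res = ec.eem_charges(mols[0], ps)
print(desc.id, ps.id)
print([round(q, 3) for q in res.charges])
```

For the bundled phenol-like test fixture this prints

```
eem eem2015ha
[0.569, -0.093, 0.006, -0.025, 0.006, -0.093, -1.146, 0.42, 0.096, 0.055, 0.055, 0.055, 0.096]
```

ordered as the six ring carbons, the hydroxyl oxygen, the hydroxyl hydrogen
and the five ring hydrogens. The substituted carbon and the oxygen carry the
large charges of a polar C–O bond (+0.569/−1.146 e; this set is fitted to
AIM reference charges, which are large for polar bonds), the hydroxyl
(phenolic) hydrogen carries the most positive hydrogen charge (+0.420 e),
and the charges sum to the molecular charge 0 — the quantity of
interest in dissociation studies, since a more positive phenolic hydrogen
marks a more acidic phenol.

The same from the shell:

```bash
emcharge charges phenol.sdf --format mol2,txt --out results/
emcharge methods phenol.sdf         # list methods + parameter sets
```

`results/` then holds `charges.mol2`, `charges.txt` and a `manifest.json`
recording method, parameter set, solver strategy and all warnings.

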