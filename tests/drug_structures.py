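"""The seven phenolic drug compounds of the worked dissociation example.

Each entry: (name, PubChem CID, SMILES, pKa). 3D coordinates are generated
locally with RDKit's ETKDG conformer generator followed by an MMFF
relaxation, seeded for reproducibility; the CIDs identify the same
structures in PubChem.
"""

import numpy as np

import emcharge as ec

DRUGS = [
    ("2,4-dinitrophenol", 1493, "Oc1ccc(cc1[N+](=O)[O-])[N+](=O)[O-]", 4.09),
    ("4-nitrophenol", 980, "Oc1ccc(cc1)[N+](=O)[O-]", 7.15),
    ("2-chlorophenol", 7245, "Oc1ccccc1Cl", 8.56),
    ("3-chlorophenol", 7933, "Oc1cccc(Cl)c1", 9.12),
    ("m-cresol", 342, "Cc1cccc(O)c1", 10.10),
    ("o-cresol", 335, "Cc1ccccc1O", 10.30),
    ("propofol", 4943, "CC(C)c1cccc(C(C)C)c1O", 11.10),
]


def build_drug(smiles: str, seed: int = 1):
    """Embed a 3D conformer and return (Molecule, phenolic H atom index)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rdmol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise RuntimeError(f"conformer generation failed for {smiles}")
    AllChem.MMFFOptimizeMolecule(rdmol)
    conf = rdmol.GetConformer()
    atoms = [ec.Atom(a.GetIdx(), a.GetSymbol(),
                     np.array(conf.GetAtomPosition(a.GetIdx())),
                     a.GetFormalCharge())
             for a in rdmol.GetAtoms()]
    kek = Chem.Mol(rdmol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    bonds = [ec.Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                     int(b.GetBondTypeAsDouble()))
             for b in kek.GetBonds()]
    mol = ec.Molecule(smiles, atoms, bonds)

    h_idx = None
    for a in rdmol.GetAtoms():
        if a.GetSymbol() == "H":
            nb = a.GetNeighbors()[0]
            if nb.GetSymbol() == "O" and any(x.GetIsAromatic()
                                             for x in nb.GetNeighbors()):
                h_idx = a.GetIdx()
    if h_idx is None:
        raise RuntimeError(f"no phenolic hydrogen found in {smiles}")
    return mol, h_idx
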