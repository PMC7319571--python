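import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import emcharge as ec


@pytest.fixture(scope="session")
def registry():
    return {ps.id: ps for ps in ec.builtin_registry()}


@pytest.fixture
def methane():
    return ec.make_fixture(ec.FixtureSpec("methane"))


@pytest.fixture
def phenol():
    return ec.make_fixture(ec.FixtureSpec("phenol_like"))


@pytest.fixture
def ammonium():
    return ec.make_fixture(ec.FixtureSpec("ammonium"))


def rigid_transform(mol, seed=0):
    """Return a copy of ``mol`` under a random rotation + translation."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(m)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=5.0, size=3)
    atoms = [ec.Atom(a.index, a.element,
                     (q @ a.coords + t) if a.coords is not None else None,
                     a.formal_charge, a.name, a.residue_info)
             for a in mol.atoms]
    return ec.Molecule(mol.name, atoms, list(mol.bonds), mol.total_charge)


def permute(mol, perm):
    """Return a copy of ``mol`` with atoms reordered by ``perm``
    (perm[new_index] = old_index)."""
    inverse = {old: new for new, old in enumerate(perm)}
    atoms = [ec.Atom(new, mol.atoms[old].element,
                     None if mol.atoms[old].coords is None
                     else mol.atoms[old].coords.copy(),
                     mol.atoms[old].formal_charge,
                     mol.atoms[old].name, mol.atoms[old].residue_info)
             for new, old in enumerate(perm)]
    bonds = [ec.Bond(inverse[b.i], inverse[b.j], b.order) for b in mol.bonds]
    return ec.Molecule(mol.name, atoms, bonds, mol.total_charge)
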