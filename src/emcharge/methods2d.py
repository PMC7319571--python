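"""Conformationally independent (2D) charge methods: PEOE, MGC, VEEM, DelRe.

These operate on the bond graph only — no coordinates are required. All four
conserve the total molecular charge Q exactly (up to round-off) and assign
identical charges to topologically equivalent atoms.
"""

from __future__ import annotations

import math

import numpy as np

from . import elemdata
from .errors import CoverageError, EmchargeError, SingularSystemError
from .molmodel import Molecule, total_formal_charge
from .params import ParameterSet, atom_parameter_arrays
from .result import ChargeResult

#: Electronegativity of the hydrogen cation used by the original PEOE scheme
#: in place of a + b + c for hydrogen (eV).
PEOE_H_CATION_CHI = 20.02

#: Sanderson's normalization constant for converting an electronegativity
#: deviation into a partial charge.
SANDERSON_SCALE = 2.08


def _uniform_charge_shift(q: np.ndarray, Q: float) -> np.ndarray:
    """Distribute any residual of the total-charge constraint uniformly."""
    if len(q) == 0:
        return q
    return q + (Q - q.sum()) / len(q)


def _initial_charges(mol: Molecule) -> np.ndarray:
    """Starting charges for iterative transfer schemes: atomic formal
    charges, shifted uniformly when an explicit total-charge override makes
    their sum differ from Q (transfers conserve the start total)."""
    q = np.array([at.formal_charge for at in mol.atoms], dtype=float)
    return _uniform_charge_shift(q, total_formal_charge(mol))


# ---------------------------------------------------------------------------
# PEOE
# ---------------------------------------------------------------------------

def peoe_charges(mol: Molecule, ps: ParameterSet, tol: float = 1e-6,
                 max_iter: int = 100) -> ChargeResult:
    """Iterative partial equalization of orbital electronegativity.

    Each atom carries a charge-dependent electronegativity
    ``chi_i(q) = a_i + b_i q_i + c_i q_i**2``. Every cycle transfers charge
    along each bond from the less to the more electronegative atom,
    attenuated by (1/2)**k at cycle k, with the donor's cation
    electronegativity (a+b+c; 20.02 eV for H) as the normalizer. Updates
    within a cycle are synchronous, so the result does not depend on bond
    ordering. Iteration stops when the largest per-atom charge increment
    drops below ``tol`` or after ``max_iter`` cycles.
    """
    arrs = atom_parameter_arrays(ps, mol)
    a = np.array(arrs["a"])
    b = np.array(arrs["b"])
    c = np.array(arrs["c"])
    chi_plus = a + b + c
    for i, atom in enumerate(mol.atoms):
        if atom.element == "H":
            chi_plus[i] = PEOE_H_CATION_CHI

    q = _initial_charges(mol)
    warnings: list[str] = []
    converged = False
    k = 0
    for k in range(1, max_iter + 1):
        chi = a + b * q + c * q * q
        damp = 0.5 ** k
        dq = np.zeros_like(q)
        for bond in mol.bonds:
            i, j = bond.i, bond.j
            if chi[j] > chi[i]:
                t = (chi[j] - chi[i]) / chi_plus[i] * damp
                dq[i] += t
                dq[j] -= t
            elif chi[i] > chi[j]:
                t = (chi[i] - chi[j]) / chi_plus[j] * damp
                dq[j] += t
                dq[i] -= t
        q += dq
        if np.max(np.abs(dq), initial=0.0) < tol:
            converged = True
            break
    if not converged:
        warnings.append(f"PEOE did not converge within {max_iter} cycles")
    return ChargeResult(mol.name, "peoe", ps.id, "iterative", q,
                        converged=converged, iterations=k, warnings=warnings)


# ---------------------------------------------------------------------------
# MGC
# ---------------------------------------------------------------------------

def mgc_charges(mol: Molecule, electronegativity=None) -> ChargeResult:
    """Geometric-mean (Sanderson-type) electronegativity equalization.

    Within each connected component the molecular electronegativity is the
    geometric mean of the atomic (Pauling-scale) values; each atom's charge
    is the normalized deviation of its electronegativity from that mean,
    ``q_i = (chi_mol - chi_i) / (2.08 sqrt(chi_i))``, shifted uniformly so
    the component carries the sum of its formal charges. Less electronegative
    atoms come out positive.
    """
    chi_fn = electronegativity or elemdata.pauling_electronegativity
    chi = np.array([chi_fn(a.element) for a in mol.atoms], dtype=float)
    if np.any(chi <= 0):
        raise EmchargeError("MGC requires positive electronegativities")
    q = np.zeros(len(mol.atoms))
    for comp in mol.connected_components():
        idx = np.array(comp)
        chi_mol = math.exp(np.mean(np.log(chi[idx])))
        raw = (chi_mol - chi[idx]) / (SANDERSON_SCALE * np.sqrt(chi[idx]))
        q_comp = sum(mol.atoms[i].formal_charge for i in comp)
        q[idx] = raw + (q_comp - raw.sum()) / len(comp)
    q = _uniform_charge_shift(q, total_formal_charge(mol))
    return ChargeResult(mol.name, "mgc", "none", "iterative", q)


# ---------------------------------------------------------------------------
# VEEM
# ---------------------------------------------------------------------------

def veem_charges(mol: Molecule) -> ChargeResult:
    """Parameter-free valence-electron equalization.

    The valence electrons of each connected component (minus its net charge)
    are redistributed among the atoms with weights proportional to the square
    of the atomic valence-electron count, so electron-rich elements pull
    density from electron-poor ones. The charge is the difference between an
    atom's nominal valence count and its equalized population; it vanishes
    identically for neutral homonuclear systems.
    """
    v = np.array([elemdata.valence_electrons(a.element) for a in mol.atoms],
                 dtype=float)
    q = np.zeros(len(mol.atoms))
    for comp in mol.connected_components():
        idx = np.array(comp)
        q_comp = sum(mol.atoms[i].formal_charge for i in comp)
        pool = v[idx].sum() - q_comp
        w = v[idx] ** 2
        q[idx] = v[idx] - pool * w / w.sum()
    q = _uniform_charge_shift(q, total_formal_charge(mol))
    return ChargeResult(mol.name, "veem", "none", "iterative", q)


# ---------------------------------------------------------------------------
# Del Re
# ---------------------------------------------------------------------------

def delre_charges(mol: Molecule, ps: ParameterSet) -> ChargeResult:
    """Del Re's inductive sigma-charge scheme.

    Solves the linear system ``delta_i = delta0_i + sum_j gamma_ij delta_j``
    over bonded neighbours j (independently per connected component), then
    converts electronegativity-parameter differences along each bond into an
    antisymmetric pair charge ``q_ij = (delta_j - delta_i) / (2 eps_ij)``.
    An atom's charge is the sum over its incident bonds, so neutral inputs
    conserve exactly; a net molecular charge is distributed uniformly.
    """
    arrs = atom_parameter_arrays(ps, mol)
    delta0 = np.array(arrs["delta0"])
    n = len(mol.atoms)

    def bond_params(bond):
        ei = mol.atoms[bond.i].element
        ej = mol.atoms[bond.j].element
        row, _ = ps.lookup_bond(ei, ej, bond.order)
        if row is None:
            raise CoverageError(ps.id, [(f"{ei}-{ej}", "bond", str(bond.order))])
        return row

    mat = np.eye(n)
    for bond in mol.bonds:
        row = bond_params(bond)
        g = row["gamma"]
        mat[bond.i, bond.j] -= g
        mat[bond.j, bond.i] -= g
    try:
        delta = np.linalg.solve(mat, delta0)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(f"Del Re system singular for {mol.name!r}: {exc}") from exc

    q = np.zeros(n)
    for bond in mol.bonds:
        row = bond_params(bond)
        t = (delta[bond.j] - delta[bond.i]) / (2.0 * row["eps"])
        q[bond.i] += t
        q[bond.j] -= t
    q = _uniform_charge_shift(q, total_formal_charge(mol))
    return ChargeResult(mol.name, "delre", ps.id, "iterative", q)
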