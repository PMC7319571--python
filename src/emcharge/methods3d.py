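"""Conformationally dependent (3D) charge methods.

EEM, SFKEEM, QEq, EQeq and EQeq+C share one skeleton: the electronegativity
equalization linear system. At equilibrium every atom's effective
electronegativity equals the molecular value chi_bar, which together with the
total-charge constraint gives the (N+1) x (N+1) system

    [ M   -1 ] [ q  ]   [ rhs ]
    [ 1    0 ] [ chi] = [ Q   ]

where M has the method's hardness-like terms on the diagonal and its
distance-dependent interaction kernel off the diagonal. GDAC is different: a
PEOE-style iterative transfer whose damping depends on the interatomic
distance.

Units: electronegativity-like slots in eV, hardness-like in eV/e, distances
in Å; the Coulomb constant is k_e = 14.399645 eV·Å/e². (The EEM sets fitted
in the literature use their own consistent model units; charges are
dimensionless either way.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import scipy.linalg

from . import elemdata
from .errors import GeometryError, SingularSystemError
from .molmodel import Molecule, distance_matrix, total_formal_charge
from .params import ParameterSet, atom_parameter_arrays
from .result import ChargeResult

#: Coulomb constant, eV·Å/e².
K_E = 14.399645

#: Pairs closer than this (Å) are treated as coincident -> structured error.
MIN_DISTANCE = 1e-4

#: Condition-number ceiling for the dense solve.
MAX_CONDITION = 1e12


@dataclass
class Kernel:
    """Assembled per-molecule kernel of one equalization method.

    ``diag``/``rhs`` are per-atom vectors; ``offdiag_matrix`` maps a distance
    submatrix (for the given atom indices) to the interaction block. The
    off-diagonal is symmetric and either decays to zero (screened kernels)
    or to the bare Coulomb tail k_e/R.
    """

    method: str
    diag: np.ndarray
    rhs: np.ndarray
    offdiag_matrix: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def offdiagonal(self, i: int, j: int, r: float) -> float:
        """Scalar pairwise interaction (test/inspection surface)."""
        sub = self.offdiag_matrix(np.array([[0.0, r], [r, 0.0]]),
                                  np.array([i, j]))
        return float(sub[0, 1])


@dataclass
class EqualizationSystem:
    matrix: np.ndarray   # (N+1) x (N+1)
    rhs: np.ndarray      # (N+1)

    @property
    def n_atoms(self) -> int:
        return len(self.rhs) - 1


# ---------------------------------------------------------------------------
# kernel constructors
# ---------------------------------------------------------------------------

def eem_kernel(mol: Molecule, ps: ParameterSet) -> Kernel:
    """EEM: diagonal B_i, off-diagonal kappa / R_ij, right-hand side -A_i."""
    arrs = atom_parameter_arrays(ps, mol)
    A = np.array(arrs["A"])
    B = np.array(arrs["B"])
    kappa = ps.common["kappa"]

    def off(R, idx):
        out = np.zeros_like(R)
        mask = ~np.eye(len(R), dtype=bool)
        out[mask] = kappa / R[mask]
        return out

    return Kernel("eem", B.copy(), -A, off)


def sfkeem_kernel(mol: Molecule, ps: ParameterSet) -> Kernel:
    """SFKEEM: diagonal 2 B_i, off-diagonal 2 sqrt(B_i B_j) sech(sigma R_ij)."""
    arrs = atom_parameter_arrays(ps, mol)
    A = np.array(arrs["A"])
    B = np.array(arrs["B"])
    sigma = ps.common["sigma"]
    if np.any(B <= 0):
        raise GeometryError("SFKEEM requires positive hardness B for sqrt(B_i B_j)")

    def off(R, idx):
        out = 2.0 * np.sqrt(np.outer(B[idx], B[idx])) / np.cosh(sigma * R)
        np.fill_diagonal(out, 0.0)
        return out

    return Kernel("sfkeem", 2.0 * B, -A, off)


def _screened_coulomb(J: np.ndarray):
    """Ohno-style screened Coulomb: k_e / sqrt(R^2 + a_ij^2) with the contact
    value matched to the mean idempotential, a_ij = 2 k_e / (J_i + J_j).
    Decays to the bare Coulomb tail k_e/R at large separation."""

    def off(R, idx):
        Ji = J[idx]
        a = 2.0 * K_E / np.add.outer(Ji, Ji)
        out = K_E / np.sqrt(R * R + a * a)
        np.fill_diagonal(out, 0.0)
        return out

    return off


def qeq_kernel(mol: Molecule, ps: ParameterSet,
               q_prev: Optional[np.ndarray] = None) -> Kernel:
    """QEq: electronegativity chi_i, idempotential J_i, screened Coulomb
    off-diagonal. Hydrogen's idempotential is charge-dependent,
    J_H(q) = J_H0 (1 + q_H), supplied through ``q_prev`` by the
    self-consistent outer loop (floored at 0.1 J_H0 to stay positive)."""
    arrs = atom_parameter_arrays(ps, mol)
    chi = np.array(arrs["chi"])
    J = np.array(arrs["J"]).copy()
    if q_prev is not None:
        for i, atom in enumerate(mol.atoms):
            if atom.element == "H":
                J[i] = max(J[i] * (1.0 + q_prev[i]), 0.1 * J[i])
    return Kernel("qeq", J.copy(), -chi, _screened_coulomb(J))


def eqeq_kernel(mol: Molecule, ps: ParameterSet) -> Kernel:
    """EQeq: like QEq but chi/J derive from ionization potentials and
    electron affinities (chi = (IP+EA)/2, J = IP-EA); no charge-dependent
    hydrogen term."""
    arrs = atom_parameter_arrays(ps, mol)
    chi = np.array(arrs["chi"])
    J = np.array(arrs["J"])
    k = Kernel("eqeq", J.copy(), -chi, _screened_coulomb(J))
    return k


KERNELS = {"eem": eem_kernel, "sfkeem": sfkeem_kernel, "eqeq": eqeq_kernel,
           "eqeqc": eqeq_kernel}


# ---------------------------------------------------------------------------
# system assembly & solve
# ---------------------------------------------------------------------------

def build_system(mol: Molecule, kernel: Kernel,
                 indices: Optional[np.ndarray] = None,
                 total_charge: Optional[float] = None,
                 dist: Optional[np.ndarray] = None) -> EqualizationSystem:
    """Assemble the bordered (N+1) x (N+1) equalization system.

    ``indices`` restricts the system to a subset of atoms (used by the
    cutoff/cover solvers); the constraint row then carries ``total_charge``
    of that fragment.
    """
    if indices is None:
        indices = np.arange(len(mol.atoms))
    indices = np.asarray(indices, dtype=int)
    if dist is None:
        xyz = mol.coords_array()[indices]
        diff = xyz[:, None, :] - xyz[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    n = len(indices)
    off = ~np.eye(n, dtype=bool)
    if n > 1 and dist[off].min() < MIN_DISTANCE:
        flat = np.where(off & (dist < MIN_DISTANCE))
        i, j = int(flat[0][0]), int(flat[1][0])
        raise GeometryError(
            f"atoms {indices[i]} and {indices[j]} are coincident "
            f"(R = {dist[i, j]:.2e} Å)")
    if total_charge is None:
        total_charge = total_formal_charge(mol)

    m = np.zeros((n + 1, n + 1))
    m[:n, :n] = kernel.offdiag_matrix(dist, indices)
    np.fill_diagonal(m[:n, :n], kernel.diag[indices])
    m[:n, n] = -1.0
    m[n, :n] = 1.0
    rhs = np.zeros(n + 1)
    rhs[:n] = kernel.rhs[indices]
    rhs[n] = total_charge
    return EqualizationSystem(m, rhs)


def solve_equalization(system: EqualizationSystem) -> tuple[np.ndarray, float]:
    """Exact dense solve; returns (charges, chi_bar).

    Raises :class:`SingularSystemError` when the matrix is singular or its
    estimated condition number exceeds 1e12. The residual of the returned
    solution is verified to be below 1e-8 in the infinity norm.
    """
    m, rhs = system.matrix, system.rhs
    try:
        lu, piv = scipy.linalg.lu_factor(m)
    except (ValueError, scipy.linalg.LinAlgError) as exc:
        raise SingularSystemError(str(exc)) from exc
    anorm = np.abs(m).sum(axis=1).max()
    rcond = scipy.linalg.lapack.dgecon(lu, anorm, norm="I")[0]
    if not np.isfinite(rcond) or rcond == 0 or 1.0 / rcond > MAX_CONDITION:
        raise SingularSystemError(
            f"equalization system ill-conditioned (cond ~ {1.0 / max(rcond, 1e-300):.2e})")
    x = scipy.linalg.lu_solve((lu, piv), rhs)
    residual = np.max(np.abs(m @ x - rhs))
    scale = max(1.0, np.max(np.abs(rhs)))
    if residual > 1e-8 * scale:
        raise SingularSystemError(f"solve residual too large: {residual:.2e}")
    return x[:-1], float(x[-1])


def _dispatch(mol: Molecule, ps: ParameterSet, kernel: Kernel, method: str,
              strategy: str, radius: float) -> ChargeResult:
    """Route a linear-system method through full/cutoff/cover per strategy."""
    from . import bigsolver

    plan = bigsolver.route_strategy(len(mol.atoms), strategy, radius)
    if plan.kind == "full":
        system = build_system(mol, kernel)
        q, chi_bar = solve_equalization(system)
        return ChargeResult(mol.name, method, ps.id, "full", q, chi_bar=chi_bar)
    if plan.kind == "cutoff":
        q = bigsolver.cutoff_solve(mol, kernel, plan.cutoff_radius)
    else:
        q = bigsolver.cover_solve(mol, kernel, plan.cutoff_radius)
    return ChargeResult(mol.name, method, ps.id, plan.kind, q)


# ---------------------------------------------------------------------------
# public method entry points
# ---------------------------------------------------------------------------

def eem_charges(mol: Molecule, ps: ParameterSet, strategy: str = "auto",
                radius: float = 12.0) -> ChargeResult:
    """Electronegativity equalization method (Mortier-style A/B/kappa)."""
    return _dispatch(mol, ps, eem_kernel(mol, ps), "eem", strategy, radius)


def sfkeem_charges(mol: Molecule, ps: ParameterSet, strategy: str = "auto",
                   radius: float = 12.0) -> ChargeResult:
    """Selfconsistent functional kernel EEM (sech-screened interaction)."""
    return _dispatch(mol, ps, sfkeem_kernel(mol, ps), "sfkeem", strategy, radius)


def eqeq_charges(mol: Molecule, ps: ParameterSet, strategy: str = "auto",
                 radius: float = 12.0) -> ChargeResult:
    """Extended charge equilibration (ionization-derived chi and J)."""
    return _dispatch(mol, ps, eqeq_kernel(mol, ps), "eqeq", strategy, radius)


def eqeqc_charges(mol: Molecule, ps: ParameterSet, strategy: str = "auto",
                  radius: float = 12.0) -> ChargeResult:
    """EQeq plus an additive, bond-order-dependent per-bond correction.

    Each bond (i, j) shifts charge antisymmetrically by the tabulated
    correction D for its (element pair, order); absent entries default to 0,
    so an empty correction table reproduces EQeq exactly and the total charge
    is preserved by construction.
    """
    if not mol.bonds and len(mol.atoms) > 1:
        raise GeometryError("EQeq+C requires bond information for its correction term")
    res = _dispatch(mol, ps, eqeq_kernel(mol, ps), "eqeqc", strategy, radius)
    q = res.charges.copy()
    for bond in mol.bonds:
        row, sign = ps.lookup_bond(mol.atoms[bond.i].element,
                                   mol.atoms[bond.j].element, bond.order)
        if row is not None:
            d = sign * row.get("D", 0.0)
            q[bond.i] += d
            q[bond.j] -= d
    res.charges = q
    return res


def qeq_charges(mol: Molecule, ps: ParameterSet, strategy: str = "auto",
                radius: float = 12.0, tol: float = 1e-8,
                max_iter: int = 50) -> ChargeResult:
    """Charge equilibration with the self-consistent hydrogen term.

    The equalization system is re-assembled with hydrogen's idempotential
    evaluated at the previous iterate's hydrogen charges and re-solved until
    the charges are stationary (damped fixed point, mixing 0.5). Molecules
    without hydrogen converge in a single outer iteration.
    """
    has_h = any(a.element == "H" for a in mol.atoms)
    q = np.zeros(len(mol.atoms))
    warnings: list[str] = []
    converged = True
    iters = 1
    chi_bar = None

    def solve_with(qp):
        kernel = qeq_kernel(mol, ps, q_prev=qp)
        return _dispatch(mol, ps, kernel, "qeq", strategy, radius)

    res = solve_with(None if not has_h else q)
    q = res.charges
    chi_bar = res.chi_bar
    if has_h:
        converged = False
        mixing = 0.5
        prev_delta = np.inf
        for iters in range(2, max_iter + 1):
            res = solve_with(q)
            q_new = (1.0 - mixing) * q + mixing * res.charges
            delta = np.max(np.abs(q_new - q))
            if delta > prev_delta:  # oscillating fixed point: damp harder
                mixing = max(mixing * 0.5, 1.0 / 64.0)
            prev_delta = delta
            q = q_new
            chi_bar = res.chi_bar
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.append(f"QEq hydrogen loop did not converge within {max_iter} iterations")
    return ChargeResult(mol.name, "qeq", ps.id, res.strategy, q,
                        converged=converged, iterations=iters,
                        chi_bar=chi_bar, warnings=warnings)


def gdac_charges(mol: Molecule, ps: ParameterSet, tol: float = 1e-6,
                 max_iter: int = 100) -> ChargeResult:
    """Geometry-damped iterative charge transfer.

    A PEOE-style scheme in which the per-bond attenuation depends on the
    actual interatomic distance: f_ij = 0.5 (r_cov,i + r_cov,j) / R_ij,
    raised to the cycle number. At the covalent contact distance this reduces
    to PEOE's (1/2)^k damping; stretched bonds transfer less, compressed
    bonds more. Electronegativities use the same a + b q + c q^2 polynomial
    slots as PEOE.
    """
    arrs = atom_parameter_arrays(ps, mol)
    a = np.array(arrs["a"])
    b = np.array(arrs["b"])
    c = np.array(arrs["c"])
    chi_plus = a + b + c
    for i, atom in enumerate(mol.atoms):
        if atom.element == "H":
            chi_plus[i] = 20.02

    from .methods2d import _initial_charges

    dist = distance_matrix(mol)
    f = np.empty(len(mol.bonds))
    for bi, bond in enumerate(mol.bonds):
        r = dist[bond.i, bond.j]
        if r < MIN_DISTANCE:
            raise GeometryError(f"atoms {bond.i} and {bond.j} are coincident")
        rc = elemdata.covalent_radius(mol.atoms[bond.i].element) + \
            elemdata.covalent_radius(mol.atoms[bond.j].element)
        f[bi] = 0.5 * rc / r
    if np.any(f >= 1.0):
        raise GeometryError("GDAC damping factor >= 1 (severely compressed bond)")

    q = _initial_charges(mol)
    warnings: list[str] = []
    converged = False
    k = 0
    for k in range(1, max_iter + 1):
        chi = a + b * q + c * q * q
        dq = np.zeros_like(q)
        for bi, bond in enumerate(mol.bonds):
            i, j = bond.i, bond.j
            damp = f[bi] ** k
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
        warnings.append(f"GDAC did not converge within {max_iter} cycles")
    return ChargeResult(mol.name, "gdac", ps.id, "iterative", q,
                        converged=converged, iterations=k, warnings=warnings)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def effective_electronegativities(mol: Molecule, ps: ParameterSet,
                                  method: str,
                                  charges: np.ndarray) -> np.ndarray:
    """Per-atom effective electronegativity at the given charges.

    For an exact equalization solution every entry equals chi_bar; the spread
    of this vector is the 'equalization certificate' checked by the test
    suite. QEq's hydrogen hardness is evaluated at the supplied charges,
    matching the converged self-consistent system.
    """
    if method == "qeq":
        kernel = qeq_kernel(mol, ps, q_prev=np.asarray(charges))
    else:
        kernel = KERNELS[method](mol, ps)
    system = build_system(mol, kernel)
    n = len(mol.atoms)
    m = system.matrix[:n, :n]
    return m @ np.asarray(charges) - system.rhs[:n]
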