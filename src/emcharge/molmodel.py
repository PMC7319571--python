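"""Molecular data model and graph utilities.

A :class:`Molecule` is an ordered list of atoms plus an explicit bond list and
an integer total charge. It is deliberately minimal: no aromaticity model, no
protonation logic — just what the empirical charge kernels consume. Atom
indices are 0-based everywhere inside the library; 1-based indices appear only
at file-format boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import EmchargeError, MissingCoordinatesError

# All IUPAC element symbols (Z = 1..118); used only for input validation.
ELEMENTS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

SCHEMES = ("plain", "hbo", "hyb")


def normalize_element(symbol: str) -> str:
    """Map arbitrary-case symbols (``CL``, ``cl``) to canonical form (``Cl``)."""
    s = symbol.strip()
    if not s:
        raise EmchargeError("empty element symbol")
    canon = s[0].upper() + s[1:].lower()
    if canon not in ELEMENTS:
        raise EmchargeError(f"unknown element symbol: {symbol!r}")
    return canon


@dataclass
class Atom:
    index: int
    element: str
    coords: Optional[np.ndarray] = None  # Å
    formal_charge: int = 0
    name: str = ""
    residue_info: Optional[tuple] = None  # (resname, resnum, chain)

    def __post_init__(self):
        if self.element not in ELEMENTS:
            self.element = normalize_element(self.element)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
                raise EmchargeError(
                    f"atom {self.index} ({self.element}): coords must be a finite 3-vector"
                )


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int = 1

    def __post_init__(self):
        if self.i == self.j:
            raise EmchargeError(f"bond connects atom {self.i} to itself")
        if self.order not in (1, 2, 3):
            raise EmchargeError(f"bond order must be 1, 2 or 3 (got {self.order})")

    @property
    def key(self) -> tuple:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass(frozen=True)
class AtomTypeKey:
    """(element, classifier scheme, classifier value) triple keying parameters."""

    element: str
    scheme: str
    value: str

    def as_tuple(self) -> tuple:
        return (self.element, self.scheme, self.value)


@dataclass
class Molecule:
    name: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    #: explicit override of the total molecular charge Q; None means
    #: "sum of atomic formal charges".
    total_charge: Optional[int] = None

    def __post_init__(self):
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise EmchargeError(
                    f"molecule {self.name!r}: bond ({b.i},{b.j}) out of range (N={n})"
                )
            if b.key in seen:
                raise EmchargeError(
                    f"molecule {self.name!r}: duplicate bond {b.key}"
                )
            seen.add(b.key)
        for pos, a in enumerate(self.atoms):
            if a.index != pos:
                a.index = pos

    # -- convenience --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def has_coordinates(self) -> bool:
        return all(a.coords is not None for a in self.atoms)

    def coords_array(self) -> np.ndarray:
        for a in self.atoms:
            if a.coords is None:
                raise MissingCoordinatesError(f"{a.index} ({a.element})")
        return np.array([a.coords for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def neighbors(self) -> list[list[tuple[int, int]]]:
        """Adjacency: for each atom, list of (neighbor index, bond order)."""
        adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append((b.j, b.order))
            adj[b.j].append((b.i, b.order))
        return adj

    def connected_components(self) -> list[list[int]]:
        adj = self.neighbors()
        seen = [False] * len(self.atoms)
        comps = []
        for start in range(len(self.atoms)):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v, _ in adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            comps.append(sorted(comp))
        return comps


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def total_formal_charge(mol: Molecule) -> int:
    """Total molecular charge Q: explicit override, else sum of formal charges."""
    if mol.total_charge is not None:
        return int(mol.total_charge)
    return int(sum(a.formal_charge for a in mol.atoms))


def distance_matrix(mol: Molecule) -> np.ndarray:
    """Pairwise Euclidean distances in Å (symmetric, zero diagonal)."""
    xyz = mol.coords_array()
    diff = xyz[:, None, :] - xyz[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def classify_atom(mol: Molecule, idx: int, scheme: str = "plain") -> AtomTypeKey:
    """Atom-type key for parameter lookup.

    plain
        element only; value ``"*"``.
    hbo
        highest incident bond order as a string; isolated atoms get ``"1"``
        so monoatomic species remain parameterizable.
    hyb
        crude hybridisation from bond orders: any triple bond or at least two
        double bonds → ``sp``; exactly one double bond → ``sp2``; else
        ``sp3``.
    """
    if not (0 <= idx < len(mol.atoms)):
        raise EmchargeError(f"atom index {idx} out of range")
    el = mol.atoms[idx].element
    if scheme == "plain":
        return AtomTypeKey(el, "plain", "*")
    orders = [b.order for b in mol.bonds if idx in (b.i, b.j)]
    if scheme == "hbo":
        return AtomTypeKey(el, "hbo", str(max(orders) if orders else 1))
    if scheme == "hyb":
        n_double = orders.count(2)
        if 3 in orders or n_double >= 2:
            value = "sp"
        elif n_double == 1:
            value = "sp2"
        else:
            value = "sp3"
        return AtomTypeKey(el, "hyb", value)
    raise EmchargeError(f"unknown classification scheme: {scheme!r}")


def classify_all(mol: Molecule, scheme: str = "plain") -> list[AtomTypeKey]:
    return [classify_atom(mol, i, scheme) for i in range(len(mol.atoms))]


def symmetry_orbits(mol: Molecule) -> list[list[int]]:
    """Partition atoms into topological-equivalence orbits.

    Morgan-style iterative refinement: start from (element, formal charge),
    refine each atom's label with the sorted multiset of (neighbor label,
    bond order) until the partition stabilises. Atoms sharing a final label
    are topologically equivalent, hence must receive identical charges from
    any graph-determined method.
    """
    n = len(mol.atoms)
    adj = mol.neighbors()
    labels = [(a.element, a.formal_charge) for a in mol.atoms]

    def canon(lbls):
        uniq = {l: r for r, l in enumerate(sorted(set(lbls), key=repr))}
        return [uniq[l] for l in lbls]

    ranks = canon(labels)
    for _ in range(n + 1):
        new = [
            (ranks[i], tuple(sorted((ranks[v], o) for v, o in adj[i])))
            for i in range(n)
        ]
        new_ranks = canon(new)
        if new_ranks == ranks:
            break
        ranks = new_ranks
    orbits: dict[int, list[int]] = {}
    for i, r in enumerate(ranks):
        orbits.setdefault(r, []).append(i)
    return sorted(orbits.values())
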