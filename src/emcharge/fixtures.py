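"""Deterministic synthetic molecules and toy parameter sets.

Everything here is reproducible from a single integer seed (each generator
draws from its own named PCG64 stream; no global random state) so every
method and solver can be exercised without downloading structures. Geometry
is idealised — exact tetrahedra, hexagons and helices — which makes symmetry
assertions exact, and is not meant to resemble relaxed conformers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import elemdata
from .errors import EmchargeError, UnknownMethodError
from .molmodel import Atom, Bond, Molecule
from .params import METHODS, ParameterSet

KINDS = ("diatomic", "methane", "ammonium", "phenol_like", "chain", "helix",
         "random_polymer")


@dataclass
class FixtureSpec:
    kind: str
    n_atoms: Optional[int] = None
    elements: Sequence[str] = ("C",)
    seed: int = 0
    bond_length: float = 1.5          # Å
    total_charge: int = 0
    helix_radius: float = 2.3         # Å
    helix_rise: float = 0.6           # Å per atom
    helix_turn: float = 0.6           # rad per atom

    def __post_init__(self):
        if self.kind not in KINDS:
            raise EmchargeError(f"unknown fixture kind {self.kind!r}")


def make_fixture(spec: FixtureSpec) -> Molecule:
    """Build the molecule a :class:`FixtureSpec` describes (bit-reproducible)."""
    return _BUILDERS[spec.kind](spec)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _diatomic(spec: FixtureSpec) -> Molecule:
    els = list(spec.elements) * 2
    a = Atom(0, els[0], np.array([0.0, 0.0, 0.0]))
    b = Atom(1, els[1], np.array([spec.bond_length, 0.0, 0.0]))
    a.formal_charge = spec.total_charge  # carried on the first atom
    return Molecule(f"diatomic-{els[0]}{els[1]}", [a, b], [Bond(0, 1)])


def _methane(spec: FixtureSpec) -> Molecule:
    d = 1.09 / math.sqrt(3.0)
    corners = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
    atoms = [Atom(0, "C", np.zeros(3))]
    atoms += [Atom(i + 1, "H", np.array(c, dtype=float) * d)
              for i, c in enumerate(corners)]
    bonds = [Bond(0, i) for i in range(1, 5)]
    return Molecule("methane", atoms, bonds)


def _ammonium(spec: FixtureSpec) -> Molecule:
    d = 1.02 / math.sqrt(3.0)
    corners = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
    n = Atom(0, "N", np.zeros(3), formal_charge=1)
    atoms = [n] + [Atom(i + 1, "H", np.array(c, dtype=float) * d)
                   for i, c in enumerate(corners)]
    return Molecule("ammonium", atoms, [Bond(0, i) for i in range(1, 5)])


def _phenol_like(spec: FixtureSpec) -> Molecule:
    """Planar C6 ring (alternating single/double bonds) with five ring H and
    one OH; exact mirror symmetry across the C-O axis."""
    r_ring, r_ch, r_co, r_oh = 1.39, 1.09, 1.36, 0.96
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    for i in range(6):
        ang = math.pi / 3.0 * i
        atoms.append(Atom(i, "C", np.array(
            [r_ring * math.cos(ang), r_ring * math.sin(ang), 0.0])))
    for i in range(6):
        bonds.append(Bond(i, (i + 1) % 6, order=1 + (i % 2)))
    # O on C0 (along +x), H on C1..C5
    o_idx = 6
    atoms.append(Atom(o_idx, "O", np.array([r_ring + r_co, 0.0, 0.0])))
    bonds.append(Bond(0, o_idx, order=1))
    atoms.append(Atom(7, "H", np.array([r_ring + r_co + r_oh, 0.0, 0.0])))
    bonds.append(Bond(o_idx, 7, order=1))
    scale = (r_ring + r_ch) / r_ring
    for i in range(1, 6):
        x, y, _ = atoms[i].coords
        atoms.append(Atom(len(atoms), "H", np.array([x * scale, y * scale, 0.0])))
        bonds.append(Bond(i, len(atoms) - 1, order=1))
    return Molecule("phenol_like", atoms, bonds)


def _chain(spec: FixtureSpec) -> Molecule:
    """Planar zig-zag chain; elements cycle through the palette."""
    n = spec.n_atoms or 10
    dx = spec.bond_length * math.cos(math.pi / 6.0)
    dy = spec.bond_length * math.sin(math.pi / 6.0)
    atoms = [Atom(i, spec.elements[i % len(spec.elements)],
                  np.array([i * dx, (i % 2) * dy, 0.0]))
             for i in range(n)]
    bonds = [Bond(i, i + 1) for i in range(n - 1)]
    mol = Molecule(f"chain-{n}", atoms, bonds)
    mol.total_charge = spec.total_charge
    return mol


def _helix(spec: FixtureSpec) -> Molecule:
    n = spec.n_atoms or 100
    atoms = []
    for i in range(n):
        ang = spec.helix_turn * i
        atoms.append(Atom(i, spec.elements[i % len(spec.elements)], np.array(
            [spec.helix_radius * math.cos(ang),
             spec.helix_radius * math.sin(ang),
             spec.helix_rise * i])))
    bonds = [Bond(i, i + 1) for i in range(n - 1)]
    mol = Molecule(f"helix-{n}", atoms, bonds)
    mol.total_charge = spec.total_charge
    return mol


def _random_polymer(spec: FixtureSpec) -> Molecule:
    """Self-avoiding-ish random walk with bond lengths in [1.3, 1.6] Å."""
    n = spec.n_atoms or 50
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    coords = np.zeros((n, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n):
        for _ in range(200):
            step = direction + 0.8 * rng.normal(size=3)
            step /= np.linalg.norm(step)
            length = rng.uniform(1.3, 1.6)
            cand = coords[i - 1] + step * length
            # keep a clash-free margin to all previous atoms except the parent
            d = np.linalg.norm(coords[: max(i - 1, 0)] - cand, axis=1)
            if i == 1 or d.min() > 1.0:
                coords[i] = cand
                direction = step
                break
        else:  # pragma: no cover - practically unreachable
            raise EmchargeError("random_polymer could not place an atom")
    atoms = [Atom(i, spec.elements[i % len(spec.elements)], coords[i])
             for i in range(n)]
    bonds = [Bond(i, i + 1) for i in range(n - 1)]
    mol = Molecule(f"random_polymer-{n}-s{spec.seed}", atoms, bonds)
    mol.total_charge = spec.total_charge
    return mol


_BUILDERS = {
    "diatomic": _diatomic,
    "methane": _methane,
    "ammonium": _ammonium,
    "phenol_like": _phenol_like,
    "chain": _chain,
    "helix": _helix,
    "random_polymer": _random_polymer,
}


# ---------------------------------------------------------------------------
# toy parameter sets
# ---------------------------------------------------------------------------

def make_toy_parameters(method: str, elements: Sequence[str],
                        seed: int = 0) -> ParameterSet:
    """Full-coverage random-but-reproducible parameters for ``method``.

    Hardness-like slots are bounded well away from zero so the resulting
    equalization systems stay comfortably non-singular; magnitudes mirror the
    bundled literature sets.
    """
    if method not in METHODS:
        raise UnknownMethodError(f"unknown method id {method!r}")
    desc = METHODS[method]
    rng = np.random.default_rng(np.random.PCG64(seed))
    elements = sorted(set(elements))

    ranges = {
        "A": (2.0, 3.2), "B": (0.25, 0.6),          # eem/sfkeem
        "J": (8.0, 15.0),                           # qeq/eqeq
        "a": (7.0, 15.0), "b": (7.0, 12.0), "c": (0.4, 2.0),  # peoe/gdac
        "delta0": (0.0, 0.5),                       # delre
    }
    atom = {}
    for el in elements:
        row = {}
        for slot in desc.atom_slots:
            if slot == "chi":
                # anchor electronegativities to the Pauling ordering so the
                # toy chemistry stays physical (H less electronegative than
                # O/N; keeps the QEq hydrogen loop well inside convergence)
                row[slot] = float(1.8 * elemdata.pauling_electronegativity(el)
                                  + rng.uniform(0.0, 0.8))
            else:
                row[slot] = float(rng.uniform(*ranges[slot]))
        atom[(el, "plain", "*")] = row
    bond = {}
    if method == "delre":
        for i, e1 in enumerate(elements):
            for e2 in elements[i:]:
                for order in (1, 2, 3):
                    bond[(e1, e2, order)] = {
                        "gamma": float(rng.uniform(0.05, 0.25)),
                        "eps": float(rng.uniform(0.6, 1.4)),
                    }
    elif method == "eqeqc":
        for i, e1 in enumerate(elements):
            for e2 in elements[i:]:
                for order in (1, 2, 3):
                    bond[(e1, e2, order)] = {
                        "D": float(rng.uniform(-0.05, 0.05)) if e1 != e2 else 0.0,
                    }
    common = {}
    if method == "eem":
        common["kappa"] = 0.25
    elif method == "sfkeem":
        common["sigma"] = 0.6
    return ParameterSet(
        id=f"toy-{method}-s{seed}",
        method=method,
        citation="synthetic toy parameters (test support)",
        description=f"random full-coverage {method} parameters over {elements}",
        scheme="plain",
        common=common,
        atom=atom,
        bond=bond,
    )
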