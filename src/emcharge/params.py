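"""Parameter-set registry, applicability checking and automatic selection.

Parameter sets live in a small JSON dialect (see ``docs/methods.md`` for the
schema). Each file carries the citation of the publication its values were
transcribed from. A bundled registry under ``emcharge/data/parameters`` is
scanned on first use; user directories can be added on top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .errors import SchemaError, UnknownMethodError
from .molmodel import ELEMENTS, SCHEMES, AtomTypeKey, Molecule, classify_all

FORMAT_VERSION = "1"


@dataclass(frozen=True)
class MethodDescriptor:
    """Static description of one charge-calculation method."""

    id: str
    name: str
    dimensionality: str          # "2D" | "3D"
    needs_parameters: bool
    atom_slots: tuple[str, ...] = ()
    global_slots: tuple[str, ...] = ()
    bond_slots: tuple[str, ...] = ()
    supports_cutoff_cover: bool = False
    citation: str = ""


#: The ten implemented methods. 2D methods use the bond graph only; 3D
#: methods need coordinates. Cutoff/cover applies to the equalization
#: linear-system family only (iterative schemes use different machinery).
METHODS: dict[str, MethodDescriptor] = {
    m.id: m
    for m in [
        MethodDescriptor("peoe", "PEOE (Gasteiger-Marsili)", "2D", True,
                         atom_slots=("a", "b", "c"),
                         citation="Gasteiger & Marsili 1980, Tetrahedron 36:3219"),
        MethodDescriptor("mgc", "MGC (geometric-mean equalization)", "2D", False,
                         citation="Sanderson-type geometric-mean electronegativity equalization"),
        MethodDescriptor("delre", "Del Re", "2D", True,
                         atom_slots=("delta0",), bond_slots=("gamma", "eps"),
                         citation="Del Re 1958, J Chem Soc 4031"),
        MethodDescriptor("veem", "VEEM (valence-electron equalization)", "2D", False,
                         citation="parameter-free valence-electron equalization"),
        MethodDescriptor("eem", "EEM", "3D", True,
                         atom_slots=("A", "B"), global_slots=("kappa",),
                         supports_cutoff_cover=True,
                         citation="Mortier et al. 1986, J Am Chem Soc 108:4315"),
        MethodDescriptor("sfkeem", "SFKEEM", "3D", True,
                         atom_slots=("A", "B"), global_slots=("sigma",),
                         supports_cutoff_cover=True,
                         citation="Chaves et al. 2006, J Chem Inf Model 46:1657"),
        MethodDescriptor("qeq", "QEq", "3D", True,
                         atom_slots=("chi", "J"), supports_cutoff_cover=True,
                         citation="Rappe & Goddard 1991, J Phys Chem 95:3358"),
        MethodDescriptor("eqeq", "EQeq", "3D", True,
                         atom_slots=("chi", "J"), supports_cutoff_cover=True,
                         citation="Wilmer et al. 2012, J Phys Chem Lett 3:2506"),
        MethodDescriptor("eqeqc", "EQeq+C", "3D", True,
                         atom_slots=("chi", "J"), bond_slots=("D",),
                         supports_cutoff_cover=True,
                         citation="Martin-Noble et al. 2015, J Chem Theory Comput 11:3364"),
        MethodDescriptor("gdac", "GDAC (geometry-damped charges)", "3D", True,
                         atom_slots=("a", "b", "c"),
                         citation="geometry-damped iterative electronegativity equalization"),
    ]
}

#: Automatic-selection priority (first applicable wins).
PRIORITY_3D = ("eem", "sfkeem", "qeq", "eqeq", "eqeqc", "gdac")
PRIORITY_2D = ("peoe", "mgc", "delre", "veem")

#: Registry order of the bundled sets; also the tie-break order in
#: parameter-set selection. eem2015ha heads the list: it is the set whose
#: charges match the worked phenol example of the reference web service.
_BUILTIN_ORDER = [
    "eem2015ha", "eem2015hm", "eem2015hn",
    "eem2015ba", "eem2015bm", "eem2015bn",
    "qeq-rappe-goddard", "peoe-gasteiger", "gdac-gasteiger",
    "eqeq-ionization", "eqeqc-ionization",
]


@dataclass
class ParameterSet:
    id: str
    method: str
    citation: str = ""
    description: str = ""
    scheme: str = "plain"
    common: dict[str, float] = field(default_factory=dict)
    #: (element, scheme, value) -> {slot: value}
    atom: dict[tuple[str, str, str], dict[str, float]] = field(default_factory=dict)
    #: (element_i, element_j, order) -> {slot: value}; ordered as stored
    bond: dict[tuple[str, str, int], dict[str, float]] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    @property
    def descriptor(self) -> MethodDescriptor:
        return METHODS[self.method]

    def lookup_atom(self, key: AtomTypeKey) -> Optional[dict[str, float]]:
        """Exact (element, scheme, value) match, falling back to the
        wildcard value ``"*"`` for the same element and scheme."""
        hit = self.atom.get(key.as_tuple())
        if hit is None and key.value != "*":
            hit = self.atom.get((key.element, key.scheme, "*"))
        return hit

    def lookup_bond(self, el_i: str, el_j: str, order: int):
        """Bond parameters for an element pair; tries both orientations.

        Returns (params, sign) where sign is -1 when the stored orientation is
        reversed — antisymmetric slots (EQeq+C corrections) must be negated.
        """
        hit = self.bond.get((el_i, el_j, order))
        if hit is not None:
            return hit, 1
        hit = self.bond.get((el_j, el_i, order))
        if hit is not None:
            return hit, -1
        return None, 1

    def covered_elements(self) -> set[str]:
        return {el for el, _, _ in self.atom}


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------

def parameter_set_from_dict(obj: dict, source: str = "<dict>") -> ParameterSet:
    def fail(msg: str):
        raise SchemaError(f"{source}: {msg}")

    if not isinstance(obj, dict):
        fail("top level must be a JSON object")
    if obj.get("format_version") != FORMAT_VERSION:
        fail(f"format_version must be {FORMAT_VERSION!r}")
    method = obj.get("method")
    if method not in METHODS:
        raise UnknownMethodError(f"{source}: unknown method id {method!r}")
    desc = METHODS[method]
    scheme = obj.get("scheme", "plain")
    if scheme not in SCHEMES:
        fail(f"unknown scheme {scheme!r}")

    common = {k: float(v) for k, v in obj.get("common", {}).items()}
    for slot in desc.global_slots:
        if slot not in common:
            fail(f"method {method!r} requires global slot {slot!r} in 'common'")

    atom: dict[tuple, dict] = {}
    for row in obj.get("atom", []):
        el = row.get("element")
        if el not in ELEMENTS:
            fail(f"unknown element {el!r} in atom table")
        value = str(row.get("value", "*"))
        params = row.get("params", {})
        for slot in desc.atom_slots:
            if slot not in params:
                fail(f"atom entry {el}/{value}: missing slot {slot!r}")
        key = (el, scheme, value)
        if key in atom:
            fail(f"duplicate atom-type key {el}/{scheme}/{value}")
        atom[key] = {k: float(v) for k, v in params.items()}

    bond: dict[tuple, dict] = {}
    for row in obj.get("bond", []):
        els = row.get("elements")
        if not (isinstance(els, (list, tuple)) and len(els) == 2):
            fail("bond entry needs 'elements': [el_i, el_j]")
        order = int(row.get("order", 1))
        params = row.get("params", {})
        for slot in desc.bond_slots:
            if slot not in params:
                fail(f"bond entry {els}: missing slot {slot!r}")
        key = (els[0], els[1], order)
        if key in bond:
            fail(f"duplicate bond key {key}")
        bond[key] = {k: float(v) for k, v in params.items()}

    return ParameterSet(
        id=str(obj.get("id") or Path(source).stem),
        method=method,
        citation=str(obj.get("citation", "")),
        description=str(obj.get("description", "")),
        scheme=scheme,
        common=common,
        atom=atom,
        bond=bond,
        units=dict(obj.get("units", {})),
    )


def load_parameter_set(path) -> ParameterSet:
    """Load and validate one parameter-set JSON file."""
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return parameter_set_from_dict(obj, source=str(path))


_registry_cache: Optional[list[ParameterSet]] = None


def builtin_registry() -> list[ParameterSet]:
    """The bundled parameter sets, in registry (priority) order."""
    global _registry_cache
    if _registry_cache is None:
        root = resources.files("emcharge").joinpath("data/parameters")
        by_id = {}
        for entry in root.iterdir():
            if entry.name.endswith(".json"):
                ps = parameter_set_from_dict(json.loads(entry.read_text()),
                                             source=entry.name)
                by_id[ps.id] = ps
        ordered = [by_id.pop(i) for i in _BUILTIN_ORDER if i in by_id]
        _registry_cache = ordered + [by_id[k] for k in sorted(by_id)]
    return list(_registry_cache)


def full_registry(extra_dirs: Optional[list] = None) -> list[ParameterSet]:
    """Builtin registry plus any user directories (scanned in given order)."""
    reg = builtin_registry()
    for d in extra_dirs or []:
        for path in sorted(Path(d).glob("*.json")):
            reg.append(load_parameter_set(path))
    return reg


def atom_parameter_arrays(ps: ParameterSet, mol: Molecule) -> dict[str, list[float]]:
    """Per-atom parameter vectors for every declared atom slot.

    Raises :class:`CoverageError` listing every uncovered atom type.
    """
    from .errors import CoverageError  # local import to keep module deps flat

    slots = ps.descriptor.atom_slots
    out: dict[str, list[float]] = {s: [] for s in slots}
    missing = []
    for key in classify_all(mol, ps.scheme):
        row = ps.lookup_atom(key)
        if row is None:
            missing.append(key.as_tuple())
            continue
        for s in slots:
            out[s].append(row[s])
    if missing:
        raise CoverageError(ps.id, missing)
    return out


# ---------------------------------------------------------------------------
# applicability & selection
# ---------------------------------------------------------------------------

def applicability(ps: ParameterSet, mol: Molecule) -> tuple[bool, list[AtomTypeKey]]:
    """Does ``ps`` cover every atom of ``mol``? Returns (ok, missing keys)."""
    missing = []
    for key in classify_all(mol, ps.scheme):
        if ps.lookup_atom(key) is None:
            missing.append(key)
    uniq = sorted(set(missing), key=lambda k: k.as_tuple())
    return (not uniq, uniq)


def method_applicable(method: MethodDescriptor, mols: list[Molecule],
                      registry: list[ParameterSet]) -> Optional[ParameterSet]:
    """First parameter set (selection rule below) making ``method`` runnable
    on every molecule, or a bare None-parameter marker for parameter-free
    methods. Returns None when the method is not applicable.

    Among a method's applicable sets the one covering the inputs with the
    fewest surplus atom types wins; ties resolve to registry order.
    """
    if method.dimensionality == "3D" and not all(m.has_coordinates() for m in mols):
        return None
    if not method.needs_parameters:
        return ParameterSet(id="none", method=method.id)
    best = None
    best_surplus = None
    for ps in registry:
        if ps.method != method.id:
            continue
        if all(applicability(ps, m)[0] for m in mols):
            used = set()
            for m in mols:
                used.update(k.as_tuple() for k in classify_all(m, ps.scheme))
            surplus = sum(
                1 for key in ps.atom
                if key not in used
                and not any(u[0] == key[0] and key[2] == "*" for u in used)
            )
            if best is None or surplus < best_surplus:
                best, best_surplus = ps, surplus
    return best


def select_automatic(mols: list[Molecule],
                     registry: Optional[list[ParameterSet]] = None
                     ) -> tuple[MethodDescriptor, Optional[ParameterSet]]:
    """Deterministic automatic method/parameter-set choice.

    3D methods are preferred whenever all molecules carry coordinates, in the
    fixed order EEM, SFKEEM, QEq, EQeq, EQeq+C, GDAC; otherwise the 2D order
    PEOE, MGC, DelRe, VEEM applies. The result does not depend on molecule
    ordering.
    """
    if not mols:
        raise ValueError("select_automatic requires at least one molecule")
    registry = registry if registry is not None else builtin_registry()
    all_3d = all(m.has_coordinates() for m in mols)
    orders = (PRIORITY_3D + PRIORITY_2D) if all_3d else PRIORITY_2D
    for mid in orders:
        desc = METHODS[mid]
        ps = method_applicable(desc, mols, registry)
        if ps is not None:
            return desc, (None if ps.id == "none" else ps)
    raise UnknownMethodError("no applicable method for the given molecules")
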