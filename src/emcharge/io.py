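"""Structure readers/writers and input validation.

Readers: SDF (V2000), MOL2 (TRIPOS), PDB and mmCIF, plus zip / tar.gz
archives of those. PDB/mmCIF go through gemmi; SDF and MOL2 are parsed here
because validation must point at the offending line. Formats that carry no
bond list get bonds perceived from covalent radii.

Writers: PQR, MOL2 and plaintext, with computed charges; SDF and PDB writers
exist for fixture round-trips.

Validation is total: any byte sequence maps to a :class:`ValidationReport`
entry, never an unstructured crash.
"""

from __future__ import annotations

import io as _io
import tarfile
import tempfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import elemdata
from .errors import EmchargeError, FormatError
from .molmodel import ELEMENTS, Atom, Bond, Molecule, normalize_element
from .result import ChargeResult

DEFAULT_MAX_FILE_SIZE = 10 * 1024 * 1024  # bytes; mirrors the 10 MB guard

#: perceived bond criterion: r_cov(i) + r_cov(j) + BOND_TOLERANCE >= R > MIN_BOND
BOND_TOLERANCE = 0.4   # Å
MIN_BOND = 0.4         # Å; closer pairs are steric clashes, not bonds


@dataclass
class Issue:
    severity: str        # "error" | "warning"
    message: str
    file: str = ""
    molecule: str = ""


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def error(self, message, file="", molecule=""):
        self.issues.append(Issue("error", message, file, molecule))

    def warning(self, message, file="", molecule=""):
        self.issues.append(Issue("warning", message, file, molecule))

    def extend(self, other: "ValidationReport"):
        self.issues.extend(other.issues)


# ---------------------------------------------------------------------------
# bond perception
# ---------------------------------------------------------------------------

def perceive_bonds(mol: Molecule, report: ValidationReport | None = None) -> Molecule:
    """Create order-1 bonds for every pair with R <= r_cov(i)+r_cov(j)+0.4 Å
    (and R > 0.4 Å; closer pairs get a clash warning instead)."""
    report = report if report is not None else ValidationReport()
    xyz = mol.coords_array()
    radii = np.array([elemdata.covalent_radius(a.element) for a in mol.atoms])
    bonds: list[Bond] = []
    # grid-free O(N^2) would not scale to proteins; use a KD-tree
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    rmax = 2 * radii.max() + BOND_TOLERANCE
    for i, j in sorted(tree.query_pairs(rmax)):
        r = float(np.linalg.norm(xyz[i] - xyz[j]))
        if r <= MIN_BOND:
            report.warning(
                f"atoms {i} ({mol.atoms[i].element}) and {j} "
                f"({mol.atoms[j].element}) clash at {r:.2f} Å",
                molecule=mol.name)
            continue
        if r <= radii[i] + radii[j] + BOND_TOLERANCE:
            bonds.append(Bond(i, j, 1))
    mol.bonds = bonds
    mol.validate()
    return mol


# ---------------------------------------------------------------------------
# SDF (V2000)
# ---------------------------------------------------------------------------

def _parse_sdf(text: str, source: str, report: ValidationReport) -> list[Molecule]:
    mols = []
    records = text.replace("\r\n", "\n").split("$$$$\n")
    for rec in records:
        if not rec.strip():
            continue
        lines = rec.split("\n")
        if len(lines) < 4:
            report.error("SDF record too short (no counts line)", file=source)
            continue
        name = lines[0].strip() or f"mol{len(mols) + 1}"
        counts = lines[3]
        if "V3000" in counts:
            report.error(
                f"{name}: SDF V3000 is not supported (V2000 only)",
                file=source, molecule=name)
            continue
        try:
            n_atoms = int(counts[0:3])
            n_bonds = int(counts[3:6])
        except (ValueError, IndexError):
            report.error(f"{name}: malformed counts line (line 4): {counts!r}",
                         file=source, molecule=name)
            continue
        try:
            atoms, bonds = [], []
            for i in range(n_atoms):
                ln = lines[4 + i]
                x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
                el = normalize_element(ln[31:34])
                atoms.append(Atom(i, el, np.array([x, y, z])))
            for k in range(n_bonds):
                ln = lines[4 + n_atoms + k]
                i, j, order = int(ln[0:3]), int(ln[3:6]), int(ln[6:9])
                bonds.append(Bond(i - 1, j - 1, min(order, 3)))
            for ln in lines[4 + n_atoms + n_bonds:]:
                if ln.startswith("M  CHG"):
                    fields = ln.split()
                    n_entries = int(fields[2])
                    for e in range(n_entries):
                        ai = int(fields[3 + 2 * e]) - 1
                        atoms[ai].formal_charge = int(fields[4 + 2 * e])
                elif ln.startswith("M  END"):
                    break
            mols.append(Molecule(name, atoms, bonds))
        except (ValueError, IndexError, EmchargeError) as exc:
            report.error(f"{name}: unparsable V2000 block "
                         f"(around line {4 + len(atoms) + 1}): {exc}",
                         file=source, molecule=name)
    if not mols and not report.issues:
        report.error("empty SDF input", file=source)
    return mols


def write_sdf(mols: list[Molecule], path) -> None:
    """Minimal V2000 writer (fixture export / round-trips)."""
    out = []
    for mol in mols:
        out.append(mol.name)
        out.append("  emcharge")
        out.append("")
        out.append(f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
        for a in mol.atoms:
            x, y, z = (a.coords if a.coords is not None else (0.0, 0.0, 0.0))
            out.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
        for b in mol.bonds:
            out.append(f"{b.i + 1:3d}{b.j + 1:3d}{b.order:3d}  0")
        charged = [(a.index + 1, a.formal_charge) for a in mol.atoms if a.formal_charge]
        for k in range(0, len(charged), 8):
            chunk = charged[k:k + 8]
            out.append("M  CHG" + f"{len(chunk):3d}" +
                       "".join(f"{i:4d}{c:4d}" for i, c in chunk))
        out.append("M  END")
        out.append("$$$$")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# MOL2 (TRIPOS)
# ---------------------------------------------------------------------------

_MOL2_ORDERS = {"1": 1, "2": 2, "3": 3, "am": 1, "ar": 1, "du": 1, "un": 1}


def _parse_mol2(text: str, source: str, report: ValidationReport) -> list[Molecule]:
    mols = []
    chunks = text.replace("\r\n", "\n").split("@<TRIPOS>MOLECULE")
    for chunk in chunks[1:]:
        lines = chunk.split("\n")
        name = (lines[1].strip() if len(lines) > 1 else "") or f"mol{len(mols) + 1}"
        sections: dict[str, list[str]] = {}
        current = None
        for ln in lines[2:]:
            if ln.startswith("@<TRIPOS>"):
                current = ln[9:].strip().upper()
                sections[current] = []
            elif current is not None:
                sections[current].append(ln)
        try:
            atoms = []
            aromatic_seen = False
            for ln in sections.get("ATOM", []):
                f = ln.split()
                if not f:
                    continue
                idx = len(atoms)
                el = f[5].split(".")[0]
                atoms.append(Atom(idx, normalize_element(el),
                                  np.array([float(f[2]), float(f[3]), float(f[4])]),
                                  name=f[1]))
            bonds = []
            for ln in sections.get("BOND", []):
                f = ln.split()
                if not f:
                    continue
                typ = f[3].lower()
                if typ not in _MOL2_ORDERS:
                    raise FormatError(f"unknown TRIPOS bond type {typ!r}")
                if typ in ("ar", "am"):
                    aromatic_seen = True
                bonds.append(Bond(int(f[1]) - 1, int(f[2]) - 1, _MOL2_ORDERS[typ]))
            if not atoms:
                report.error(f"{name}: MOL2 record has no ATOM section",
                             file=source, molecule=name)
                continue
            if aromatic_seen:
                report.warning(
                    f"{name}: aromatic/amide MOL2 bonds read as order 1 "
                    "(no aromaticity model)", file=source, molecule=name)
            mols.append(Molecule(name, atoms, bonds))
        except (ValueError, IndexError, EmchargeError) as exc:
            report.error(f"{name}: unparsable MOL2 record: {exc}",
                         file=source, molecule=name)
    if not mols and not report.issues:
        report.error("no @<TRIPOS>MOLECULE record found", file=source)
    return mols


def _write_mol2(mols, results, path):
    out = []
    for mol, res in zip(mols, results):
        out.append("@<TRIPOS>MOLECULE")
        out.append(mol.name)
        out.append(f"{len(mol.atoms)} {len(mol.bonds)} 0 0 0")
        out.append("SMALL")
        out.append(res.method.upper() if res else "NO_CHARGES")
        out.append("@<TRIPOS>ATOM")
        for a in mol.atoms:
            x, y, z = a.coords if a.coords is not None else (0.0, 0.0, 0.0)
            q = res.charges[a.index] if res else 0.0
            label = a.name or f"{a.element}{a.index + 1}"
            out.append(f"{a.index + 1:>7} {label:<8} {x:9.4f} {y:9.4f} {z:9.4f} "
                       f"{a.element:<5} 1 UNL {q:9.4f}")
        out.append("@<TRIPOS>BOND")
        for k, b in enumerate(mol.bonds):
            out.append(f"{k + 1:>6} {b.i + 1:>5} {b.j + 1:>5} {b.order}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# PDB / mmCIF via gemmi
# ---------------------------------------------------------------------------

def _structure_to_molecule(st: gemmi.Structure, source: str,
                           report: ValidationReport) -> Molecule | None:
    st.setup_entities()
    if len(st) == 0:
        report.error("structure contains no models", file=source)
        return None
    if len(st) > 1:
        report.warning(f"{len(st)} models present; reading the first only",
                       file=source, molecule=st.name)
    model = st[0]
    atoms: list[Atom] = []
    # altloc policy: keep highest occupancy, ties -> first encountered
    for chain in model:
        for residue in chain:
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in residue:
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > prev.occ:
                    best[at.name] = at
            for nm in order:
                at = best[nm]
                el = at.element.name
                if el not in ELEMENTS:
                    report.warning(f"skipping atom {nm} with unknown element {el!r}",
                                   file=source, molecule=st.name)
                    continue
                atoms.append(Atom(len(atoms), el,
                                  np.array([at.pos.x, at.pos.y, at.pos.z]),
                                  formal_charge=int(at.charge),
                                  name=nm,
                                  residue_info=(residue.name, residue.seqid.num,
                                                chain.name)))
    if not atoms:
        report.error("no atoms found", file=source)
        return None
    name = st.name or Path(source).stem
    mol = Molecule(name, atoms, [])
    if not any(a.element == "H" for a in atoms):
        report.warning("polymer input contains no hydrogen atoms; charges will "
                       "refer to the heavy-atom-only structure",
                       file=source, molecule=name)
    return mol


def _conect_bonds(text: str, mol: Molecule, serial_to_index: dict[int, int]) -> list[Bond]:
    pairs = set()
    for ln in text.splitlines():
        if ln.startswith("CONECT"):
            fields = ln.split()
            try:
                serials = [int(x) for x in fields[1:]]
            except ValueError:
                continue
            if not serials:
                continue
            a = serial_to_index.get(serials[0])
            for s in serials[1:]:
                b = serial_to_index.get(s)
                if a is not None and b is not None and a != b:
                    pairs.add((min(a, b), max(a, b)))
    return [Bond(i, j, 1) for i, j in sorted(pairs)]


def _parse_pdb(text: str, source: str, report: ValidationReport) -> list[Molecule]:
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        report.error(f"unparsable PDB: {exc}", file=source)
        return []
    mol = _structure_to_molecule(st, source, report)
    if mol is None:
        return []
    # honour CONECT records where present; map serials via a second pass
    serial_to_index = {}
    idx = 0
    for ln in text.splitlines():
        if ln.startswith(("ATOM  ", "HETATM")):
            alt = ln[16] if len(ln) > 16 else " "
            if alt not in (" ", "A"):  # matches the keep-first-altloc policy
                continue
            try:
                serial_to_index[int(ln[6:11])] = idx
            except ValueError:
                pass
            idx += 1
    bonds = _conect_bonds(text, mol, serial_to_index) if "CONECT" in text else []
    if bonds and idx == len(mol.atoms):
        mol.bonds = bonds
        mol.validate()
    else:
        perceive_bonds(mol, report)
    return [mol]


def _parse_cif(text: str, source: str, report: ValidationReport) -> list[Molecule]:
    try:
        doc = gemmi.cif.read_string(text)
        st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        report.error(f"unparsable mmCIF: {exc}", file=source)
        return []
    mol = _structure_to_molecule(st, source, report)
    if mol is None:
        return []
    perceive_bonds(mol, report)
    return [mol]


# ---------------------------------------------------------------------------
# format detection & top-level reading
# ---------------------------------------------------------------------------

_EXTENSIONS = {".sdf": "sdf", ".mol": "sdf", ".mol2": "mol2",
               ".pdb": "pdb", ".ent": "pdb", ".cif": "cif", ".mmcif": "cif"}


def detect_format(path: Path, text: str) -> str | None:
    fmt = _EXTENSIONS.get(path.suffix.lower())
    if fmt:
        return fmt
    if "@<TRIPOS>MOLECULE" in text:
        return "mol2"
    head = text[:4096]
    if head.lstrip().startswith("data_") or "_atom_site" in text:
        return "cif"
    if any(ln.startswith(("ATOM  ", "HETATM", "HEADER")) for ln in head.splitlines()):
        return "pdb"
    lines = text.split("\n")
    if len(lines) > 3 and ("V2000" in lines[3] or "V3000" in lines[3]):
        return "sdf"
    return None


_PARSERS = {"sdf": _parse_sdf, "mol2": _parse_mol2, "pdb": _parse_pdb,
            "cif": _parse_cif}


def _is_archive(path: Path) -> bool:
    name = path.name.lower()
    return (name.endswith(".zip") or name.endswith(".tar.gz")
            or name.endswith(".tgz") or name.endswith(".tar"))


def read_structures(path, max_file_size: int = DEFAULT_MAX_FILE_SIZE,
                    _nested: bool = False) -> tuple[list[Molecule], ValidationReport]:
    """Read one structure file or archive; never raises on bad input.

    Returns every molecule found plus a validation report. Archive members
    are processed recursively (one level; nested archives are rejected).
    """
    report = ValidationReport()
    path = Path(path)
    if not path.exists():
        report.error(f"no such file: {path}")
        return [], report
    if path.stat().st_size > max_file_size:
        report.error(f"{path.name}: file exceeds the "
                     f"{max_file_size // (1024 * 1024)} MB size limit", file=str(path))
        return [], report

    if _is_archive(path):
        if _nested:
            report.error(f"{path.name}: nested archives are not supported",
                         file=str(path))
            return [], report
        return _read_archive(path, max_file_size, report)

    try:
        text = path.read_text(errors="replace")
    except OSError as exc:
        report.error(f"{path.name}: unreadable ({exc})", file=str(path))
        return [], report
    if not text.strip():
        report.error(f"{path.name}: empty input", file=str(path))
        return [], report
    fmt = detect_format(path, text)
    if fmt is None:
        report.error(f"{path.name}: unsupported or unrecognized format "
                     "(expected SDF, MOL2, PDB or mmCIF)", file=str(path))
        return [], report
    try:
        mols = _PARSERS[fmt](text, path.name, report)
    except Exception as exc:  # total validation: no unstructured crashes
        report.error(f"{path.name}: internal parse failure ({exc})", file=str(path))
        return [], report
    return mols, report


def _read_archive(path: Path, max_file_size, report):
    mols: list[Molecule] = []
    try:
        with tempfile.TemporaryDirectory() as tmp:
            members: list[Path] = []
            if path.name.lower().endswith(".zip"):
                with zipfile.ZipFile(path) as zf:
                    zf.extractall(tmp)
            else:
                with tarfile.open(path) as tf:
                    tf.extractall(tmp, filter="data")
            for member in sorted(Path(tmp).rglob("*")):
                if member.is_file():
                    members.append(member)
            if not members:
                report.error(f"{path.name}: archive is empty", file=str(path))
            for member in members:
                sub_mols, sub_report = read_structures(
                    member, max_file_size, _nested=True)
                for issue in sub_report.issues:
                    issue.file = f"{path.name}:{member.name}"
                report.extend(sub_report)
                mols.extend(sub_mols)
    except (zipfile.BadZipFile, tarfile.TarError, OSError) as exc:
        report.error(f"{path.name}: broken archive ({exc})", file=str(path))
    return mols, report


# ---------------------------------------------------------------------------
# charge writers
# ---------------------------------------------------------------------------

def _write_txt(mols, results, path):
    out = []
    for mol, res in zip(mols, results):
        out.append(mol.name)
        out.append(" ".join(f"{q:.4f}" for q in res.charges))
    Path(path).write_text("\n".join(out) + "\n")


def _write_pqr(mols, results, path):
    out = []
    for mol, res in zip(mols, results):
        for a in mol.atoms:
            if a.residue_info is None:
                raise FormatError(
                    f"{mol.name}: PQR requires residue information "
                    "(polymer input); use the txt format for small molecules")
            resname, resnum, chain = a.residue_info
            x, y, z = a.coords if a.coords is not None else (0.0, 0.0, 0.0)
            out.append(
                f"ATOM {a.index + 1:6d} {a.name or a.element:<4} {resname:<4} "
                f"{chain or 'A'} {resnum:4d} "
                f"{x:8.3f} {y:8.3f} {z:8.3f} "
                f"{res.charges[a.index]:8.4f} {elemdata.covalent_radius(a.element):7.4f}")
        out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


def write_charges(results: list[ChargeResult], mols: list[Molecule],
                  fmt: str, path) -> None:
    """Write computed charges in ``pqr``, ``mol2`` or ``txt`` format."""
    if len(results) != len(mols):
        raise EmchargeError("results and molecules are not aligned")
    writers = {"txt": _write_txt, "pqr": _write_pqr, "mol2": _write_mol2}
    if fmt not in writers:
        raise FormatError(f"unknown output format {fmt!r} (pqr, mol2 or txt)")
    writers[fmt](mols, results, path)


def write_pdb(mol: Molecule, path) -> None:
    """Minimal PDB writer (fixture export)."""
    out = []
    for a in mol.atoms:
        resname, resnum, chain = a.residue_info or ("UNL", 1, "A")
        x, y, z = a.coords if a.coords is not None else (0.0, 0.0, 0.0)
        out.append(f"HETATM{a.index + 1:5d} {(a.name or a.element):<4}"
                   f"{resname:>4} {chain}{resnum:4d}    "
                   f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                   f"{a.element:>2}")
    for b in mol.bonds:
        out.append(f"CONECT{b.i + 1:5d}{b.j + 1:5d}")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")
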