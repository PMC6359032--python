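"""Shared domain types and readers/writers for the formats the pipeline touches.

Covers XYZ geometries (Å), Gaussian cube scalar fields (Bohr), and the
delimited summary-table format that carries frontier-orbital energies,
Hirshfeld charge triplets, species enthalpies and bond-critical-point
properties into the analysis stages.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .units import ANGSTROM_TO_BOHR


class ReactikitError(Exception):
    """Base class for all package errors."""


class FormatError(ReactikitError):
    """A file does not follow its declared convention."""


class SchemaError(ReactikitError):
    """A summary table is missing a required column or section."""


class UnitError(ReactikitError):
    """A required unit declaration is absent or unrecognised."""


class MediumError(ReactikitError):
    """A medium is unknown or lacks required reference enthalpies."""


class ContractError(ReactikitError):
    """An operation was called with inputs violating its contract."""


# Atomic numbers for the elements the pipeline can meet; extend as needed.
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element symbol, Cartesian position in Å, 1-based index."""

    element: str
    position: np.ndarray  # (3,) float, Å
    index: int

    def __post_init__(self):
        if self.element not in ATOMIC_NUMBERS:
            raise ContractError(f"unrecognised element symbol {self.element!r}")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise ContractError("position must be a 3-vector")
        if self.index < 1:
            raise ContractError("atom indices are 1-based")


@dataclass
class MoleculeGeometry:
    """A named molecule: ordered atoms plus optional named fragments.

    Fragments are named groups of 1-based atom indices; they may cover only
    a subset of atoms but must not overlap. They drive the intra/inter
    partition of the IGM delta-g descriptor.
    """

    name: str
    atoms: list[AtomRecord]
    fragments: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise ContractError("atom indices must be unique within a molecule")
        seen: set[int] = set()
        valid = set(indices)
        for fname, members in self.fragments.items():
            for i in members:
                if i not in valid:
                    raise ContractError(
                        f"fragment {fname!r} references unknown atom index {i}")
                if i in seen:
                    raise ContractError(
                        f"fragments overlap at atom index {i}")
                seen.add(i)

    def __len__(self) -> int:
        return len(self.atoms)

    def positions_angstrom(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def positions_bohr(self) -> np.ndarray:
        return self.positions_angstrom() * ANGSTROM_TO_BOHR

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


@dataclass(frozen=True)
class Medium:
    """A solvent environment (or the gas phase).

    ``reference_enthalpies`` holds H(H•), H(e−), H(H+) in kcal/mol; they are
    required for any thermodynamic-cycle work. The gas-phase values are the
    commonly accepted −312.30, 0.75 and 1.48 kcal/mol; solvent values are
    literature inputs the user must supply.
    """

    name: str
    dielectric: float
    H_hydrogen_atom: float | None = None  # H(H•), kcal/mol
    H_electron: float | None = None       # H(e−), kcal/mol
    H_proton: float | None = None         # H(H+), kcal/mol

    def __post_init__(self):
        if not self.dielectric > 0:
            raise ContractError("dielectric must be positive")

    @property
    def has_references(self) -> bool:
        return None not in (self.H_hydrogen_atom, self.H_electron, self.H_proton)

    @property
    def cycle_constant(self) -> float:
        """H(H+) + H(e−) − H(H•) in kcal/mol (gas: 314.53)."""
        if not self.has_references:
            raise MediumError(
                f"medium {self.name!r} has no reference enthalpies configured")
        return self.H_proton + self.H_electron - self.H_hydrogen_atom


GAS_REFERENCE_ENTHALPIES = {
    "H_hydrogen_atom": -312.30,
    "H_electron": 0.75,
    "H_proton": 1.48,
}

#: Media studied by the pipeline's reference system; dielectrics are the SMD
#: inputs of the source calculations. Gas dielectric is vacuum (1.0).
DEFAULT_MEDIA: dict[str, Medium] = {
    "gas": Medium("gas", 1.0, **GAS_REFERENCE_ENTHALPIES),
    "benzene": Medium("benzene", 2.27),
    "acetic acid": Medium("acetic acid", 6.25),
    "ethanol": Medium("ethanol", 24.85),
    "lactic acid": Medium("lactic acid", 22.00),
    "formic acid": Medium("formic acid", 51.1),
    "water": Medium("water", 78.35),
}


def normalize_medium_name(name: str) -> str:
    """Case-insensitive, whitespace-trimmed medium key ('Gas phase' → 'gas')."""
    key = name.strip().lower()
    if key.endswith(" phase"):
        key = key[: -len(" phase")].strip()
    return key


def resolve_medium(name: str,
                   media: Mapping[str, Medium] | None = None) -> Medium:
    registry = dict(DEFAULT_MEDIA)
    if media:
        registry.update({normalize_medium_name(k): v for k, v in media.items()})
    key = normalize_medium_name(name)
    if key not in registry:
        raise MediumError(f"unknown medium {name!r}")
    return registry[key]


@dataclass
class GridField:
    """A scalar field sampled on a regular 3-D grid (Bohr units)."""

    origin: np.ndarray   # (3,) Bohr
    spacing: np.ndarray  # (3,) Bohr
    dims: tuple[int, int, int]
    values: np.ndarray   # dims-shaped
    quantity: str = "field"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ContractError("grid spacing components must be positive")
        self.dims = tuple(int(d) for d in self.dims)
        if any(d <= 0 for d in self.dims):
            raise ContractError("grid dims must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != int(np.prod(self.dims)):
            raise ContractError("value count must equal the product of dims")
        self.values = self.values.reshape(self.dims)

    def points_bohr(self) -> np.ndarray:
        """All grid points, shape (nx*ny*nz, 3), z-fastest order."""
        nx, ny, nz = self.dims
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        idx = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3)
        return self.origin + idx * self.spacing


# ---------------------------------------------------------------------------
# XYZ

def read_xyz(path) -> MoleculeGeometry:
    """Read an XYZ file (count line, comment line, `element x y z` rows, Å)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        declared = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: line 1: unparseable atom count") from exc
    name = lines[1].strip() if len(lines) > 1 else ""
    atoms: list[AtomRecord] = []
    for lineno, raw in enumerate(lines[2:], start=3):
        if not raw.strip():
            continue
        parts = raw.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: line {lineno}: expected `element x y z`")
        try:
            pos = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno}: unparseable coordinate") from exc
        atoms.append(AtomRecord(parts[0], np.array(pos), len(atoms) + 1))
    if len(atoms) != declared:
        raise FormatError(
            f"{path}: declared {declared} atoms but found {len(atoms)}")
    return MoleculeGeometry(name=name or path.stem, atoms=atoms)


def write_xyz(geometry: MoleculeGeometry, path) -> None:
    path = Path(path)
    out = [str(len(geometry)), geometry.name]
    for a in geometry.atoms:
        x, y, z = a.position
        out.append(f"{a.element:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Gaussian cube

def write_cube(fieldobj: GridField, geometry: MoleculeGeometry, path) -> None:
    """Write a Gaussian cube file: header in Bohr, values z-fastest, 6/line."""
    path = Path(path)
    nx, ny, nz = fieldobj.dims
    if fieldobj.values.shape != (nx, ny, nz):
        raise ContractError("field dims and values disagree")
    buf = io.StringIO()
    buf.write(f"reactikit cube: {fieldobj.quantity}\n")
    buf.write(f"molecule: {geometry.name}\n")
    natom = len(geometry)
    ox, oy, oz = fieldobj.origin
    buf.write(f"{natom:5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}\n")
    sx, sy, sz = fieldobj.spacing
    buf.write(f"{nx:5d} {sx:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
    buf.write(f"{ny:5d} {0.0:12.6f} {sy:12.6f} {0.0:12.6f}\n")
    buf.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {sz:12.6f}\n")
    for a in geometry.atoms:
        z = ATOMIC_NUMBERS[a.element]
        bx, by, bz = a.position * ANGSTROM_TO_BOHR
        buf.write(f"{z:5d} {float(z):12.6f} {bx:12.6f} {by:12.6f} {bz:12.6f}\n")
    flat = fieldobj.values.reshape(-1)  # C order == z fastest
    for start in range(0, flat.size, 6):
        chunk = flat[start:start + 6]
        buf.write(" ".join(f"{v: .5E}" for v in chunk) + "\n")
    path.write_text(buf.getvalue())


def read_cube(path) -> tuple[GridField, MoleculeGeometry]:
    """Read a Gaussian cube file written by :func:`write_cube` (tests/round-trips)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    quantity = lines[0].split(":", 1)[-1].strip() or "field"
    natom_line = lines[2].split()
    natom = int(natom_line[0])
    origin = np.array([float(v) for v in natom_line[1:4]])
    dims, spacing = [], []
    for axis in range(3):
        parts = lines[3 + axis].split()
        dims.append(int(parts[0]))
        spacing.append(float(parts[1 + axis]))
    atoms = []
    sym = {v: k for k, v in ATOMIC_NUMBERS.items()}
    for i in range(natom):
        parts = lines[6 + i].split()
        z = int(parts[0])
        pos_bohr = np.array([float(v) for v in parts[2:5]])
        atoms.append(AtomRecord(sym[z], pos_bohr / ANGSTROM_TO_BOHR, i + 1))
    values = []
    for raw in lines[6 + natom:]:
        values.extend(float(v) for v in raw.split())
    fieldobj = GridField(origin, spacing, tuple(dims), np.array(values), quantity)
    geom = MoleculeGeometry(name=path.stem, atoms=atoms)
    return fieldobj, geom


# ---------------------------------------------------------------------------
# Summary tables

#: required columns per section of the summary-table format
_SECTION_SCHEMAS = {
    "orbitals": ("molecule", "medium", "E_HOMO", "E_LUMO"),
    "charges": ("molecule", "medium", "atom", "q_N", "q_Nminus1", "q_Nplus1"),
    "enthalpies": ("molecule", "medium", "site",
                   "H_ROH", "H_cation", "H_radical", "H_anion"),
    "bcp": ("molecule", "medium", "bond", "rho", "lap", "V", "G"),
}

_EXPECTED_UNITS = {
    "orbitals": {"ev"},
    "charges": {"e"},
    "enthalpies": {"kcal/mol"},
    "bcp": {"a.u.", "au"},
}


@dataclass(frozen=True)
class OrbitalRow:
    molecule: str
    medium: str
    E_HOMO: float  # eV
    E_LUMO: float  # eV


@dataclass(frozen=True)
class ChargeRow:
    molecule: str
    medium: str
    atom: str
    q_N: float
    q_Nminus1: float
    q_Nplus1: float


@dataclass(frozen=True)
class EnthalpyRow:
    molecule: str
    medium: str
    site: str
    H_ROH: float
    H_cation: float
    H_radical: float
    H_anion: float


@dataclass(frozen=True)
class BCPRow:
    molecule: str
    medium: str
    bond: str
    rho: float
    lap: float
    V: float
    G: float


@dataclass
class SummaryTables:
    orbitals: list[OrbitalRow]
    charges: list[ChargeRow]
    enthalpies: list[EnthalpyRow]
    bcp: list[BCPRow]
    media: dict[str, Medium]


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _parse_config(lines: list[str]) -> dict[str, str]:
    cfg = {}
    for raw in lines:
        stripped = raw.strip().lstrip("#").strip()
        if not stripped or "=" not in stripped:
            continue
        key, _, value = stripped.partition("=")
        cfg[key.strip().lower()] = value.strip()
    return cfg


def read_summary_tables(path) -> SummaryTables:
    """Parse a summary-table file into typed records.

    The format is a key-value configuration block (``units.<section> = <unit>``
    and optional ``medium.<name>.<field> = <value>`` lines, ``#`` prefixes
    allowed) followed by ``[section]`` blocks each holding a delimited table
    (comma or tab) with a header row. Sections: orbitals, charges,
    enthalpies, bcp; any subset may be present.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    # split into preamble + sections
    sections: dict[str, list[str]] = {}
    preamble: list[str] = []
    current: list[str] | None = None
    for raw in lines:
        m = re.fullmatch(r"\[([a-zA-Z_]+)\]", raw.strip())
        if m:
            name = m.group(1).lower()
            if name not in _SECTION_SCHEMAS:
                raise SchemaError(f"{path}: unknown section [{name}]")
            current = sections.setdefault(name, [])
            continue
        if current is None:
            preamble.append(raw)
        elif raw.strip() and not raw.strip().startswith("#"):
            current.append(raw)

    cfg = _parse_config(preamble)

    # media from config
    media: dict[str, Medium] = {}
    med_fields: dict[str, dict[str, float]] = {}
    for key, value in cfg.items():
        m = re.fullmatch(r"medium\.(.+)\.([a-z_]+)", key)
        if m:
            med_fields.setdefault(m.group(1), {})[m.group(2)] = float(value)
    for name, fields in med_fields.items():
        media[normalize_medium_name(name)] = Medium(
            name=name,
            dielectric=fields.get("dielectric", 1.0),
            H_hydrogen_atom=fields.get("h_hydrogen_atom"),
            H_electron=fields.get("h_electron"),
            H_proton=fields.get("h_proton"),
        )

    def check_unit(section: str) -> None:
        declared = cfg.get(f"units.{section}")
        if declared is None:
            raise UnitError(
                f"{path}: missing `units.{section}` declaration")
        if declared.strip().lower() not in _EXPECTED_UNITS[section]:
            raise UnitError(
                f"{path}: units.{section} = {declared!r} is not supported")

    def parse_section(name: str) -> list[dict[str, str]]:
        body = sections.get(name, [])
        if not body:
            return []
        check_unit(name)
        delim = _sniff_delimiter(body[0])
        reader = csv.DictReader(io.StringIO("\n".join(body)), delimiter=delim)
        header = reader.fieldnames or []
        for col in _SECTION_SCHEMAS[name]:
            if col not in header:
                raise SchemaError(
                    f"{path}: section [{name}] missing required column {col!r}")
        return list(reader)

    def medium_of(name: str, *, need_refs: bool) -> Medium:
        key = normalize_medium_name(name)
        if key in media:
            med = media[key]
        elif key in DEFAULT_MEDIA:
            med = DEFAULT_MEDIA[key]
        else:
            raise MediumError(
                f"{path}: unknown medium {name!r} (declare it in the config block)")
        if need_refs and not med.has_references:
            raise MediumError(
                f"{path}: medium {name!r} has no reference enthalpies; "
                "supply medium.<name>.h_hydrogen_atom/h_electron/h_proton")
        return med

    orbitals = [
        OrbitalRow(r["molecule"], normalize_medium_name(r["medium"]),
                   float(r["E_HOMO"]), float(r["E_LUMO"]))
        for r in parse_section("orbitals")
        if medium_of(r["medium"], need_refs=False)
    ]
    charges = [
        ChargeRow(r["molecule"], normalize_medium_name(r["medium"]), r["atom"],
                  float(r["q_N"]), float(r["q_Nminus1"]), float(r["q_Nplus1"]))
        for r in parse_section("charges")
        if medium_of(r["medium"], need_refs=False)
    ]
    enthalpies = [
        EnthalpyRow(r["molecule"], normalize_medium_name(r["medium"]), r["site"],
                    float(r["H_ROH"]), float(r["H_cation"]),
                    float(r["H_radical"]), float(r["H_anion"]))
        for r in parse_section("enthalpies")
        if medium_of(r["medium"], need_refs=True)
    ]
    bcp = [
        BCPRow(r["molecule"], normalize_medium_name(r["medium"]), r["bond"],
               float(r["rho"]), float(r["lap"]), float(r["V"]), float(r["G"]))
        for r in parse_section("bcp")
        if medium_of(r["medium"], need_refs=False)
    ]
    return SummaryTables(orbitals, charges, enthalpies, bcp, media)
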