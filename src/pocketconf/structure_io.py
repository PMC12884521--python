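"""Molecular structures and volumetric grids: containers plus file I/O.

Coordinates are Angstrom everywhere inside the package; bohr appears only at
the Gaussian-cube boundary.  PDB reading is delegated to gemmi; XYZ
(single- and multi-frame) and Gaussian cube files are written in their plain
canonical dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from . import elements

ANGSTROM_TO_BOHR = 1.8897259886
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR

#: residue names treated as water
WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3"})

FRAGMENT_LIGAND = "ligand"
FRAGMENT_SITE = "site"
FRAGMENT_CAP = "cap"

__all__ = [
    "Atom",
    "MolecularStructure",
    "GridField",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "read_xyz_frames",
    "write_xyz",
    "write_xyz_frames",
    "write_cube",
    "read_cube",
    "ANGSTROM_TO_BOHR",
    "BOHR_TO_ANGSTROM",
]


@dataclass
class Atom:
    """A single atom with element identity and residue context.

    ``fragment`` tags the atom as part of the flexible ligand, the rigid
    binding site, or a capping hydrogen added when peptide fragments are
    excised.
    """

    element: str
    coords: np.ndarray
    name: str = ""
    residue_name: str = "UNK"
    residue_seq: int = 1
    chain: str = "A"
    fragment: str = FRAGMENT_SITE
    partial_charge: float = 0.0

    def __post_init__(self) -> None:
        self.element = elements.normalize_symbol(self.element)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if not self.name:
            self.name = self.element

    @property
    def mass(self) -> float:
        return elements.atomic_mass(self.element)

    @property
    def vdw_radius(self) -> float:
        return elements.vdw_radius(self.element)

    @property
    def atomic_number(self) -> int:
        return elements.atomic_number(self.element)

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class MolecularStructure:
    """An ordered collection of atoms; order is stable under I/O round-trips."""

    atoms: list[Atom] = field(default_factory=list)
    title: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        """(n, 3) array of coordinates in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row.copy()

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def symbols(self) -> list[str]:
        return [a.element for a in self.atoms]

    def select(self, predicate) -> "MolecularStructure":
        return MolecularStructure(
            atoms=[a.copy() for a in self.atoms if predicate(a)], title=self.title
        )

    def fragment_atoms(self, fragment: str) -> "MolecularStructure":
        return self.select(lambda a: a.fragment == fragment)

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(atoms=[a.copy() for a in self.atoms], title=self.title)

    def translated(self, vector: np.ndarray) -> "MolecularStructure":
        out = self.copy()
        vec = np.asarray(vector, dtype=float)
        for atom in out.atoms:
            atom.coords = atom.coords + vec
        return out


@dataclass
class GridField:
    """A scalar field on a regular 3D grid (all lengths in bohr)."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, rows are step vectors
    dims: tuple[int, int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.dims = tuple(int(d) for d in self.dims)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,) or self.axes.shape != (3, 3):
            raise ValueError("origin must be 3-vector, axes 3x3")
        if any(d <= 0 for d in self.dims):
            raise ValueError("grid dims must be positive")
        if abs(np.linalg.det(self.axes)) < 1e-12:
            raise ValueError("grid axes must be linearly independent")
        expected = self.dims[0] * self.dims[1] * self.dims[2]
        if self.values.size != expected:
            raise ValueError(
                f"values has {self.values.size} entries, expected {expected}"
            )
        self.values = self.values.reshape(self.dims)

    def points(self) -> np.ndarray:
        """All grid points as an (N, 3) array in bohr, z-fastest order."""
        ii, jj, kk = np.meshgrid(
            np.arange(self.dims[0]),
            np.arange(self.dims[1]),
            np.arange(self.dims[2]),
            indexing="ij",
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        return self.origin + idx @ self.axes


class FormatError(ValueError):
    """Raised for malformed structure or grid files."""


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy, ties to first listed."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-9:
            chosen[atom.name] = atom
    # preserve file order of the winning copies
    out, seen = [], set()
    for atom in residue:
        if atom.name not in seen and chosen[atom.name] is atom:
            out.append(atom)
            seen.add(atom.name)
        elif atom.name not in seen and chosen[atom.name] is not atom:
            # winner appears later; emit it at the first occurrence slot
            out.append(chosen[atom.name])
            seen.add(atom.name)
    return out


def read_pdb(path: str | Path, ligand_code: str | None = None) -> MolecularStructure:
    """Read ATOM/HETATM records from a PDB file.

    HETATM residues matching ``ligand_code`` are tagged ``fragment='ligand'``;
    everything else is tagged ``'site'``.  Element symbols come from the
    element column when present, with a fall-back to gemmi's atom-name
    heuristics.  Alternate locations keep the highest-occupancy copy.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    st.setup_entities()
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            is_ligand = ligand_code is not None and residue.name == ligand_code
            for gatom in _pick_altloc(residue):
                el = gatom.element
                if el.atomic_number == 0:
                    # element column missing/bogus: infer from the atom name
                    guess = gatom.name.strip().lstrip("0123456789")
                    el = gemmi.Element(guess[:2].capitalize())
                    if el.atomic_number == 0:
                        el = gemmi.Element(guess[:1].upper())
                    if el.atomic_number == 0:
                        raise FormatError(
                            f"cannot infer element for atom {gatom.name!r} in "
                            f"{residue.name} {residue.seqid.num}"
                        )
                atoms.append(
                    Atom(
                        element=el.name,
                        name=gatom.name,
                        coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        residue_name=residue.name,
                        residue_seq=residue.seqid.num,
                        chain=chain.name,
                        fragment=FRAGMENT_LIGAND if is_ligand else FRAGMENT_SITE,
                    )
                )
    if not atoms:
        raise FormatError(f"no ATOM/HETATM records found in {path}")
    return MolecularStructure(atoms=atoms, title=path.stem)


def write_pdb(structure: MolecularStructure, path: str | Path) -> None:
    """Write a structure as PDB via gemmi. Cap hydrogens keep their residue id."""
    if not structure.atoms:
        raise ValueError("cannot write an empty structure")
    # gemmi's add_residue/add_chain copy their argument, so the hierarchy is
    # assembled bottom-up: atoms into residues, residues into chains, ...
    grouped: dict[str, dict[tuple, list[Atom]]] = {}
    for atom in structure.atoms:
        key = (atom.residue_seq, atom.residue_name, atom.fragment == FRAGMENT_LIGAND)
        grouped.setdefault(atom.chain or "A", {}).setdefault(key, []).append(atom)
    st = gemmi.Structure()
    model = gemmi.Model("1")
    for chain_name, residues in grouped.items():
        ch = gemmi.Chain(chain_name)
        for (seq, resname, is_ligand), atoms in residues.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(seq, " ")
            res.het_flag = "H" if is_ligand else "A"
            for atom in atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = 1.0
                res.add_atom(ga)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz_frames(
    frames: Sequence[MolecularStructure], path: str | Path, precision: int = 8
) -> None:
    """Write one or more structures as a (multi-frame) XYZ file."""
    if not frames:
        raise ValueError("no frames to write")
    lines: list[str] = []
    for frame in frames:
        if not frame.atoms:
            raise ValueError("cannot write an empty structure")
        lines.append(str(len(frame.atoms)))
        lines.append(frame.title.replace("\n", " "))
        for atom in frame.atoms:
            x, y, z = atom.coords
            lines.append(
                f"{atom.element:<3s} {x:> .{precision}f} {y:> .{precision}f} "
                f"{z:> .{precision}f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(structure: MolecularStructure, path: str | Path, precision: int = 8) -> None:
    write_xyz_frames([structure], path, precision=precision)


def read_xyz_frames(path: str | Path) -> list[MolecularStructure]:
    """Read all frames of an XYZ file, preserving order."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    lines = path.read_text().splitlines()
    frames: list[MolecularStructure] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}:{i + 1}: expected atom count") from exc
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            pass
        title = lines[i + 1] if i + 1 < len(lines) else ""
        body = lines[i + 2 : i + 2 + natoms]
        if len(body) != natoms:
            raise FormatError(
                f"{path}: frame at line {i + 1} declares {natoms} atoms, "
                f"found {len(body)}"
            )
        atoms = []
        for j, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{i + 3 + j}: malformed XYZ atom line")
            try:
                xyz = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{i + 3 + j}: unparsable coordinates"
                ) from exc
            atoms.append(Atom(element=parts[0], coords=xyz, fragment=FRAGMENT_LIGAND))
        frames.append(MolecularStructure(atoms=atoms, title=title.strip()))
        i += 2 + natoms
    if not frames:
        raise FormatError(f"{path}: no XYZ frames found")
    return frames


def read_xyz(path: str | Path) -> MolecularStructure:
    return read_xyz_frames(path)[0]


# ---------------------------------------------------------------------------
# Gaussian cube
# ---------------------------------------------------------------------------

def write_cube(
    grid: GridField,
    structure: MolecularStructure,
    path: str | Path,
    comment: str = "pocketconf volumetric field",
    isovalue: float | None = None,
) -> None:
    """Write a Gaussian-cube file (lengths in bohr, z-fastest value order)."""
    if not structure.atoms:
        raise ValueError("cube files require at least one atom")
    second = "values in a.u."
    if isovalue is not None:
        second += f"; suggested isovalue {isovalue:g}"
    lines = [comment, second]
    lines.append(
        f"{len(structure.atoms):5d} {grid.origin[0]:12.6f} {grid.origin[1]:12.6f} "
        f"{grid.origin[2]:12.6f}"
    )
    for d, ax in zip(grid.dims, grid.axes):
        lines.append(f"{d:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}")
    for atom in structure.atoms:
        xb, yb, zb = atom.coords * ANGSTROM_TO_BOHR
        lines.append(
            f"{atom.atomic_number:5d} {float(atom.atomic_number):12.6f} "
            f"{xb:12.6f} {yb:12.6f} {zb:12.6f}"
        )
    flat = grid.values.reshape(-1)  # C order == z-fastest for (nx, ny, nz)
    for start in range(0, flat.size, 6):
        chunk = flat[start : start + 6]
        lines.append(" ".join(f"{v:13.5E}" for v in chunk))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> tuple[GridField, MolecularStructure]:
    """Read back a cube file written by :func:`write_cube`."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise FormatError(f"{path}: truncated cube file")
    natoms_line = lines[2].split()
    natoms = int(natoms_line[0])
    origin = np.array([float(v) for v in natoms_line[1:4]])
    dims, axes = [], []
    for k in range(3):
        parts = lines[3 + k].split()
        dims.append(int(parts[0]))
        axes.append([float(v) for v in parts[1:4]])
    atoms = []
    for k in range(natoms):
        parts = lines[6 + k].split()
        z = int(parts[0])
        pos = np.array([float(v) for v in parts[2:5]]) * BOHR_TO_ANGSTROM
        atoms.append(Atom(element=gemmi.Element(z).name, coords=pos))
    values = []
    for line in lines[6 + natoms :]:
        values.extend(float(v) for v in line.split())
    grid = GridField(
        origin=origin, axes=np.array(axes), dims=tuple(dims), values=np.array(values)
    )
    return grid, MolecularStructure(atoms=atoms, title=lines[0])
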