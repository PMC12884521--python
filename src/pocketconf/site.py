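"""Active-site definition: distance-based residue selection around a ligand,
rule-based protonation at physiological pH, and hydrogen capping of excised
peptide termini.

The selection is residue-atomic: a residue is kept whole or not at all.  Two
distance readings are supported, because "all residues within R of the ligand
centre of mass" and "all residues with an atom within R of any ligand atom"
give very different pockets for an elongated ligand:

* ``com_sphere`` — a residue is kept if any of its atoms lies within the
  radius of the ligand's centre of mass;
* ``any_atom`` (default) — a residue is kept if its minimum atom-to-ligand
  atom distance is within the radius.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import (
    Atom,
    MolecularStructure,
    FRAGMENT_CAP,
    FRAGMENT_LIGAND,
    FRAGMENT_SITE,
    WATER_NAMES,
)

__all__ = [
    "ActiveSite",
    "center_of_mass",
    "select_site",
    "protonate",
    "cap_termini",
]

N_H_BOND = 1.01  # Angstrom, amide/amine N-H
C_H_BOND = 1.09  # Angstrom, aliphatic C-H
O_H_BOND = 0.96
S_H_BOND = 1.34
_BOND_LENGTH = {"N": N_H_BOND, "C": C_H_BOND, "O": O_H_BOND, "S": S_H_BOND}

#: hydrogens carried by polar/ionizable side-chain heavy atoms at pH 7.4
#: (aspartate/glutamate deprotonated, lysine/arginine protonated,
#: histidine neutral with the N-epsilon tautomer)
_PROTONATION_RULES: dict[str, dict[str, int]] = {
    "ALA": {},
    "GLY": {},
    "VAL": {},
    "LEU": {},
    "ILE": {},
    "PRO": {},
    "PHE": {},
    "MET": {},
    "ASP": {"OD1": 0, "OD2": 0},
    "GLU": {"OE1": 0, "OE2": 0},
    "LYS": {"NZ": 3},
    "ARG": {"NE": 1, "NH1": 2, "NH2": 2},
    "HIS": {"ND1": 0, "NE2": 1},
    "SER": {"OG": 1},
    "THR": {"OG1": 1},
    "TYR": {"OH": 1},
    "CYS": {"SG": 1},
    "TRP": {"NE1": 1},
    "ASN": {"ND2": 2},
    "GLN": {"NE2": 2},
}

_H_COVALENT_CUTOFF = 1.25  # Angstrom: an H within this distance counts as bonded


@dataclass
class ActiveSite:
    """The excised binding pocket: site residues plus any cap hydrogens."""

    atoms: list[Atom] = field(default_factory=list)
    source_residues: list[tuple[str, int, str]] = field(default_factory=list)
    radius: float = 6.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("site radius must be positive")
        self.center = np.asarray(self.center, dtype=float)

    def as_structure(self) -> MolecularStructure:
        return MolecularStructure(atoms=[a.copy() for a in self.atoms], title="active site")

    def copy(self) -> "ActiveSite":
        return ActiveSite(
            atoms=[a.copy() for a in self.atoms],
            source_residues=list(self.source_residues),
            radius=self.radius,
            center=self.center.copy(),
        )

    def __len__(self) -> int:
        return len(self.atoms)


def center_of_mass(structure: MolecularStructure) -> np.ndarray:
    """Mass-weighted mean position (Angstrom)."""
    if not structure.atoms:
        raise ValueError("cannot take the centre of mass of an empty structure")
    masses = structure.masses()
    total = masses.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    return (masses[:, None] * structure.coords()).sum(axis=0) / total


def select_site(
    structure: MolecularStructure,
    ligand_selector=None,
    radius: float = 6.0,
    mode: str = "any_atom",
    include_waters: bool = False,
) -> ActiveSite:
    """Select whole residues around the ligand by a distance rule.

    ``ligand_selector`` is a predicate on :class:`Atom`; by default atoms
    already tagged ``fragment='ligand'`` are used.  Waters are excluded unless
    ``include_waters`` is set.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if mode not in ("com_sphere", "any_atom"):
        raise ValueError(f"unknown selection mode: {mode!r}")
    if ligand_selector is None:
        ligand_selector = lambda a: a.fragment == FRAGMENT_LIGAND  # noqa: E731
    ligand_atoms = [a for a in structure.atoms if ligand_selector(a)]
    if not ligand_atoms:
        raise ValueError("structure contains no ligand atoms")
    ligand = MolecularStructure(atoms=[a.copy() for a in ligand_atoms])
    com = center_of_mass(ligand)
    lig_xyz = ligand.coords()

    # group the non-ligand atoms by residue, preserving order
    residues: dict[tuple[str, int, str], list[Atom]] = {}
    for atom in structure.atoms:
        if ligand_selector(atom):
            continue
        residues.setdefault((atom.chain, atom.residue_seq, atom.residue_name), []).append(atom)
    if not residues:
        raise ValueError("structure contains no non-ligand residues")

    kept_atoms: list[Atom] = []
    kept_ids: list[tuple[str, int, str]] = []
    for key, res_atoms in residues.items():
        if not include_waters and key[2] in WATER_NAMES:
            continue
        xyz = np.array([a.coords for a in res_atoms])
        if mode == "com_sphere":
            dmin = np.linalg.norm(xyz - com, axis=1).min()
        else:
            dmin = cdist(xyz, lig_xyz).min()
        if dmin <= radius:
            kept_ids.append(key)
            for a in res_atoms:
                c = a.copy()
                c.fragment = FRAGMENT_SITE
                kept_atoms.append(c)
    return ActiveSite(atoms=kept_atoms, source_residues=kept_ids, radius=radius, center=com)


def _bonded_hydrogens(heavy: Atom, atoms: list[Atom]) -> list[Atom]:
    out = []
    for a in atoms:
        if a.element != "H":
            continue
        if np.linalg.norm(a.coords - heavy.coords) <= _H_COVALENT_CUTOFF:
            out.append(a)
    return out


def _heavy_neighbors(center: Atom, atoms: list[Atom]) -> list[Atom]:
    from . import elements

    out = []
    for a in atoms:
        if a is center or a.element == "H":
            continue
        cutoff = elements.covalent_radius(center.element) + elements.covalent_radius(a.element) + 0.45
        if np.linalg.norm(a.coords - center.coords) <= cutoff:
            out.append(a)
    return out


def _place_hydrogens(center: Atom, neighbors: list[Atom], count: int, bond: float) -> list[np.ndarray]:
    """Place ``count`` hydrogens around ``center`` completing a roughly
    tetrahedral geometry given the existing bonded neighbours."""
    if count <= 0:
        return []
    dirs = []
    for nb in neighbors:
        v = nb.coords - center.coords
        n = np.linalg.norm(v)
        if n > 1e-8:
            dirs.append(v / n)
    if not dirs:
        axis = np.array([0.0, 0.0, 1.0])
    else:
        s = -np.sum(dirs, axis=0)
        n = np.linalg.norm(s)
        axis = s / n if n > 1e-8 else np.array([0.0, 0.0, 1.0])
    if count == 1 and len(dirs) != 1:
        return [center.coords + bond * axis]
    # cone of directions around `axis`, half-angle ~70.5 deg so that the
    # H-X-neighbour angle is near tetrahedral when one neighbour exists
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    half = math.radians(180.0 - 109.47) if dirs else math.radians(109.47 / 2)
    positions = []
    for k in range(count):
        phi = 2.0 * math.pi * k / max(count, 1)
        d = math.cos(half) * axis + math.sin(half) * (math.cos(phi) * u + math.sin(phi) * v)
        positions.append(center.coords + bond * d / np.linalg.norm(d))
    return positions


def protonate(site: ActiveSite, ph: float = 7.4) -> ActiveSite:
    """Add polar/ionizable hydrogens by residue templates for pH ~7.4.

    Carboxylates stay bare, lysine and arginine are fully protonated,
    histidine is the neutral N-epsilon tautomer, and hydroxyl/thiol/amide
    groups carry their neutral hydrogen complement.  Existing hydrogens are
    counted, so the operation is idempotent.  Backbone amide nitrogens
    receive one hydrogen (none for proline).  Unknown residues pass through
    with a warning.
    """
    if not (6.0 <= ph <= 8.5):
        warnings.warn(
            f"protonation templates are parameterised for physiological pH; got {ph}"
        )
    out = site.copy()
    by_residue: dict[tuple[str, int, str], list[Atom]] = {}
    for atom in out.atoms:
        by_residue.setdefault((atom.chain, atom.residue_seq, atom.residue_name), []).append(atom)
    new_atoms: list[Atom] = []
    for (chain, seq, resname), res_atoms in by_residue.items():
        rules = _PROTONATION_RULES.get(resname)
        if rules is None:
            warnings.warn(f"no protonation template for residue {resname}; left unmodified")
            continue
        targets = dict(rules)
        if resname != "PRO":
            targets.setdefault("N", 1)
        for atom in res_atoms:
            want = targets.get(atom.name)
            if want is None:
                continue
            have = len(_bonded_hydrogens(atom, res_atoms))
            missing = want - have
            if missing <= 0:
                continue
            neighbors = _heavy_neighbors(atom, res_atoms) + _bonded_hydrogens(atom, res_atoms)
            bond = _BOND_LENGTH.get(atom.element, 1.0)
            for pos in _place_hydrogens(atom, neighbors, missing, bond):
                new_atoms.append(
                    Atom(
                        element="H",
                        name=f"H{atom.name}",
                        coords=pos,
                        residue_name=resname,
                        residue_seq=seq,
                        chain=chain,
                        fragment=FRAGMENT_SITE,
                    )
                )
    out.atoms.extend(new_atoms)
    return out


def cap_termini(site: ActiveSite, parent: MolecularStructure | None = None) -> ActiveSite:
    """Cap cut peptide bonds with hydrogens.

    For a backbone N whose preceding carbonyl C is missing from the site, one
    hydrogen is added along the former N->C direction at 1.01 A; for a
    carbonyl C whose following N is missing, one hydrogen along the former
    C->N direction at 1.09 A.  When the full parent structure is given, the
    true positions of the absent partners orient the caps; otherwise the local
    backbone geometry (CA, O) supplies the direction.
    """
    out = site.copy()
    present: dict[tuple[str, int], dict[str, Atom]] = {}
    for atom in out.atoms:
        present.setdefault((atom.chain, atom.residue_seq), {})[atom.name] = atom
    parent_atoms: dict[tuple[str, int], dict[str, Atom]] = {}
    if parent is not None:
        for atom in parent.atoms:
            parent_atoms.setdefault((atom.chain, atom.residue_seq), {})[atom.name] = atom

    caps: list[Atom] = []
    for (chain, seq), names in present.items():
        resname = next(iter(names.values())).residue_name
        if resname in WATER_NAMES or "CA" not in names:
            continue
        # N-terminal side: preceding residue's C missing from the site?
        n_cut = "N" in names and "C" not in present.get((chain, seq - 1), {})
        if n_cut and parent is not None:
            # absent from the parent too means a true N-terminus, not a cut
            n_cut = "C" in parent_atoms.get((chain, seq - 1), {})
        if n_cut:
            natom = names["N"]
            direction = None
            prev = parent_atoms.get((chain, seq - 1), {})
            if "C" in prev:
                v = prev["C"].coords - natom.coords
                direction = v / np.linalg.norm(v)
            else:
                ca = names.get("CA")
                if ca is None:
                    raise ValueError(f"cannot orient N-cap: missing CA in {resname} {seq}")
                neighbors = [ca] + _bonded_hydrogens(natom, list(names.values()))
                s = np.zeros(3)
                for nb in neighbors:
                    v = nb.coords - natom.coords
                    s += v / np.linalg.norm(v)
                n = np.linalg.norm(s)
                if n < 1e-8:
                    raise ValueError(f"degenerate N-cap geometry in {resname} {seq}")
                direction = -s / n
            caps.append(
                Atom(
                    element="H",
                    name="HCAP",
                    coords=natom.coords + N_H_BOND * direction,
                    residue_name=resname,
                    residue_seq=seq,
                    chain=chain,
                    fragment=FRAGMENT_CAP,
                )
            )
        # C-terminal side: following residue's N missing from the site?
        c_cut = "C" in names and "N" not in present.get((chain, seq + 1), {})
        if c_cut and parent is not None:
            c_cut = "N" in parent_atoms.get((chain, seq + 1), {})
        if c_cut:
            catom = names["C"]
            direction = None
            nxt = parent_atoms.get((chain, seq + 1), {})
            if "N" in nxt:
                v = nxt["N"].coords - catom.coords
                direction = v / np.linalg.norm(v)
            else:
                ca, ox = names.get("CA"), names.get("O")
                if ca is None or ox is None:
                    raise ValueError(
                        f"cannot orient C-cap: missing CA or O in {resname} {seq}"
                    )
                s = np.zeros(3)
                for nb in (ca, ox):
                    v = nb.coords - catom.coords
                    s += v / np.linalg.norm(v)
                n = np.linalg.norm(s)
                if n < 1e-8:
                    raise ValueError(f"degenerate C-cap geometry in {resname} {seq}")
                direction = -s / n
            caps.append(
                Atom(
                    element="H",
                    name="HCAP",
                    coords=catom.coords + C_H_BOND * direction,
                    residue_name=resname,
                    residue_seq=seq,
                    chain=chain,
                    fragment=FRAGMENT_CAP,
                )
            )
    out.atoms.extend(caps)
    return out
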