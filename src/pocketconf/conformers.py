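"""Systematic conformer generation for a flexible ligand in a rigid pocket.

Poses are enumerated as the Cartesian product of dihedral-angle increments
(the input pose defines the 0-degree reference of every scanned dihedral)
and a rigid translation grid.  Sterically infeasible poses are removed with
a scaled van-der-Waals overlap filter, survivors are locally minimized with
an energy backend while the pocket heavy atoms stay fixed, near-duplicate
poses are merged by best-superposition RMSD, and minima can be verified with
a numerical Hessian.  The module is fully deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .structure_io import MolecularStructure

__all__ = [
    "DihedralSpec",
    "RigidTransform",
    "ConformerRecord",
    "rotate_dihedral",
    "enumerate_poses",
    "clash_filter",
    "local_minimize",
    "verify_minimum",
    "deduplicate",
    "kabsch_rmsd",
    "translation_grid",
]

#: refuse to enumerate more poses than this unless the caller raises the cap
DEFAULT_POSE_CAP = 2_000_000


@dataclass(frozen=True)
class DihedralSpec:
    """A rotatable dihedral: four defining atom indices and the set of atoms
    displaced by rotation about the j-k bond."""

    atom_indices: tuple[int, int, int, int]
    rotating_set: tuple[int, ...]

    def __post_init__(self) -> None:
        i, j, k, l = self.atom_indices
        if len({i, j, k, l}) != 4:
            raise ValueError("dihedral atom indices must be distinct")
        rs = set(self.rotating_set)
        if l not in rs:
            raise ValueError("rotating_set must contain the terminal atom l")
        if rs & {i, j, k}:
            raise ValueError("rotating_set must exclude atoms i, j, k")


@dataclass(frozen=True)
class RigidTransform:
    """A rigid-body translation of the whole ligand (Angstrom)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.translation):
            raise ValueError("translation components must be finite")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz + np.asarray(self.translation)


@dataclass
class ConformerRecord:
    """A ligand pose with its generating dihedral tuple and translation."""

    pose: MolecularStructure
    dihedral_values: tuple[float, ...] = ()
    transform: RigidTransform = field(default_factory=RigidTransform)
    energy: float | None = None
    is_minimum: bool | None = None
    provenance: str = "scan"

    def __post_init__(self) -> None:
        self.dihedral_values = tuple(v % 360.0 for v in self.dihedral_values)

    def copy(self) -> "ConformerRecord":
        return replace(self, pose=self.pose.copy())


def translation_grid(extent: float = 1.0, points_per_axis: int = 3) -> list[RigidTransform]:
    """Symmetric ``n x n x n`` translation grid spanning +/- extent per axis."""
    if points_per_axis < 1:
        raise ValueError("points_per_axis must be >= 1")
    if points_per_axis == 1:
        axis = [0.0]
    else:
        axis = list(np.linspace(-extent, extent, points_per_axis))
    return [RigidTransform((x, y, z)) for x in axis for y in axis for z in axis]


def rotate_dihedral(
    pose: MolecularStructure, spec: DihedralSpec, angle: float
) -> MolecularStructure:
    """Rotate the spec's rotating set about the j->k axis by ``angle`` degrees
    (right-hand rule looking from j towards k)."""
    out = pose.copy()
    xyz = out.coords()
    _, j, k, _ = spec.atom_indices
    axis = xyz[k] - xyz[j]
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        raise ValueError("degenerate dihedral axis: atoms j and k coincide")
    axis = axis / norm
    theta = math.radians(angle)
    ct, st = math.cos(theta), math.sin(theta)
    idx = list(spec.rotating_set)
    rel = xyz[idx] - xyz[k]
    # Rodrigues rotation of the rotating set about the axis through atom k
    rotated = (
        rel * ct
        + np.cross(axis, rel) * st
        + np.outer(rel @ axis, axis) * (1.0 - ct)
    )
    xyz[idx] = rotated + xyz[k]
    out.set_coords(xyz)
    return out


def measure_dihedral(pose: MolecularStructure, spec: DihedralSpec) -> float:
    """Torsion angle (degrees, [0, 360)) of the spec's four atoms."""
    xyz = pose.coords()
    i, j, k, l = spec.atom_indices
    b1 = xyz[j] - xyz[i]
    b2 = xyz[k] - xyz[j]
    b3 = xyz[l] - xyz[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    # sign chosen so that rotate_dihedral(pose, spec, +theta) increases the
    # measured angle by theta (right-hand rule looking from j to k)
    angle = -math.degrees(math.atan2(m1 @ n2, n1 @ n2))
    return angle % 360.0


def dihedral_offsets(
    pose: MolecularStructure,
    reference: MolecularStructure,
    specs: list[DihedralSpec],
) -> tuple[float, ...]:
    """Measured dihedrals of ``pose`` relative to the reference pose's
    dihedrals (the scan's zero convention), each in [0, 360)."""
    return tuple(
        (measure_dihedral(pose, s) - measure_dihedral(reference, s)) % 360.0
        for s in specs
    )


def enumerate_poses(
    pose: MolecularStructure,
    specs: list[DihedralSpec],
    angle_step: float,
    translation_grid: list[RigidTransform] | None = None,
    cap: int = DEFAULT_POSE_CAP,
) -> list[ConformerRecord]:
    """Full Cartesian product of dihedral increments and rigid translations,
    in deterministic lexicographic order (dihedrals outer, translations inner).
    """
    if angle_step <= 0 or abs(360.0 / angle_step - round(360.0 / angle_step)) > 1e-9:
        raise ValueError("360 must be divisible by angle_step")
    grid = translation_grid if translation_grid else [RigidTransform()]
    n_angles = int(round(360.0 / angle_step))
    total = n_angles ** len(specs) * len(grid)
    if total > cap:
        raise ValueError(
            f"refusing to enumerate {total} poses (cap {cap}); "
            "raise the cap or coarsen the scan"
        )
    angle_values = [i * angle_step for i in range(n_angles)]
    records: list[ConformerRecord] = []
    for combo in itertools.product(angle_values, repeat=len(specs)):
        rotated = pose
        for spec, angle in zip(specs, combo):
            if angle != 0.0:
                rotated = rotate_dihedral(rotated, spec, angle)
        base_xyz = rotated.coords()
        for tr in grid:
            rec_pose = rotated.copy()
            rec_pose.set_coords(tr.apply(base_xyz))
            records.append(
                ConformerRecord(pose=rec_pose, dihedral_values=combo, transform=tr)
            )
    return records


def clash_filter(
    records: list[ConformerRecord],
    site: MolecularStructure,
    scale: float = 0.7,
) -> list[ConformerRecord]:
    """Keep poses whose every ligand-site distance is at least
    ``scale * (vdW_i + vdW_j)``."""
    if not 0 < scale <= 1:
        raise ValueError("clash scale must be in (0, 1]")
    if not site.atoms:
        return list(records)
    site_xyz = site.coords()
    site_vdw = np.array([a.vdw_radius for a in site.atoms])
    out = []
    for rec in records:
        lig_xyz = rec.pose.coords()
        lig_vdw = np.array([a.vdw_radius for a in rec.pose.atoms])
        dist = cdist(lig_xyz, site_xyz)
        limit = scale * (lig_vdw[:, None] + site_vdw[None, :])
        if np.all(dist >= limit):
            out.append(rec)
    return out


def _compose(ligand: MolecularStructure, site: MolecularStructure) -> MolecularStructure:
    combined = MolecularStructure(title="ligand+site")
    combined.atoms = [a.copy() for a in ligand.atoms] + [a.copy() for a in site.atoms]
    return combined


def _free_indices(combined: MolecularStructure, n_ligand: int, free_atoms: str) -> list[int]:
    if free_atoms == "ligand":
        return list(range(n_ligand))
    if free_atoms == "ligand+site_hydrogens":
        idx = list(range(n_ligand))
        for i, atom in enumerate(combined.atoms[n_ligand:], start=n_ligand):
            if atom.element == "H":
                idx.append(i)
        return idx
    if free_atoms == "all":
        return list(range(len(combined.atoms)))
    raise ValueError(f"unknown free-atom selector: {free_atoms!r}")


def local_minimize(
    record: ConformerRecord,
    site: MolecularStructure,
    backend,
    free_atoms: str = "ligand+site_hydrogens",
    gtol: float = 1e-4,
    max_steps: int = 2000,
) -> ConformerRecord:
    """Quasi-Newton (L-BFGS-B) minimization over the free atoms only.

    The pocket heavy atoms never move; convergence is declared when the
    largest gradient component drops below ``gtol`` kcal/mol/A.
    """
    combined = _compose(record.pose, site)
    n_lig = len(record.pose.atoms)
    free = _free_indices(combined, n_lig, free_atoms)
    x0 = combined.coords()[free].ravel()
    base_xyz = combined.coords()

    def objective(x: np.ndarray):
        xyz = base_xyz.copy()
        xyz[free] = x.reshape(-1, 3)
        combined.set_coords(xyz)
        e = backend.energy(combined)
        g = backend.gradient(combined, free)
        return e, g.ravel()

    try:
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_steps, "gtol": gtol, "ftol": 0.0},
        )
    except Exception as exc:  # pragma: no cover - backend failure path
        raise RuntimeError(f"energy backend failed during minimization: {exc}") from exc
    xyz = base_xyz.copy()
    xyz[free] = res.x.reshape(-1, 3)
    combined.set_coords(xyz)
    energy = backend.energy(combined)
    out = record.copy()
    out.pose.set_coords(xyz[:n_lig])
    out.energy = float(energy)
    out.provenance = record.provenance + "+minimized"
    return out


def verify_minimum(
    record: ConformerRecord,
    site: MolecularStructure,
    backend,
    free_atoms: str = "ligand+site_hydrogens",
    fd_step: float = 1e-3,
    eig_tol: float = -1e-6,
    grad_tol: float = 1e-2,
) -> bool:
    """Check a converged pose for true-minimum character.

    A central-difference Hessian is built over the free coordinates; the pose
    is a minimum iff no eigenvalue falls below ``eig_tol`` (the tolerance
    absorbs near-zero rigid-body modes).  Non-stationary inputs are a
    contract violation and raise.
    """
    combined = _compose(record.pose, site)
    n_lig = len(record.pose.atoms)
    free = _free_indices(combined, n_lig, free_atoms)
    base_xyz = combined.coords()
    g0 = backend.gradient(combined, free).ravel()
    if np.max(np.abs(g0)) > grad_tol:
        raise ValueError(
            "verify_minimum requires a stationary point "
            f"(max |g| = {np.max(np.abs(g0)):.3g} kcal/mol/A)"
        )
    n = len(free) * 3
    hess = np.empty((n, n))
    for a in range(n):
        for sign, store in ((+1, 0), (-1, 1)):
            xyz = base_xyz.copy()
            flat = xyz[free].ravel()
            flat[a] += sign * fd_step
            xyz[free] = flat.reshape(-1, 3)
            combined.set_coords(xyz)
            g = backend.gradient(combined, free).ravel()
            if sign > 0:
                gp = g
            else:
                gm = g
        hess[:, a] = (gp - gm) / (2.0 * fd_step)
    combined.set_coords(base_xyz)
    hess = 0.5 * (hess + hess.T)
    if not np.all(np.isfinite(hess)):
        raise ValueError("non-finite entries in the numerical Hessian")
    eigs = np.linalg.eigvalsh(hess)
    return bool(eigs.min() >= eig_tol)


def kabsch_rmsd(
    pose_a: MolecularStructure,
    pose_b: MolecularStructure,
    superpose: bool = True,
    center: bool | None = None,
) -> float:
    """RMSD between corresponding atoms, optionally after optimal
    (proper-rotation) Kabsch superposition.

    ``center`` controls centroid removal; it defaults to the value of
    ``superpose`` so that plain RMSD is computed in the laboratory frame.
    """
    if len(pose_a.atoms) != len(pose_b.atoms):
        raise ValueError("poses must have equal atom counts")
    A = pose_a.coords()
    B = pose_b.coords()
    if center is None:
        center = superpose
    if center:
        A = A - A.mean(axis=0)
        B = B - B.mean(axis=0)
    if superpose:
        if len(pose_a.atoms) < 3 or np.linalg.matrix_rank(A - A[0], tol=1e-8) < 2:
            raise ValueError(
                "Kabsch superposition needs at least 3 non-collinear atoms"
            )
        H = B.T @ A
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(U @ Vt))
        D = np.diag([1.0, 1.0, d])
        R = U @ D @ Vt
        B = B @ R
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def deduplicate(
    records: list[ConformerRecord], rmsd_threshold: float = 0.5
) -> list[ConformerRecord]:
    """Greedy clustering in ascending-energy order.

    A record is distinct when its best-superposition RMSD to every kept
    record exceeds the threshold; the kept member of each cluster is its
    lowest-energy representative.  Output energies are non-decreasing.
    """
    if not records:
        return []
    counts = {len(r.pose.atoms) for r in records}
    if len(counts) != 1:
        raise ValueError("all records must share the same atom count")
    if any(r.energy is None for r in records):
        raise ValueError("all records must be scored before deduplication")
    order = sorted(records, key=lambda r: r.energy)
    kept: list[ConformerRecord] = []
    for rec in order:
        distinct = True
        for ref in kept:
            try:
                r = kabsch_rmsd(rec.pose, ref.pose, superpose=True)
            except ValueError:
                r = kabsch_rmsd(rec.pose, ref.pose, superpose=False, center=True)
            if r <= rmsd_threshold:
                distinct = False
                break
        if distinct:
            kept.append(rec)
    return kept
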