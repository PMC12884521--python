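"""Noncovalent-interaction (NCI) analysis on promolecular densities.

The electron density is approximated as a sum of spherical atomic densities,
each a sum of exponential shells rho(r) = sum_i c_i exp(-r/zeta_i) (atomic
units).  Shell coefficients and decay lengths are generated from Slater-rule
screened nuclear charges: shell n of an atom with effective charge Z_eff
decays with length n/(2 Z_eff) bohr and is normalised to its electron count.
This keeps every atomic density positive, strictly decreasing and analytic,
which is what the closed-form gradient/Hessian machinery below needs.

From rho the module derives the reduced density gradient

    s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3)),

the density signed by the middle Hessian eigenvalue sign(lambda_2) rho, the
attractive / van-der-Waals / repulsive classification, 2D scatter data, cube
export and a geometric hydrogen-bond table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import elements
from .structure_io import (
    ANGSTROM_TO_BOHR,
    Atom,
    GridField,
    MolecularStructure,
    FRAGMENT_LIGAND,
    write_cube,
)

__all__ = [
    "PromolecularModel",
    "slater_promolecular_model",
    "promolecular_density",
    "reduced_density_gradient",
    "signed_density",
    "NCIGridResult",
    "nci_grid",
    "classify_points",
    "scatter_export",
    "HBondContact",
    "hbond_table",
    "export_cubes",
    "RDG_PREFACTOR",
    "DEFAULT_ISOVALUE",
]

RDG_PREFACTOR = 2.0 * (3.0 * math.pi**2) ** (1.0 / 3.0)
#: conventional RDG isovalue used when exporting cube metadata
DEFAULT_ISOVALUE = 0.3

_HB_ELEMENTS = frozenset({"N", "O", "S"})


@dataclass(frozen=True)
class PromolecularModel:
    """Per-element exponential-shell atomic densities (atomic units).

    ``shells[element]`` is a tuple of (coefficient, decay length) pairs with
    all entries positive, so every atomic density is strictly decreasing.
    """

    shells: dict[str, tuple[tuple[float, float], ...]]

    def __post_init__(self) -> None:
        for el, sh in self.shells.items():
            for c, z in sh:
                if c <= 0 or z <= 0:
                    raise ValueError(
                        f"promolecular shell for {el} must have positive c, zeta"
                    )

    def atom_shells(self, element: str) -> tuple[tuple[float, float], ...]:
        try:
            return self.shells[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} is not parameterized in the promolecular model"
            ) from None

    def rho_at_nucleus(self, element: str) -> float:
        return sum(c for c, _ in self.atom_shells(element))


def _slater_shells(z: int) -> list[tuple[float, float]]:
    """Shell (coefficient, decay length) pairs for atomic number ``z`` <= 18.

    Slater screening: same-group electrons screen 0.35 (0.30 within 1s), the
    (n-1) shell screens 0.85, deeper shells 1.00.  A density shell with
    principal number n and effective charge Z_eff decays as
    exp(-2 Z_eff r / n); its coefficient normalises the shell to its electron
    count: integral of c exp(-r/zeta) over space = 8 pi c zeta^3.
    """
    if not 1 <= z <= 18:
        raise ValueError("Slater-rule promolecular shells cover H through Ar")
    n1 = min(z, 2)
    n2 = min(max(z - 2, 0), 8)
    n3 = min(max(z - 10, 0), 8)
    shells = []
    for n, n_el, inner, deep in (
        (1, n1, 0, 0),
        (2, n2, n1, 0),
        (3, n3, n2, n1),
    ):
        if n_el == 0:
            continue
        if n == 1:
            screen = 0.30 * (n_el - 1)
        else:
            screen = 0.35 * (n_el - 1) + 0.85 * inner + 1.00 * deep
        z_eff = max(z - screen, 0.1)
        zeta = n / (2.0 * z_eff)  # bohr
        c = n_el / (8.0 * math.pi * zeta**3)
        shells.append((c, zeta))
    return shells


def slater_promolecular_model(max_z: int = 18) -> PromolecularModel:
    """Build the packaged promolecular model for elements H..Ar."""
    import gemmi

    shells = {}
    for z in range(1, max_z + 1):
        shells[gemmi.Element(z).name] = tuple(_slater_shells(z))
    return PromolecularModel(shells=shells)


def promolecular_density(
    structure: MolecularStructure,
    model: PromolecularModel | None = None,
    points: np.ndarray | None = None,
    chunk: int = 20000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Density, gradient and Hessian of the promolecular density.

    ``points`` is an (N, 3) array in bohr; atom coordinates (Angstrom) are
    converted internally.  All derivatives are closed-form: for a shell
    f(r) = c exp(-r/zeta),

        grad = f'(r) u,   H = f''(r) u u^T + (f'(r)/r) (I - u u^T)

    with u the unit vector from the nucleus.  Returns (rho[N], grad[N,3],
    hessian[N,3,3]) in atomic units.
    """
    if model is None:
        model = slater_promolecular_model()
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array in bohr")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    n = pts.shape[0]
    rho = np.zeros(n)
    grad = np.zeros((n, 3))
    hess = np.zeros((n, 3, 3))
    eye = np.eye(3)
    centers = structure.coords() * ANGSTROM_TO_BOHR
    shells_per_atom = [model.atom_shells(a.element) for a in structure.atoms]
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        p = pts[sl]
        for center, shells in zip(centers, shells_per_atom):
            d = p - center
            r = np.linalg.norm(d, axis=1)
            r = np.maximum(r, 1e-10)
            u = d / r[:, None]
            for c, zeta in shells:
                f = c * np.exp(-r / zeta)
                fp = -f / zeta
                fpp = f / zeta**2
                rho[sl] += f
                grad[sl] += fp[:, None] * u
                uu = u[:, :, None] * u[:, None, :]
                hess[sl] += (
                    fpp[:, None, None] * uu
                    + (fp / r)[:, None, None] * (eye[None, :, :] - uu)
                )
    return rho, grad, hess


def reduced_density_gradient(rho: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3)), dimensionless."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("reduced density gradient requires strictly positive rho")
    gnorm = np.linalg.norm(np.asarray(grad, dtype=float), axis=-1)
    return gnorm / (RDG_PREFACTOR * rho ** (4.0 / 3.0))


def signed_density(rho: np.ndarray, hessian: np.ndarray) -> np.ndarray:
    """sign(lambda_2) * rho with lambda_2 the middle Hessian eigenvalue."""
    rho = np.asarray(rho, dtype=float)
    H = np.asarray(hessian, dtype=float)
    if H.shape[-2:] != (3, 3):
        raise ValueError("hessian must be (..., 3, 3)")
    asym = np.abs(H - np.swapaxes(H, -1, -2)).max()
    if asym > 1e-10:
        raise ValueError(f"hessian is not symmetric (max asymmetry {asym:.3g})")
    eigs = np.linalg.eigvalsh(H)  # ascending
    lam2 = eigs[..., 1]
    return np.sign(lam2) * rho


@dataclass
class NCIGridResult:
    """NCI fields on a regular axis-aligned grid (all lengths bohr)."""

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    rho: np.ndarray
    rdg: np.ndarray
    signed_rho: np.ndarray
    scatter_mask: np.ndarray  # True where the point enters the 2D scatter
    fragment_rho: dict[str, np.ndarray] = field(default_factory=dict)

    def grid_field(self, which: str = "rho") -> GridField:
        values = {"rho": self.rho, "rdg": self.rdg, "signed_rho": self.signed_rho}[which]
        return GridField(
            origin=self.origin,
            axes=np.eye(3) * self.spacing,
            dims=self.dims,
            values=values.reshape(self.dims),
        )


def nci_grid(
    complex_structure: MolecularStructure,
    model: PromolecularModel | None = None,
    spacing: float = 0.2,
    padding: float = 2.0,
    rho_cutoff: float = 0.05,
    intermolecular_only: bool = False,
    min_fragment_share: float = 0.05,
) -> NCIGridResult:
    """Evaluate rho, s and sign(lambda_2) rho on a regular grid.

    ``spacing`` is in bohr, ``padding`` in Angstrom around the bounding box.
    Points with rho above ``rho_cutoff`` (covalent/core regions) are excluded
    from the scatter set; with ``intermolecular_only`` points must draw at
    least ``min_fragment_share`` of their density from the ligand fragment
    and from the rest of the system alike.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if not complex_structure.atoms:
        raise ValueError("cannot build an NCI grid for an empty structure")
    if model is None:
        model = slater_promolecular_model()
    xyz_bohr = complex_structure.coords() * ANGSTROM_TO_BOHR
    pad = padding * ANGSTROM_TO_BOHR
    lo = xyz_bohr.min(axis=0) - pad
    hi = xyz_bohr.max(axis=0) + pad
    dims = tuple(int(math.floor((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    if any(d < 2 for d in dims):
        raise ValueError("empty or degenerate NCI grid; increase padding")
    axes_pts = [lo[k] + spacing * np.arange(dims[k]) for k in range(3)]
    ii, jj, kk = np.meshgrid(*axes_pts, indexing="ij")
    points = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)

    rho, grad, hess = promolecular_density(complex_structure, model, points)
    rdg = reduced_density_gradient(rho, grad)
    signed = signed_density(rho, hess)

    mask = rho <= rho_cutoff
    fragment_rho: dict[str, np.ndarray] = {}
    if intermolecular_only:
        lig = complex_structure.select(lambda a: a.fragment == FRAGMENT_LIGAND)
        rest = complex_structure.select(lambda a: a.fragment != FRAGMENT_LIGAND)
        for label, frag in (("ligand", lig), ("environment", rest)):
            if frag.atoms:
                frho, _, _ = promolecular_density(frag, model, points)
            else:
                frho = np.zeros_like(rho)
            fragment_rho[label] = frho
        share_lig = fragment_rho["ligand"] / rho
        share_env = fragment_rho["environment"] / rho
        mask &= (share_lig >= min_fragment_share) & (share_env >= min_fragment_share)

    return NCIGridResult(
        origin=lo,
        spacing=spacing,
        dims=dims,
        rho=rho,
        rdg=rdg,
        signed_rho=signed,
        scatter_mask=mask,
        fragment_rho=fragment_rho,
    )


def classify_points(signed_rho: np.ndarray, threshold: float = 0.01) -> np.ndarray:
    """Partition each point into attractive / van_der_waals / repulsive.

    Attractive: sign(lambda_2) rho < -threshold; repulsive: > +threshold;
    van der Waals in between (inclusive).
    """
    if threshold < 0:
        raise ValueError("classification band threshold must be non-negative")
    v = np.asarray(signed_rho, dtype=float)
    out = np.full(v.shape, "van_der_waals", dtype=object)
    out[v < -threshold] = "attractive"
    out[v > threshold] = "repulsive"
    return out


def scatter_export(result: NCIGridResult, path) -> None:
    """Write the 2D scatter data (sign(lambda_2) rho, s) as two-column text."""
    data = np.column_stack(
        [result.signed_rho[result.scatter_mask], result.rdg[result.scatter_mask]]
    )
    header = "signed_rho_au rdg"
    np.savetxt(path, data, header=header, fmt="%.8e")


def export_cubes(
    result: NCIGridResult,
    structure: MolecularStructure,
    prefix,
    isovalue: float = DEFAULT_ISOVALUE,
) -> list[str]:
    """Write density and RDG cube files (``<prefix>-dens.cube``,
    ``<prefix>-grad.cube``) and return their paths."""
    paths = []
    for tag, which in (("dens", "rho"), ("grad", "rdg")):
        p = f"{prefix}-{tag}.cube"
        write_cube(
            result.grid_field(which),
            structure,
            p,
            comment=f"pocketconf NCI {which} field",
            isovalue=isovalue,
        )
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Geometric hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondContact:
    """One D-H...A contact with the indices into the source structure."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    distance: float  # H...A, Angstrom
    angle: float  # D-H...A, degrees
    role: str  # "ligand->protein" or "protein->ligand"

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("H...A distance must be positive")
        if not 0 < self.angle <= 180:
            raise ValueError("D-H...A angle must be in (0, 180]")


def _covalent_partner(h_atom: Atom, candidates: list[tuple[int, Atom]]) -> tuple[int, Atom] | None:
    best = None
    best_d = math.inf
    for idx, atom in candidates:
        cutoff = (
            elements.covalent_radius("H") + elements.covalent_radius(atom.element) + 0.4
        )
        d = float(np.linalg.norm(atom.coords - h_atom.coords))
        if d <= cutoff and d < best_d:
            best, best_d = (idx, atom), d
    return best


def hbond_table(
    structure: MolecularStructure,
    dist_max: float = 2.5,
    angle_min: float = 120.0,
    intermolecular_only: bool = True,
    quiet: bool = False,
) -> list[HBondContact]:
    """Detect hydrogen bonds geometrically.

    A contact requires an electronegative donor (O/N/S) covalently bonded to
    the hydrogen (covalent-radius cutoff), an O/N/S acceptor with
    H...A <= ``dist_max`` and a D-H...A angle >= ``angle_min``.  The role is
    assigned from the donor's fragment tag.  With no hydrogens present the
    table is empty (with a warning unless ``quiet``).
    """
    hydrogens = [(i, a) for i, a in enumerate(structure.atoms) if a.element == "H"]
    if not hydrogens:
        if not quiet:
            warnings.warn("no hydrogens present; hydrogen-bond table is empty")
        return []
    heavies = [
        (i, a) for i, a in enumerate(structure.atoms) if a.element in _HB_ELEMENTS
    ]
    contacts: list[HBondContact] = []
    for hi, h in hydrogens:
        donor = _covalent_partner(h, heavies)
        if donor is None:
            continue
        di, datom = donor
        for ai, aatom in heavies:
            if ai == di:
                continue
            if intermolecular_only:
                d_is_lig = datom.fragment == FRAGMENT_LIGAND
                a_is_lig = aatom.fragment == FRAGMENT_LIGAND
                if d_is_lig == a_is_lig:
                    continue
            d_ha = float(np.linalg.norm(aatom.coords - h.coords))
            if d_ha > dist_max or d_ha < 1e-6:
                continue
            v1 = datom.coords - h.coords
            v2 = aatom.coords - h.coords
            cosang = float(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            )
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle < angle_min:
                continue
            role = (
                "ligand->protein"
                if datom.fragment == FRAGMENT_LIGAND
                else "protein->ligand"
            )
            contacts.append(
                HBondContact(
                    donor_index=di,
                    hydrogen_index=hi,
                    acceptor_index=ai,
                    distance=d_ha,
                    angle=angle,
                    role=role,
                )
            )
    contacts.sort(key=lambda c: c.distance)
    return contacts
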