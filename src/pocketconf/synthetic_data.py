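"""Seeded synthetic fixtures with the geometric/statistical structure each
pipeline stage assumes: a rigid pocket enclosing a flexible chain ligand with
a planted scan-grid energy minimum, conformer energy sets with prescribed
gaps, ideal-geometry hydrogen-bond dimers, and electronic-transition tables.

Every generator is a pure function of its spec and seed; randomness flows
through one named ``numpy`` generator and never global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conformers import DihedralSpec, rotate_dihedral
from .energetics import (
    GAS_CONSTANT_KCAL,
    ForceFieldBackend,
    ForceFieldParams,
)
from .site import ActiveSite
from .spectra import TransitionRecord
from .structure_io import (
    Atom,
    MolecularStructure,
    FRAGMENT_LIGAND,
    FRAGMENT_SITE,
)

__all__ = [
    "ToyComplexSpec",
    "make_toy_complex",
    "toy_backend",
    "make_energy_set",
    "energies_for_populations",
    "make_hbond_dimer",
    "make_transition_table",
]

_BOND_LENGTH = 1.5  # Angstrom, toy chain heavy-atom bond
_BOND_ANGLE = math.radians(109.47)


@dataclass(frozen=True)
class ToyComplexSpec:
    """Specification of a synthetic pocket/ligand pair.

    ``planted_minimum`` is the dihedral tuple (degrees, multiples of
    ``scan_step``) at which attractor atoms make the force-field energy over
    the scan grid globally minimal.  The seed fixes the pocket cage; the
    ligand chain and the attractors are deterministic functions of the spec
    so the planted optimum is seed-independent by construction.
    """

    n_rotatable: int = 2
    planted_minimum: tuple[float, ...] = (90.0, 270.0)
    seed: int = 0
    n_ligand_atoms: int | None = None  # default: n_rotatable + 3
    n_pocket_atoms: int = 12
    pocket_radius: float = 7.0
    scan_step: float = 90.0
    marker_charge: float = 0.35  # e; alternating sign along the chain markers
    cage_depth: float = 1e-4  # kcal/mol, deliberately negligible

    def __post_init__(self) -> None:
        if self.n_rotatable < 1:
            raise ValueError("need at least one rotatable bond")
        if len(self.planted_minimum) != self.n_rotatable:
            raise ValueError("planted_minimum length must equal n_rotatable")
        for v in self.planted_minimum:
            if abs((v / self.scan_step) - round(v / self.scan_step)) > 1e-9:
                raise ValueError(
                    "planted minimum angles must be multiples of the scan step"
                )
        n_atoms = self.n_ligand_atoms or (self.n_rotatable + 3)
        if self.n_rotatable > n_atoms - 3:
            raise ValueError(
                "infeasible spec: n_rotatable exceeds chain length - 3"
            )

    @property
    def chain_length(self) -> int:
        return self.n_ligand_atoms or (self.n_rotatable + 3)


def _zigzag_chain(n: int) -> np.ndarray:
    """A planar zigzag chain with tetrahedral-like angles (bond 1.5 A)."""
    coords = np.zeros((n, 3))
    direction = np.array([1.0, 0.0, 0.0])
    up = np.array([0.0, 1.0, 0.0])
    half = _BOND_ANGLE / 2.0
    for i in range(1, n):
        flip = 1.0 if i % 2 else -1.0
        step = math.sin(half) * direction + flip * math.cos(half) * up
        coords[i] = coords[i - 1] + _BOND_LENGTH * step
    return coords


def _toy_params(spec: ToyComplexSpec) -> ForceFieldParams:
    eps = {
        "C": 0.05,  # chain atoms: a shallow dispersion background
        "O": 0.10,  # attractor oxygens; wells are electrostatic, not LJ
        "N": spec.cage_depth,  # cage atoms: scenery only
        "H": 0.01,
    }
    sigma = {"C": 3.4, "O": 3.2, "N": 3.5, "H": 2.8}
    return ForceFieldParams(epsilon=eps, sigma=sigma)


def make_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[ActiveSite, MolecularStructure, list[DihedralSpec], ForceFieldParams]:
    """Build the pocket, ligand, dihedral specs and force-field parameters.

    The ligand is a carbon chain whose atoms carry alternating +/- partial
    charges.  One oppositely charged "attractor" oxygen sits at the
    LJ-plus-Coulomb pair-potential optimum distance from each atom's
    position in the planted pose, so the whole planted geometry is pinned:
    any other dihedral combination (or rigid translation) must pull at least
    one atom out of its well, and relaxation from any scan point cannot find
    a basin deeper than the relaxed planted pose.  A seeded cage of
    near-inert nitrogen atoms on a sphere supplies pocket scenery without
    moving the optimum.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.chain_length
    chain_xyz = _zigzag_chain(n)
    ligand = MolecularStructure(
        atoms=[
            Atom(element="C", name=f"C{i+1}", coords=chain_xyz[i],
                 residue_name="LIG", fragment=FRAGMENT_LIGAND)
            for i in range(n)
        ],
        title="toy chain ligand",
    )
    dihedrals = [
        DihedralSpec(
            atom_indices=(t, t + 1, t + 2, t + 3),
            rotating_set=tuple(range(t + 3, n)),
        )
        for t in range(spec.n_rotatable)
    ]

    # pose at the planted dihedral combination
    planted = ligand
    for dih, angle in zip(dihedrals, spec.planted_minimum):
        if angle != 0.0:
            planted = rotate_dihedral(planted, dih, angle)
    planted_xyz = planted.coords()
    centroid = planted_xyz.mean(axis=0)

    params = _toy_params(spec)
    sigma_co = 0.5 * (params.sigma["C"] + params.sigma["O"])
    eps_co = math.sqrt(params.epsilon["C"] * params.epsilon["O"])
    # optimum of the combined LJ + Coulomb marker-attractor pair potential,
    # so the identity translation sits exactly in the planted wells
    from scipy.optimize import brentq

    q2k = params.coulomb_k * spec.marker_charge**2

    def dvdr(r: float) -> float:
        return (
            4.0 * eps_co * (-12.0 * sigma_co**12 / r**13 + 6.0 * sigma_co**6 / r**7)
            + q2k / r**2
        )

    contact = brentq(dvdr, 0.5 * sigma_co, 1.3 * sigma_co)

    pocket_atoms: list[Atom] = []
    chain_axis = planted_xyz[-1] - planted_xyz[0]
    chain_axis /= max(np.linalg.norm(chain_axis), 1e-8)
    for i in range(n):
        # alternating signs localise each atom to its own wells; the graded
        # magnitude breaks the head/tail symmetry of the chain
        sign = 1.0 if i % 2 == 0 else -1.0
        magnitude = spec.marker_charge * (1.0 + 0.15 * i)
        ligand.atoms[i].partial_charge = sign * magnitude
        anchor = planted_xyz[i]
        outward = anchor - centroid
        norm = np.linalg.norm(outward)
        outward = outward / norm if norm > 1e-8 else np.array([0.0, 0.0, 1.0])
        # Split each atom's well into a half-charge pair fanned +/-40 degrees
        # about the chain axis.  A single well is a sphere, and a torsion
        # circle meets a sphere at two mirror-related points; the split pair
        # is only simultaneously satisfied at the planted point, which
        # removes that reflection degeneracy without changing the overall
        # well depth.
        theta = math.radians(40.0)
        for tag, ang in (("A", theta), ("B", -theta)):
            ct, st = math.cos(ang), math.sin(ang)
            direction = (
                outward * ct
                + np.cross(chain_axis, outward) * st
                + chain_axis * (chain_axis @ outward) * (1.0 - ct)
            )
            direction /= np.linalg.norm(direction)
            pocket_atoms.append(
                Atom(
                    element="O",
                    name=f"AT{tag}{i+1}",
                    coords=anchor + contact * direction,
                    residue_name="POC",
                    residue_seq=1,
                    fragment=FRAGMENT_SITE,
                    partial_charge=-0.5 * sign * magnitude,
                )
            )
    # seeded cage on a sphere around the ligand centroid
    for k in range(spec.n_pocket_atoms):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        pocket_atoms.append(
            Atom(
                element="N",
                name=f"CAGE{k+1}",
                coords=centroid + spec.pocket_radius * v,
                residue_name="POC",
                residue_seq=2,
                fragment=FRAGMENT_SITE,
            )
        )
    site = ActiveSite(
        atoms=pocket_atoms,
        source_residues=[("A", 1, "POC"), ("A", 2, "POC")],
        radius=spec.pocket_radius,
        center=centroid,
    )
    return site, ligand, dihedrals, params


def toy_backend(
    spec: ToyComplexSpec,
    params: ForceFieldParams,
    ligand: MolecularStructure,
    restrain_bonds: bool = True,
    pair_scope: str = "inter_fragment",
) -> ForceFieldBackend:
    """A backend for the toy complex.

    Interaction energy is ligand-pocket only (the chain has no internal
    nonbonded surface worth modelling).  Harmonic 1-2 and 1-3 distance
    restraints keep bond lengths and angles intact during minimization while
    leaving the torsions free, which is the degree of freedom the scan
    explores.
    """
    restraints = None
    if restrain_bonds:
        n = len(ligand.atoms)
        r13 = 2.0 * _BOND_LENGTH * math.sin(_BOND_ANGLE / 2.0)
        restraints = [(i, i + 1, _BOND_LENGTH, 300.0) for i in range(n - 1)]
        restraints += [(i, i + 2, r13, 150.0) for i in range(n - 2)]
    return ForceFieldBackend(
        params=params,
        pair_scope=pair_scope,
        restraints=restraints,
        name="toy-pocket-ff",
    )


def make_energy_set(
    n: int,
    gaps: float | list[float] = 0.5,
    seed: int = 0,
    jitter: float = 0.0,
) -> list[float]:
    """Conformer energies (kcal/mol) with specified consecutive gaps plus
    optional seeded Gaussian jitter.  A scalar gap is applied uniformly."""
    if n < 1:
        raise ValueError("need at least one conformer")
    if isinstance(gaps, (int, float)):
        gap_list = [float(gaps)] * (n - 1)
    else:
        gap_list = [float(g) for g in gaps]
        if len(gap_list) != n - 1:
            raise ValueError("need exactly n - 1 gaps")
    energies = np.concatenate([[0.0], np.cumsum(gap_list)])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        energies = energies + rng.normal(scale=jitter, size=n)
    return [float(e) for e in energies]


def energies_for_populations(
    populations, temperature: float = 298.15
) -> list[float]:
    """Invert the Boltzmann relation: energies (kcal/mol, ground state at 0)
    that reproduce the given population fractions exactly."""
    p = np.asarray(list(populations), dtype=float)
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("populations must be positive and sum to 1")
    rt = GAS_CONSTANT_KCAL * temperature
    dg = -rt * np.log(p)
    dg -= dg.min()
    return [float(v) for v in dg]


def make_hbond_dimer(distance: float = 1.8, angle: float = 170.0) -> MolecularStructure:
    """An O-H...O dimer at the exact requested H...A distance and D-H...A
    angle; the donor hydroxyl is tagged as ligand, the acceptor as site."""
    if distance <= 0:
        raise ValueError("H...A distance must be positive")
    if not 0 < angle <= 180:
        raise ValueError("angle must be in (0, 180] degrees")
    h_pos = np.zeros(3)
    d_pos = np.array([-0.96, 0.0, 0.0])  # O-H bond along -x
    a = math.radians(angle)
    u = np.array([-math.cos(a), math.sin(a), 0.0])  # angle `a` away from H->D
    a_pos = h_pos + distance * u
    atoms = [
        Atom(element="O", name="OD", coords=d_pos, residue_name="DON",
             residue_seq=1, fragment=FRAGMENT_LIGAND),
        Atom(element="H", name="HD", coords=h_pos, residue_name="DON",
             residue_seq=1, fragment=FRAGMENT_LIGAND),
        Atom(element="O", name="OA", coords=a_pos, residue_name="ACC",
             residue_seq=2, fragment=FRAGMENT_SITE),
    ]
    return MolecularStructure(atoms=atoms, title="synthetic H-bond dimer")


def make_transition_table(n_states: int, seed: int = 0) -> list[TransitionRecord]:
    """A seeded stick table with one designated predominant transition."""
    if n_states < 1:
        raise ValueError("need at least one state")
    rng = np.random.default_rng(seed)
    lambdas = rng.uniform(160.0, 320.0, size=n_states)
    strengths = rng.uniform(0.05, 0.6, size=n_states)
    dipoles = rng.uniform(1.0, 5.0, size=n_states)
    top = int(np.argmax(strengths))
    records = []
    for i in range(n_states):
        records.append(
            TransitionRecord(
                state=i + 1,
                lambda_nm=float(lambdas[i]),
                f=float(strengths[i]),
                mu_tr=float(dipoles[i]),
                assignment="H -> L" if i == top else f"H -> L+{i}",
                character=("LE",),
                weight_percent=float(rng.uniform(20.0, 99.0)),
                predominant=(i == top),
            )
        )
    return records
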