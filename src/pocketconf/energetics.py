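"""Energies: a nonbonded force-field surrogate backend, the two-layer ONIOM
extrapolation, Boltzmann conformer populations, binding-energy decomposition,
and the dissociation-constant <-> free-energy bridge.

All energies are kcal/mol, distances Angstrom, temperatures Kelvin.

The force field is a Dreiding-flavoured nonbonded model: 12-6 Lennard-Jones
with Lorentz-Berthelot combination, an optional 12-10 hydrogen-bond well for
geometrically detected D-H...A triples, and Coulomb electrostatics with a
constant or distance-dependent dielectric.  Valence terms are deliberately
absent: fragments are either internally rigid or relaxed by the backend
itself, so only the interaction surface matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import MolecularStructure, FRAGMENT_LIGAND

__all__ = [
    "GAS_CONSTANT_KCAL",
    "COULOMB_CONSTANT",
    "ForceFieldParams",
    "ForceFieldBackend",
    "default_params",
    "ff_energy",
    "OniomResult",
    "oniom2_combine",
    "oniom2_score",
    "BoltzmannResult",
    "boltzmann_populations",
    "BindingResult",
    "binding_energy",
    "delta_g_from_kd",
]

#: gas constant, kcal/(mol K)
GAS_CONSTANT_KCAL = 1.98720425864e-3
#: Coulomb constant, kcal A / (mol e^2)
COULOMB_CONSTANT = 332.0637

# Dreiding-style nonbonded well positions R0 (A) and depths D0 (kcal/mol);
# sigma = R0 / 2^(1/6)
_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)
_DEFAULT_R0_D0 = {
    "H": (3.195, 0.0152),
    "C": (3.8983, 0.0951),
    "N": (3.6621, 0.0774),
    "O": (3.4046, 0.0957),
    "F": (3.4720, 0.0725),
    "P": (4.1500, 0.3200),
    "S": (4.0300, 0.3440),
    "Cl": (3.9503, 0.2833),
}


@dataclass
class ForceFieldParams:
    """Per-element Lennard-Jones parameters plus hydrogen-bond and
    electrostatic settings."""

    epsilon: dict[str, float] = field(default_factory=dict)  # kcal/mol
    sigma: dict[str, float] = field(default_factory=dict)  # Angstrom
    d_hb: float = 4.0  # kcal/mol, 12-10 well depth
    r_hb: float = 2.75  # Angstrom, 12-10 optimum (donor-acceptor distance scale)
    dielectric: str = "constant"  # or "distance_dependent"
    dielectric_constant: float = 1.0
    coulomb_k: float = COULOMB_CONSTANT

    def __post_init__(self) -> None:
        if self.d_hb < 0 or self.r_hb <= 0:
            raise ValueError("hydrogen-bond parameters must be non-negative / positive")
        if any(e < 0 for e in self.epsilon.values()):
            raise ValueError("epsilon must be non-negative")
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("sigma must be positive")
        if self.dielectric not in ("constant", "distance_dependent"):
            raise ValueError(f"unknown dielectric model: {self.dielectric!r}")

    def lookup(self, element: str) -> tuple[float, float]:
        try:
            return self.epsilon[element], self.sigma[element]
        except KeyError:
            raise KeyError(
                f"no Lennard-Jones parameters for element {element!r}"
            ) from None


def default_params(eps_scale: float = 1.0, **overrides) -> ForceFieldParams:
    """The packaged Dreiding-flavoured nonbonded parameter set.

    ``eps_scale`` uniformly scales the well depths, which is how the two
    layers of an ONIOM test problem can be given genuinely different
    Hamiltonians while sharing the same functional form.
    """
    eps = {el: d0 * eps_scale for el, (_, d0) in _DEFAULT_R0_D0.items()}
    sig = {el: r0 / _SIXTH_ROOT_2 for el, (r0, _) in _DEFAULT_R0_D0.items()}
    return ForceFieldParams(epsilon=eps, sigma=sig, **overrides)


def _pair_indices(
    structure: MolecularStructure,
    pair_scope: str,
    bonds: list[tuple[int, int]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(structure.atoms)
    ii, jj = np.triu_indices(n, k=1)
    if pair_scope == "inter_fragment":
        frag = np.array([a.fragment == FRAGMENT_LIGAND for a in structure.atoms])
        keep = frag[ii] != frag[jj]
        ii, jj = ii[keep], jj[keep]
    elif pair_scope != "all":
        raise ValueError(f"unknown pair scope: {pair_scope!r}")
    if bonds:
        adjacency: dict[int, set[int]] = {}
        for a, b in bonds:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
        excluded = set()
        for a, b in bonds:
            excluded.add((min(a, b), max(a, b)))  # 1-2
        for center, nbrs in adjacency.items():
            nl = sorted(nbrs)
            for x in range(len(nl)):
                for y in range(x + 1, len(nl)):
                    excluded.add((nl[x], nl[y]))  # 1-3
        keep = np.array(
            [(int(a), int(b)) not in excluded for a, b in zip(ii, jj)], dtype=bool
        )
        ii, jj = ii[keep], jj[keep]
    return ii, jj


def ff_energy_and_gradient(
    structure: MolecularStructure,
    params: ForceFieldParams,
    pair_scope: str = "all",
    bonds: list[tuple[int, int]] | None = None,
    hbond_pairs: set[tuple[int, int]] | None = None,
) -> tuple[float, np.ndarray]:
    """Total nonbonded energy and its analytic gradient (kcal/mol, per-atom
    kcal/mol/A).  ``hbond_pairs`` are (hydrogen, acceptor) index pairs whose
    Lennard-Jones term is replaced by the 12-10 hydrogen-bond well."""
    atoms = structure.atoms
    if not atoms:
        raise ValueError("empty structure")
    xyz = structure.coords()
    eps = np.empty(len(atoms))
    sig = np.empty(len(atoms))
    for i, atom in enumerate(atoms):
        eps[i], sig[i] = params.lookup(atom.element)
    charges = np.array([a.partial_charge for a in atoms])

    ii, jj = _pair_indices(structure, pair_scope, bonds)
    grad = np.zeros_like(xyz)
    if ii.size == 0:
        return 0.0, grad

    dvec = xyz[ii] - xyz[jj]
    r = np.linalg.norm(dvec, axis=1)
    if np.any(r < 1e-12):
        # coincident atoms: infinite repulsion, gradient undefined but finite-capped
        return math.inf, grad
    unit = dvec / r[:, None]

    hb_mask = np.zeros(ii.size, dtype=bool)
    if hbond_pairs:
        normalized = {(min(a, b), max(a, b)) for a, b in hbond_pairs}
        hb_mask = np.array(
            [(int(a), int(b)) in normalized for a, b in zip(ii, jj)], dtype=bool
        )

    e_pairs = np.zeros(ii.size)
    de_dr = np.zeros(ii.size)

    lj = ~hb_mask
    if np.any(lj):
        e_ij = np.sqrt(eps[ii[lj]] * eps[jj[lj]])
        s_ij = 0.5 * (sig[ii[lj]] + sig[jj[lj]])
        sr6 = (s_ij / r[lj]) ** 6
        sr12 = sr6 * sr6
        e_pairs[lj] += 4.0 * e_ij * (sr12 - sr6)
        de_dr[lj] += 4.0 * e_ij * (-12.0 * sr12 + 6.0 * sr6) / r[lj]

    if np.any(hb_mask):
        rr = params.r_hb / r[hb_mask]
        rr10 = rr ** 10
        rr12 = rr ** 12
        e_pairs[hb_mask] += params.d_hb * (5.0 * rr12 - 6.0 * rr10)
        de_dr[hb_mask] += params.d_hb * (-60.0 * rr12 + 60.0 * rr10) / r[hb_mask]

    qq = charges[ii] * charges[jj]
    nz = qq != 0.0
    if np.any(nz):
        k = params.coulomb_k
        if params.dielectric == "constant":
            epsr = params.dielectric_constant
            e_pairs[nz] += k * qq[nz] / (epsr * r[nz])
            de_dr[nz] += -k * qq[nz] / (epsr * r[nz] ** 2)
        else:  # distance-dependent: eps(r) = r
            e_pairs[nz] += k * qq[nz] / (r[nz] ** 2)
            de_dr[nz] += -2.0 * k * qq[nz] / (r[nz] ** 3)

    energy = float(e_pairs.sum())
    pair_grad = de_dr[:, None] * unit
    np.add.at(grad, ii, pair_grad)
    np.add.at(grad, jj, -pair_grad)
    return energy, grad


def ff_energy(
    structure: MolecularStructure,
    params: ForceFieldParams,
    pair_scope: str = "all",
    bonds: list[tuple[int, int]] | None = None,
    hbond_pairs: set[tuple[int, int]] | None = None,
) -> float:
    """Nonbonded force-field energy (kcal/mol); see
    :func:`ff_energy_and_gradient`."""
    return ff_energy_and_gradient(structure, params, pair_scope, bonds, hbond_pairs)[0]


class ForceFieldBackend:
    """Energy-backend contract implementation over the nonbonded force field.

    ``detect_hbonds`` turns on geometric D-H...A detection (delegated to the
    NCI module's hydrogen-bond rule) at every energy evaluation; the detected
    pair set is held fixed within a single energy/gradient call so the two
    stay mutually consistent.
    """

    def __init__(
        self,
        params: ForceFieldParams | None = None,
        pair_scope: str = "all",
        bonds: list[tuple[int, int]] | None = None,
        detect_hbonds: bool = False,
        restraints: list[tuple[int, int, float, float]] | None = None,
        name: str = "nonbonded-ff",
    ) -> None:
        self.params = params if params is not None else default_params()
        self.pair_scope = pair_scope
        self.bonds = bonds
        self.detect_hbonds = detect_hbonds
        #: harmonic pair restraints (i, j, r0 A, k kcal/mol/A^2)
        self.restraints = restraints or []
        self.name = name

    def _restraint_terms(self, structure: MolecularStructure) -> tuple[float, np.ndarray]:
        xyz = structure.coords()
        e = 0.0
        g = np.zeros_like(xyz)
        for i, j, r0, k in self.restraints:
            d = xyz[i] - xyz[j]
            r = float(np.linalg.norm(d))
            if r < 1e-12:
                continue
            e += k * (r - r0) ** 2
            dg = 2.0 * k * (r - r0) * d / r
            g[i] += dg
            g[j] -= dg
        return e, g

    def _hbond_pairs(self, structure: MolecularStructure) -> set[tuple[int, int]] | None:
        if not self.detect_hbonds:
            return None
        from .nci import hbond_table  # local import: nci depends on structure_io only

        contacts = hbond_table(structure, quiet=True)
        return {(c.hydrogen_index, c.acceptor_index) for c in contacts}

    def energy(self, structure: MolecularStructure) -> float:
        e, _ = ff_energy_and_gradient(
            structure, self.params, self.pair_scope, self.bonds,
            self._hbond_pairs(structure),
        )
        if self.restraints:
            e += self._restraint_terms(structure)[0]
        return e

    def gradient(self, structure: MolecularStructure, free_indices) -> np.ndarray:
        grad = ff_energy_and_gradient(
            structure, self.params, self.pair_scope, self.bonds,
            self._hbond_pairs(structure),
        )[1]
        if self.restraints:
            grad = grad + self._restraint_terms(structure)[1]
        return grad[list(free_indices)]


# ---------------------------------------------------------------------------
# ONIOM two-layer extrapolation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OniomResult:
    """The three component energies of the two-layer extrapolation and the
    combined total E = E(high, model) + E(low, real) - E(low, model)."""

    e_high_model: float
    e_low_real: float
    e_low_model: float

    def __post_init__(self) -> None:
        for v in (self.e_high_model, self.e_low_real, self.e_low_model):
            if not math.isfinite(v):
                raise ValueError("ONIOM component energies must be finite")

    @property
    def e_oniom2(self) -> float:
        return self.e_high_model + self.e_low_real - self.e_low_model


def oniom2_combine(
    e_high_model: float, e_low_real: float, e_low_model: float
) -> OniomResult:
    """Pure arithmetic combination of the three layer energies."""
    return OniomResult(float(e_high_model), float(e_low_real), float(e_low_model))


def oniom2_score(
    complex_structure: MolecularStructure,
    ligand_selector,
    high_backend,
    low_backend,
    boundary_check: bool = True,
) -> OniomResult:
    """Score a complex with the model layer set to the whole ligand.

    The ligand must be a complete molecule: a ligand selection that crosses a
    covalent bond into the site would require link atoms, which this scheme
    does not support.
    """
    ligand = complex_structure.select(ligand_selector)
    if not ligand.atoms:
        raise ValueError("ligand selector matched no atoms")
    if boundary_check:
        from . import elements

        site_atoms = [a for a in complex_structure.atoms if not ligand_selector(a)]
        if site_atoms:
            lig_xyz = ligand.coords()
            for satom in site_atoms:
                d = np.linalg.norm(lig_xyz - satom.coords, axis=1)
                cut = np.array(
                    [
                        elements.covalent_radius(a.element)
                        + elements.covalent_radius(satom.element)
                        for a in ligand.atoms
                    ]
                ) * 1.15
                if np.any(d < cut):
                    raise ValueError(
                        "ligand selection crosses a covalent bond to the site; "
                        "link atoms are not supported"
                    )
    return oniom2_combine(
        high_backend.energy(ligand),
        low_backend.energy(complex_structure),
        low_backend.energy(ligand),
    )


# ---------------------------------------------------------------------------
# Boltzmann populations
# ---------------------------------------------------------------------------

@dataclass
class BoltzmannResult:
    """Conformer populations P_i = exp(-dG_i/RT) / sum_j exp(-dG_j/RT)."""

    delta_g: np.ndarray
    temperature: float
    populations: np.ndarray
    gas_constant: float = GAS_CONSTANT_KCAL

    @property
    def percentages(self) -> np.ndarray:
        """Populations as percentages rounded to one decimal."""
        return np.round(100.0 * self.populations, 1)


def boltzmann_populations(
    delta_g, temperature: float = 298.15
) -> BoltzmannResult:
    """Boltzmann population analysis of a set of conformer (free) energies.

    Uses the max-shifted (overflow-safe) softmax form with a deterministic
    summation order; populations are invariant to adding a constant to all
    energies.
    """
    dg = np.asarray(list(delta_g), dtype=float)
    if dg.size == 0:
        raise ValueError("at least one energy is required")
    if not np.all(np.isfinite(dg)):
        raise ValueError("energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = 1.0 / (GAS_CONSTANT_KCAL * temperature)
    x = -beta * (dg - dg.min())
    w = np.exp(x)
    pops = w / w.sum()
    return BoltzmannResult(delta_g=dg, temperature=temperature, populations=pops)


# ---------------------------------------------------------------------------
# Binding energy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingResult:
    """Binding energy E_bind = E_complex - (E_site + E_ligand)."""

    e_complex: float
    e_active_site: float
    e_ligand: float

    @property
    def binding_energy(self) -> float:
        return self.e_complex - (self.e_active_site + self.e_ligand)


def binding_energy(
    e_complex: float, e_active_site: float, e_ligand: float
) -> BindingResult:
    for v in (e_complex, e_active_site, e_ligand):
        if not math.isfinite(v):
            raise ValueError("component energies must be finite")
    return BindingResult(float(e_complex), float(e_active_site), float(e_ligand))


def delta_g_from_kd(kd: float, temperature: float = 298.15) -> float:
    """Binding free energy (kcal/mol) from a dissociation constant in mol/L:
    dG = R T ln(K_d / 1 M).  Sub-molar K_d gives a negative (favourable) dG."""
    if kd <= 0:
        raise ValueError("dissociation constant must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)
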