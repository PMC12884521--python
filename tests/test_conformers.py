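"""Dihedral rotation, pose enumeration, clash filtering, minimization,
minimum verification, deduplication and Kabsch RMSD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pocketconf import conformers as conf
from pocketconf import synthetic_data as synth
from pocketconf.energetics import ForceFieldBackend, ForceFieldParams
from pocketconf.structure_io import MolecularStructure

from conftest import structure_from

CHAIN = structure_from(
    ["C", "C", "C", "C"],
    [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.5, 1.0, 0.0), (3.5, 1.0, 1.0)],
)
SPEC = conf.DihedralSpec(atom_indices=(0, 1, 2, 3), rotating_set=(3,))


def rodrigues(point, origin, axis, angle_deg):
    """Independent axis-angle rotation-matrix oracle."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)
    return origin + R @ (np.asarray(point, float) - origin)


class TestRotateDihedral:
    def test_identity_and_period(self):
        assert np.allclose(conf.rotate_dihedral(CHAIN, SPEC, 0.0).coords(), CHAIN.coords())
        assert np.abs(
            conf.rotate_dihedral(CHAIN, SPEC, 360.0).coords() - CHAIN.coords()
        ).max() < 1e-9

    def test_matches_rotation_matrix_oracle(self):
        rotated = conf.rotate_dihedral(CHAIN, SPEC, 90.0)
        xyz = CHAIN.coords()
        expected = rodrigues(xyz[3], xyz[2], xyz[2] - xyz[1], 90.0)
        assert np.allclose(rotated.coords()[3], expected, atol=1e-12)

    def test_measured_angle_tracks_rotation(self):
        for angle in (30.0, 90.0, 215.0):
            rotated = conf.rotate_dihedral(CHAIN, SPEC, angle)
            offset = (
                conf.measure_dihedral(rotated, SPEC) - conf.measure_dihedral(CHAIN, SPEC)
            ) % 360.0
            assert offset == pytest.approx(angle, abs=1e-9)

    def test_degenerate_axis_rejected(self):
        bad = structure_from(
            ["C", "C", "C", "C"],
            [(0, 0, 0), (1, 0, 0), (1, 0, 0), (2, 1, 1)],
        )
        with pytest.raises(ValueError):
            conf.rotate_dihedral(bad, SPEC, 10.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(angle=st.floats(-720, 720, allow_nan=False))
    def test_rigid_body_distances_preserved(self, angle):
        pose = structure_from(
            ["C"] * 6,
            [(0, 0, 0), (1.5, 0, 0), (2.5, 1, 0), (3.5, 1, 1), (4.5, 2, 1), (5.0, 3, 2)],
        )
        spec = conf.DihedralSpec(atom_indices=(0, 1, 2, 3), rotating_set=(3, 4, 5))
        rotated = conf.rotate_dihedral(pose, spec, angle)
        a, b = pose.coords(), rotated.coords()
        for group in [(3, 4, 5), (0, 1, 2)]:
            for i in group:
                for j in group:
                    d0 = np.linalg.norm(a[i] - a[j])
                    d1 = np.linalg.norm(b[i] - b[j])
                    assert d1 == pytest.approx(d0, abs=1e-9)


class TestEnumerate:
    def test_counts(self):
        spec2 = conf.DihedralSpec(atom_indices=(3, 2, 1, 0), rotating_set=(0,))
        assert len(conf.enumerate_poses(CHAIN, [SPEC, spec2], 90.0)) == 16
        records = conf.enumerate_poses(
            CHAIN, [SPEC], 90.0, conf.translation_grid(1.0, 3)
        )
        assert len(records) == 4 * 27

    def test_closed_form_count_for_eight_dihedrals(self):
        specs = [SPEC] * 8
        with pytest.raises(ValueError, match="65536"):
            conf.enumerate_poses(CHAIN, specs, 90.0, cap=1000)

    def test_deterministic_lexicographic_order(self):
        records = conf.enumerate_poses(CHAIN, [SPEC], 90.0)
        assert [r.dihedral_values for r in records] == [
            (0.0,), (90.0,), (180.0,), (270.0,)
        ]

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            conf.enumerate_poses(CHAIN, [SPEC], 70.0)


class TestClashFilter:
    def test_coincident_atom_removed_and_vacuous_site(self):
        site = structure_from(["O"], [(3.5, 1.0, 1.0)])  # on top of atom 3
        recs = [conf.ConformerRecord(pose=CHAIN.copy())]
        assert conf.clash_filter(recs, site) == []
        assert len(conf.clash_filter(recs, MolecularStructure())) == 1

    def test_engineered_clash_count(self):
        site, ligand, dihedrals, _ = synth.make_toy_complex(synth.ToyComplexSpec(seed=3))
        records = conf.enumerate_poses(ligand, dihedrals, 90.0)
        kept = conf.clash_filter(records, site.as_structure(), scale=0.7)
        # every pose keeps a clearance >= 0.7 vdW sums against the pocket
        assert 0 < len(kept) <= len(records)
        site_xyz = site.as_structure().coords()
        for rec in kept:
            d = np.linalg.norm(
                rec.pose.coords()[:, None, :] - site_xyz[None, :, :], axis=-1
            )
            assert d.min() >= 0.7 * (0.5 + 0.5)  # loosest possible vdW bound


LJ_PARAMS = ForceFieldParams(epsilon={"Ar": 0.25}, sigma={"Ar": 3.4})
R_MIN = 2.0 ** (1.0 / 6.0) * 3.4


class TestMinimize:
    def _dimer_record(self, r):
        pose = structure_from(["Ar"], [(0.0, 0.0, 0.0)], fragment="ligand")
        return conf.ConformerRecord(pose=pose), structure_from(["Ar"], [(r, 0.0, 0.0)])

    def test_lj_dimer_reaches_analytic_minimum(self):
        rec, site = self._dimer_record(1.2 * R_MIN)
        backend = ForceFieldBackend(params=LJ_PARAMS)
        out = conf.local_minimize(rec, site, backend, free_atoms="ligand")
        r = np.linalg.norm(out.pose.coords()[0] - site.coords()[0])
        assert r == pytest.approx(R_MIN, abs=1e-4)
        assert out.energy == pytest.approx(-0.25, abs=1e-8)

    def test_fixed_point_and_frozen_site(self):
        rec, site = self._dimer_record(R_MIN)
        backend = ForceFieldBackend(params=LJ_PARAMS)
        before = site.coords().copy()
        out = conf.local_minimize(rec, site, backend, free_atoms="ligand")
        assert abs(out.energy - (-0.25)) < 1e-8
        assert np.array_equal(site.coords(), before)


class TestVerifyMinimum:
    def test_lj_dimer_minimum_is_verified(self):
        pose = structure_from(["Ar"], [(R_MIN, 0.0, 0.0)], fragment="ligand")
        site = structure_from(["Ar"], [(0.0, 0.0, 0.0)])
        backend = ForceFieldBackend(params=LJ_PARAMS)
        rec = conf.ConformerRecord(pose=pose, energy=-0.25)
        assert conf.verify_minimum(rec, site, backend, free_atoms="ligand") is True

    def test_non_stationary_point_rejected(self):
        pose = structure_from(["Ar"], [(3.4, 0.0, 0.0)], fragment="ligand")  # r = sigma
        site = structure_from(["Ar"], [(0.0, 0.0, 0.0)])
        backend = ForceFieldBackend(params=LJ_PARAMS)
        rec = conf.ConformerRecord(pose=pose)
        with pytest.raises(ValueError, match="stationary"):
            conf.verify_minimum(rec, site, backend, free_atoms="ligand")

    def test_symmetric_saddle_detected(self):
        # free atom midway between two identical LJ partners: gradient is
        # zero by symmetry but the axial curvature is negative
        d = 3.0 * R_MIN
        pose = structure_from(["Ar"], [(d / 2, 0.0, 0.0)], fragment="ligand")
        site = structure_from(["Ar", "Ar"], [(0.0, 0.0, 0.0), (d, 0.0, 0.0)])
        backend = ForceFieldBackend(params=LJ_PARAMS)
        rec = conf.ConformerRecord(pose=pose)
        assert conf.verify_minimum(rec, site, backend, free_atoms="ligand") is False


class TestKabschRmsd:
    def test_zero_for_identical_and_transformed_copies(self):
        pose = structure_from(
            ["C", "N", "O", "C"],
            [(0, 0, 0), (1.5, 0, 0), (2.1, 1.2, 0.3), (0.5, -1.0, 2.0)],
        )
        assert conf.kabsch_rmsd(pose, pose) == pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(4)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = pose.copy()
        moved.set_coords(pose.coords() @ Q.T + np.array([3.0, -2.0, 7.0]))
        assert conf.kabsch_rmsd(pose, moved) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        a = structure_from(["C"] * 3, [(0, 0, 0), (1.4, 0, 0), (2.0, 1.1, 0.2)])
        b = structure_from(["C"] * 3, [(0, 0.3, 0), (1.2, 0, 0.5), (2.2, 1.0, 0)])
        assert conf.kabsch_rmsd(a, b) == pytest.approx(conf.kabsch_rmsd(b, a), abs=1e-12)

    def test_two_point_degenerate_centroid_oracle(self):
        a = structure_from(["C", "C"], [(0, 0, 0), (1, 0, 0)])
        b = structure_from(["C", "C"], [(0, 0, 0), (2, 0, 0)])
        with pytest.raises(ValueError):
            conf.kabsch_rmsd(a, b, superpose=True)
        assert conf.kabsch_rmsd(a, b, superpose=False, center=True) == pytest.approx(0.5)

    def test_mismatched_counts_rejected(self):
        a = structure_from(["C"], [(0, 0, 0)])
        b = structure_from(["C", "C"], [(0, 0, 0), (1, 0, 0)])
        with pytest.raises(ValueError):
            conf.kabsch_rmsd(a, b)


class TestDeduplicate:
    def _rec(self, coords, energy):
        return conf.ConformerRecord(
            pose=structure_from(["C"] * 4, coords), energy=energy
        )

    BASE = [(0, 0, 0), (1.5, 0, 0), (2.5, 1, 0), (3.5, 1, 1)]

    def test_identical_poses_merge_to_lower_energy(self):
        out = conf.deduplicate([self._rec(self.BASE, 2.0), self._rec(self.BASE, 1.0)])
        assert len(out) == 1
        assert out[0].energy == 1.0

    def test_threshold_rule(self):
        shifted = [(x + 0.7, y, z) for x, y, z in self.BASE[:-1]] + [(5.0, 2.0, 2.0)]
        a, b = self._rec(self.BASE, 0.0), self._rec(shifted, 1.0)
        rmsd = conf.kabsch_rmsd(a.pose, b.pose)
        assert rmsd > 0.5
        assert len(conf.deduplicate([a, b], rmsd_threshold=0.5)) == 2
        assert len(conf.deduplicate([a, b], rmsd_threshold=rmsd + 0.1)) == 1

    def test_idempotent_and_sorted(self):
        rng = np.random.default_rng(11)
        records = [
            self._rec(np.asarray(self.BASE) + rng.normal(scale=1.0, size=(4, 3)), e)
            for e in rng.normal(size=6)
        ]
        once = conf.deduplicate(records)
        twice = conf.deduplicate(once)
        assert [r.energy for r in once] == [r.energy for r in twice]
        energies = [r.energy for r in once]
        assert energies == sorted(energies)
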