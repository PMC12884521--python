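"""Promolecular density derivatives, reduced density gradient,
sign(lambda_2) rho, grid analysis, classification and hydrogen bonds."""


import numpy as np
import pytest

from pocketconf import nci
from pocketconf.structure_io import ANGSTROM_TO_BOHR
from pocketconf.synthetic_data import make_hbond_dimer

from conftest import structure_from

SINGLE_SHELL = nci.PromolecularModel(shells={"H": ((0.3, 0.7),)})


def _points(rng, n, lo=-4.0, hi=4.0):
    return rng.uniform(lo, hi, size=(n, 3))


class TestPromolecularDensity:
    def test_nuclear_value_is_coefficient_sum(self):
        model = nci.slater_promolecular_model()
        atom = structure_from(["C"], [(0.0, 0.0, 0.0)])
        rho, _, _ = nci.promolecular_density(atom, model, np.zeros((1, 3)))
        # the nuclear-cusp guard (r clipped at 1e-10 bohr) bounds the error
        assert rho[0] == pytest.approx(model.rho_at_nucleus("C"), rel=1e-8)

    def test_fragment_additivity(self):
        model = nci.slater_promolecular_model()
        a = structure_from(["O"], [(0.0, 0.0, 0.0)])
        b = structure_from(["N"], [(1.1, 0.4, -0.2)])
        both = structure_from(["O", "N"], [(0.0, 0.0, 0.0), (1.1, 0.4, -0.2)])
        pts = _points(np.random.default_rng(0), 50)
        r_a, _, _ = nci.promolecular_density(a, model, pts)
        r_b, _, _ = nci.promolecular_density(b, model, pts)
        r_ab, _, _ = nci.promolecular_density(both, model, pts)
        assert np.allclose(r_ab, r_a + r_b, rtol=1e-12)

    def test_far_field_decay(self):
        atom = structure_from(["H"], [(0.0, 0.0, 0.0)])
        rho, grad, _ = nci.promolecular_density(
            atom, nci.slater_promolecular_model(), np.array([[200.0, 0.0, 0.0]])
        )
        assert rho[0] < 1e-30
        assert np.linalg.norm(grad[0]) < 1e-30

    def test_derivatives_match_finite_differences(self):
        model = nci.slater_promolecular_model()
        st = structure_from(["O", "H", "H"], [(0, 0, 0), (0.96, 0, 0), (-0.3, 0.9, 0)])
        rng = np.random.default_rng(3)
        pts = _points(rng, 20, lo=-3.0, hi=3.0)
        rho, grad, hess = nci.promolecular_density(st, model, pts)
        h = 1e-5
        for k in range(3):
            shift = np.zeros(3)
            shift[k] = h
            rp, gp, _ = nci.promolecular_density(st, model, pts + shift)
            rm, gm, _ = nci.promolecular_density(st, model, pts - shift)
            fd_grad = (rp - rm) / (2 * h)
            assert np.abs(fd_grad - grad[:, k]).max() / np.abs(grad).max() < 1e-6
            fd_hess = (gp - gm) / (2 * h)
            assert np.abs(fd_hess - hess[:, :, k]).max() / np.abs(hess).max() < 1e-6

    def test_unparameterized_element_rejected(self):
        st = structure_from(["Fe"], [(0, 0, 0)])
        with pytest.raises(KeyError):
            nci.promolecular_density(st, nci.slater_promolecular_model(), np.zeros((1, 3)))


class TestReducedDensityGradient:
    def test_uniform_density_zero(self):
        s = nci.reduced_density_gradient(np.array([0.3]), np.zeros((1, 3)))
        assert s[0] == 0.0

    def test_single_shell_closed_form(self):
        c, zeta = 0.3, 0.7
        atom = structure_from(["H"], [(0.0, 0.0, 0.0)])
        rng = np.random.default_rng(9)
        pts = _points(rng, 40, lo=-2.5, hi=2.5)
        rho, grad, _ = nci.promolecular_density(atom, SINGLE_SHELL, pts)
        s = nci.reduced_density_gradient(rho, grad)
        r = np.linalg.norm(pts, axis=1)
        expected = np.exp(r / (3 * zeta)) / (nci.RDG_PREFACTOR * zeta * c ** (1.0 / 3.0))
        assert np.abs(s / expected - 1.0).max() < 1e-10

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(2)
        rho = rng.uniform(0.01, 1.0, size=10)
        grad = rng.normal(size=(10, 3))
        s1 = nci.reduced_density_gradient(rho, grad)
        s2 = nci.reduced_density_gradient(7.0 * rho, 7.0 * grad)
        assert np.allclose(s2, 7.0 ** (-1.0 / 3.0) * s1, rtol=1e-12)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            nci.reduced_density_gradient(np.array([0.0]), np.zeros((1, 3)))


class TestSignedDensity:
    def test_single_atom_off_nucleus_negative_lambda2(self):
        atom = structure_from(["H"], [(0.0, 0.0, 0.0)])
        pts = np.array([[1.5, 0.3, -0.2]])
        rho, _, hess = nci.promolecular_density(atom, SINGLE_SHELL, pts)
        signed = nci.signed_density(rho, hess)
        assert signed[0] == pytest.approx(-rho[0], rel=1e-12)

    def test_midpoint_of_close_dimer_attractive(self):
        d = 1.8 / ANGSTROM_TO_BOHR  # 1.8 bohr separation expressed in Angstrom
        dimer = structure_from(["H", "H"], [(0.0, 0.0, 0.0), (d, 0.0, 0.0)])
        mid = np.array([[0.9, 0.0, 0.0]])
        rho, _, hess = nci.promolecular_density(dimer, SINGLE_SHELL, mid)
        signed = nci.signed_density(rho, hess)
        assert signed[0] < 0

    def test_mirror_symmetry(self):
        d = 2.0 / ANGSTROM_TO_BOHR
        dimer = structure_from(["H", "H"], [(0.0, 0.0, 0.0), (d, 0.0, 0.0)])
        pts = np.array([[0.6, 0.4, 0.1], [1.4, 0.4, 0.1]])  # mirror pair (bohr)
        rho, _, hess = nci.promolecular_density(dimer, SINGLE_SHELL, pts)
        signed = nci.signed_density(rho, hess)
        assert signed[0] == pytest.approx(signed[1], rel=1e-10)

    def test_asymmetric_hessian_rejected(self):
        H = np.zeros((1, 3, 3))
        H[0, 0, 1] = 1e-3
        with pytest.raises(ValueError):
            nci.signed_density(np.array([0.1]), H)


class TestGridAndClassification:
    def test_isolated_atom_has_no_intermolecular_points(self):
        atom = structure_from(["H"], [(0.0, 0.0, 0.0)], fragment="ligand")
        res = nci.nci_grid(atom, spacing=0.8, padding=1.5, intermolecular_only=True)
        assert res.scatter_mask.sum() == 0

    def test_hbond_dimer_shows_attractive_trough(self):
        dimer = make_hbond_dimer(1.8, 170.0)
        res = nci.nci_grid(dimer, spacing=0.35, padding=1.5, intermolecular_only=True)
        signed = res.signed_rho[res.scatter_mask]
        rdg = res.rdg[res.scatter_mask]
        assert res.scatter_mask.sum() > 0
        low_s = rdg < 1.0
        assert low_s.any()
        assert signed[low_s].min() < 0  # attractive-like channel between fragments

    def test_classification_partition_and_examples(self):
        values = np.array([-0.03, 0.0, 0.03, 0.009, -0.011])
        labels = nci.classify_points(values, threshold=0.01)
        assert list(labels) == [
            "attractive", "van_der_waals", "repulsive", "van_der_waals", "attractive",
        ]
        assert set(labels) <= {"attractive", "van_der_waals", "repulsive"}

    def test_scatter_export_masks(self, tmp_path):
        dimer = make_hbond_dimer(1.8, 170.0)
        res = nci.nci_grid(dimer, spacing=0.8, padding=1.0, intermolecular_only=False)
        p = tmp_path / "scatter.dat"
        nci.scatter_export(res, p)
        data = np.loadtxt(p)
        assert data.shape[0] == res.scatter_mask.sum()
        res.scatter_mask[:] = False
        nci.scatter_export(res, p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert lines == []  # header-only file when everything is masked

    def test_rotation_invariance_of_rdg(self):
        st = structure_from(["O", "H"], [(0, 0, 0), (0.96, 0, 0)])
        rng = np.random.default_rng(5)
        pts = _points(rng, 30, lo=-2.0, hi=2.0)
        model = nci.slater_promolecular_model()
        rho, grad, _ = nci.promolecular_density(st, model, pts)
        s0 = nci.reduced_density_gradient(rho, grad)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rot = st.copy()
        rot.set_coords(st.coords() @ Q.T)
        rho_r, grad_r, _ = nci.promolecular_density(rot, model, pts @ Q.T)
        s1 = nci.reduced_density_gradient(rho_r, grad_r)
        assert np.abs(s0 - s1).max() < 1e-9


class TestHBonds:
    def test_ideal_contact_detected_with_role(self):
        dimer = make_hbond_dimer(1.8, 170.0)
        contacts = nci.hbond_table(dimer)
        assert len(contacts) == 1
        c = contacts[0]
        assert c.role == "ligand->protein"
        assert c.distance == pytest.approx(1.8, abs=1e-9)
        assert c.angle == pytest.approx(170.0, abs=1e-6)

    @pytest.mark.parametrize("dist,angle", [(3.5, 170.0), (1.8, 90.0)])
    def test_rule_negations(self, dist, angle):
        assert nci.hbond_table(make_hbond_dimer(dist, angle)) == []

    def test_reverse_role(self):
        dimer = make_hbond_dimer(1.9, 165.0)
        for a in dimer.atoms:
            a.fragment = "site" if a.fragment == "ligand" else "ligand"
        contacts = nci.hbond_table(dimer)
        assert len(contacts) == 1
        assert contacts[0].role == "protein->ligand"

    def test_no_hydrogens_warns_empty(self):
        st = structure_from(["O", "O"], [(0, 0, 0), (2.0, 0, 0)])
        with pytest.warns(UserWarning):
            assert nci.hbond_table(st) == []
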