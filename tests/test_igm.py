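import numpy as np
import pytest

from reactikit.core_io import ContractError
from reactikit.igm import (AtomicDensityModel, DENSITY_FLOOR, ModelError,
                           RDG_PREFACTOR, delta_g, igm_grid_analysis,
                           locate_bcp, molecular_grid, promolecular_field,
                           rdg_field, scatter_table, signed_lambda2_density,
                           vdw_surface_mask)
from reactikit.synthetic import toy_geometry
from tests.conftest import make_pair


class TestPromolecularField:
    def test_single_atom_closed_form(self, toy_h_model):
        g = make_pair(2.0)
        g.atoms = g.atoms[:1]
        r = 1.3
        ft = promolecular_field(g, toy_h_model, np.array([[r, 0.0, 0.0]]))
        assert ft.rho[0] == pytest.approx(0.2 * np.exp(-2.0 * r), rel=1e-12)
        # gradient points toward the nucleus with magnitude c*alpha*exp(-alpha r)
        assert ft.grad[0, 0] == pytest.approx(-0.4 * np.exp(-2.0 * r), rel=1e-12)
        assert ft.grad[0, 1] == ft.grad[0, 2] == 0.0

    def test_midpoint_gradient_vanishes_by_symmetry(self, toy_h_model,
                                                    h2_pair_2bohr):
        ft = promolecular_field(h2_pair_2bohr, toy_h_model,
                                np.array([[1.0, 0.0, 0.0]]))
        assert np.abs(ft.grad).max() < 1e-14

    @pytest.mark.parametrize("use_default", [False, True])
    def test_analytic_derivatives_match_finite_differences(
            self, toy_h_model, default_model, h2_pair_2bohr, use_default):
        model = default_model if use_default else toy_h_model
        geom = toy_geometry("hbonded_dimer", 1) if use_default else h2_pair_2bohr
        rng = np.random.default_rng(42)
        pts = rng.uniform(-1.5, 3.5, size=(8, 3))
        ft = promolecular_field(geom, model, pts)
        h = 1e-5
        for k, p in enumerate(pts):
            fd_grad = np.zeros(3)
            fd_hess = np.zeros((3, 3))
            for i in range(3):
                e = np.zeros(3)
                e[i] = h
                fp = promolecular_field(geom, model, (p + e)[None])
                fm = promolecular_field(geom, model, (p - e)[None])
                fd_grad[i] = (fp.rho[0] - fm.rho[0]) / (2 * h)
                fd_hess[i] = (fp.grad[0] - fm.grad[0]) / (2 * h)
            assert np.abs(ft.grad[k] - fd_grad).max() < 1e-6
            assert np.abs(ft.hessian[k] - fd_hess).max() < 1e-4

    def test_missing_element_named(self, toy_h_model):
        g = toy_geometry("hbonded_dimer", 0)  # contains O
        with pytest.raises(ModelError, match="'O'"):
            promolecular_field(g, toy_h_model, np.zeros((1, 3)))


class TestRDG:
    def test_zero_gradient(self):
        assert rdg_field(np.array([0.1]), np.zeros((1, 3)))[0] == 0.0

    def test_unit_point(self):
        rho = 1.0 / (3 * np.pi ** 2)
        gnorm = 2.0 / (3 * np.pi ** 2)
        assert rdg_field(np.array([rho]), np.array([gnorm]))[0] == \
            pytest.approx(1.0, rel=1e-12)

    def test_homogeneity_under_density_scaling(self):
        rng = np.random.default_rng(5)
        rho = rng.uniform(0.01, 1.0, 20)
        grad = rng.normal(size=(20, 3))
        lam = 3.7
        s1 = rdg_field(rho, grad)
        s2 = rdg_field(lam * rho, lam * grad)
        assert np.allclose(s2, lam ** (-1.0 / 3.0) * s1, rtol=1e-12)

    def test_vanishing_density_masked_not_raised(self):
        s = rdg_field(np.array([0.0, -1e-3, 0.1]),
                      np.ones((3, 3)))
        assert np.isnan(s[0]) and np.isnan(s[1]) and np.isfinite(s[2])


class TestDeltaG:
    def test_single_atom_zero_everywhere(self, toy_h_model):
        g = make_pair(2.0)
        g.atoms = g.atoms[:1]
        pts = np.random.default_rng(0).uniform(-2, 2, size=(30, 3))
        dg = delta_g(g, toy_h_model, pts, fragments=False)["delta_g"]
        assert np.abs(dg).max() < 1e-14

    def test_midpoint_closed_form(self, toy_h_model, h2_pair_2bohr):
        # both gradients cancel at the midpoint: delta_g = 2 c a e^{-a}
        dg = delta_g(h2_pair_2bohr, toy_h_model,
                     np.array([[1.0, 0.0, 0.0]]), fragments=False)["delta_g"]
        assert dg[0] == pytest.approx(2 * 0.2 * 2.0 * np.exp(-2.0), abs=1e-6)
        assert dg[0] == pytest.approx(0.108268, abs=1e-6)

    def test_whole_molecule_fragment_degenerate_partition(self, toy_h_model,
                                                          h2_pair_2bohr):
        pts = np.random.default_rng(1).uniform(-1, 3, size=(20, 3))
        out = delta_g(h2_pair_2bohr, toy_h_model, pts,
                      fragments={"all": (1, 2)})
        assert np.abs(out["delta_g_inter"]).max() < 1e-14
        assert np.allclose(out["delta_g_intra"], out["delta_g"])

    def test_singleton_fragments_make_inter_equal_total(self, toy_h_model,
                                                        h2_pair_2bohr):
        pts = np.random.default_rng(2).uniform(-1, 3, size=(20, 3))
        out = delta_g(h2_pair_2bohr, toy_h_model, pts,
                      fragments={"a": (1,), "b": (2,)})
        assert np.allclose(out["delta_g_inter"], out["delta_g"], atol=1e-14)
        assert np.abs(out["delta_g_intra"]).max() < 1e-12

    def test_partition_nonnegative_and_additive_on_grid(self, default_model):
        g = toy_geometry("hbonded_dimer", 0)
        spec = molecular_grid(g, spacing=0.5, padding=2.0)
        out = delta_g(g, default_model, spec.points())
        for key in ("delta_g", "delta_g_intra", "delta_g_inter"):
            assert out[key].min() > -1e-12, key
        assert np.allclose(out["delta_g_intra"] + out["delta_g_inter"],
                           out["delta_g"], atol=1e-12)

    def test_overlapping_fragments_rejected(self, toy_h_model, h2_pair_2bohr):
        with pytest.raises(ContractError):
            delta_g(h2_pair_2bohr, toy_h_model, np.zeros((1, 3)),
                    fragments={"a": (1, 2), "b": (2,)})


class TestSignedLambda2:
    def test_diagonal_cases(self):
        v, flag = signed_lambda2_density(np.diag([1.0, 2.0, 3.0]), 0.01)
        assert v == pytest.approx(0.01) and not flag
        v, _ = signed_lambda2_density(np.diag([-3.0, -1.0, 2.0]), 0.01)
        assert v == pytest.approx(-0.01)

    def test_zero_lambda2_flagged_positive(self):
        v, flag = signed_lambda2_density(np.diag([-1.0, 0.0, 2.0]), 0.01)
        assert v == pytest.approx(0.01) and flag

    def test_off_nucleus_spherical_atom_is_negative(self, toy_h_model):
        g = make_pair(2.0)
        g.atoms = g.atoms[:1]
        ft = promolecular_field(g, toy_h_model, np.array([[0.9, 0.4, -0.2]]))
        v, _ = signed_lambda2_density(ft.hessian[0], ft.rho[0])
        assert v == pytest.approx(-ft.rho[0], rel=1e-12)

    def test_asymmetric_hessian_rejected(self):
        H = np.diag([1.0, 2.0, 3.0])
        H[0, 1] = 0.5
        with pytest.raises(ContractError):
            signed_lambda2_density(H, 0.01)


class TestScatterTable:
    def test_empty_grid(self):
        df = scatter_table(np.empty(0), np.empty(0))
        assert len(df) == 0

    def test_widening_range_is_monotone(self, toy_h_model, h2_pair_2bohr):
        spec = molecular_grid(h2_pair_2bohr, spacing=0.4, padding=2.0)
        ft = promolecular_field(h2_pair_2bohr, toy_h_model, spec.points())
        dg = delta_g(h2_pair_2bohr, toy_h_model, spec.points(),
                     fragments=False, field=ft)["delta_g"]
        signed, _ = signed_lambda2_density(ft.hessian, ft.rho)
        n_narrow = len(scatter_table(signed, dg, (-0.01, 0.01)))
        n_default = len(scatter_table(signed, dg, (-0.05, 0.05)))
        n_wide = len(scatter_table(signed, dg, (-1.0, 1.0)))
        assert n_narrow <= n_default <= n_wide

    def test_dimer_delta_g_peaks_at_bond_midpoint_voxel(self, toy_h_model,
                                                        h2_pair_2bohr):
        spec = molecular_grid(h2_pair_2bohr, spacing=0.25, padding=2.0)
        pts = spec.points()
        dg = delta_g(h2_pair_2bohr, toy_h_model, pts,
                     fragments=False)["delta_g"]
        assert dg.min() > -1e-12
        # brute-force argmax over voxels lands at the internuclear midpoint
        best = pts[np.argmax(dg)]
        midpoint = np.array([1.0, 0.0, 0.0])
        assert np.linalg.norm(best - midpoint) <= \
            np.linalg.norm(spec.spacing) / 2 + 1e-9


class TestLocateBCP:
    def test_symmetric_pair_converges_to_midpoint(self, toy_h_model,
                                                  h2_pair_2bohr):
        res = locate_bcp(h2_pair_2bohr, toy_h_model, 1, 2)
        assert res.converged
        assert np.abs(res.position - [1.0, 0.0, 0.0]).max() < 1e-6
        assert res.grad_norm < 1e-8

    def test_asymmetric_pair_matches_grid_search_oracle(self):
        model = AtomicDensityModel({"H": [(0.2, 2.0)], "He": [(0.5, 3.0)]})
        g = make_pair(2.0, elements=("H", "He"))
        res = locate_bcp(g, model, 1, 2)
        assert res.converged
        xs = np.arange(0.05, 1.95, 1e-4)
        pts = np.zeros((len(xs), 3))
        pts[:, 0] = xs
        ft = promolecular_field(g, model, pts)
        x_oracle = xs[np.argmin(np.abs(ft.grad[:, 0]))]
        assert abs(res.position[0] - x_oracle) < 1e-3
        assert abs(res.position[1]) < 1e-9 and abs(res.position[2]) < 1e-9

    def test_saddle_signature(self, toy_h_model, h2_pair_2bohr):
        res = locate_bcp(h2_pair_2bohr, toy_h_model, 1, 2)
        lams = np.linalg.eigvalsh(res.hessian)
        assert lams[0] < 0 and lams[1] < 0 and lams[2] > 0
        assert res.signature == -1

    def test_identical_positions_rejected(self, toy_h_model):
        g = make_pair(0.0)
        with pytest.raises(ContractError):
            locate_bcp(g, toy_h_model, 1, 2)


def test_vdw_surface_nonempty_for_default_grid(default_model):
    g = toy_geometry("intramolecular_chain", 4)
    spec = molecular_grid(g, spacing=0.4, padding=4.0)
    ft = promolecular_field(g, default_model, spec.points())
    mask = vdw_surface_mask(ft.rho.reshape(spec.dims))
    assert mask.sum() > 0


def test_grid_analysis_outputs_consistent(default_model):
    g = toy_geometry("hbonded_dimer", 0)
    out = igm_grid_analysis(g, default_model, spacing=0.5, padding=2.5)
    dims = out["grid"].dims
    for key in ("rho", "rdg", "delta_g", "delta_g_intra", "delta_g_inter",
                "sign_lambda2_rho"):
        assert out[key].values.shape == dims
    dg = out["delta_g"].values
    assert np.nanmin(dg) > -1e-12
    assert (out["scatter"]["y"] >= 0).all()
    assert np.abs(out["scatter"]["sign_lambda2_rho"]).max() <= 0.05
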