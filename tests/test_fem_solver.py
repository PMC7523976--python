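"""Nonlinear FE solver: consistency, oracle agreement, robustness."""

import numpy as np
import pytest

from plaquestress import fem_solver as fs
from plaquestress.constitutive import YeohParams
from plaquestress import materials as mt
from conftest import make_annulus_mesh

NEO = YeohParams(c10=61.15, order=1)  # isotropic media initial stiffness


@pytest.fixture(scope="module")
def coarse_model():
    mesh = make_annulus_mesh(3.0, 4.0, 32, 4)
    return fs.PlaneStrainModel(mesh, {"ft": NEO}, None)


@pytest.fixture(scope="module")
def tube_oracle():
    return fs.tube_inflation_reference(3.0, [4.0], [NEO], 13.0)


def lumen_radius(mesh, sol):
    x = sol.deformed[mesh.lumen_loop]
    c = x.mean(axis=0)
    return np.linalg.norm(x - c, axis=1)


class TestAssemble:
    def test_zero_state_zero_residual(self, coarse_model):
        r, K = coarse_model.assemble(np.zeros((len(coarse_model.mesh.nodes), 2)), 0.0)
        assert np.linalg.norm(r) == 0.0
        assert K.shape == (coarse_model.ndof, coarse_model.ndof)

    def test_tangent_matches_residual_differences(self, coarse_model):
        rng = np.random.default_rng(0)
        u = 1e-3 * rng.normal(size=(len(coarse_model.mesh.nodes), 2))
        r, K = coarse_model.assemble(u, 5.0)
        for _ in range(3):
            du = rng.normal(size=coarse_model.ndof)
            du /= np.linalg.norm(du)
            h = 1e-6
            rp, _ = coarse_model.assemble(u + h * du.reshape(-1, 2), 5.0, tangent=False)
            rm, _ = coarse_model.assemble(u - h * du.reshape(-1, 2), 5.0, tangent=False)
            fd = (rp - rm) / (2 * h)
            assert np.linalg.norm(K @ du - fd) / np.linalg.norm(fd) < 1e-5

    def test_rigid_translation_leaves_internal_force_unchanged(self, coarse_model):
        rng = np.random.default_rng(1)
        u = 1e-3 * rng.normal(size=(len(coarse_model.mesh.nodes), 2))
        r0, _ = coarse_model.assemble(u, 0.0, tangent=False)
        r1, _ = coarse_model.assemble(u + np.array([0.37, -1.2]), 0.0, tangent=False)
        np.testing.assert_allclose(r0, r1, atol=1e-8)

    def test_inverted_element_reported(self, coarse_model):
        u = np.zeros((len(coarse_model.mesh.nodes), 2))
        # push one node through the opposite edge of its element
        q = coarse_model.mesh.quads[0]
        opposite_mid = coarse_model.mesh.nodes[q[1:3]].mean(axis=0)
        u[q[0]] = 1.5 * (opposite_mid - coarse_model.mesh.nodes[q[0]])
        with pytest.raises(fs.AssemblyError):
            coarse_model.assemble(u, 0.0)


class TestNewtonSolve:
    def test_zero_pressure_zero_displacement(self, coarse_model):
        sol = coarse_model.solve(fs.LoadCase(pressure=0.0))
        np.testing.assert_allclose(sol.u, 0.0)

    def test_inflation_matches_semianalytic_oracle(self, tube_oracle):
        mesh = make_annulus_mesh(3.0, 4.0, 128, 16)
        model = fs.PlaneStrainModel(mesh, {"ft": NEO}, None)
        sol = model.solve(fs.LoadCase(13.0))
        ri = lumen_radius(mesh, sol)
        ur_ref = tube_oracle["inner_radius_deformed"] - 3.0
        assert ri.mean() - 3.0 == pytest.approx(ur_ref, rel=0.005)
        assert ri.std() < 1e-9  # deformed lumen stays circular

    def test_load_step_count_does_not_change_the_answer(self, coarse_model):
        from dataclasses import replace

        s5 = coarse_model.solve(fs.LoadCase(13.0), fs.SolverSettings(n_load_steps=5))
        s2 = coarse_model.solve(fs.LoadCase(13.0), fs.SolverSettings(n_load_steps=2))
        np.testing.assert_allclose(s5.u, s2.u, atol=1e-6)

    def test_global_equilibrium(self, coarse_model):
        sol = coarse_model.solve(fs.LoadCase(13.0))
        r, _ = coarse_model.assemble(sol.u, 13.0, tangent=False)
        # the pressure load on the closed lumen is self-equilibrated, so even
        # the constrained dofs carry (essentially) zero reaction
        assert np.linalg.norm(r) / coarse_model.reference_force(13.0) < 1e-6

    def test_incompressibility_quality(self, coarse_model):
        sol = coarse_model.solve(fs.LoadCase(13.0))
        _, _, J, _, J0 = coarse_model.kinematics(sol.u)
        assert np.abs(J0 - 1).max() < 1e-3

    def test_pin_choice_insensitive(self):
        from plaquestress.stress_post import principal_max, recover_stresses

        mesh = make_annulus_mesh(3.0, 4.0, 64, 8)
        model = fs.PlaneStrainModel(mesh, {"ft": NEO}, None)
        peaks = []
        nr1 = mesh.n_radial + 1
        outer = np.arange(mesh.n_theta) * nr1 + mesh.n_radial
        for shift in (0, 5):
            pins = (int(outer[mesh.n_theta // 4 + shift]),
                    int(outer[3 * mesh.n_theta // 4 + shift]))
            sol = model.solve(fs.LoadCase(13.0, pin_nodes=pins))
            fld = recover_stresses(model, sol)
            peaks.append(principal_max(fld).max())
        assert abs(peaks[0] - peaks[1]) / peaks[0] < 1e-3

    def test_nonconvergence_carries_log(self):
        mesh = make_annulus_mesh(3.0, 4.0, 16, 2)
        model = fs.PlaneStrainModel(mesh, {"ft": YeohParams(c10=0.05, order=1)}, None)
        with pytest.raises(fs.NonConvergenceError) as err:
            # 100x the physiological pressure on near-fluid tissue
            model.solve(fs.LoadCase(1300.0), fs.SolverSettings(max_iterations=5,
                                                               n_load_steps=1))
        assert len(err.value.log) > 0


class TestTubeInflationReference:
    def test_zero_pressure(self):
        ref = fs.tube_inflation_reference(3.0, [4.0], [NEO], 0.0)
        assert ref["inner_radius_deformed"] == 3.0
        np.testing.assert_allclose(ref["sigma_r"], 0.0, atol=1e-12)
        np.testing.assert_allclose(ref["sigma_theta"], 0.0, atol=1e-12)

    def test_thin_wall_limit_recovers_membrane_formula(self):
        R, t, p = 3.0, 0.03, 2.0
        ref = fs.tube_inflation_reference(R, [R + t], [YeohParams(c10=300.0, order=1)], p)
        sig_t_mid = ref["sigma_theta"][len(ref["R"]) // 2]
        r_mid = ref["r"][len(ref["R"]) // 2]
        t_def = ref["r"][-1] - ref["r"][0]
        assert sig_t_mid == pytest.approx(p * r_mid / t_def, rel=0.02)

    def test_two_layer_radial_continuity_hoop_jump(self):
        ref = fs.tube_inflation_reference(
            3.0, [3.25, 3.5], [mt.MEDIA_ISO, mt.ADVENTITIA], 13.0, n_profile=4001
        )
        R = ref["R"]
        k = int(np.searchsorted(R, 3.25))
        # sigma_r continuous across the interface
        assert abs(ref["sigma_r"][k + 1] - ref["sigma_r"][k - 1]) < 0.1
        # sigma_theta jumps by the stiffness mismatch
        assert abs(ref["sigma_theta"][k + 1] - ref["sigma_theta"][k - 1]) > 1.0
        assert ref["sigma_r"][0] == pytest.approx(-13.0, abs=1e-6)
        assert abs(ref["sigma_r"][-1]) < 1e-6

    def test_anisotropic_layer_rejected(self):
        with pytest.raises(ValueError):
            fs.tube_inflation_reference(3.0, [4.0], [mt.MEDIA_ANISO], 13.0)


class TestFeVsOracleStress:
    def test_hoop_stress_converges_below_one_percent(self, tube_oracle):
        from plaquestress.stress_post import recover_stresses

        errs = []
        for nt, nr in [(64, 8), (128, 16)]:
            mesh = make_annulus_mesh(3.0, 4.0, nt, nr)
            model = fs.PlaneStrainModel(mesh, {"ft": NEO}, None)
            sol = model.solve(fs.LoadCase(13.0))
            fld = recover_stresses(model, sol)
            cents = mesh.centroids()
            th = np.arctan2(cents[:, 1], cents[:, 0])
            et = np.column_stack([-np.sin(th), np.cos(th), np.zeros_like(th)])
            s_t = np.einsum("mi,mij,mj->m", et, fld.sigma, et)
            s_ref = np.interp(np.linalg.norm(cents, axis=1), tube_oracle["R"],
                              tube_oracle["sigma_theta"])
            errs.append(np.abs(s_t - s_ref).max() / np.abs(s_ref).max())
        assert errs[1] < errs[0]  # second-order trend
        assert errs[1] < 0.01
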