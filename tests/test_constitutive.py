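"""Strain-energy functions, homogeneous stress responses and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

from plaquestress import constitutive as ct
from plaquestress import materials as mt


def random_incompressible_C(rng, spread=0.08):
    lam = np.exp(rng.normal(0, spread, 3))
    lam /= lam.prod() ** (1 / 3)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return Q @ np.diag(lam**2) @ Q.T


class TestInvariants:
    def test_identity(self):
        st = ct.DeformationState.from_principal(1, 1, 1)
        for phi in (0.0, 30.0, 90.0):
            assert ct.invariants(st, phi) == pytest.approx((3.0, 1.0))

    def test_biaxial_state_plain_arithmetic(self):
        lt, lz = 1.2, 1.0
        st = ct.DeformationState.from_principal(1 / 1.2, lt, lz)
        phi = 6.9
        I1, I4 = ct.invariants(st, phi)
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        assert I1 == pytest.approx((1 / 1.2) ** 2 + 1.2**2 + 1.0, rel=1e-12)
        assert I4 == pytest.approx(1.2**2 * c**2 + 1.0 * s**2, rel=1e-12)

    def test_axial_fibers_see_axial_stretch_only(self):
        st = ct.DeformationState.from_principal(0.5, 2.0, 1.0)
        _, I4 = ct.invariants(st, 90.0)
        assert I4 == pytest.approx(1.0)

    def test_nonpositive_stretch_rejected(self):
        with pytest.raises(ct.InvalidStateError):
            ct.DeformationState.from_principal(-1.0, 1.0, 1.0)


class TestStrainEnergy:
    @pytest.mark.parametrize("model", list(mt.MATERIALS.values()), ids=list(mt.MATERIALS))
    def test_zero_at_identity(self, model):
        st = ct.DeformationState.from_principal(1, 1, 1)
        assert ct.strain_energy(model, st) == 0.0

    def test_media_equibiaxial_closed_form(self):
        # independent evaluation of the printed energy at lam = 1.05
        lam = 1.05
        st = ct.DeformationState.from_principal(lam**-2, lam, lam)
        m = mt.MEDIA_ANISO
        I1 = lam**-4 + 2 * lam**2
        I4 = lam**2  # cos^2 + sin^2 at equal theta/z stretches
        q = m.k2 * ((1 - m.rho) * (I1 - 3) ** 2 + m.rho * (I4 - 1) ** 2)
        expected = m.mu / 2 * (I1 - 3) + m.k1 / (2 * m.k2) * (np.exp(q) - 1)
        assert ct.strain_energy(m, st) == pytest.approx(expected, rel=1e-12)

    def test_neohookean_lc_uniaxial(self):
        lam = 1.2
        st = ct.DeformationState.from_principal(lam**-0.5, lam**-0.5, lam)
        I1 = lam**2 + 2 / lam
        assert ct.strain_energy(mt.LIPID_CORE_HARD, st) == pytest.approx(50.0 * (I1 - 3))

    def test_media_overflow_reported(self):
        st = ct.DeformationState.from_principal(1 / 16.0, 4.0, 4.0)
        with pytest.raises(ct.RangeError):
            ct.strain_energy(mt.MEDIA_ANISO, st)

    def test_nonnegative_near_identity(self):
        rng = np.random.default_rng(7)
        st_id = ct.DeformationState.from_principal(1, 1, 1)
        for model in mt.MATERIALS.values():
            assert ct.strain_energy(model, st_id) == 0.0
            for _ in range(50):
                lam = np.exp(rng.uniform(np.log(0.8), np.log(1.3), 3))
                lam /= lam.prod() ** (1 / 3)
                st = ct.DeformationState.from_principal(*lam)
                psi = ct.strain_energy(model, st)
                if np.abs(lam - 1).max() > 1e-6:
                    assert psi > 0


class TestCauchyPrincipal:
    def test_identity_zero(self):
        st = ct.DeformationState.from_principal(1, 1, 1)
        for model in mt.MATERIALS.values():
            np.testing.assert_allclose(
                ct.cauchy_stress_principal(model, st, "r"), 0.0, atol=1e-9
            )

    def test_neohookean_uniaxial_closed_form(self):
        c10, lam = 50.0, 1.2
        model = ct.YeohParams(c10=c10, order=1)
        st = ct.DeformationState.from_principal(lam**-0.5, lam**-0.5, lam)
        sig = ct.cauchy_stress_principal(model, st, zero_stress_axis="r")
        assert sig[2] == pytest.approx(2 * c10 * (lam**2 - 1 / lam), rel=1e-12)
        assert sig[0] == pytest.approx(0.0, abs=1e-9)
        assert sig[1] == pytest.approx(0.0, abs=1e-9)

    def test_equibiaxial_symmetry_isotropic(self):
        lam = 1.1
        st = ct.DeformationState.from_principal(lam**-2, lam, lam)
        for model in (mt.FIBROUS_TISSUE_SOFT, mt.ADVENTITIA, mt.LIPID_CORE_SOFT):
            sig = ct.cauchy_stress_principal(model, st, "r")
            assert sig[1] == pytest.approx(sig[2], rel=1e-12)

    def test_compressible_state_rejected(self):
        st = ct.DeformationState.from_principal(1.0, 1.1, 1.0)
        with pytest.raises(ct.InvalidStateError):
            ct.cauchy_stress_principal(mt.FIBROUS_TISSUE_SOFT, st, "r")


class TestPk2AndTangent:
    def test_identity_stress_free(self):
        for model in mt.MATERIALS.values():
            S, _ = ct.pk2_stress_and_tangent(model, np.eye(3))
            np.testing.assert_allclose(S, 0.0, atol=1e-8)

    @pytest.mark.parametrize("name", list(mt.MATERIALS))
    def test_stress_matches_energy_gradient(self, name):
        from plaquestress._symdiff import eval3d

        model = mt.MATERIALS[name]
        rng = np.random.default_rng(3)
        K = ct.default_bulk_penalty([model])
        kind = model.kind
        params = (
            (model.mu, model.k1, model.k2, model.rho, model.phi_rad)
            if kind == "media"
            else model.constants
        )
        C = random_incompressible_C(rng)
        S, CC = ct.pk2_stress_and_tangent(model, C, bulk_penalty=K)
        for _ in range(4):
            D = rng.normal(size=(3, 3))
            D = (D + D.T) / 2
            h = 1e-6
            dpsi = (eval3d(kind, C + h * D, params, K)[0]
                    - eval3d(kind, C - h * D, params, K)[0]) / (2 * h)
            assert dpsi == pytest.approx(0.5 * np.tensordot(S, D), rel=1e-5, abs=1e-6)
            Sp, _ = ct.pk2_stress_and_tangent(model, C + h * D, bulk_penalty=K)
            Sm, _ = ct.pk2_stress_and_tangent(model, C - h * D, bulk_penalty=K)
            dS = (Sp - Sm) / (2 * h)
            ref = 0.5 * np.einsum("ijkl,kl->ij", CC, D)
            np.testing.assert_allclose(dS, ref, rtol=1e-5, atol=1e-4 * np.abs(dS).max())

    def test_yeoh_isotropy_under_permutation(self):
        model = mt.FIBROUS_TISSUE_HARD
        lam = np.array([0.9, 1.05, 1 / (0.9 * 1.05)])
        vals = []
        for perm in ([0, 1, 2], [1, 2, 0], [2, 0, 1]):
            st = ct.DeformationState.from_principal(*lam[perm])
            sig = np.sort(ct.cauchy_stress_principal(model, st, "r"))
            vals.append(sig - sig.min())  # differences are pressure-free
        np.testing.assert_allclose(vals[0], vals[1], atol=1e-9)
        np.testing.assert_allclose(vals[0], vals[2], atol=1e-9)

    def test_rho_zero_removes_fiber_dependence(self):
        m0 = ct.MediaAnisoParams(mu=122.3, k1=24.7, k2=16.5, phi_deg=0.0, rho=1e-12)
        m90 = ct.MediaAnisoParams(mu=122.3, k1=24.7, k2=16.5, phi_deg=90.0, rho=1e-12)
        st = ct.DeformationState.from_principal(1 / 1.1, 1.05, 1 / 1.05 * 1.1)
        assert ct.strain_energy(m0, st) == pytest.approx(ct.strain_energy(m90, st), rel=1e-9)

    def test_rho_weighting_exponents(self):
        # phi = 0, stretch along theta: I4 - 1 = I1 - 3 would differ; the two
        # pure weightings differ only through their exponent arguments
        lam = 1.06
        st = ct.DeformationState.from_principal(1 / lam, lam, 1.0)
        I1, I4 = ct.invariants(st, 0.0)
        for rho in (0.0, 1.0):
            m = ct.MediaAnisoParams(mu=122.3, k1=24.7, k2=16.5, phi_deg=0.0,
                                    rho=max(rho, 1e-14))
            q = 16.5 * ((1 - rho) * (I1 - 3) ** 2 + rho * (I4 - 1) ** 2)
            expect = 122.3 / 2 * (I1 - 3) + 24.7 / (2 * 16.5) * (np.exp(q) - 1)
            assert ct.strain_energy(m, st) == pytest.approx(expect, rel=1e-6)

    def test_non_spd_rejected(self):
        C = np.diag([1.0, -0.5, 1.0])
        with pytest.raises(ct.InvalidStateError):
            ct.pk2_stress_and_tangent(mt.FIBROUS_TISSUE_SOFT, C)


class TestEnergyProperties:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        lt=st_.floats(0.85, 1.25),
        lz=st_.floats(0.85, 1.25),
        phi=st_.floats(0.0, 90.0),
    )
    def test_invariant_definitions_hold_for_any_incompressible_state(self, lt, lz, phi):
        lr = 1.0 / (lt * lz)
        state = ct.DeformationState.from_principal(lr, lt, lz)
        I1, I4 = ct.invariants(state, phi)
        c2 = np.cos(np.deg2rad(phi)) ** 2
        assert I1 == pytest.approx(lr**2 + lt**2 + lz**2, rel=1e-12)
        assert I4 == pytest.approx(lt**2 * c2 + lz**2 * (1 - c2), rel=1e-12)
        assert I1 >= 3.0 - 1e-12  # AM-GM at unit volume

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        lt=st_.floats(0.85, 1.25),
        lz=st_.floats(0.85, 1.25),
        rho=st_.floats(0.0, 1.0),
    )
    def test_media_energy_nonnegative_and_fiber_free_at_rho_zero(self, lt, lz, rho):
        lr = 1.0 / (lt * lz)
        state = ct.DeformationState.from_principal(lr, lt, lz)
        model = ct.MediaAnisoParams(mu=122.3, k1=24.7, k2=16.5, phi_deg=30.0,
                                    rho=max(rho, 1e-14))
        assert ct.strain_energy(model, state) >= 0.0
        if rho < 1e-12:
            m90 = ct.MediaAnisoParams(mu=122.3, k1=24.7, k2=16.5, phi_deg=90.0,
                                      rho=1e-14)
            assert ct.strain_energy(model, state) == pytest.approx(
                ct.strain_energy(m90, state), rel=1e-9)


class TestFitInitialStiffness:
    def test_exact_recovery(self):
        lam = np.linspace(1.02, 1.3, 20)
        sigma = ct.yeoh_uniaxial_stress(lam, 2.7, 20.0)
        fit = ct.fit_initial_stiffness(np.column_stack([lam, sigma]), fixed_c20=20.0)
        assert fit.c10 == pytest.approx(2.7, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(42)
        lam = np.linspace(1.02, 1.3, 30)
        sigma = ct.yeoh_uniaxial_stress(lam, 2.7, 20.0) * (1 + 0.01 * rng.normal(size=30))
        fit = ct.fit_initial_stiffness(np.column_stack([lam, sigma]), fixed_c20=20.0)
        assert fit.c10 == pytest.approx(2.7, rel=0.02)
        assert fit.r_squared > 0.8

    def test_degenerate_data_rejected(self):
        lam = np.linspace(1.05, 1.2, 5)
        with pytest.raises(ct.FitError):
            ct.fit_initial_stiffness(np.column_stack([lam, np.zeros(5)]))

    def test_reads_delimited_text(self, tmp_path):
        lam = np.linspace(1.02, 1.25, 12)
        sigma = ct.yeoh_uniaxial_stress(lam, 10.0, 20.0)
        p = tmp_path / "uniaxial.csv"
        p.write_text("stretch,stress_kpa\n" + "\n".join(
            f"{l:.6f},{s:.6f}" for l, s in zip(lam, sigma)))
        data = ct.read_stress_stretch(p)
        fit = ct.fit_initial_stiffness(data)
        assert fit.c10 == pytest.approx(10.0, rel=1e-4)
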