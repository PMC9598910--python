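"""Kinematics, strain energy and analytic stress of the four-fiber model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutmech import (
    MaterialParams,
    cauchy_stress,
    kinematics_from_F,
    make_fiber_set,
    membrane_true_stress,
    psi_prime,
    strain_energy,
    stretch_from_green_lagrange,
)
from gutmech import mechanics as mech

from conftest import fd_cauchy_stress, random_deformations


class TestFiberSet:
    def test_reference_arrangement_at_30_degrees(self):
        fs = make_fiber_set(30.0)
        assert np.allclose(fs.a01, [1, 0, 0])
        assert np.allclose(fs.a02, [0, 1, 0])
        assert np.allclose(fs.a03, [math.sqrt(3) / 2, 0.5, 0])
        assert np.allclose(fs.a04, [math.sqrt(3) / 2, -0.5, 0])
        assert fs.a01 @ fs.a02 == 0.0

    def test_zero_angle_collapses_onto_longitudinal_axis(self):
        fs = make_fiber_set(0.0)
        assert np.allclose(fs.a03, fs.a01)
        assert np.allclose(fs.a04, fs.a01)

    @given(st.floats(0.0, 89.99))
    @settings(max_examples=25, deadline=None)
    def test_unit_norm_and_reflection_for_any_angle(self, alpha):
        fs = make_fiber_set(alpha)
        for a in fs:
            assert math.isclose(np.linalg.norm(a), 1.0, rel_tol=1e-12)
        # a03 and a04 are reflections across e1; all in the e1-e2 plane
        assert np.allclose(fs.a03 * [1, -1, 1], fs.a04)
        assert all(a[2] == 0 for a in fs)

    @pytest.mark.parametrize("alpha", [-1.0, 90.0, 120.0])
    def test_rejects_out_of_range_angle(self, alpha):
        with pytest.raises(ValueError):
            make_fiber_set(alpha)


class TestKinematics:
    def test_identity(self, fibers):
        d = kinematics_from_F(np.eye(3), fibers)
        assert d.J == pytest.approx(1.0)
        assert d.I1_bar == pytest.approx(3.0)
        assert all(v == pytest.approx(1.0) for v in d.I4_bar.values())

    @pytest.mark.parametrize("lam", [0.5, 1.0, 1.7])
    def test_pure_dilatation_is_isochorically_neutral(self, fibers, lam):
        d = kinematics_from_F(lam * np.eye(3), fibers)
        assert d.I1_bar == pytest.approx(3.0)
        assert all(v == pytest.approx(1.0) for v in d.I4_bar.values())
        assert np.linalg.det(d.C_bar) == pytest.approx(1.0)

    def test_equibiaxial_invariants(self, fibers):
        F = np.diag([1.2, 1.2, 1.0 / 1.44])
        d = kinematics_from_F(F, fibers)
        assert d.J == pytest.approx(1.0)
        assert d.I4_bar["a01"] == pytest.approx(1.44)
        # cos^2(30) * 1.44 + sin^2(30) * 1.44
        assert d.I4_bar["a03"] == pytest.approx(1.44)

    def test_invariants_match_quadratic_form(self, fibers):
        rng = np.random.default_rng(7)
        for F in random_deformations(10, rng):
            d = kinematics_from_F(F, fibers)
            for name, a in fibers.as_dict().items():
                assert d.I4_bar[name] == pytest.approx(a @ d.C_bar @ a)

    def test_rejects_reflecting_gradient(self, fibers):
        with pytest.raises(ValueError):
            kinematics_from_F(np.diag([-1.0, 1.0, 1.0]), fibers)


class TestPsiPrime:
    def test_vanishes_at_unit_invariant(self):
        assert psi_prime(1.0, 0.003, 10.0) == 0.0

    def test_tension_only_switch(self):
        assert psi_prime(0.9, 0.003, 10.0) == 0.0

    def test_s1_muscular_value(self):
        # k1 (I4-1) exp(k2 (I4-1)^2) at I4 = 1.2 with S1 muscular constants
        got = psi_prime(1.2, 0.0030, 10.6781)
        assert got == pytest.approx(9.197e-4, rel=1e-3)


class TestStrainEnergy:
    def test_reference_state_stores_no_isochoric_energy(self, fibers, s1):
        d = kinematics_from_F(np.eye(3), fibers)
        e = strain_energy(d, s1.material)
        assert e.psi_iso == 0.0
        assert e.psi_sm == 0.0
        assert all(v == 0.0 for v in e.psi_mus.values())

    def test_full_damage_leaves_matrix_only(self, fibers, s1_penalty_material):
        F = np.diag([1.3, 1.1, 0.8])
        d = kinematics_from_F(F, fibers)
        e = strain_energy(d, s1_penalty_material, {"lm": 1, "cm": 1, "sm": 1})
        assert e.total == pytest.approx(e.psi_vol + e.psi_iso)

    def test_matches_independent_term_by_term_evaluation(self, fibers, s1):
        # Re-derive every term with plain scalar arithmetic, no shared code.
        m = s1.material
        lam, lamz = 1.2, 1.0 / 1.44
        d = kinematics_from_F(np.diag([lam, lam, lamz]), fibers)
        i1 = 2 * lam**2 + lamz**2
        psi_iso = m.mu0 / 2 * (i1 - 3)
        x = lam**2 - 1  # all four families see I4 = lam^2 here
        psi_mus_one = m.k1_mus / (2 * m.k2_mus) * (math.exp(m.k2_mus * x**2) - 1)
        psi_sm_one = m.k1_sm / (2 * m.k2_sm) * (math.exp(m.k2_sm * x**2) - 1)
        expected = psi_iso + 2 * psi_mus_one + 2 * psi_sm_one
        e = strain_energy(d, m)
        assert e.total == pytest.approx(expected, rel=1e-12)
        assert e.psi_vol == 0.0  # incompressible mode

    def test_rejects_damage_outside_unit_interval(self, fibers, s1):
        d = kinematics_from_F(np.eye(3), fibers)
        with pytest.raises(ValueError):
            strain_energy(d, s1.material, {"lm": 1.2, "cm": 0, "sm": 0})


class TestCauchyStress:
    def test_stress_free_reference(self, fibers, s1_penalty_material):
        d = kinematics_from_F(np.eye(3), fibers)
        s = cauchy_stress(d, s1_penalty_material)
        assert np.allclose(s.sigma, 0.0, atol=1e-15)

    def test_full_damage_kills_fiber_contributions(self, fibers, s1_penalty_material):
        d = kinematics_from_F(np.diag([1.4, 1.2, 0.7]), fibers)
        s = cauchy_stress(d, s1_penalty_material, {"lm": 1, "cm": 1, "sm": 1})
        # the 1e-12 floor on (1 - D) leaves only a vanishing remnant
        for key in ("mus_a01", "mus_a02", "sm"):
            assert np.abs(s.components[key]).max() < 1e-10

    def test_components_sum_to_total(self, fibers, s1_penalty_material):
        rng = np.random.default_rng(11)
        for F in random_deformations(10, rng):
            s = cauchy_stress(
                kinematics_from_F(F, fibers), s1_penalty_material,
                {"lm": 0.3, "cm": 0.1, "sm": 0.5},
            )
            total = sum(s.components.values())
            assert np.allclose(s.sigma, total, rtol=0, atol=1e-15)

    def test_matches_finite_difference_of_energy(self, fibers, s1_penalty_material):
        rng = np.random.default_rng(3)
        dam = {"lm": 0.2, "cm": 0.0, "sm": 0.4}
        for F in random_deformations(20, rng):
            sig = cauchy_stress(
                kinematics_from_F(F, fibers), s1_penalty_material, dam
            ).sigma
            sig_fd = fd_cauchy_stress(F, s1_penalty_material, fibers, dam)
            scale = max(np.abs(sig).max(), 1e-8)
            assert np.abs(sig - sig_fd).max() / scale < 1e-6

    def test_compressed_fibers_carry_no_stress(self, fibers, s1_penalty_material):
        # isochoric in-plane compression: every fiber family shortens
        F = np.diag([0.8, 0.95, 1.0 / (0.8 * 0.95)])
        d = kinematics_from_F(F, fibers)
        assert all(v < 1.0 for v in d.I4_bar.values())
        s = cauchy_stress(d, s1_penalty_material)
        for key in ("mus_a01", "mus_a02", "sm"):
            assert np.abs(s.components[key]).max() == 0.0

    def test_45_degree_symmetry_swaps_directions(self, s1):
        fs = make_fiber_set(45.0)
        m = s1.material
        mat = MaterialParams(mu0=m.mu0, k1_mus=m.k1_mus, k2_mus=m.k2_mus,
                             k1_sm=m.k1_sm, k2_sm=m.k2_sm, kappa0=1.0)
        lamL, lamC = 1.25, 1.1
        lamz = 1.0 / (lamL * lamC)
        s_ab = cauchy_stress(
            kinematics_from_F(np.diag([lamL, lamC, lamz]), fs), mat
        ).sigma
        s_ba = cauchy_stress(
            kinematics_from_F(np.diag([lamC, lamL, lamz]), fs), mat
        ).sigma
        assert s_ab[0, 0] == pytest.approx(s_ba[1, 1], rel=1e-12)
        assert s_ab[1, 1] == pytest.approx(s_ba[0, 0], rel=1e-12)

    def test_incompressible_mode_requires_pressure(self, fibers, s1):
        d = kinematics_from_F(np.eye(3), fibers)
        with pytest.raises(ValueError):
            cauchy_stress(d, s1.material)


class TestConversions:
    @pytest.mark.parametrize(
        "E, lam", [(0.0, 1.0), (1.5, 2.0), (0.405, 1.3454)]
    )
    def test_stretch_from_green_lagrange(self, E, lam):
        assert stretch_from_green_lagrange(E) == pytest.approx(lam, abs=1e-4)

    def test_green_lagrange_domain_error(self):
        with pytest.raises(ValueError):
            stretch_from_green_lagrange(-0.6)

    def test_membrane_stress_values(self):
        assert membrane_true_stress(0.0, 1.3, 40.0, 1.188) == 0.0
        assert membrane_true_stress(10.0, 1.3, 40.0, 1.188) == pytest.approx(
            0.2736, abs=2e-4
        )
        # engineering-stress limit at lambda = 1
        assert membrane_true_stress(5.0, 1.0, 40.0, 1.188) == pytest.approx(
            5.0 / (40.0 * 1.188)
        )

    def test_membrane_stress_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            membrane_true_stress(1.0, 1.1, 0.0, 1.0)
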