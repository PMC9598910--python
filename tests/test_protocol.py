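"""Plane-stress biaxial paths and the single-brick simulation."""

import numpy as np
import pytest

from gutmech import (
    MaterialParams,
    cauchy_stress,
    equibiaxial_stress,
    kinematics_from_F,
    run_path,
    simulate_brick,
)
from gutmech.protocol import PLANE_STRESS_TOL, LoadPath, path_response


def _matrix_only(mu0=1e-4):
    # vanishing fiber stiffness: k1 must stay positive, so use a negligible one
    return MaterialParams(mu0=mu0, k1_mus=1e-30, k2_mus=0.0,
                          k1_sm=1e-30, k2_sm=0.0)


class TestEquibiaxialStress:
    def test_reference_state_is_stress_free(self, s1):
        assert equibiaxial_stress(1.0, 1.0, s1.material) == (0.0, 0.0)

    def test_matrix_only_reduces_to_neo_hookean_plane_stress(self):
        lam = 1.2
        lamz2 = 1.0 / lam**4
        sLL, sCC = equibiaxial_stress(lam, lam, _matrix_only())
        expected = 1e-4 * (lam**2 - lamz2)  # approx 9.58e-5 MPa
        assert sLL == pytest.approx(expected, rel=1e-12)
        assert sCC == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(9.58e-5, rel=1e-3)

    def test_closed_form_matches_tensor_engine(self, s1, fibers):
        """The vectorized in-plane formula must agree component-wise with
        the general tensor evaluation once the plane-stress pressure is
        eliminated."""
        lam = 1.25
        F = np.diag([lam, lam, 1.0 / lam**2])
        defm = kinematics_from_F(F, fibers)
        # pressure from sigma_zz = 0 with the deviatoric parts at p = 0
        dev = cauchy_stress(defm, s1.material, pressure=0.0)
        p = -dev.sigma[2, 2]
        full = cauchy_stress(defm, s1.material, pressure=p).sigma
        sLL, sCC = equibiaxial_stress(lam, lam, s1.material)
        assert sLL == pytest.approx(full[0, 0], rel=1e-12)
        assert sCC == pytest.approx(full[1, 1], rel=1e-12)
        assert full[2, 2] == pytest.approx(0.0, abs=1e-15)


class TestRunPath:
    def test_below_thresholds_matches_undamaged_model(self, s1):
        path = LoadPath.equibiaxial_ramp(1.05, 40)
        curve_d, traj = run_path(path, s1.material, s1.damage)
        curve_0, _ = run_path(path, s1.material, None)
        assert all(np.all(traj.D[k] == 0) for k in traj.D)
        assert np.allclose(curve_d.sigma_LL, curve_0.sigma_LL)
        assert np.allclose(curve_d.sigma_CC, curve_0.sigma_CC)

    def test_slope_drops_when_longitudinal_layer_fails(self, s1):
        path = LoadPath.equibiaxial_ramp(1.32, 640)
        curve, traj = run_path(path, s1.material, s1.damage)
        onset = int(np.nonzero(traj.D["lm"] > 0)[0][0])
        slope = np.gradient(curve.sigma_LL, curve.lambda_L)
        # slope rises up to the lm threshold, then drops sharply
        assert slope[onset + 2] < slope[onset - 2]
        assert traj.tau["lm"][onset] > s1.damage.lm.tau0

    def test_unloading_branch_lies_below_loading_branch(self, s1):
        up = np.linspace(1.0, 1.3, 150)
        lam = np.concatenate([up, up[::-1][1:]])
        sLL, _, traj = path_response(lam, lam, s1.material, s1.damage)
        n = len(up)
        d_end = {k: traj.D[k][-1] for k in traj.D}
        # damage froze at the turning point
        assert all(traj.D[k][n - 1] == d_end[k] for k in traj.D)
        for i in range(1, n - 1):
            j = 2 * n - 2 - i  # same stretch on the way down
            if traj.D["lm"][j] > traj.D["lm"][i]:
                assert sLL[j] < sLL[i]

    def test_unloading_stress_is_reduction_scaled_elastic_stress(self, s1):
        up = np.linspace(1.0, 1.3, 150)
        lam = np.concatenate([up, up[::-1][1:]])
        sLL, sCC, traj = path_response(lam, lam, s1.material, s1.damage)
        from gutmech.protocol import biaxial_stress_arrays

        D_frozen = {k: traj.D[k][-1] for k in traj.D}
        n = len(up)
        ref_LL, ref_CC = biaxial_stress_arrays(
            lam[n:], lam[n:], s1.material, D=D_frozen
        )
        assert np.allclose(sLL[n:], ref_LL, rtol=1e-12)
        assert np.allclose(sCC[n:], ref_CC, rtol=1e-12)

    def test_step_refinement_leaves_final_stress_unchanged(self, s1):
        coarse, _ = run_path(
            LoadPath.equibiaxial_ramp(1.3, 100), s1.material, s1.damage
        )
        fine, _ = run_path(
            LoadPath.equibiaxial_ramp(1.3, 200), s1.material, s1.damage
        )
        assert fine.sigma_LL[-1] == pytest.approx(
            coarse.sigma_LL[-1], rel=1e-3
        )

    def test_45_degree_symmetric_material_gives_equal_stresses(self, s1):
        # symmetry needs equal per-direction damage parameters too
        from gutmech.damage import DamageParams

        sym_damage = DamageParams(lm=s1.damage.lm, cm=s1.damage.lm,
                                  sm=s1.damage.sm)
        path = LoadPath.equibiaxial_ramp(1.3, 100)
        curve, _ = run_path(path, s1.material, sym_damage, alpha_deg=45.0)
        assert np.allclose(curve.sigma_LL, curve.sigma_CC, rtol=1e-12)

    def test_path_must_start_at_unit_stretch(self):
        with pytest.raises(ValueError):
            LoadPath(lambda_L=[1.1, 1.2], lambda_C=[1.0, 1.1])


class TestBrick:
    def test_zero_displacement(self, s1):
        r = simulate_brick(0.0, 0.0, s1.material, s1.damage, steps=3)
        assert np.allclose(r.DZ, 0.0)
        assert np.allclose(r.sigma_xx, 0.0, atol=1e-12)

    def test_incompressible_thickness_contraction(self, s1):
        r = simulate_brick(0.31, 0.38, s1.material, s1.damage,
                           mode="incompressible", steps=50)
        assert r.DZ[-1] == pytest.approx(1.0 / (1.31 * 1.38) - 1.0, abs=1e-12)
        assert np.allclose(r.J, 1.0)

    def test_penalty_converges_monotonically_to_incompressible(self, s1):
        dz_inc = 1.0 / (1.31 * 1.38) - 1.0
        gaps = []
        for kappa0 in (10.0, 1e2, 1e3, 1e4):
            r = simulate_brick(0.31, 0.38, s1.material, s1.damage,
                               kappa0=kappa0, steps=20, mode="penalty")
            assert np.abs(r.sigma_zz).max() < PLANE_STRESS_TOL
            assert np.all(r.J >= 1.0 - 1e-12)  # in-plane tension dilates
            gaps.append(r.DZ[-1] - dz_inc)
    # the penalty solution approaches from above and the gap shrinks ~1/kappa0
        assert all(g > 0 for g in gaps)
        assert all(b < a for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-4

    def test_plane_stress_residual_everywhere(self, s1):
        r = simulate_brick(0.31, 0.38, s1.material, s1.damage,
                           kappa0=68.0, steps=30, mode="penalty")
        assert np.abs(r.sigma_zz).max() < PLANE_STRESS_TOL

    def test_damage_history_carries_across_increments(self, s1):
        r = simulate_brick(0.45, 0.45, s1.material, s1.damage,
                           kappa0=68.0, steps=60, mode="penalty")
        for k, d in r.D.items():
            assert np.all(np.diff(d) >= -1e-15), k
        assert r.D["cm"][-1] > 0  # cm threshold is crossed on this ramp

    def test_rejects_negative_displacement(self, s1):
        with pytest.raises(ValueError):
            simulate_brick(-0.1, 0.2, s1.material)
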