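import numpy as np
import pytest

from gutmech import MaterialParams, make_fiber_set
from gutmech import mechanics as mech
from gutmech.params import REFERENCE_SPECIMENS


@pytest.fixture
def s1():
    """Reference parameter set of specimen S1."""
    return REFERENCE_SPECIMENS["S1"]


@pytest.fixture
def fibers():
    return make_fiber_set(30.0)


@pytest.fixture
def s1_penalty_material(s1):
    """S1 hyperelastic constants with a finite bulk modulus for FD checks."""
    m = s1.material
    return MaterialParams(
        mu0=m.mu0, k1_mus=m.k1_mus, k2_mus=m.k2_mus,
        k1_sm=m.k1_sm, k2_sm=m.k2_sm, kappa0=0.5,
    )


def fd_cauchy_stress(F, mat, fibers, damage=None, h=1e-6):
    """Finite-difference oracle: sigma = (1/J) (d psi / dF) F^T.

    Central differences on the total strain energy (penalty mode), pushed
    forward to the current configuration.  Independent of the analytic
    stress assembly it is used to check.
    """
    F = np.asarray(F, dtype=float)

    def psi(Fx):
        d = mech.kinematics_from_F(Fx, fibers)
        return mech.strain_energy(d, mat, damage).total

    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp = F.copy()
            Fp[i, j] += h
            Fm = F.copy()
            Fm[i, j] -= h
            P[i, j] = (psi(Fp) - psi(Fm)) / (2.0 * h)
    sig = P @ F.T / np.linalg.det(F)
    return 0.5 * (sig + sig.T)


def random_deformations(n, rng, include_shear=True):
    """Random deformation gradients with principal stretches in [0.85, 1.6]."""
    out = []
    while len(out) < n:
        F = np.diag(rng.uniform(0.85, 1.6, size=3))
        if include_shear and len(out) % 2:
            F = F + rng.uniform(-0.05, 0.05, size=(3, 3))
        if np.linalg.det(F) > 0.1:
            out.append(F)
    return out
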