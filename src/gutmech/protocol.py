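"""Plane-stress biaxial loading paths and the single-brick simulation.

Equibiaxial (and general biaxial) stretching of a thin membrane specimen
is treated as a homogeneous deformation ``F = diag(lamL, lamC, lamz)``
under plane stress (``sigma_zz = 0``).  In incompressible mode the
thickness stretch is ``lamz = 1/(lamL lamC)`` and the plane-stress
condition fixes the indeterminate hydrostatic pressure; in penalty mode
``p = kappa0 (J - 1)`` and plane stress is enforced by root-finding on
``lamz``.  Shear components are ignored on this path (the measured shear
strains are orders of magnitude below the normal strains); the full
tensor engine in :mod:`gutmech.mechanics` remains available for general
deformations.

Damage history is advanced frame by frame before each stress evaluation,
so monotone ramps produce J-shaped curves with post-threshold softening
and unloading branches scale by the frozen ``1 - D`` factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import damage as dmg
from . import mechanics as mech
from .damage import DamageParams, DamageState
from .mechanics import BiaxialCurve, MaterialParams

__all__ = [
    "LoadPath",
    "DamageTrajectory",
    "BrickResult",
    "equibiaxial_stress",
    "biaxial_stress_arrays",
    "path_response",
    "run_path",
    "simulate_brick",
]

#: (1 - D) floor mirrored from the tensor engine.
_D_TOL = 1e-12


@dataclass(frozen=True)
class LoadPath:
    """An ordered sequence of in-plane stretch pairs, starting at (1, 1)."""

    lambda_L: np.ndarray
    lambda_C: np.ndarray
    mode: Literal["incompressible", "penalty"] = "incompressible"

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambda_L", np.asarray(self.lambda_L, dtype=float))
        object.__setattr__(self, "lambda_C", np.asarray(self.lambda_C, dtype=float))
        if len(self.lambda_L) != len(self.lambda_C):
            raise ValueError("stretch sequences must share length")
        if len(self.lambda_L) == 0:
            raise ValueError("empty load path")
        if np.any(self.lambda_L <= 0) or np.any(self.lambda_C <= 0):
            raise ValueError("stretches must be positive")
        if abs(self.lambda_L[0] - 1) > 1e-9 or abs(self.lambda_C[0] - 1) > 1e-9:
            raise ValueError("load path must start at (1, 1)")

    @property
    def steps(self) -> int:
        return len(self.lambda_L)

    @classmethod
    def equibiaxial_ramp(cls, lambda_max: float, steps: int) -> "LoadPath":
        lam = np.linspace(1.0, lambda_max, steps)
        return cls(lambda_L=lam, lambda_C=lam.copy())

    @classmethod
    def ramp(cls, lambda_L_max: float, lambda_C_max: float, steps: int) -> "LoadPath":
        return cls(
            lambda_L=np.linspace(1.0, lambda_L_max, steps),
            lambda_C=np.linspace(1.0, lambda_C_max, steps),
        )


@dataclass
class DamageTrajectory:
    """Per-frame equivalent strains and damage scalars along a path."""

    lambda_L: np.ndarray
    lambda_C: np.ndarray
    tau: dict[str, np.ndarray]
    D: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        cols = {"lambda_L": self.lambda_L, "lambda_C": self.lambda_C}
        for k in mech.LAYERS:
            cols[f"tau_{k}"] = self.tau[k]
        for k in mech.LAYERS:
            cols[f"D_{k}"] = self.D[k]
        return pd.DataFrame(cols)

    def final_state(self) -> DamageState:
        return DamageState(
            tau_max={k: float(np.max(self.tau[k])) for k in mech.LAYERS},
            D={k: float(self.D[k][-1]) for k in mech.LAYERS},
        )


def _layer_invariants(lamL, lamC, alpha_deg: float):
    """Modified fourth invariants on the incompressible diagonal path."""
    lamL = np.asarray(lamL, dtype=float)
    lamC = np.asarray(lamC, dtype=float)
    a = np.deg2rad(alpha_deg)
    c2, s2 = np.cos(a) ** 2, np.sin(a) ** 2
    I4_a01 = lamL**2
    I4_a02 = lamC**2
    I4_sm = c2 * lamL**2 + s2 * lamC**2  # same for both +/- alpha fibers
    return I4_a01, I4_a02, I4_sm


def _layer_energies(lamL, lamC, mat: MaterialParams, alpha_deg: float):
    """Undamaged per-layer energies (lm, cm, sm) on the diagonal path."""
    I4_1, I4_2, I4_sm = _layer_invariants(lamL, lamC, alpha_deg)
    return {
        "lm": mech.fiber_energy(I4_1, mat.k1_mus, mat.k2_mus),
        "cm": mech.fiber_energy(I4_2, mat.k1_mus, mat.k2_mus),
        "sm": 2.0 * mech.fiber_energy(I4_sm, mat.k1_sm, mat.k2_sm),
    }


def biaxial_stress_arrays(
    lamL,
    lamC,
    mat: MaterialParams,
    D: Mapping[str, object] | None = None,
    alpha_deg: float = 30.0,
):
    """In-plane true stresses for incompressible plane-stress biaxial stretch.

    Closed form obtained by eliminating the pressure through
    ``sigma_zz = 0`` with ``lamz = 1/(lamL lamC)``::

        sigma_LL = mu0 (lamL^2 - lamz^2)
                   + 2 (1-D_lm) psi'(lamL^2) lamL^2
                   + 4 (1-D_sm) psi'(I4_sm) cos^2(alpha) lamL^2

    and symmetrically for ``sigma_CC`` (circumferential muscular fiber,
    ``sin^2`` submucosal weight).  Vectorized over the path; ``D`` maps
    layers to scalars or per-frame arrays.
    """
    lamL = np.asarray(lamL, dtype=float)
    lamC = np.asarray(lamC, dtype=float)
    lamz2 = 1.0 / (lamL * lamC) ** 2
    a = np.deg2rad(alpha_deg)
    c2, s2 = np.cos(a) ** 2, np.sin(a) ** 2
    I4_1, I4_2, I4_sm = _layer_invariants(lamL, lamC, alpha_deg)
    if D is None:
        red = {k: 1.0 for k in mech.LAYERS}
    else:
        red = {k: np.maximum(1.0 - np.asarray(D[k], dtype=float), _D_TOL)
               for k in mech.LAYERS}
    dpsi_sm = mech.psi_prime(I4_sm, mat.k1_sm, mat.k2_sm)
    sig_LL = (
        mat.mu0 * (lamL**2 - lamz2)
        + 2.0 * red["lm"] * mech.psi_prime(I4_1, mat.k1_mus, mat.k2_mus) * lamL**2
        + 4.0 * red["sm"] * dpsi_sm * c2 * lamL**2
    )
    sig_CC = (
        mat.mu0 * (lamC**2 - lamz2)
        + 2.0 * red["cm"] * mech.psi_prime(I4_2, mat.k1_mus, mat.k2_mus) * lamC**2
        + 4.0 * red["sm"] * dpsi_sm * s2 * lamC**2
    )
    return sig_LL, sig_CC


def equibiaxial_stress(
    lambda_L: float,
    lambda_C: float,
    mat: MaterialParams,
    state: DamageState | None = None,
    alpha_deg: float = 30.0,
) -> tuple[float, float]:
    """In-plane true stresses at one biaxial stretch state.

    Applies the *current* damage factors of ``state`` (no history
    update); pristine material when ``state`` is None.
    """
    D = state.D if state is not None else None
    sLL, sCC = biaxial_stress_arrays(
        np.atleast_1d(lambda_L), np.atleast_1d(lambda_C), mat, D=D,
        alpha_deg=alpha_deg,
    )
    return float(sLL[0]), float(sCC[0])


def path_response(
    lamL,
    lamC,
    mat: MaterialParams,
    damage_params: DamageParams | None = None,
    alpha_deg: float = 30.0,
):
    """Stress and damage history along a sampled incompressible path.

    Damage at each frame is the closed-form state function of the running
    maximum of the equivalent strain up to that frame, evaluated before
    the stress; works for monotone and non-monotone paths alike.

    Returns ``(sigma_LL, sigma_CC, trajectory)``.
    """
    lamL = np.asarray(lamL, dtype=float)
    lamC = np.asarray(lamC, dtype=float)
    energies = _layer_energies(lamL, lamC, mat, alpha_deg)
    if damage_params is None:
        zeros = np.zeros_like(lamL)
        tau = {k: dmg.equivalent_strain(energies[k]) for k in mech.LAYERS}
        D = {k: zeros.copy() for k in mech.LAYERS}
    else:
        tau, D = dmg.path_damage(energies, damage_params)
    sig_LL, sig_CC = biaxial_stress_arrays(lamL, lamC, mat, D=D, alpha_deg=alpha_deg)
    traj = DamageTrajectory(lambda_L=lamL, lambda_C=lamC, tau=tau, D=D)
    return sig_LL, sig_CC, traj


def run_path(
    path: LoadPath,
    mat: MaterialParams,
    damage_params: DamageParams | None = None,
    alpha_deg: float = 30.0,
) -> tuple[BiaxialCurve, DamageTrajectory]:
    """Drive the constitutive model through a load path.

    Returns the resulting stress–stretch curve plus the per-layer damage
    trajectory.  Below every threshold the output coincides with the
    zero-damage forward model.
    """
    sig_LL, sig_CC, traj = path_response(
        path.lambda_L, path.lambda_C, mat, damage_params, alpha_deg
    )
    curve = BiaxialCurve(
        lambda_L=path.lambda_L, lambda_C=path.lambda_C,
        sigma_LL=sig_LL, sigma_CC=sig_CC,
    )
    return curve, traj


@dataclass
class BrickResult:
    """Displacement-controlled biaxial response of a 1 mm unit cube."""

    DX: np.ndarray
    DY: np.ndarray
    DZ: np.ndarray
    J: np.ndarray
    sigma_xx: np.ndarray
    sigma_yy: np.ndarray
    sigma_zz: np.ndarray
    D: dict[str, np.ndarray]
    mode: str
    kappa0: float | None

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "DX_mm": self.DX, "DY_mm": self.DY, "DZ_mm": self.DZ, "J": self.J,
            "sigma_xx_MPa": self.sigma_xx, "sigma_yy_MPa": self.sigma_yy,
            "sigma_zz_MPa": self.sigma_zz,
        }
        for k in mech.LAYERS:
            cols[f"D_{k}"] = self.D[k]
        return pd.DataFrame(cols)


#: Largest acceptable plane-stress residual |sigma_zz| at a converged step.
PLANE_STRESS_TOL = 1e-9


def _sigma_zz_penalty(
    lamz: float,
    lamx: float,
    lamy: float,
    mat: MaterialParams,
    fibers: mech.FiberSet,
    damage_params: DamageParams | None,
    state: DamageState,
    kappa0: float,
) -> tuple[float, DamageState]:
    """Normal stress and trial damage state at a candidate thickness stretch."""
    F = np.diag([lamx, lamy, lamz])
    defm = mech.kinematics_from_F(F, fibers)
    trial = state
    if damage_params is not None:
        energies = mech.strain_energy(defm, mat).layer_energies()
        trial = dmg.update_state(state, energies, damage_params)
    pen = MaterialParams(
        mu0=mat.mu0, k1_mus=mat.k1_mus, k2_mus=mat.k2_mus,
        k1_sm=mat.k1_sm, k2_sm=mat.k2_sm, kappa0=kappa0,
    )
    stress = mech.cauchy_stress(defm, pen, damage=trial.D)
    return float(stress.sigma[2, 2]), trial


def simulate_brick(
    DX: float,
    DY: float,
    mat: MaterialParams,
    damage_params: DamageParams | None = None,
    kappa0: float | None = None,
    steps: int = 100,
    mode: Literal["incompressible", "penalty"] = "penalty",
    alpha_deg: float = 30.0,
) -> BrickResult:
    """Proportional biaxial displacement ramp on a 1 mm unit cube.

    ``DX``/``DY`` are the final in-plane edge displacements in mm (edge
    length 1 mm, so stretches are ``1 + DX`` and ``1 + DY``).  At each
    increment the thickness displacement ``DZ`` follows from plane
    stress: exactly ``lamz = 1/(lamx lamy)`` in incompressible mode, or
    by bracketing root-finding on ``sigma_zz(lamz) = 0`` with
    ``p = kappa0 (J - 1)`` in penalty mode.  Damage history is carried
    across increments.
    """
    if DX < 0 or DY < 0:
        raise ValueError("displacements must be non-negative")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    fibers = mech.make_fiber_set(alpha_deg)
    if mode == "penalty" and kappa0 is None:
        kappa0 = mat.kappa0 if mat.kappa0 is not None else mat.default_kappa0()

    u = np.linspace(0.0, 1.0, steps + 1)
    lamx_path = 1.0 + u * DX
    lamy_path = 1.0 + u * DY

    if mode == "incompressible":
        lamz_path = 1.0 / (lamx_path * lamy_path)
        sLL, sCC, traj = path_response(
            lamx_path, lamy_path, mat, damage_params, alpha_deg
        )
        return BrickResult(
            DX=lamx_path - 1.0, DY=lamy_path - 1.0, DZ=lamz_path - 1.0,
            J=np.ones_like(u),
            sigma_xx=sLL, sigma_yy=sCC, sigma_zz=np.zeros_like(u),
            D={k: traj.D[k] for k in mech.LAYERS},
            mode=mode, kappa0=None,
        )
    if mode != "penalty":
        raise ValueError(f"unknown mode {mode!r}")

    state = DamageState.pristine()
    lamz_sol = np.empty_like(u)
    J_sol = np.empty_like(u)
    sxx = np.empty_like(u)
    syy = np.empty_like(u)
    szz = np.empty_like(u)
    Dhist = {k: np.empty_like(u) for k in mech.LAYERS}
    for i, (lx, ly) in enumerate(zip(lamx_path, lamy_path)):
        guess = 1.0 / (lx * ly)

        def f(lz: float) -> float:
            return _sigma_zz_penalty(
                lz, lx, ly, mat, fibers, damage_params, state, kappa0
            )[0]

        lo, hi = 0.2 * guess, 1.2 * guess
        flo, fhi = f(lo), f(hi)
        tries = 0
        while flo * fhi > 0:  # expand the bracket geometrically
            lo *= 0.5
            hi *= 1.5
            flo, fhi = f(lo), f(hi)
            tries += 1
            if tries > 40:
                raise RuntimeError(
                    f"step {i}: sigma_zz root not bracketed in [{lo}, {hi}]"
                )
        lamz = brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
        res, state = _sigma_zz_penalty(
            lamz, lx, ly, mat, fibers, damage_params, state, kappa0
        )
        if abs(res) > PLANE_STRESS_TOL:
            raise RuntimeError(
                f"step {i}: plane-stress residual {res:.3e} MPa above tolerance"
            )
        F = np.diag([lx, ly, lamz])
        defm = mech.kinematics_from_F(F, fibers)
        pen = MaterialParams(
            mu0=mat.mu0, k1_mus=mat.k1_mus, k2_mus=mat.k2_mus,
            k1_sm=mat.k1_sm, k2_sm=mat.k2_sm, kappa0=kappa0,
        )
        stress = mech.cauchy_stress(defm, pen, damage=state.D)
        lamz_sol[i] = lamz
        J_sol[i] = defm.J
        sxx[i] = stress.sigma[0, 0]
        syy[i] = stress.sigma[1, 1]
        szz[i] = stress.sigma[2, 2]
        for k in mech.LAYERS:
            Dhist[k][i] = state.D[k]

    return BrickResult(
        DX=lamx_path - 1.0, DY=lamy_path - 1.0, DZ=lamz_sol - 1.0, J=J_sol,
        sigma_xx=sxx, sigma_yy=syy, sigma_zz=szz,
        D=Dhist, mode=mode, kappa0=kappa0,
    )
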