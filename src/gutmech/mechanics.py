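"""Finite-strain kinematics and the four-fiber strain-energy function.

The intestinal wall is modeled as an incompressible (or nearly
incompressible) fiber-reinforced composite: a neo-Hookean ground matrix
plus four collagen fiber families — one each in the longitudinal (``a01``)
and circumferential (``a02``) muscular layers and a crosswise ``±alpha``
pair (``a03``, ``a04``) in the submucosa.  Each family carries an
exponential (Holzapfel–Gasser–Ogden type) strain energy driven by the
modified fourth invariant, active in tension only.  The muscular families
share one (k1, k2) pair; the submucosal pair shares another.

Stress is evaluated from the decoupled volumetric/isochoric split of the
deformation gradient.  Per-layer Kachanov reduction factors ``(1 - D_k)``
scale the fiber contributions; the matrix and volumetric terms are never
damaged.  Units are MPa–mm–N throughout; stretches are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "LAYERS",
    "FIBER_NAMES",
    "FiberSet",
    "MaterialParams",
    "Deformation",
    "StressTensor",
    "BiaxialCurve",
    "make_fiber_set",
    "kinematics_from_F",
    "fiber_energy",
    "psi_prime",
    "strain_energy",
    "EnergyBreakdown",
    "cauchy_stress",
    "stretch_from_green_lagrange",
    "membrane_true_stress",
]

#: Damage-bearing collagenous layers: longitudinal muscular, circumferential
#: muscular, submucosal.
LAYERS = ("lm", "cm", "sm")

FIBER_NAMES = ("a01", "a02", "a03", "a04")

#: Largest exponent passed to exp(); keeps far-out-of-range trial parameters
#: finite (and their squared residuals representable) during optimization.
#: Physically reachable values of k2 (I4-1)^2 stay far below this.
_EXP_CAP = 60.0

_D_TOL = 1e-12


@dataclass(frozen=True)
class FiberSet:
    """Reference fiber directions of the four collagen families.

    ``a01``/``a02`` are the longitudinal and circumferential muscular
    fibers (mutually perpendicular); ``a03``/``a04`` are the submucosal
    fibers at ``±alpha_deg`` to the longitudinal axis.  All vectors are
    unit vectors in the e1–e2 plane.
    """

    a01: np.ndarray
    a02: np.ndarray
    a03: np.ndarray
    a04: np.ndarray
    alpha_deg: float = 30.0

    def __iter__(self):
        return iter((self.a01, self.a02, self.a03, self.a04))

    def as_dict(self) -> dict[str, np.ndarray]:
        return dict(zip(FIBER_NAMES, self))


def make_fiber_set(alpha_deg: float = 30.0) -> FiberSet:
    """Build the four-family fiber set for a submucosal half-angle.

    Parameters
    ----------
    alpha_deg:
        Half-angle of the crosswise submucosal fiber pair, measured from
        the longitudinal axis e1, in degrees.  Must lie in ``[0, 90)``.
    """
    if not (0.0 <= alpha_deg < 90.0):
        raise ValueError(f"alpha_deg must be in [0, 90), got {alpha_deg}")
    a = np.deg2rad(alpha_deg)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 1.0, 0.0])
    a03 = np.array([np.cos(a), np.sin(a), 0.0])
    a04 = np.array([np.cos(a), -np.sin(a), 0.0])
    return FiberSet(a01=e1, a02=e2, a03=a03, a04=a04, alpha_deg=float(alpha_deg))


@dataclass(frozen=True)
class MaterialParams:
    """Hyperelastic constants of the matrix and the two collagen families.

    Attributes
    ----------
    mu0:
        Initial shear modulus of the neo-Hookean ground matrix (MPa).
    k1_mus, k2_mus:
        Stress-like constant (MPa) and dimensionless exponent shared by
        the two muscular fiber families.
    k1_sm, k2_sm:
        Same for the submucosal ``±alpha`` pair.
    kappa0:
        Initial bulk modulus (MPa) for the volumetric penalty.  ``None``
        selects exact incompressibility (curve-level computations).
    """

    mu0: float
    k1_mus: float
    k2_mus: float
    k1_sm: float
    k2_sm: float
    kappa0: float | None = None

    def __post_init__(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        for name in ("k1_mus", "k1_sm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("k2_mus", "k2_sm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kappa0 is not None and self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive when given")

    def k1k2(self, fiber: str) -> tuple[float, float]:
        """(k1, k2) pair for a fiber name ``a01``..``a04``."""
        if fiber in ("a01", "a02"):
            return self.k1_mus, self.k2_mus
        if fiber in ("a03", "a04"):
            return self.k1_sm, self.k2_sm
        raise KeyError(fiber)

    def default_kappa0(self) -> float:
        """Penalty bulk modulus used when none is configured.

        Chosen large relative to the stiffest deviatoric constant so the
        penalty solution sits close to the incompressible one.
        """
        return 1e4 * max(self.mu0, self.k1_mus, self.k1_sm)


@dataclass(frozen=True)
class Deformation:
    """A deformation gradient with its derived modified invariants."""

    F: np.ndarray
    J: float
    C: np.ndarray
    B: np.ndarray
    C_bar: np.ndarray
    B_bar: np.ndarray
    I1_bar: float
    I4_bar: dict[str, float]
    fibers: FiberSet


def kinematics_from_F(F: np.ndarray, fibers: FiberSet) -> Deformation:
    """Compute Cauchy–Green tensors and modified invariants from ``F``.

    Raises ``ValueError`` for non-invertible or orientation-reversing
    deformation gradients (``det F <= 0``).
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise ValueError(f"F must be 3x3, got shape {F.shape}")
    J = float(np.linalg.det(F))
    if J <= 0:
        raise ValueError(f"det F must be positive, got {J}")
    C = F.T @ F
    B = F @ F.T
    scale = J ** (-2.0 / 3.0)
    C_bar = scale * C
    B_bar = scale * B
    I1_bar = float(np.trace(C_bar))
    I4_bar = {name: float(a @ C_bar @ a) for name, a in fibers.as_dict().items()}
    return Deformation(
        F=F, J=J, C=C, B=B, C_bar=C_bar, B_bar=B_bar,
        I1_bar=I1_bar, I4_bar=I4_bar, fibers=fibers,
    )


def fiber_energy(I4_bar, k1: float, k2: float):
    """Energy of one fiber family, k1/(2 k2) [exp(k2 (I4-1)^2) - 1].

    Tension-only: zero for ``I4_bar < 1``.  The ``k2 -> 0`` limit
    ``k1 (I4-1)^2 / 2`` is used when ``k2 == 0``.  Accepts scalars or
    arrays.
    """
    x = np.maximum(np.asarray(I4_bar, dtype=float) - 1.0, 0.0)
    if k2 == 0.0:
        out = 0.5 * k1 * x * x
    else:
        out = k1 / (2.0 * k2) * np.expm1(np.minimum(k2 * x * x, _EXP_CAP))
    return out if out.ndim else float(out)


def psi_prime(I4_bar, k1: float, k2: float):
    """Derivative of one fiber family's energy w.r.t. its invariant.

    ``k1 (I4-1) exp(k2 (I4-1)^2)`` for ``I4_bar >= 1``, else zero.
    Total function; accepts scalars or arrays.
    """
    i4 = np.asarray(I4_bar, dtype=float)
    x = i4 - 1.0
    out = np.where(
        x >= 0.0,
        k1 * x * np.exp(np.minimum(k2 * x * x, _EXP_CAP)),
        0.0,
    )
    return out if out.ndim else float(out)


def _check_damage(damage: Mapping[str, float] | None) -> dict[str, float]:
    if damage is None:
        return {k: 0.0 for k in LAYERS}
    d = {k: float(damage.get(k, 0.0)) for k in LAYERS}
    for k, v in d.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"damage scalar D_{k} = {v} outside [0, 1]")
    return d


@dataclass(frozen=True)
class EnergyBreakdown:
    """Strain energy split by source (all MPa = mJ/mm^3).

    ``psi_mus`` holds the *undamaged* per-fiber muscular energies keyed
    ``a01``/``a02``; ``psi_sm`` pools the two submucosal fibers.  ``total``
    is the damage-weighted sum.
    """

    psi_vol: float
    psi_iso: float
    psi_mus: dict[str, float]
    psi_sm: float
    total: float

    def layer_energies(self) -> dict[str, float]:
        """Undamaged energies keyed by damage layer (lm, cm, sm)."""
        return {"lm": self.psi_mus["a01"], "cm": self.psi_mus["a02"], "sm": self.psi_sm}


def strain_energy(
    defm: Deformation,
    mat: MaterialParams,
    damage: Mapping[str, float] | None = None,
) -> EnergyBreakdown:
    """Evaluate the strain-energy function, split by source.

    The volumetric term is ``kappa0 (J-1)^2 / 2`` in penalty mode and 0
    in incompressible mode (``kappa0 is None``).  Damage weights only the
    fiber terms: longitudinal muscular fiber by ``1 - D_lm``,
    circumferential by ``1 - D_cm``, and the pooled submucosal pair by
    ``1 - D_sm``.
    """
    d = _check_damage(damage)
    psi_vol = 0.0
    if mat.kappa0 is not None:
        psi_vol = 0.5 * mat.kappa0 * (defm.J - 1.0) ** 2
    psi_iso = 0.5 * mat.mu0 * (defm.I1_bar - 3.0)
    psi_mus = {
        name: float(fiber_energy(defm.I4_bar[name], mat.k1_mus, mat.k2_mus))
        for name in ("a01", "a02")
    }
    psi_sm = float(
        fiber_energy(defm.I4_bar["a03"], mat.k1_sm, mat.k2_sm)
        + fiber_energy(defm.I4_bar["a04"], mat.k1_sm, mat.k2_sm)
    )
    total = (
        psi_vol
        + psi_iso
        + (1.0 - d["lm"]) * psi_mus["a01"]
        + (1.0 - d["cm"]) * psi_mus["a02"]
        + (1.0 - d["sm"]) * psi_sm
    )
    return EnergyBreakdown(psi_vol=psi_vol, psi_iso=psi_iso, psi_mus=psi_mus,
                           psi_sm=psi_sm, total=total)


@dataclass(frozen=True)
class StressTensor:
    """Symmetric Cauchy stress with its per-source decomposition (MPa)."""

    sigma: np.ndarray
    components: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def _dev(A: np.ndarray) -> np.ndarray:
    return A - (np.trace(A) / 3.0) * np.eye(3)


def cauchy_stress(
    defm: Deformation,
    mat: MaterialParams,
    damage: Mapping[str, float] | None = None,
    pressure: float | None = None,
) -> StressTensor:
    """Analytic Cauchy stress of the damage-weighted strain energy.

    In penalty mode (``mat.kappa0`` set) the hydrostatic pressure is
    ``p = kappa0 (J - 1)``; in incompressible mode the caller must supply
    ``pressure`` (the plane-stress solvers determine it from a zero
    normal-stress condition).

    The per-source parts returned in ``components`` ('volumetric',
    'isotropic', 'mus_a01', 'mus_a02', 'sm') sum to the total tensor;
    fiber parts already carry their ``1 - D`` reduction factors, floored
    at ``1e-12`` to avoid exact-zero tangent stiffness.
    """
    d = _check_damage(damage)
    if pressure is None:
        if mat.kappa0 is None:
            raise ValueError(
                "incompressible mode (kappa0=None) needs an explicit pressure"
            )
        pressure = mat.kappa0 * (defm.J - 1.0)

    J = defm.J
    I = np.eye(3)
    sig_vol = pressure * I
    sig_iso = (mat.mu0 / J) * (defm.B_bar - (defm.I1_bar / 3.0) * I)

    Fbar = J ** (-1.0 / 3.0) * defm.F
    reduction = {
        "a01": max(1.0 - d["lm"], _D_TOL),
        "a02": max(1.0 - d["cm"], _D_TOL),
        "a03": max(1.0 - d["sm"], _D_TOL),
        "a04": max(1.0 - d["sm"], _D_TOL),
    }
    fiber_parts: dict[str, np.ndarray] = {}
    for name, a0 in defm.fibers.as_dict().items():
        k1, k2 = mat.k1k2(name)
        dpsi = psi_prime(defm.I4_bar[name], k1, k2)
        abar = Fbar @ a0
        Abar = np.outer(abar, abar)  # trace = I4_bar
        fiber_parts[name] = reduction[name] * (2.0 / J) * dpsi * _dev(Abar)

    components = {
        "volumetric": sig_vol,
        "isotropic": sig_iso,
        "mus_a01": fiber_parts["a01"],
        "mus_a02": fiber_parts["a02"],
        "sm": fiber_parts["a03"] + fiber_parts["a04"],
    }
    sigma = sum(components.values())
    return StressTensor(sigma=sigma, components=components)


def stretch_from_green_lagrange(E):
    """Stretch from Green–Lagrange strain, lambda = sqrt(2 E + 1)."""
    E = np.asarray(E, dtype=float)
    if np.any(E < -0.5):
        raise ValueError("Green-Lagrange strain below -0.5 has no real stretch")
    lam = np.sqrt(2.0 * E + 1.0)
    return lam if lam.ndim else float(lam)


def membrane_true_stress(P, lam, L: float, T: float):
    """True (Cauchy) stress of an incompressible membrane, sigma = P lam / (L T).

    ``P`` is the axial force in N, ``lam`` the stretch along that axis,
    ``L`` the specimen edge length and ``T`` its thickness, both in mm.
    """
    if L <= 0 or T <= 0:
        raise ValueError("specimen geometry must be positive")
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    sig = np.asarray(P, dtype=float) * lam / (L * T)
    return sig if sig.ndim else float(sig)


@dataclass
class BiaxialCurve:
    """A sampled biaxial loading path with true stresses in both directions.

    Longitudinal (L) and circumferential (C) stretches start at 1; Cauchy
    stresses are in MPa.  Optional raw channels carry Green–Lagrange
    strains and actuator forces together with the specimen geometry that
    links force to true stress.
    """

    lambda_L: np.ndarray
    lambda_C: np.ndarray
    sigma_LL: np.ndarray
    sigma_CC: np.ndarray
    time: np.ndarray | None = None
    E_LL: np.ndarray | None = None
    E_CC: np.ndarray | None = None
    P_L: np.ndarray | None = None
    P_C: np.ndarray | None = None
    edge_mm: float | None = None
    thickness_mm: float | None = None

    _START_TOL = 1e-3
    _STRETCH_FLOOR = 1e-6

    def __post_init__(self) -> None:
        arrays = {
            "lambda_L": self.lambda_L, "lambda_C": self.lambda_C,
            "sigma_LL": self.sigma_LL, "sigma_CC": self.sigma_CC,
        }
        for name, arr in arrays.items():
            setattr(self, name, np.asarray(arr, dtype=float))
        n = len(self.lambda_L)
        for name in ("lambda_C", "sigma_LL", "sigma_CC"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from lambda_L")
        for name in ("time", "E_LL", "E_CC", "P_L", "P_C"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if len(val) != n:
                    raise ValueError(f"{name} length differs from lambda_L")
                setattr(self, name, val)
        if n == 0:
            raise ValueError("curve must have at least one sample")
        if np.any(self.lambda_L < self._STRETCH_FLOOR) or np.any(
            self.lambda_C < self._STRETCH_FLOOR
        ):
            raise ValueError("stretches must be positive")
        for name in ("lambda_L", "lambda_C"):
            lam0 = getattr(self, name)[0]
            if abs(lam0 - 1.0) > self._START_TOL:
                raise ValueError(f"{name} must start at 1 (got {lam0})")

    def __len__(self) -> int:
        return len(self.lambda_L)
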