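"""Per-layer scalar damage with irreversible history.

Each load-bearing collagenous layer (longitudinal muscular ``lm``,
circumferential muscular ``cm``, submucosal ``sm``) carries a scalar
damage variable ``D in [0, 1]`` driven by the equivalent strain
``tau = sqrt(2 psi_bar)`` of the layer's *undamaged* deviatoric energy.
Damage starts once ``tau`` first exceeds the initial threshold ``tau0``
and then follows the closed-form exponential evolution

    D(tau) = 1 - (tau0 / tau) * exp(A * (1 - tau / tau0)),
    A = 1 / (gf / tau0**2 - 1/2),

where ``gf`` is the fracture energy per unit volume.  ``D`` is a state
function of the history maximum of ``tau``, so it is irreversible by
construction: unloading and elastic reloading below the running maximum
leave it frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .mechanics import LAYERS

__all__ = [
    "LayerDamageParams",
    "DamageParams",
    "DamageState",
    "equivalent_strain",
    "damage_A",
    "damage_value",
    "update_state",
    "internal_dissipation",
    "path_damage",
]


def damage_A(tau0: float, gf: float) -> float:
    """Exponential-evolution exponent A = 1 / (gf/tau0^2 - 1/2).

    Well posed only for ``gf > tau0^2 / 2`` (positive A); smaller fracture
    energies would make the post-threshold response non-dissipative.
    """
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    ratio = gf / tau0**2 - 0.5
    if ratio <= 0:
        raise ValueError(
            f"non-physical damage pair: gf={gf} must exceed tau0^2/2={tau0**2 / 2}"
        )
    return 1.0 / ratio


@dataclass(frozen=True)
class LayerDamageParams:
    """Damage threshold (MPa^1/2) and fracture energy (MPa) of one layer."""

    tau0: float
    gf: float

    def __post_init__(self) -> None:
        damage_A(self.tau0, self.gf)  # validates positivity and gf > tau0^2/2

    @property
    def A(self) -> float:
        return damage_A(self.tau0, self.gf)


@dataclass(frozen=True)
class DamageParams:
    """Damage parameters of the three collagenous layers."""

    lm: LayerDamageParams
    cm: LayerDamageParams
    sm: LayerDamageParams

    def layer(self, k: str) -> LayerDamageParams:
        return getattr(self, k)

    @classmethod
    def from_flat(cls, flat: Mapping[str, float]) -> "DamageParams":
        """Build from keys ``tau0_lm, gf_lm, tau0_cm, gf_cm, tau0_sm, gf_sm``."""
        layers = {}
        for k in LAYERS:
            try:
                layers[k] = LayerDamageParams(
                    tau0=float(flat[f"tau0_{k}"]), gf=float(flat[f"gf_{k}"])
                )
            except ValueError as exc:
                raise ValueError(f"layer {k}: {exc}") from None
        return cls(**layers)

    def to_flat(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for k in LAYERS:
            lp = self.layer(k)
            out[f"tau0_{k}"] = lp.tau0
            out[f"gf_{k}"] = lp.gf
        return out


def equivalent_strain(psi_bar):
    """Equivalent strain tau = sqrt(2 psi_bar), units MPa^1/2.

    ``psi_bar`` is the *undamaged* deviatoric energy of the layer.
    """
    psi = np.asarray(psi_bar, dtype=float)
    if np.any(psi < 0):
        raise ValueError("layer energy must be non-negative")
    tau = np.sqrt(2.0 * psi)
    return tau if tau.ndim else float(tau)


def damage_value(tau, tau0: float, A: float):
    """Damage state function D(tau); zero at and below the threshold.

    Continuous at ``tau = tau0``, monotone non-decreasing, with
    ``D -> 1`` as ``tau -> inf``.  Result is clamped to [0, 1].
    Accepts scalars or arrays.
    """
    t = np.asarray(tau, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(t > 0, tau0 / np.where(t > 0, t, 1.0), 1.0)
        d = 1.0 - ratio * np.exp(np.minimum(A * (1.0 - t / tau0), 0.0))
    d = np.where(t <= tau0, 0.0, np.clip(d, 0.0, 1.0))
    return d if d.ndim else float(d)


@dataclass(frozen=True)
class DamageState:
    """History maximum of the equivalent strain and current damage per layer."""

    tau_max: dict[str, float]
    D: dict[str, float]

    @classmethod
    def pristine(cls) -> "DamageState":
        return cls(tau_max={k: 0.0 for k in LAYERS}, D={k: 0.0 for k in LAYERS})


def update_state(
    state: DamageState,
    layer_energies: Mapping[str, float],
    params: DamageParams,
) -> DamageState:
    """Advance the damage state with the current undamaged layer energies.

    Per layer: if the current equivalent strain exceeds the stored history
    maximum, the maximum moves up and ``D`` is re-evaluated from the
    closed-form evolution; otherwise (unloading or elastic reloading) the
    state is unchanged.  ``D`` never decreases.
    """
    tau_max = dict(state.tau_max)
    D = dict(state.D)
    for k in LAYERS:
        tau = equivalent_strain(layer_energies[k])
        if tau > tau_max[k]:
            tau_max[k] = tau
            lp = params.layer(k)
            D[k] = max(D[k], damage_value(tau, lp.tau0, lp.A))
    return DamageState(tau_max=tau_max, D=D)


def internal_dissipation(
    dD: Mapping[str, float], psi_bar: Mapping[str, float]
) -> float:
    """Incremental internal dissipation sum_k dD_k * psi_bar_k (MPa).

    Non-negative on every admissible update (dD_k >= 0, psi_bar_k >= 0);
    a negative value flags a broken update rule.
    """
    return math.fsum(float(dD[k]) * float(psi_bar[k]) for k in LAYERS)


def path_damage(
    layer_energies: Mapping[str, np.ndarray], params: DamageParams
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Vectorized damage history along a sampled loading path.

    ``layer_energies`` maps each layer to the per-frame undamaged energy.
    Returns ``(tau, D)`` arrays per layer, where ``D`` at frame i is the
    state function of the running maximum of ``tau`` up to frame i.
    """
    tau: dict[str, np.ndarray] = {}
    D: dict[str, np.ndarray] = {}
    for k in LAYERS:
        t = equivalent_strain(np.asarray(layer_energies[k], dtype=float))
        t_max = np.maximum.accumulate(t)
        lp = params.layer(k)
        tau[k] = t
        D[k] = damage_value(t_max, lp.tau0, lp.A)
    return tau, D
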