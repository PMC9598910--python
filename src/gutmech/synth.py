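"""Synthetic equibiaxial experiments with the structure of a biaxial rig.

Emulates displacement-controlled equibiaxial tension on square membrane
specimens: 40 mm x 40 mm edge, thickness either fixed at the cohort mean
1.188 mm or sampled per specimen from the observed 0.68–2.15 mm range,
crosshead speed 10 mm/min per axis, frames at 1 Hz.  Noise-free true
stresses come from the plane-stress forward model; actuator forces are
back-computed through the incompressible-membrane relation
``P = sigma L T / lambda``; measurement noise is multiplicative Gaussian
on the force signal plus an additive sensor floor.  Rupture is emulated
by truncating the record once the specimen has completely failed — by
default when every load-bearing layer's damage exceeds a cap, matching a
rig that keeps stretching until nothing carries load.  The
needle-fixation tearing artifact of real rigs is deliberately not
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import numpy as np

from . import mechanics as mech
from .mechanics import BiaxialCurve
from .params import ParamSet
from .protocol import DamageTrajectory, path_response

__all__ = ["RigProtocol", "SyntheticCurve", "generate_curve", "generate_cohort"]


@dataclass(frozen=True)
class RigProtocol:
    """Geometry, kinematic protocol and noise model of the synthetic rig.

    Attributes
    ----------
    edge_mm:
        Square specimen edge length L (mm).
    thickness_mm:
        Fixed specimen thickness T (mm); ignored when ``thickness_range``
        is set.
    thickness_range:
        Optional (low, high) in mm; each specimen draws T uniformly.
        A uniform draw over the observed range is a stand-in — real
        cohort thicknesses are not uniformly distributed.
    speed_mm_per_min:
        Crosshead speed per axis; with edge L the stretch rate is
        ``speed / 60 / L`` per second.
    frame_rate_hz:
        Sampling rate of force/strain frames.
    max_stretch:
        Hard stop of the ramp if no rupture occurs first.
    damage_cap:
        Damage level counting as failure of a layer (rupture emulation).
    rupture:
        ``"all_layers"`` (default) truncates the record at the first
        frame where *every* layer's D exceeds the cap — complete rupture,
        the point where the rig protocol stops.  ``"any_layer"``
        truncates at the first single-layer failure instead.
    noise_rel:
        Relative std of multiplicative Gaussian noise on the force signal.
    force_floor_n:
        Std of the additive force-sensor floor (N).
    strain_jitter:
        Std of additive jitter on the Green–Lagrange strain channels.
    """

    edge_mm: float = 40.0
    thickness_mm: float = 1.188
    thickness_range: tuple[float, float] | None = None
    speed_mm_per_min: float = 10.0
    frame_rate_hz: float = 1.0
    max_stretch: float = 2.0
    damage_cap: float = 0.99
    rupture: str = "all_layers"
    noise_rel: float = 0.02
    force_floor_n: float = 0.01
    strain_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.edge_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("specimen geometry must be positive")
        if self.speed_mm_per_min <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("protocol rates must be positive")
        if self.thickness_range is not None:
            lo, hi = self.thickness_range
            if not (0 < lo <= hi):
                raise ValueError("invalid thickness range")
        if not (0 < self.damage_cap <= 1):
            raise ValueError("damage_cap must lie in (0, 1]")
        if self.rupture not in ("all_layers", "any_layer"):
            raise ValueError("rupture must be 'all_layers' or 'any_layer'")
        if self.noise_rel < 0 or self.force_floor_n < 0 or self.strain_jitter < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def stretch_rate_per_s(self) -> float:
        return self.speed_mm_per_min / 60.0 / self.edge_mm

    def noiseless(self) -> "RigProtocol":
        """Copy of this protocol with every noise source switched off."""
        d = asdict(self)
        d.update(noise_rel=0.0, force_floor_n=0.0, strain_jitter=0.0)
        d["thickness_range"] = self.thickness_range
        return RigProtocol(**d)


@dataclass
class SyntheticCurve:
    """A generated experiment: observed curve + ground truth + provenance."""

    curve: BiaxialCurve
    truth: DamageTrajectory
    meta: dict[str, Any] = field(default_factory=dict)


def generate_curve(
    params: ParamSet,
    protocol: RigProtocol | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> SyntheticCurve:
    """Generate one synthetic equibiaxial experiment.

    The stretch grid is ``lambda(t_i) = 1 + rate * t_i`` on both axes at
    the protocol frame rate; stresses come from the damage-coupled
    plane-stress forward model and are truncated at rupture (damage
    cap).  With all noise levels zero the stored stresses are exactly
    the model response, so a refit recovers the generating parameters.
    """
    protocol = protocol or RigProtocol()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    if protocol.thickness_range is not None:
        lo, hi = protocol.thickness_range
        T = float(rng.uniform(lo, hi))
    else:
        T = protocol.thickness_mm
    L = protocol.edge_mm

    dlam = protocol.stretch_rate_per_s / protocol.frame_rate_hz
    n = int(np.floor((protocol.max_stretch - 1.0) / dlam)) + 1
    t = np.arange(n) / protocol.frame_rate_hz
    lam = 1.0 + dlam * np.arange(n)

    sig_LL, sig_CC, traj = path_response(
        lam, lam, params.material, params.damage, params.alpha_deg
    )
    reduce = np.minimum if protocol.rupture == "all_layers" else np.maximum
    Dcrit = reduce.reduce([traj.D[k] for k in mech.LAYERS])
    over = np.nonzero(Dcrit >= protocol.damage_cap)[0]
    end = int(over[0]) + 1 if over.size else n
    sl = slice(0, end)
    lam, t = lam[sl], t[sl]
    sig_LL, sig_CC = sig_LL[sl], sig_CC[sl]
    traj = DamageTrajectory(
        lambda_L=lam, lambda_C=lam,
        tau={k: traj.tau[k][sl] for k in mech.LAYERS},
        D={k: traj.D[k][sl] for k in mech.LAYERS},
    )

    # Forces as the rig records them, then noise on the force channel.
    P_L = sig_LL * L * T / lam
    P_C = sig_CC * L * T / lam
    if protocol.noise_rel > 0:
        P_L = P_L * (1.0 + protocol.noise_rel * rng.standard_normal(len(lam)))
        P_C = P_C * (1.0 + protocol.noise_rel * rng.standard_normal(len(lam)))
    if protocol.force_floor_n > 0:
        P_L = P_L + protocol.force_floor_n * rng.standard_normal(len(lam))
        P_C = P_C + protocol.force_floor_n * rng.standard_normal(len(lam))
    # Observed stresses re-derived from the noisy forces (round-trip
    # consistent with the incompressible-membrane conversion).
    sig_LL_obs = mech.membrane_true_stress(P_L, lam, L, T)
    sig_CC_obs = mech.membrane_true_stress(P_C, lam, L, T)

    E = 0.5 * (lam**2 - 1.0)
    E_LL, E_CC = E.copy(), E.copy()
    if protocol.strain_jitter > 0:
        E_LL = E_LL + protocol.strain_jitter * rng.standard_normal(len(lam))
        E_CC = E_CC + protocol.strain_jitter * rng.standard_normal(len(lam))

    curve = BiaxialCurve(
        lambda_L=lam, lambda_C=lam.copy(),
        sigma_LL=sig_LL_obs, sigma_CC=sig_CC_obs,
        time=t, E_LL=E_LL, E_CC=E_CC, P_L=P_L, P_C=P_C,
        edge_mm=L, thickness_mm=T,
    )
    meta = {
        "thickness_mm": T,
        "frames": len(lam),
        "truncated_by_damage": bool(over.size),
        "params": params.to_dict(),
        "protocol": {**asdict(protocol),
                     "thickness_range": protocol.thickness_range},
    }
    return SyntheticCurve(curve=curve, truth=traj, meta=meta)


def generate_cohort(
    param_table: Mapping[str, ParamSet],
    protocol: RigProtocol | None = None,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[dict[str, SyntheticCurve], dict[str, Any]]:
    """Generate a seeded cohort of synthetic experiments.

    One curve per (specimen row, replicate), each with an independent
    child seed spawned from ``seed``.  Returns the curves keyed
    ``"<row>_r<rep>"`` plus a manifest recording every seed, parameter
    set and the protocol, sufficient to regenerate the cohort bitwise.
    """
    protocol = protocol or RigProtocol()
    root = np.random.SeedSequence(seed)
    curves: dict[str, SyntheticCurve] = {}
    manifest: dict[str, Any] = {
        "seed": seed,
        "n_replicates": n_replicates,
        "protocol": {**asdict(protocol), "thickness_range": protocol.thickness_range},
        "curves": {},
    }
    for name, params in param_table.items():
        for rep in range(n_replicates):
            child = root.spawn(1)[0]
            key = f"{name}_r{rep}"
            curves[key] = generate_curve(
                params, protocol, np.random.default_rng(child)
            )
            manifest["curves"][key] = {
                "specimen": name,
                "replicate": rep,
                "entropy": int(child.entropy),
                "spawn_key": [int(x) for x in child.spawn_key],
                "params": params.to_dict(),
            }
    return curves, manifest
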