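"""Bundled material + damage parameter sets and their JSON schema.

The flat key schema is::

    mu0, kappa0 (optional), k1_mus, k2_mus, k1_sm, k2_sm,
    tau0_lm, gf_lm, tau0_cm, gf_cm, tau0_sm, gf_sm, alpha_deg (optional)

with units MPa for moduli / stress-like constants and fracture energies,
MPa^1/2 for damage thresholds, degrees for the submucosal fiber
half-angle.  A missing ``kappa0`` selects exact incompressibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from .damage import DamageParams
from .mechanics import MaterialParams

__all__ = ["ParamSet", "REFERENCE_SPECIMENS", "load_params", "save_params"]

_MATERIAL_KEYS = ("mu0", "k1_mus", "k2_mus", "k1_sm", "k2_sm")
_DAMAGE_KEYS = ("tau0_lm", "gf_lm", "tau0_cm", "gf_cm", "tau0_sm", "gf_sm")


@dataclass(frozen=True)
class ParamSet:
    """One specimen's full parameter set: hyperelastic + damage + geometry."""

    material: MaterialParams
    damage: DamageParams
    alpha_deg: float = 30.0

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParamSet":
        missing = [k for k in (*_MATERIAL_KEYS, *_DAMAGE_KEYS) if k not in d]
        if missing:
            raise ValueError(f"missing parameter keys: {', '.join(missing)}")
        unknown = set(d) - {*_MATERIAL_KEYS, *_DAMAGE_KEYS, "kappa0", "alpha_deg"}
        if unknown:
            raise ValueError(f"unknown parameter keys: {', '.join(sorted(unknown))}")
        mat = MaterialParams(
            mu0=float(d["mu0"]),
            k1_mus=float(d["k1_mus"]),
            k2_mus=float(d["k2_mus"]),
            k1_sm=float(d["k1_sm"]),
            k2_sm=float(d["k2_sm"]),
            kappa0=float(d["kappa0"]) if d.get("kappa0") is not None else None,
        )
        dmg = DamageParams.from_flat(d)
        return cls(material=mat, damage=dmg, alpha_deg=float(d.get("alpha_deg", 30.0)))

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "mu0": self.material.mu0,
            "k1_mus": self.material.k1_mus,
            "k2_mus": self.material.k2_mus,
            "k1_sm": self.material.k1_sm,
            "k2_sm": self.material.k2_sm,
        }
        if self.material.kappa0 is not None:
            out["kappa0"] = self.material.kappa0
        out.update(self.damage.to_flat())
        out["alpha_deg"] = self.alpha_deg
        return out


def load_params(path: str | Path) -> ParamSet:
    """Read a parameter JSON file, validating schema and damage feasibility."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a JSON object")
    try:
        return ParamSet.from_dict(data)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def save_params(params: ParamSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params.to_dict(), fh, indent=2)
        fh.write("\n")


def _ref(row: dict[str, float]) -> ParamSet:
    return ParamSet.from_dict(row)


#: Fitted parameter sets for four porcine large-intestine specimens
#: (S1-S4) identified from equibiaxial tension tests.  mu0 sits on its
#: fitting floor of 1e-4 MPa in every specimen; the muscular (mus) pair
#: of fiber families shares one (k1, k2), the submucosal (sm) +/-30 deg
#: pair another; (tau0, gf) are the per-layer damage threshold and
#: fracture energy.
REFERENCE_SPECIMENS: dict[str, ParamSet] = {
    "S1": _ref({
        "mu0": 0.0001, "k1_mus": 0.0030, "k2_mus": 10.6781,
        "k1_sm": 0.0068, "k2_sm": 13.3155,
        "tau0_lm": 0.1149, "gf_lm": 0.0073,
        "tau0_cm": 0.0110, "gf_cm": 0.0169,
        "tau0_sm": 0.0624, "gf_sm": 0.0125,
    }),
    "S2": _ref({
        "mu0": 0.0001, "k1_mus": 0.0138, "k2_mus": 0.6804,
        "k1_sm": 0.0002, "k2_sm": 7.4843,
        "tau0_lm": 0.1241, "gf_lm": 0.0083,
        "tau0_cm": 0.2236, "gf_cm": 0.0387,
        "tau0_sm": 0.0379, "gf_sm": 0.0089,
    }),
    "S3": _ref({
        "mu0": 0.0001, "k1_mus": 0.0096, "k2_mus": 4.1802,
        "k1_sm": 0.0094, "k2_sm": 7.0591,
        "tau0_lm": 0.1439, "gf_lm": 0.0118,
        "tau0_cm": 0.0257, "gf_cm": 0.0346,
        "tau0_sm": 0.0750, "gf_sm": 0.0224,
    }),
    "S4": _ref({
        "mu0": 0.0001, "k1_mus": 0.0272, "k2_mus": 0.0144,
        "k1_sm": 0.0055, "k2_sm": 2.9810,
        "tau0_lm": 0.2308, "gf_lm": 0.0278,
        "tau0_cm": 0.2921, "gf_cm": 0.0461,
        "tau0_sm": 0.1302, "gf_sm": 0.0738,
    }),
}
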