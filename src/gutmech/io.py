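"""Readers and writers for the curve CSV dialect and damage trajectories.

The curve dialect is a comma-separated, dot-decimal, UTF-8 file with
header ``time_s,lambda_L,lambda_C,sigma_LL_MPa,sigma_CC_MPa`` and
optional extra columns ``E_LL,E_CC,P_L_N,P_C_N``.  Stretch columns may
be omitted when the Green–Lagrange channels are present; the stretches
are then reconstructed as ``lambda = sqrt(2 E + 1)``.  Strict schema:
unknown or misspelled columns are an error, never silently coerced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .mechanics import BiaxialCurve, stretch_from_green_lagrange
from .params import load_params as read_params
from .params import save_params as write_params
from .protocol import DamageTrajectory

__all__ = [
    "SchemaError",
    "read_curve",
    "write_curve",
    "read_params",
    "write_params",
    "write_damage_trajectory",
]

_REQUIRED_STRESS = ("sigma_LL_MPa", "sigma_CC_MPa")
_STRETCH = ("lambda_L", "lambda_C")
_STRAIN = ("E_LL", "E_CC")
_OPTIONAL = ("time_s", "E_LL", "E_CC", "P_L_N", "P_C_N")
_KNOWN = {*_REQUIRED_STRESS, *_STRETCH, *_OPTIONAL}


class SchemaError(ValueError):
    """A curve file does not match the declared CSV dialect."""


def read_curve(
    path: str | Path,
    edge_mm: float | None = None,
    thickness_mm: float | None = None,
) -> BiaxialCurve:
    """Read and validate a biaxial curve CSV.

    Stretches are taken from the ``lambda_*`` columns, or derived from
    ``E_*`` when absent.  Time, if present, must be strictly
    monotone-increasing.
    """
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in _KNOWN]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {', '.join(unknown)}")
    missing = [c for c in _REQUIRED_STRESS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")

    have_lambda = all(c in df.columns for c in _STRETCH)
    have_strain = all(c in df.columns for c in _STRAIN)
    if not have_lambda and not have_strain:
        raise SchemaError(
            f"{path}: need either lambda_L/lambda_C or E_LL/E_CC columns"
        )
    if have_lambda:
        lamL = df["lambda_L"].to_numpy(float)
        lamC = df["lambda_C"].to_numpy(float)
    else:
        lamL = stretch_from_green_lagrange(df["E_LL"].to_numpy(float))
        lamC = stretch_from_green_lagrange(df["E_CC"].to_numpy(float))

    time = None
    if "time_s" in df.columns:
        time = df["time_s"].to_numpy(float)
        if np.any(np.diff(time) <= 0):
            raise SchemaError(f"{path}: time_s must be strictly increasing")

    try:
        return BiaxialCurve(
            lambda_L=lamL,
            lambda_C=lamC,
            sigma_LL=df["sigma_LL_MPa"].to_numpy(float),
            sigma_CC=df["sigma_CC_MPa"].to_numpy(float),
            time=time,
            E_LL=df["E_LL"].to_numpy(float) if "E_LL" in df.columns else None,
            E_CC=df["E_CC"].to_numpy(float) if "E_CC" in df.columns else None,
            P_L=df["P_L_N"].to_numpy(float) if "P_L_N" in df.columns else None,
            P_C=df["P_C_N"].to_numpy(float) if "P_C_N" in df.columns else None,
            edge_mm=edge_mm,
            thickness_mm=thickness_mm,
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_curve(curve: BiaxialCurve, path: str | Path) -> None:
    """Write a curve in the canonical CSV dialect."""
    cols: dict[str, Any] = {}
    if curve.time is not None:
        cols["time_s"] = curve.time
    cols["lambda_L"] = curve.lambda_L
    cols["lambda_C"] = curve.lambda_C
    cols["sigma_LL_MPa"] = curve.sigma_LL
    cols["sigma_CC_MPa"] = curve.sigma_CC
    if curve.E_LL is not None:
        cols["E_LL"] = curve.E_LL
    if curve.E_CC is not None:
        cols["E_CC"] = curve.E_CC
    if curve.P_L is not None:
        cols["P_L_N"] = curve.P_L
    if curve.P_C is not None:
        cols["P_C_N"] = curve.P_C
    pd.DataFrame(cols).to_csv(path, index=False)


def write_damage_trajectory(traj: DamageTrajectory, path: str | Path) -> None:
    """Export a damage trajectory as CSV (stretches, tau and D per layer)."""
    traj.to_frame().to_csv(path, index=False)


def write_json(data: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
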