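"""Shear-wave elastography: speed-to-modulus conversion and angle profiles.

The scanner reports shear-wave speed Vs (m/s) per image; the shear elastic
modulus is ``mu = rho * Vs**2`` with muscle density rho = 1000 kg/m^3, which
in kilopascals is numerically ``Vs**2``. Per protocol, three trials of five
images are acquired at each wrist angle from 0 to 50 deg in 10 deg steps,
and the per-angle values are averaged into a stiffness profile.

This module consumes per-image Vs/mu values only — image formation and ROI
placement happen on the scanner.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError

RHO_MUSCLE_KG_M3 = 1000.0

#: Standard acquisition grid (deg of wrist extension).
STANDARD_ANGLES_DEG: tuple[int, ...] = (0, 10, 20, 30, 40, 50)


def modulus_from_speed(vs, rho: float = RHO_MUSCLE_KG_M3):
    """Shear elastic modulus in kPa from shear-wave speed in m/s.

    mu[kPa] = rho * vs^2 / 1000, i.e. exactly vs^2 at rho = 1000 kg/m^3.
    """
    vs = np.asarray(vs, dtype=float)
    if np.any(vs < 0):
        raise DataError("shear-wave speed must be >= 0")
    mu = rho * vs ** 2 / 1000.0
    return float(mu) if mu.ndim == 0 else mu


def speed_from_modulus(mu, rho: float = RHO_MUSCLE_KG_M3):
    """Inverse conversion: Vs in m/s from mu in kPa."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise DataError("shear modulus must be >= 0")
    vs = np.sqrt(1000.0 * mu / rho)
    return float(vs) if vs.ndim == 0 else vs


def check_measurements(df: pd.DataFrame, tol: float = 1e-9) -> None:
    """Validate an elastography table (one row per image).

    Requires columns subject_id, side, angle_deg and at least one of
    vs_mps / mu_kpa; when both are present they must satisfy mu = vs^2
    (rho = 1000 kg/m^3) within ``tol``.
    """
    required = {"subject_id", "side", "angle_deg"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"elastography table missing columns: {sorted(missing)}")
    has_vs, has_mu = "vs_mps" in df.columns, "mu_kpa" in df.columns
    if not (has_vs or has_mu):
        raise DataError("elastography table needs vs_mps or mu_kpa")
    if has_vs and np.any(df["vs_mps"].to_numpy() < 0):
        raise DataError("shear-wave speed must be >= 0")
    if has_mu and np.any(df["mu_kpa"].to_numpy() < 0):
        raise DataError("shear modulus must be >= 0")
    if has_vs and has_mu:
        err = np.abs(df["mu_kpa"].to_numpy() - df["vs_mps"].to_numpy() ** 2)
        if np.any(err > tol):
            raise DataError("mu_kpa inconsistent with vs_mps**2 (rho = 1000 kg/m^3)")


def aggregate_profile(measurements: pd.DataFrame,
                      expected_angles=STANDARD_ANGLES_DEG) -> pd.DataFrame:
    """Per-angle stiffness profile for one subject/side.

    Returns one row per angle with ``mean_mu``, ``sd_mu`` (sample SD,
    n-1 denominator) and ``n_images``. Missing images are tolerated; an
    expected angle with zero measurements is omitted with a warning.
    """
    check_measurements(measurements)
    if measurements.empty:
        raise DataError("no elastography measurements")
    if measurements["subject_id"].nunique() > 1 or measurements["side"].nunique() > 1:
        raise DataError("aggregate_profile expects a single subject/side")
    df = measurements.copy()
    if "mu_kpa" not in df.columns:
        df["mu_kpa"] = modulus_from_speed(df["vs_mps"].to_numpy())
    grouped = (
        df.groupby("angle_deg")["mu_kpa"]
        .agg(mean_mu="mean", sd_mu=lambda x: x.std(ddof=1), n_images="count")
        .reset_index()
        .sort_values("angle_deg", ignore_index=True)
    )
    if expected_angles is not None:
        absent = sorted(set(expected_angles) - set(grouped["angle_deg"]))
        if absent:
            warnings.warn(f"angles with no measurements omitted: {absent}",
                          stacklevel=2)
    grouped.insert(0, "side", measurements["side"].iloc[0])
    grouped.insert(0, "subject_id", measurements["subject_id"].iloc[0])
    return grouped


def aggregate_profiles(measurements: pd.DataFrame) -> pd.DataFrame:
    """Stiffness profiles for every (subject, side) in a combined table."""
    parts = [aggregate_profile(g, expected_angles=None)
             for _, g in measurements.groupby(["subject_id", "side"], sort=True)]
    return pd.concat(parts, ignore_index=True)


def profile_contrast(profile: pd.DataFrame, profile_other: pd.DataFrame) -> dict:
    """Compare two stiffness profiles on a shared angle grid.

    Returns the per-angle difference (first minus second) and each side's
    within-profile 0-to-max-angle increase ``mu(max) - mu(min)``.
    """
    a = profile.sort_values("angle_deg", ignore_index=True)
    b = profile_other.sort_values("angle_deg", ignore_index=True)
    if not np.array_equal(a["angle_deg"].to_numpy(), b["angle_deg"].to_numpy()):
        raise DataError("profiles are on different angle grids")
    diff = pd.DataFrame({
        "angle_deg": a["angle_deg"],
        "delta_mu": a["mean_mu"].to_numpy() - b["mean_mu"].to_numpy(),
    })
    return {
        "per_angle": diff,
        "increase": float(a["mean_mu"].iloc[-1] - a["mean_mu"].iloc[0]),
        "increase_other": float(b["mean_mu"].iloc[-1] - b["mean_mu"].iloc[0]),
    }
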