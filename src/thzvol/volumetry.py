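"""Absorption-cross-section tumor volumetry.

The model links the bulk absorption change of the imaged region to the
amount of cancer tissue through the per-cell absorption cross-section

    sigma = alpha_ref * V_cell          [mm^2]

where ``alpha_ref`` is the reference absorption coefficient of cancer
tissue and ``V_cell`` the volume of a single cancer cell.  A measured
absorption change delta_alpha then implies a cancer-cell number
density

    N' = delta_alpha / sigma            [mm^-3]

and a total cancer-tissue volume inside the interrogated volume V_eff

    V = N' * V_cell * V_eff = (delta_alpha / alpha_ref) * V_eff   [mm^3].

Note that V_cell cancels algebraically in V: the volume estimate
depends only on delta_alpha, alpha_ref and V_eff.  V_cell is still a
calibration input because sigma and N' are reported alongside V.

Default calibration: alpha_ref = 1.5 mm^-1 (midpoint of the 1.400-1.600
false-color scale) and V_eff = 8 mm^3, which together give the constant
conversion V / delta_alpha = V_eff / alpha_ref = 16/3 mm^3 per mm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "VolumetryCalibration",
    "VolumeEstimate",
    "DEFAULT_CALIBRATION",
    "absorption_cross_section",
    "cancer_cell_density",
    "estimate_volume",
    "detection_limit",
    "penetration_depth",
    "round_half_up",
]


@dataclass(frozen=True)
class VolumetryCalibration:
    """Calibration constants of the cross-section volumetry.

    Attributes
    ----------
    alpha_ref:
        Reference absorption coefficient of cancer tissue (mm^-1).
    v_cell:
        Single-cancer-cell volume V_cell (mm^3); the cell number
        density at confluence is implicitly 1 / v_cell.
    v_effective:
        Interrogated tissue volume V_eff (mm^3), treated as an opaque
        calibration constant of the instrument and geometry.
    """

    alpha_ref: float = 1.5
    v_cell: float = 2e-6
    v_effective: float = 8.0

    def __post_init__(self) -> None:
        if self.alpha_ref <= 0 or self.v_cell <= 0 or self.v_effective <= 0:
            raise ValueError("all calibration constants must be strictly positive")


DEFAULT_CALIBRATION = VolumetryCalibration()


@dataclass(frozen=True)
class VolumeEstimate:
    """sigma, N' and V for one subject under a stated calibration."""

    sigma: float
    n_prime: float
    volume_mm3: float
    delta_alpha_used: float
    calibration: VolumetryCalibration


def absorption_cross_section(calib: VolumetryCalibration) -> float:
    """Per-cell absorption cross-section sigma = alpha_ref * V_cell (mm^2)."""
    return calib.alpha_ref * calib.v_cell


def cancer_cell_density(
    delta_alpha: float, calib: VolumetryCalibration = DEFAULT_CALIBRATION
) -> float:
    """Cancer-cell number density N' = delta_alpha / sigma (mm^-3)."""
    if delta_alpha < 0:
        raise ValueError(f"delta_alpha must be >= 0, got {delta_alpha}")
    return delta_alpha / absorption_cross_section(calib)


def estimate_volume(
    delta_alpha: float, calib: VolumetryCalibration = DEFAULT_CALIBRATION
) -> VolumeEstimate:
    """Total cancer-tissue volume V = (delta_alpha / alpha_ref) * V_eff.

    The volume is computed in the V_cell-free simplified form, so
    perturbing v_cell changes sigma and N' but leaves V bit-identical.
    """
    if delta_alpha < 0:
        raise ValueError(f"delta_alpha must be >= 0, got {delta_alpha}")
    return VolumeEstimate(
        sigma=absorption_cross_section(calib),
        n_prime=cancer_cell_density(delta_alpha, calib),
        volume_mm3=(delta_alpha / calib.alpha_ref) * calib.v_effective,
        delta_alpha_used=delta_alpha,
        calibration=calib,
    )


def detection_limit(
    delta_alpha_min: float, calib: VolumetryCalibration = DEFAULT_CALIBRATION
) -> float:
    """Smallest resolvable cancer volume (mm^3) for a given minimum
    detectable absorption change."""
    if delta_alpha_min < 0:
        raise ValueError("delta_alpha_min must be >= 0")
    return (delta_alpha_min / calib.alpha_ref) * calib.v_effective


def penetration_depth(dynamic_range: float, alpha: float) -> float:
    """Depth (mm) at which transmitted power falls to the noise floor.

    With a detection chain of the given dynamic range (max signal over
    noise floor) and a medium of absorption coefficient ``alpha``
    (mm^-1), transmission is detectable down to ln(dynamic_range)/alpha.
    """
    if dynamic_range <= 1:
        raise ValueError(f"dynamic_range must be > 1, got {dynamic_range}")
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return math.log(dynamic_range) / alpha


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round half away from zero, matching conventional reporting of
    volumes and delta_alpha to 3 decimal places."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
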