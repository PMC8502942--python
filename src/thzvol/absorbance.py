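"""Beer-Lambert inversion of power rasters into absorption-coefficient maps.

The absorption coefficient is recovered per pixel as

    alpha = ln(I_b / I_s) / d        [mm^-1]

with ``I_s`` the transmitted power through the sample, ``I_b`` the
background power through the cover glasses alone and ``d`` the slab
thickness in mm.  The logarithm is oriented so that an attenuating
sample yields a positive alpha.

Replicate scans are averaged in alpha-space (arithmetic mean of the
per-replicate maps), and the uniform skin layer is removed by
subtracting a scalar ``skin_optical_depth / d`` from every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phantom import PowerRaster

__all__ = [
    "AbsorbanceMap",
    "compute_absorbance",
    "average_replicates",
    "calibrate_skin_background",
    "estimate_skin_background",
]


@dataclass(frozen=True)
class AbsorbanceMap:
    """Per-pixel absorption coefficient map with its acquisition metadata.

    ``skin_corrected`` is set iff the uniform skin background has been
    subtracted (exactly once); classification requires it.
    """

    alpha_grid: np.ndarray
    thickness_mm: float
    pitch_mm: float
    frequency_ghz: float
    skin_corrected: bool = False
    n_replicates_averaged: int = 1

    def __post_init__(self) -> None:
        grid = np.asarray(self.alpha_grid, dtype=float)
        object.__setattr__(self, "alpha_grid", grid)
        if grid.ndim != 2:
            raise ValueError("alpha_grid must be 2-D")
        if not np.all(np.isfinite(grid)):
            bad = np.argwhere(~np.isfinite(grid))[0]
            raise ValueError(f"non-finite alpha at pixel {tuple(bad)}")
        if self.thickness_mm <= 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.alpha_grid.shape


def compute_absorbance(raster: PowerRaster, thickness_mm: float) -> AbsorbanceMap:
    """Invert one power raster to an absorption-coefficient map."""
    if thickness_mm <= 0:
        raise ValueError(f"thickness must be > 0, got {thickness_mm}")
    power = raster.power_grid
    if np.any(power <= 0):
        bad = np.argwhere(power <= 0)[0]
        raise ValueError(f"non-positive transmitted power at pixel {tuple(bad)}")
    if raster.background_power <= 0:
        raise ValueError("background power must be > 0")
    alpha = np.log(raster.background_power / power) / thickness_mm
    return AbsorbanceMap(
        alpha_grid=alpha,
        thickness_mm=thickness_mm,
        pitch_mm=raster.pitch_mm,
        frequency_ghz=raster.frequency_ghz,
        skin_corrected=False,
        n_replicates_averaged=1,
    )


def average_replicates(maps: list[AbsorbanceMap]) -> AbsorbanceMap:
    """Pixelwise arithmetic mean over replicate scans of the same subject.

    All inputs must agree in shape, thickness, frequency and
    skin-correction state; averaging three replicates reduces the
    pixelwise noise standard deviation by about 1/sqrt(3).
    """
    if not maps:
        raise ValueError("need at least one absorbance map")
    first = maps[0]
    for m in maps[1:]:
        if m.shape != first.shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {first.shape}")
        if m.thickness_mm != first.thickness_mm:
            raise ValueError("thickness mismatch between replicates")
        if m.frequency_ghz != first.frequency_ghz:
            raise ValueError("frequency mismatch between replicates")
        if m.skin_corrected != first.skin_corrected:
            raise ValueError("skin-correction state mismatch between replicates")
    mean = np.mean([m.alpha_grid for m in maps], axis=0)
    return replace(first, alpha_grid=mean, n_replicates_averaged=len(maps))


def calibrate_skin_background(
    amap: AbsorbanceMap, skin_optical_depth: float
) -> AbsorbanceMap:
    """Subtract the uniform, position-independent skin attenuation.

    The skin contributes a constant optical depth, i.e. a constant
    ``skin_optical_depth / d`` in alpha units, at every pixel.
    Applying the correction twice is an error.
    """
    if amap.skin_corrected:
        raise ValueError("skin background already subtracted from this map")
    if skin_optical_depth < 0:
        raise ValueError("skin_optical_depth must be >= 0")
    corrected = amap.alpha_grid - skin_optical_depth / amap.thickness_mm
    return replace(amap, alpha_grid=corrected, skin_corrected=True)


def estimate_skin_background(
    amap: AbsorbanceMap,
    reference_mask: np.ndarray,
    expected_reference_alpha: float,
) -> float:
    """Estimate the skin optical depth from a known tumor-free region.

    The excess of the mask-mean alpha over the expected tissue alpha is
    attributed entirely to skin:  ``d * (mean - expected)``, floored at
    zero so noise never produces a negative optical depth.
    """
    mask = np.asarray(reference_mask, dtype=bool)
    if mask.shape != amap.shape:
        raise ValueError(f"mask shape {mask.shape} != map shape {amap.shape}")
    if not mask.any():
        raise ValueError("reference mask is empty")
    excess = float(amap.alpha_grid[mask].mean()) - expected_reference_alpha
    return max(0.0, amap.thickness_mm * excess)
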