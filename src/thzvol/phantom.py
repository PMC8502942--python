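"""Synthetic tissue phantoms and the forward transmission-imaging model.

A phantom is a flat slab of fatty tissue sandwiched between two cover
glasses, with zero or more disc-shaped tumor inclusions that raise the
local absorption coefficient, plus a uniform skin layer modeled as a
position-independent optical depth.  The forward model is pure
Beer-Lambert attenuation: the transmitted power at a pixel is

    I_s = I_b * exp(-(skin_optical_depth + alpha * d))

where ``alpha`` (mm^-1) is the tissue absorption coefficient at the
pixel, ``d`` (mm) the slab thickness and ``I_b`` the background power
measured through the cover glasses alone.  Detector noise is i.i.d.
multiplicative Gaussian on power with relative standard deviation
``1/snr``, which preserves positivity at any realistic signal-to-noise
ratio.

Pixel convention: the scan grid has ``ceil(field / pitch)`` pixels per
axis, row-major, 0-based, origin at the top-left corner; the center of
pixel ``(i, j)`` sits at ``((j + 0.5) * pitch, (i + 0.5) * pitch)`` in
(x, y) field coordinates.  A pixel belongs to a tumor disc iff its
center lies inside the disc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhantomSpec",
    "TissueMap",
    "AcquisitionConfig",
    "PowerRaster",
    "build_phantom",
    "simulate_scan",
    "simulate_spectral_panel",
]

#: Default fatty-tissue absorption coefficient (mm^-1), inside the
#: fatty band 1.400-1.450 mm^-1 used for image classification.
DEFAULT_FAT_ALPHA = 1.42


@dataclass(frozen=True)
class TumorRegion:
    """A disc-shaped inclusion of elevated absorption.

    ``alpha_excess`` is added on top of the fatty baseline for every
    pixel whose center falls inside the disc.
    """

    center_x_mm: float
    center_y_mm: float
    radius_mm: float
    alpha_excess: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"tumor radius must be > 0, got {self.radius_mm}")
        if self.alpha_excess < 0:
            raise ValueError(
                f"tumor alpha_excess must be >= 0, got {self.alpha_excess}"
            )


def _as_region(r: "TumorRegion | Sequence[float]") -> TumorRegion:
    if isinstance(r, TumorRegion):
        return r
    return TumorRegion(*r)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and optical parameters of a synthetic phantom.

    Parameters
    ----------
    field_width_mm, field_height_mm:
        Scan area (default 10 x 10 mm^2).
    pixel_pitch_mm:
        Raster step of the X-Y scan; the grid is ``ceil(field / pitch)``
        pixels per axis.
    sandwich_thickness_mm:
        Thickness ``d`` of the glass-sandwiched tissue slab.
    skin_optical_depth:
        Dimensionless ln-attenuation contributed by the (uniform) skin
        layer; modeled as an optical depth because skin thickness is
        not resolved separately.
    fat_alpha:
        Absorption coefficient of the fatty background (mm^-1).
    tumor_regions:
        Disc inclusions, each ``(center_x_mm, center_y_mm, radius_mm,
        alpha_excess)``; every disc must lie fully inside the field.
    """

    field_width_mm: float = 10.0
    field_height_mm: float = 10.0
    pixel_pitch_mm: float = 0.1
    sandwich_thickness_mm: float = 0.5
    skin_optical_depth: float = 0.0
    fat_alpha: float = DEFAULT_FAT_ALPHA
    tumor_regions: tuple[TumorRegion, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_pitch_mm <= 0:
            raise ValueError(f"pixel pitch must be > 0, got {self.pixel_pitch_mm}")
        if self.field_width_mm <= 0 or self.field_height_mm <= 0:
            raise ValueError("field dimensions must be > 0")
        if self.sandwich_thickness_mm <= 0:
            raise ValueError("sandwich thickness must be > 0")
        if self.fat_alpha <= 0:
            raise ValueError(f"fat_alpha must be > 0, got {self.fat_alpha}")
        if self.skin_optical_depth < 0:
            raise ValueError("skin_optical_depth must be >= 0")
        regions = tuple(_as_region(r) for r in self.tumor_regions)
        object.__setattr__(self, "tumor_regions", regions)
        for r in regions:
            if (
                r.center_x_mm - r.radius_mm < 0
                or r.center_x_mm + r.radius_mm > self.field_width_mm
                or r.center_y_mm - r.radius_mm < 0
                or r.center_y_mm + r.radius_mm > self.field_height_mm
            ):
                raise ValueError(
                    f"tumor region {r} extends outside the "
                    f"{self.field_width_mm} x {self.field_height_mm} mm field"
                )

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of the scan grid."""
        return (
            math.ceil(self.field_height_mm / self.pixel_pitch_mm),
            math.ceil(self.field_width_mm / self.pixel_pitch_mm),
        )


@dataclass(frozen=True)
class TissueMap:
    """Ground-truth per-pixel tissue absorption (skin excluded)."""

    alpha_grid: np.ndarray
    skin_optical_depth: float
    thickness_mm: float
    pitch_mm: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.alpha_grid, dtype=float)
        object.__setattr__(self, "alpha_grid", grid)
        if grid.ndim != 2:
            raise ValueError("alpha_grid must be 2-D")
        if not np.all(np.isfinite(grid)) or np.any(grid <= 0):
            raise ValueError("alpha_grid must be finite and strictly positive")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Detector and scan-protocol settings for one imaging session.

    ``snr`` is the signal-to-noise ratio of the detection chain: each
    replicate scan multiplies the noiseless power by an independent
    Gaussian factor of mean 1 and standard deviation ``1/snr``.  Pass
    ``math.inf`` to disable noise.
    """

    frequency_ghz: float = 108.0
    background_power: float = 1.0
    snr: float = 1e4
    n_replicates: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError(f"snr must be > 0, got {self.snr}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.background_power <= 0:
            raise ValueError("background_power must be > 0")


@dataclass(frozen=True)
class PowerRaster:
    """One replicate scan of transmitted power I_s with its background I_b."""

    power_grid: np.ndarray
    background_power: float
    frequency_ghz: float
    pitch_mm: float
    replicate_index: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.power_grid, dtype=float)
        object.__setattr__(self, "power_grid", grid)
        if np.any(grid <= 0) or not np.all(np.isfinite(grid)):
            raise ValueError("transmitted powers must be finite and > 0")
        if self.background_power <= 0:
            raise ValueError("background_power must be > 0")


def pixel_centers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (X, Y) field coordinates (mm) of every pixel center."""
    ny, nx = spec.grid_shape
    x = (np.arange(nx) + 0.5) * spec.pixel_pitch_mm
    y = (np.arange(ny) + 0.5) * spec.pixel_pitch_mm
    return np.meshgrid(x, y)


def build_phantom(spec: PhantomSpec) -> TissueMap:
    """Rasterize a :class:`PhantomSpec` into a ground-truth tissue map.

    Where several discs overlap a pixel, the largest ``alpha_excess``
    wins (inclusions do not stack).
    """
    X, Y = pixel_centers(spec)
    excess = np.zeros_like(X)
    for r in spec.tumor_regions:
        inside = (X - r.center_x_mm) ** 2 + (Y - r.center_y_mm) ** 2 <= r.radius_mm**2
        excess = np.where(inside, np.maximum(excess, r.alpha_excess), excess)
    return TissueMap(
        alpha_grid=spec.fat_alpha + excess,
        skin_optical_depth=spec.skin_optical_depth,
        thickness_mm=spec.sandwich_thickness_mm,
        pitch_mm=spec.pixel_pitch_mm,
    )


def noiseless_power(tissue: TissueMap, background_power: float = 1.0) -> np.ndarray:
    """Beer-Lambert forward model: I_b * exp(-(skin_od + alpha * d))."""
    optical_depth = tissue.skin_optical_depth + tissue.alpha_grid * tissue.thickness_mm
    return background_power * np.exp(-optical_depth)


def simulate_scan(
    tissue: TissueMap, acq: AcquisitionConfig | None = None
) -> list[PowerRaster]:
    """Simulate ``n_replicates`` noisy transmitted-power rasters.

    Each replicate draws independent multiplicative Gaussian noise with
    relative standard deviation ``1/snr``; powers are floored at the
    smallest positive float so the Beer-Lambert inversion stays defined
    even for pathological noise draws.  Fully reproducible for a fixed
    ``acq.rng_seed``.
    """
    acq = acq or AcquisitionConfig()
    clean = noiseless_power(tissue, acq.background_power)
    rng = np.random.default_rng(acq.rng_seed)
    rasters = []
    for k in range(acq.n_replicates):
        if math.isinf(acq.snr):
            power = clean.copy()
        else:
            factor = rng.normal(loc=1.0, scale=1.0 / acq.snr, size=clean.shape)
            power = np.clip(clean * factor, np.finfo(float).tiny, None)
        rasters.append(
            PowerRaster(
                power_grid=power,
                background_power=acq.background_power,
                frequency_ghz=acq.frequency_ghz,
                pitch_mm=tissue.pitch_mm,
                replicate_index=k,
            )
        )
    return rasters


def simulate_spectral_panel(
    tissue_alphas: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    frequencies_ghz: Sequence[float],
    n_animals: int,
    thickness_mm: float,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-animal, per-tissue spectroscopy panel.

    For each tissue, ``tissue_alphas[label] = (means, sds)`` gives the
    population mean and standard deviation of the absorption
    coefficient at each frequency.  Each animal's true alpha is drawn
    from a normal law truncated at 0 and converted to a transmitted
    power ratio I_s/I_b through the Beer-Lambert forward model.

    Returns a tidy DataFrame with columns ``animal``, ``tissue``,
    ``frequency_ghz``, ``true_alpha``, ``power_ratio``.
    """
    freqs = np.asarray(frequencies_ghz, dtype=float)
    if freqs.size == 0:
        raise ValueError("frequency list must not be empty")
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if thickness_mm <= 0:
        raise ValueError("thickness must be > 0")

    rng = np.random.default_rng(rng_seed)
    records = []
    for tissue, (means, sds) in tissue_alphas.items():
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        if means.shape != freqs.shape or sds.shape != freqs.shape:
            raise ValueError(
                f"tissue {tissue!r}: means/sds must match the frequency grid"
            )
        if np.any(means <= 0):
            raise ValueError(f"tissue {tissue!r}: mean alphas must be > 0")
        if np.any(sds < 0):
            raise ValueError(f"tissue {tissue!r}: alpha SDs must be >= 0")
        for animal in range(n_animals):
            for f, m, s in zip(freqs, means, sds):
                if s == 0:
                    alpha = m
                else:
                    # normal truncated at zero: alpha stays physical
                    alpha = stats.truncnorm.rvs(
                        a=-m / s, b=np.inf, loc=m, scale=s, random_state=rng
                    )
                records.append(
                    {
                        "animal": animal,
                        "tissue": tissue,
                        "frequency_ghz": f,
                        "true_alpha": alpha,
                        "power_ratio": math.exp(-alpha * thickness_mm),
                    }
                )
    return pd.DataFrame.from_records(records)
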