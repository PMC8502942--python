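"""Threshold segmentation of absorbance maps into fatty background and cancer.

Classification uses fixed absorption-coefficient bands (mm^-1):
background (fatty tissue) for 1.400 <= alpha < 1.450, cancer for
1.450 <= alpha < 1.600, saturated at and above 1.600, below-range
otherwise.  Band edges are half-open so every pixel lands in exactly
one class, and a boundary value goes to the upper class — the
conservative choice for detection.

The absorption change delta_alpha of a map is the mean alpha over the
cancer region (saturated pixels included) minus the mean over the
fatty background; as a difference of means it is invariant under any
residual constant offset left by an imperfect skin calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
from PIL import Image

from .absorbance import AbsorbanceMap

__all__ = [
    "PixelClass",
    "ClassBands",
    "LabelMap",
    "RegionSummary",
    "classify_pixels",
    "summarize_regions",
    "remove_small_components",
    "render_image",
]


class PixelClass(IntEnum):
    BELOW_RANGE = 0
    BACKGROUND = 1
    CANCER = 2
    SATURATED = 3


@dataclass(frozen=True)
class ClassBands:
    """Absorption-coefficient class edges (mm^-1) for the false-color scale."""

    background_low: float = 1.400
    background_high: float = 1.450
    cancer_high: float = 1.600

    def __post_init__(self) -> None:
        if not (self.background_low < self.background_high < self.cancer_high):
            raise ValueError(
                "bands must satisfy background_low < background_high < cancer_high, "
                f"got {self.background_low}, {self.background_high}, {self.cancer_high}"
            )


DEFAULT_BANDS = ClassBands()


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel class labels together with the bands that produced them."""

    label_grid: np.ndarray
    bands: ClassBands
    pitch_mm: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.label_grid, dtype=np.int8)
        object.__setattr__(self, "label_grid", grid)

    def count(self, cls: PixelClass) -> int:
        return int(np.count_nonzero(self.label_grid == cls))


@dataclass(frozen=True)
class RegionSummary:
    """Region means and the absorption change delta_alpha (mm^-1).

    ``n_cancer_pixels`` and ``mean_cancer_alpha`` cover the union of
    cancer and saturated pixels, so that delta_alpha reflects the full
    lesion even where the color scale clips.  ``cancer_empty`` flags a
    map with no cancer pixels, for which delta_alpha is reported as 0.
    """

    mean_background_alpha: float
    mean_cancer_alpha: float
    delta_alpha: float
    n_background_pixels: int
    n_cancer_pixels: int
    cancer_area_mm2: float
    cancer_empty: bool = False


def classify_pixels(
    amap: AbsorbanceMap, bands: ClassBands = DEFAULT_BANDS
) -> LabelMap:
    """Assign every pixel to exactly one absorption band.

    Requires a skin-corrected map: the bands are calibrated to tissue
    alpha without the skin contribution.
    """
    if not amap.skin_corrected:
        raise ValueError("classify_pixels requires a skin-corrected absorbance map")
    a = amap.alpha_grid
    labels = np.select(
        [
            a >= bands.cancer_high,
            a >= bands.background_high,
            a >= bands.background_low,
        ],
        [PixelClass.SATURATED, PixelClass.CANCER, PixelClass.BACKGROUND],
        default=PixelClass.BELOW_RANGE,
    )
    return LabelMap(label_grid=labels, bands=bands, pitch_mm=amap.pitch_mm)


def remove_small_components(labels: LabelMap, min_pixels: int) -> LabelMap:
    """Optional cleanup: relabel cancer/saturated blobs below ``min_pixels``
    as background.  Off by default in the pipeline — the reference
    analysis is pure thresholding.
    """
    if min_pixels <= 1:
        return labels
    from scipy import ndimage

    grid = labels.label_grid.copy()
    lesion = (grid == PixelClass.CANCER) | (grid == PixelClass.SATURATED)
    comp, n = ndimage.label(lesion)
    for k in range(1, n + 1):
        blob = comp == k
        if blob.sum() < min_pixels:
            grid[blob] = PixelClass.BACKGROUND
    return LabelMap(label_grid=grid, bands=labels.bands, pitch_mm=labels.pitch_mm)


def summarize_regions(amap: AbsorbanceMap, labels: LabelMap) -> RegionSummary:
    """Compute region means, delta_alpha and the lesion area.

    delta_alpha = mean(cancer union saturated) - mean(background).
    An empty background class is an error (no reference level); an
    empty cancer class yields delta_alpha = 0 with a warning.
    """
    if labels.label_grid.shape != amap.shape:
        raise ValueError(
            f"label shape {labels.label_grid.shape} != map shape {amap.shape}"
        )
    a = amap.alpha_grid
    grid = labels.label_grid
    bg = grid == PixelClass.BACKGROUND
    cancer = (grid == PixelClass.CANCER) | (grid == PixelClass.SATURATED)
    n_bg = int(bg.sum())
    n_cancer = int(cancer.sum())
    if n_bg == 0:
        raise ValueError("no background pixels: cannot establish a reference level")
    mean_bg = float(a[bg].mean())
    if n_cancer == 0:
        warnings.warn("no cancer pixels found; delta_alpha set to 0", stacklevel=2)
        mean_cancer = float("nan")
        delta = 0.0
    else:
        mean_cancer = float(a[cancer].mean())
        delta = mean_cancer - mean_bg
    return RegionSummary(
        mean_background_alpha=mean_bg,
        mean_cancer_alpha=mean_cancer,
        delta_alpha=delta,
        n_background_pixels=n_bg,
        n_cancer_pixels=n_cancer,
        cancer_area_mm2=n_cancer * labels.pitch_mm**2,
        cancer_empty=n_cancer == 0,
    )


def render_image(
    amap: AbsorbanceMap,
    bands: ClassBands = DEFAULT_BANDS,
    out_path: str | Path | None = None,
    zoom: int = 4,
    cmap: str = "jet",
) -> Image.Image:
    """Render the false-color image on a blue-to-red scale.

    The color scale is clamped to [background_low, cancer_high]; any
    alpha at or above the upper edge renders as the maximal (red)
    color.  Clamping affects display only — stored alpha values are
    never modified.  The output has ``grid_shape * zoom`` pixels.
    """
    if zoom < 1:
        raise ValueError("zoom must be a positive integer")
    import matplotlib

    lo, hi = bands.background_low, bands.cancer_high
    norm = np.clip((amap.alpha_grid - lo) / (hi - lo), 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](norm)
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb = np.repeat(np.repeat(rgb, zoom, axis=0), zoom, axis=1)
    img = Image.fromarray(rgb, mode="RGB")
    if out_path is not None:
        img.save(Path(out_path), format="PNG")
    return img
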