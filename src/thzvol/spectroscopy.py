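"""Per-tissue absorption spectra over the 108-143 GHz band.

Converts measured power ratios I_s/I_b to absorption coefficients per
frequency, aggregates across animals (mean and standard deviation of
the mean), and quantifies how well two tissue spectra separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BAND_GHZ",
    "DEFAULT_FREQUENCIES_GHZ",
    "AbsorptionSpectrum",
    "compute_spectrum",
    "aggregate_spectra",
    "separability",
    "SeparabilityResult",
]

#: Frequency band of the spectroscopy measurements (GHz).
BAND_GHZ = (108.0, 143.0)

#: Default frequency grid: the band endpoints in 5 GHz steps.
DEFAULT_FREQUENCIES_GHZ = tuple(float(f) for f in range(108, 144, 5))

_TISSUES = frozenset({"skin", "fat", "cancer"})


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Aggregated absorption spectrum of one tissue type.

    ``alpha_sd`` is the standard deviation of the mean (sample SD over
    animals divided by sqrt(n)), i.e. the error bar of the mean curve.
    """

    tissue_label: str
    frequencies_ghz: tuple[float, ...]
    alpha_mean: tuple[float, ...]
    alpha_sd: tuple[float, ...]
    n_animals: int

    def __post_init__(self) -> None:
        if self.tissue_label not in _TISSUES:
            raise ValueError(
                f"tissue_label must be one of {sorted(_TISSUES)}, "
                f"got {self.tissue_label!r}"
            )
        f = np.asarray(self.frequencies_ghz, dtype=float)
        m = np.asarray(self.alpha_mean, dtype=float)
        s = np.asarray(self.alpha_sd, dtype=float)
        if not (f.size == m.size == s.size):
            raise ValueError("frequencies, means and SDs must share length")
        if f.size and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if f.size and (f[0] < BAND_GHZ[0] or f[-1] > BAND_GHZ[1]):
            raise ValueError(f"frequencies must lie within {BAND_GHZ} GHz")
        if np.any(s < 0):
            raise ValueError("alpha_sd must be >= 0")
        object.__setattr__(self, "frequencies_ghz", tuple(f))
        object.__setattr__(self, "alpha_mean", tuple(m))
        object.__setattr__(self, "alpha_sd", tuple(s))


def compute_spectrum(
    power_ratios: Sequence[float], thickness_mm: float
) -> np.ndarray:
    """alpha(f) = ln(1 / ratio) / d for one animal and tissue.

    Ratios must lie in (0, 1]: a transmission above the background
    level cannot come from pure attenuation.
    """
    if thickness_mm <= 0:
        raise ValueError(f"thickness must be > 0, got {thickness_mm}")
    r = np.asarray(power_ratios, dtype=float)
    if np.any(r <= 0) or np.any(r > 1):
        bad = r[(r <= 0) | (r > 1)][0]
        raise ValueError(f"power ratios must lie in (0, 1], got {bad}")
    return np.log(1.0 / r) / thickness_mm


def aggregate_spectra(
    per_animal_alphas: Sequence[Sequence[float]],
    frequencies_ghz: Sequence[float],
    tissue_label: str,
) -> AbsorptionSpectrum:
    """Aggregate per-animal alpha curves into a mean spectrum.

    The error bar is the standard deviation of the mean: sample SD
    (ddof=1) over animals divided by sqrt(n).  Needs at least two
    animals on a common frequency grid.
    """
    alphas = np.asarray(per_animal_alphas, dtype=float)
    freqs = np.asarray(frequencies_ghz, dtype=float)
    if alphas.ndim != 2:
        raise ValueError("per_animal_alphas must be a 2-D (animals x freq) array")
    n = alphas.shape[0]
    if n < 2:
        raise ValueError("need at least two animals to aggregate")
    if alphas.shape[1] != freqs.size:
        raise ValueError(
            f"alpha curves have {alphas.shape[1]} points but grid has {freqs.size}"
        )
    sem = alphas.std(axis=0, ddof=1) / np.sqrt(n)
    return AbsorptionSpectrum(
        tissue_label=tissue_label,
        frequencies_ghz=tuple(freqs),
        alpha_mean=tuple(alphas.mean(axis=0)),
        alpha_sd=tuple(sem),
        n_animals=n,
    )


@dataclass(frozen=True)
class SeparabilityResult:
    """Per-frequency standardized gap between two spectra and the
    overall separability flag (gap > 2 everywhere)."""

    gap: tuple[float, ...]
    separable: bool


def separability(
    spec_a: AbsorptionSpectrum, spec_b: AbsorptionSpectrum
) -> SeparabilityResult:
    """Standardized gap (mean_a - mean_b) / sqrt(sd_a^2 + sd_b^2) per
    frequency; the flag is set when the gap exceeds 2 at every point.

    Antisymmetric in the argument order.  With both SDs zero the gap is
    0 for equal means, +/-inf otherwise.
    """
    fa = np.asarray(spec_a.frequencies_ghz)
    fb = np.asarray(spec_b.frequencies_ghz)
    if fa.shape != fb.shape or not np.allclose(fa, fb):
        raise ValueError("spectra are on different frequency grids")
    diff = np.asarray(spec_a.alpha_mean) - np.asarray(spec_b.alpha_mean)
    pooled = np.sqrt(
        np.asarray(spec_a.alpha_sd) ** 2 + np.asarray(spec_b.alpha_sd) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        gap = np.where(
            pooled > 0,
            diff / np.where(pooled > 0, pooled, 1.0),
            np.where(diff == 0, 0.0, np.sign(diff) * np.inf),
        )
    return SeparabilityResult(gap=tuple(gap), separable=bool(np.all(gap > 2)))
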