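"""End-to-end analysis: phantom or raster files -> absorbance -> skin
calibration -> segmentation -> delta_alpha -> volume report.

One :class:`PipelineConfig` describes one subject.  The stages are

1. simulate the replicate scans from a phantom spec, or load raster
   files from disk;
2. invert each replicate to an absorbance map (Beer-Lambert);
3. average the replicates pixelwise;
4. subtract the uniform skin background (fixed optical depth, or
   estimated from a tumor-free border frame);
5. classify pixels into the absorption bands;
6. summarize regions (delta_alpha) and convert to a volume estimate.

Identical config and seed give byte-identical reports.  For panels of
several subjects, each subject gets its own RNG stream derived from the
master seed and the subject index, so adding a subject never perturbs
the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .absorbance import (
    AbsorbanceMap,
    average_replicates,
    calibrate_skin_background,
    compute_absorbance,
    estimate_skin_background,
)
from .phantom import AcquisitionConfig, PhantomSpec, build_phantom, simulate_scan
from .segmentation import (
    ClassBands,
    LabelMap,
    RegionSummary,
    classify_pixels,
    remove_small_components,
    render_image,
    summarize_regions,
)
from .volumetry import (
    DEFAULT_CALIBRATION,
    VolumeEstimate,
    VolumetryCalibration,
    estimate_volume,
    round_half_up,
)

__all__ = [
    "SkinEstimateConfig",
    "PipelineConfig",
    "PipelineReport",
    "PanelReport",
    "PipelineStageError",
    "run_pipeline",
    "run_mouse_panel",
]

logger = logging.getLogger("thzvol")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        super().__init__(f"[subject {subject_id}] stage {stage!r} failed: {cause}")
        self.stage = stage
        self.subject_id = subject_id
        self.cause = cause


@dataclass(frozen=True)
class SkinEstimateConfig:
    """Estimate the skin optical depth from the border frame of the map,
    assumed tumor-free fatty tissue of known alpha."""

    expected_reference_alpha: float
    border_margin_mm: float = 1.0


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to analyze one subject.

    Exactly one of ``phantom`` (simulate) or ``raster_paths`` (load
    from disk) must be given.  Skin handling is either a fixed
    ``skin_optical_depth`` or a :class:`SkinEstimateConfig`; exactly
    one must be set.
    """

    subject_id: str = "subject-0"
    phantom: PhantomSpec | None = None
    raster_paths: tuple[str, ...] | None = None
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    thickness_mm: float | None = None
    skin_optical_depth: float | None = None
    skin_estimate: SkinEstimateConfig | None = None
    bands: ClassBands = field(default_factory=ClassBands)
    calibration: VolumetryCalibration = DEFAULT_CALIBRATION
    min_component_pixels: int = 0
    output_dir: str | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.raster_paths is None):
            raise ValueError(
                "exactly one input source (phantom | raster_paths) must be set"
            )
        if (self.skin_optical_depth is None) == (self.skin_estimate is None):
            raise ValueError(
                "exactly one skin handling mode "
                "(skin_optical_depth | skin_estimate) must be set"
            )
        if self.skin_optical_depth is not None and self.skin_optical_depth < 0:
            raise ValueError("skin_optical_depth must be >= 0")
        if self.raster_paths is not None and self.thickness_mm is None:
            raise ValueError("thickness_mm is required when loading raster files")

    @property
    def effective_thickness_mm(self) -> float:
        if self.thickness_mm is not None:
            return self.thickness_mm
        assert self.phantom is not None
        return self.phantom.sandwich_thickness_mm


@dataclass(frozen=True)
class PipelineReport:
    """Per-subject result of a pipeline run."""

    subject_id: str
    region_summary: RegionSummary
    volume_estimate: VolumeEstimate
    absorbance_map: AbsorbanceMap
    label_map: LabelMap
    output_paths: dict[str, str]

    def row(self) -> dict[str, float | str | int]:
        rs, ve = self.region_summary, self.volume_estimate
        return {
            "subject": self.subject_id,
            "delta_alpha_mm^-1": round_half_up(rs.delta_alpha, 3),
            "sigma_mm^2": ve.sigma,
            "n_prime_mm^-3": ve.n_prime,
            "volume_mm^3": round_half_up(ve.volume_mm3, 3),
            "v_over_delta_alpha": ve.calibration.v_effective
            / ve.calibration.alpha_ref,
            "n_cancer_pixels": rs.n_cancer_pixels,
            "cancer_area_mm^2": rs.cancer_area_mm2,
        }


def _border_mask(shape: tuple[int, int], margin_mm: float, pitch_mm: float) -> np.ndarray:
    k = max(1, int(round(margin_mm / pitch_mm)))
    mask = np.zeros(shape, dtype=bool)
    mask[:k, :] = mask[-k:, :] = True
    mask[:, :k] = mask[:, -k:] = True
    return mask


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full single-subject analysis chain."""
    sid = config.subject_id

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raise with context
                raise PipelineStageError(name, sid, e) from e

        return deco

    d = config.effective_thickness_mm

    def _acquire():
        if config.phantom is not None:
            spec = config.phantom
            acq = config.acquisition
            if config.rng_seed is not None:
                spec = replace(spec, rng_seed=config.rng_seed)
                acq = replace(acq, rng_seed=config.rng_seed)
            tissue = build_phantom(spec)
            return simulate_scan(tissue, acq)
        return [tio.read_raster(p) for p in config.raster_paths]

    rasters = stage("acquire")(_acquire)
    logger.info("[%s] acquired %d replicate raster(s)", sid, len(rasters))

    maps = stage("absorbance")(
        lambda: [compute_absorbance(r, d) for r in rasters]
    )
    averaged = stage("average")(lambda: average_replicates(maps))

    def _skin():
        if config.skin_optical_depth is not None:
            depth = config.skin_optical_depth
        else:
            est = config.skin_estimate
            mask = _border_mask(averaged.shape, est.border_margin_mm, averaged.pitch_mm)
            depth = estimate_skin_background(
                averaged, mask, est.expected_reference_alpha
            )
            logger.info("[%s] estimated skin optical depth %.4f", sid, depth)
        return calibrate_skin_background(averaged, depth)

    corrected = stage("skin_calibration")(_skin)

    def _segment():
        labels = classify_pixels(corrected, config.bands)
        if config.min_component_pixels > 1:
            labels = remove_small_components(labels, config.min_component_pixels)
        return labels

    labels = stage("classify")(_segment)
    summary = stage("summarize")(lambda: summarize_regions(corrected, labels))
    volume = stage("volumetry")(
        lambda: estimate_volume(max(0.0, summary.delta_alpha), config.calibration)
    )
    logger.info(
        "[%s] delta_alpha=%.4f mm^-1 -> V=%.3f mm^3",
        sid,
        summary.delta_alpha,
        volume.volume_mm3,
    )

    paths: dict[str, str] = {}
    if config.output_dir is not None:
        out = Path(config.output_dir) / sid
        out.mkdir(parents=True, exist_ok=True)
        paths["absorbance"] = str(tio.write_absorbance(corrected, out / "absorbance.txt"))
        paths["labels"] = str(tio.write_labels(labels, out / "labels.txt"))
        render_image(corrected, config.bands, out / "image.png")
        paths["image"] = str(out / "image.png")
        report = PipelineReport(sid, summary, volume, corrected, labels, paths)
        table = pd.DataFrame([report.row()])
        table.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.6g")
        paths["report"] = str(out / "report.tsv")
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(_config_provenance(config), fh, sort_keys=True)
        paths["config"] = str(out / "resolved_config.yaml")
        return report

    return PipelineReport(sid, summary, volume, corrected, labels, paths)


def _config_provenance(config: PipelineConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    if d.get("acquisition", {}).get("snr") == float("inf"):
        d["acquisition"]["snr"] = "inf"
    return d


@dataclass(frozen=True)
class PanelReport:
    """Combined report over several subjects."""

    table: pd.DataFrame
    reports: tuple[PipelineReport, ...]
    failures: tuple[tuple[str, str], ...]  # (subject_id, message)


def run_mouse_panel(
    configs: Sequence[PipelineConfig], master_seed: int | None = None
) -> PanelReport:
    """Analyze a panel of subjects; one row per subject.

    Per-subject failures are collected and reported while the rest of
    the panel continues.  With ``master_seed`` given, subject ``i``
    runs with an independent seed derived from ``(master_seed, i)``.
    """
    if not configs:
        raise ValueError("panel needs at least one subject config")
    reports: list[PipelineReport] = []
    failures: list[tuple[str, str]] = []
    for i, cfg in enumerate(configs):
        if master_seed is not None:
            sub_seed = int(
                np.random.SeedSequence([master_seed, i]).generate_state(1)[0]
                % (2**31)
            )
            cfg = replace(cfg, rng_seed=sub_seed)
        try:
            reports.append(run_pipeline(cfg))
        except PipelineStageError as e:
            logger.error("%s", e)
            failures.append((cfg.subject_id, str(e)))
    table = pd.DataFrame([r.row() for r in reports])
    return PanelReport(table=table, reports=tuple(reports), failures=tuple(failures))
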