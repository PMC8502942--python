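"""Plain-text serialization: delimited grids with YAML metadata sidecars,
and YAML round-tripping of phantom / acquisition / pipeline configs.

A grid file ``foo.txt`` is whitespace-delimited, one line per pixel row,
period decimal separator; its sidecar ``foo.meta.yaml`` carries units
and acquisition metadata.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .absorbance import AbsorbanceMap
from .phantom import AcquisitionConfig, PhantomSpec, PowerRaster, TumorRegion
from .segmentation import ClassBands, LabelMap

__all__ = [
    "sidecar_path",
    "write_grid",
    "read_grid",
    "write_raster",
    "read_raster",
    "write_absorbance",
    "read_absorbance",
    "write_labels",
    "read_labels",
    "phantom_spec_to_yaml",
    "phantom_spec_from_yaml",
    "acquisition_to_yaml",
    "acquisition_from_yaml",
]

_FLOAT_FMT = "%.12g"


def sidecar_path(grid_path: str | Path) -> Path:
    p = Path(grid_path)
    return p.with_name(p.stem + ".meta.yaml")


def write_grid(path: str | Path, grid: np.ndarray, metadata: dict[str, Any]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = "%d" if np.issubdtype(np.asarray(grid).dtype, np.integer) else _FLOAT_FMT
    np.savetxt(path, np.asarray(grid), fmt=fmt)
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=True)
    return path


def read_grid(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    path = Path(path)
    grid = np.loadtxt(path, ndmin=2)
    meta_file = sidecar_path(path)
    metadata: dict[str, Any] = {}
    if meta_file.exists():
        with open(meta_file) as fh:
            metadata = yaml.safe_load(fh) or {}
    return grid, metadata


def write_raster(raster: PowerRaster, path: str | Path) -> Path:
    return write_grid(
        path,
        raster.power_grid,
        {
            "kind": "power_raster",
            "units": "arbitrary_power",
            "background_power": float(raster.background_power),
            "frequency_ghz": float(raster.frequency_ghz),
            "pitch_mm": float(raster.pitch_mm),
            "replicate_index": int(raster.replicate_index),
        },
    )


def read_raster(path: str | Path) -> PowerRaster:
    grid, meta = read_grid(path)
    if meta.get("kind") not in (None, "power_raster"):
        raise ValueError(f"{path} is a {meta.get('kind')}, not a power raster")
    return PowerRaster(
        power_grid=grid,
        background_power=float(meta.get("background_power", 1.0)),
        frequency_ghz=float(meta.get("frequency_ghz", 108.0)),
        pitch_mm=float(meta.get("pitch_mm", 0.1)),
        replicate_index=int(meta.get("replicate_index", 0)),
    )


def write_absorbance(amap: AbsorbanceMap, path: str | Path) -> Path:
    return write_grid(
        path,
        amap.alpha_grid,
        {
            "kind": "absorbance_map",
            "units": "mm^-1",
            "thickness_mm": float(amap.thickness_mm),
            "pitch_mm": float(amap.pitch_mm),
            "frequency_ghz": float(amap.frequency_ghz),
            "skin_corrected": bool(amap.skin_corrected),
            "n_replicates_averaged": int(amap.n_replicates_averaged),
        },
    )


def read_absorbance(path: str | Path) -> AbsorbanceMap:
    grid, meta = read_grid(path)
    if meta.get("kind") not in (None, "absorbance_map"):
        raise ValueError(f"{path} is a {meta.get('kind')}, not an absorbance map")
    if "thickness_mm" not in meta:
        raise ValueError(f"{path}: sidecar must state thickness_mm")
    return AbsorbanceMap(
        alpha_grid=grid,
        thickness_mm=float(meta["thickness_mm"]),
        pitch_mm=float(meta.get("pitch_mm", 0.1)),
        frequency_ghz=float(meta.get("frequency_ghz", 108.0)),
        skin_corrected=bool(meta.get("skin_corrected", False)),
        n_replicates_averaged=int(meta.get("n_replicates_averaged", 1)),
    )


def write_labels(labels: LabelMap, path: str | Path) -> Path:
    return write_grid(
        path,
        labels.label_grid.astype(int),
        {
            "kind": "label_map",
            "classes": {
                "0": "below_range",
                "1": "background",
                "2": "cancer",
                "3": "saturated",
            },
            "bands": asdict(labels.bands),
            "pitch_mm": float(labels.pitch_mm),
        },
    )


def read_labels(path: str | Path) -> LabelMap:
    grid, meta = read_grid(path)
    bands = ClassBands(**meta["bands"]) if "bands" in meta else ClassBands()
    return LabelMap(
        label_grid=grid.astype(np.int8),
        bands=bands,
        pitch_mm=float(meta.get("pitch_mm", 0.1)),
    )


def _spec_to_dict(spec: PhantomSpec) -> dict[str, Any]:
    d = asdict(spec)
    d["tumor_regions"] = [
        [r.center_x_mm, r.center_y_mm, r.radius_mm, r.alpha_excess]
        for r in spec.tumor_regions
    ]
    return d


def phantom_spec_to_yaml(spec: PhantomSpec, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=True)
    return path


def phantom_spec_from_yaml(path: str | Path) -> PhantomSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return phantom_spec_from_dict(data)


def phantom_spec_from_dict(data: dict[str, Any]) -> PhantomSpec:
    data = dict(data)
    regions = tuple(
        TumorRegion(*r) if not isinstance(r, dict) else TumorRegion(**r)
        for r in data.pop("tumor_regions", [])
    )
    return PhantomSpec(tumor_regions=regions, **data)


def acquisition_to_yaml(acq: AcquisitionConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = asdict(acq)
    if d["snr"] == float("inf"):
        d["snr"] = "inf"
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
    return path


def acquisition_from_yaml(path: str | Path) -> AcquisitionConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return acquisition_from_dict(data)


def acquisition_from_dict(data: dict[str, Any]) -> AcquisitionConfig:
    data = dict(data)
    if isinstance(data.get("snr"), str):
        data["snr"] = float(data["snr"])
    return AcquisitionConfig(**data)
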