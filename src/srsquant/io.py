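"""File I/O: TIFF image stacks, CSV tables, and run logs.

TIFF is the interchange format for images (one page per frame; 8/16-bit
integer or 32-bit float grayscale); CSV carries measurement and test-result
tables; configuration is structured YAML.  The Raman band of a stack comes
from the run manifest, never from file metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError
from .quantify import RegionMeasurement
from .segmentation import SegmentationMask
from .unmixing import ConcentrationMaps, FrameStack

__all__ = ["read_band_image", "write_frame_stack", "write_measurements",
           "read_measurements", "write_test_results", "write_maps",
           "write_mask", "write_run_log"]

MEASUREMENT_COLUMNS = [
    "region_id", "condition", "timepoint", "n_cells", "ld_area_per_cell",
    "lipid_intensity_per_cell", "protein_intensity_per_cell",
    "cell_area_per_cell",
]


def read_band_image(path: str | Path, band: float = 0.0) -> FrameStack:
    """Read a single- or multi-page grayscale TIFF into a FrameStack.

    The page count becomes the frame count; ``band`` (cm⁻¹) is taken from
    the caller's manifest.  RGB/multichannel TIFFs and stacks with
    mismatched page sizes are rejected; unreadable files raise a
    :class:`FormatError` rather than propagating parser internals.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            pages = [p.asarray() for p in tf.pages]
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path} contains no image pages")
    for arr in pages:
        if arr.ndim != 2:
            raise FormatError(f"{path} is not single-channel grayscale")
        if arr.shape != pages[0].shape:
            raise FormatError(f"{path} has mismatched page sizes")
    return FrameStack(frames=np.stack(pages).astype(float), band=band,
                      meta={"path": str(path)})


def write_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a FrameStack as a multi-page float32 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    return path


def write_measurements(measurements: Iterable[RegionMeasurement],
                       path: str | Path) -> Path:
    """Write per-region measurements as CSV (header always present)."""
    rows = [{c: getattr(m, c) for c in MEASUREMENT_COLUMNS}
            for m in measurements]
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_measurements(path: str | Path) -> list[RegionMeasurement]:
    """Read a measurements CSV back into RegionMeasurement records."""
    df = pd.read_csv(path)
    return [
        RegionMeasurement(
            region_id=str(r.region_id), condition=str(r.condition),
            timepoint=float(r.timepoint), n_cells=int(r.n_cells),
            ld_area_per_cell=float(r.ld_area_per_cell),
            lipid_intensity_per_cell=float(r.lipid_intensity_per_cell),
            protein_intensity_per_cell=float(r.protein_intensity_per_cell),
            cell_area_per_cell=float(r.cell_area_per_cell),
        )
        for r in df.itertuples()
    ]


def write_test_results(table: pd.DataFrame, path: str | Path) -> Path:
    table = table.copy()
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def write_maps(maps: ConcentrationMaps, outdir: str | Path,
               prefix: str) -> list[Path]:
    """Write each concentration map and the residual image as float32 TIFF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, img in zip(maps.components, maps.maps):
        p = outdir / f"{prefix}_{name}_map.tif"
        tifffile.imwrite(p, img.astype(np.float32))
        paths.append(p)
    p = outdir / f"{prefix}_residual.tif"
    tifffile.imwrite(p, maps.residual.astype(np.float32))
    paths.append(p)
    return paths


def write_mask(mask: SegmentationMask, path: str | Path) -> Path:
    """Write a segmentation mask as an 8-bit TIFF (255 = foreground)."""
    path = Path(path)
    tifffile.imwrite(path, (mask.pixels.astype(np.uint8)) * 255)
    return path


def write_run_log(outdir: str | Path, config: dict, seed: int | None,
                  stages: dict) -> Path:
    """Persist a reproducibility log: config hash, seed, version, traces.

    ``stages`` carries per-region processing traces (applied thresholds,
    iteration counts, band assignments) so every number in the output CSVs
    can be traced to a logged stage.
    """
    from . import __version__

    config_json = json.dumps(config, sort_keys=True, default=str)
    log = {
        "software_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": json.loads(config_json),
        "stages": stages,
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "run_log.json"
    path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    return path
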