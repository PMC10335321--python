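"""Per-region, per-cell morphometric and intensity metrics.

All metrics are region-level: a mask or concentration map summarises one
imaged field, and the per-cell value is the regional total divided by the
number of cells in that field.  Cell counts are supplied per region (the
acquisition workflow counts them; phantoms supply the true count); an
optional connected-component estimate from the protein mask is available
but is not used unless asked for.

The physical pixel area defaults to 22.5 μm² per pixel, the pipeline-wide
constant, and is configurable (see docs/methods.md for the caveat on this
value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import skimage.measure

from .exceptions import ValidationError
from .segmentation import SegmentationMask
from .unmixing import ConcentrationMaps

__all__ = ["RegionMeasurement", "DEFAULT_PIXEL_AREA", "ld_area_per_cell",
           "total_intensity_per_cell", "cell_area_per_cell",
           "estimate_cell_count", "measure_region"]

#: μm² per pixel: the imaging constant used for all area metrics.
DEFAULT_PIXEL_AREA = 22.5


@dataclass
class RegionMeasurement:
    """Per-cell metrics for one imaged region."""

    region_id: str
    condition: str  # "0 Gy" or "30 Gy"
    timepoint: float  # hours post-irradiation
    n_cells: int
    ld_area_per_cell: float  # μm²
    lipid_intensity_per_cell: float  # arbitrary units
    protein_intensity_per_cell: float  # arbitrary units
    cell_area_per_cell: float  # μm²

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        for name in ("ld_area_per_cell", "lipid_intensity_per_cell",
                     "protein_intensity_per_cell", "cell_area_per_cell"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _mask_pixels(mask) -> np.ndarray:
    return mask.pixels if isinstance(mask, SegmentationMask) else np.asarray(mask)


def ld_area_per_cell(ld_mask, pixel_area: float, n_cells: int) -> float:
    """Masked area (pixels × μm²/pixel) divided by the region cell count."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if pixel_area <= 0:
        raise ValidationError("pixel_area must be positive")
    return float(_mask_pixels(ld_mask).sum() * pixel_area / n_cells)


def total_intensity_per_cell(concentration_map: np.ndarray, n_cells: int) -> float:
    """Sum of a concentration map over the region divided by the cell count."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    return float(np.asarray(concentration_map, dtype=float).sum() / n_cells)


def cell_area_per_cell(protein_mask, pixel_area: float, n_cells: int) -> float:
    """Protein-mask area (μm²) divided by the region cell count."""
    return ld_area_per_cell(protein_mask, pixel_area, n_cells)


def estimate_cell_count(protein_mask, min_cell_size: int = 50) -> int:
    """Connected-component estimate of the cell count from the protein mask.

    Touching cells merge into one component, so this undercounts dense
    fields; it exists as a fallback when no counted value is available.
    """
    labels = skimage.measure.label(_mask_pixels(protein_mask))
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes >= min_cell_size).sum())


def measure_region(
    region_id: str,
    condition: str,
    timepoint: float,
    maps: ConcentrationMaps,
    ld_mask: SegmentationMask,
    protein_mask: SegmentationMask,
    n_cells: int,
    pixel_area: float = DEFAULT_PIXEL_AREA,
) -> RegionMeasurement:
    """Assemble all per-cell metrics of one region into a record."""
    return RegionMeasurement(
        region_id=region_id,
        condition=condition,
        timepoint=timepoint,
        n_cells=n_cells,
        ld_area_per_cell=ld_area_per_cell(ld_mask, pixel_area, n_cells),
        lipid_intensity_per_cell=total_intensity_per_cell(
            maps.component("lipid"), n_cells),
        protein_intensity_per_cell=total_intensity_per_cell(
            maps.component("protein"), n_cells),
        cell_area_per_cell=cell_area_per_cell(protein_mask, pixel_area, n_cells),
    )
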