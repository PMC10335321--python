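"""Lipid-droplet and cell-area segmentation by (iterative) Otsu thresholding.

Lipid droplets occupy the brightest mode of the lipid concentration map but
sit above a cytoplasmic lipid background, so a single Otsu threshold — which
splits background from cells — does not isolate them.  The droplet mask is
therefore obtained by applying Otsu iteratively: each pass re-computes the
threshold on only the pixels above the previous one, climbing the intensity
modes until the threshold stabilises.  The cell-area mask is a single Otsu
pass on the protein map, where one threshold separates cells from
background.

Otsu's threshold maximises the between-class variance of a histogram over
``n_bins`` equal-width bins spanning [min, max]; candidate thresholds are
the interior bin edges and ties are broken toward the lowest qualifying
edge, making the procedure fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import skimage.measure

from .exceptions import DegenerateInputError

__all__ = ["SegmentationMask", "otsu_threshold", "iterative_otsu_ld_mask",
           "cell_area_mask"]


@dataclass
class SegmentationMask:
    """A binary mask plus the thresholding trace that produced it."""

    pixels: np.ndarray  # (H, W) bool
    source: str  # {"lipid", "protein"}
    thresholds_applied: list[float]
    warnings: list[str] = field(default_factory=list)

    @property
    def iterations(self) -> int:
        return len(self.thresholds_applied)

    @property
    def area_pixels(self) -> int:
        return int(self.pixels.sum())


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Between-class-variance-maximising threshold of an intensity image.

    The histogram spans [min, max] of the data with ``n_bins`` equal bins;
    the returned threshold is a bin edge, and among ties the lowest edge is
    chosen.  Pixels are classified as foreground when strictly above the
    threshold.
    """
    x = np.asarray(image, dtype=float).ravel()
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateInputError("constant image has no Otsu threshold")

    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    counts = counts.astype(float)
    total = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2

    w0 = np.cumsum(counts)  # class 0 = bins 0..i (below or at edge i+1)
    sum0 = np.cumsum(counts * centers)

    # candidate threshold after bin i is edges[i+1], i = 0..n_bins-2
    w0c = w0[:-1]
    w1c = total - w0c
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = sum0[:-1] / w0c
        mu1 = (sum0[-1] - sum0[:-1]) / w1c
        sigma_b = w0c * w1c * (mu0 - mu1) ** 2
    sigma_b[(w0c == 0) | (w1c == 0)] = -np.inf
    if not np.isfinite(sigma_b).any():
        raise DegenerateInputError("histogram collapsed to a single bin")
    best = int(np.argmax(sigma_b))  # argmax takes the first (lowest) tie
    return float(edges[best + 1])


def _split_effectiveness(values: np.ndarray, threshold: float) -> float:
    """Otsu effectiveness η = between-class variance / total variance.

    η near 1 indicates a genuine bimodal split; splitting a single
    Gaussian noise mode at its optimum yields η ≈ 2/π ≈ 0.64.
    """
    total_var = values.var()
    if total_var == 0:
        return 0.0
    g1 = values[values <= threshold]
    g2 = values[values > threshold]
    if g1.size == 0 or g2.size == 0:
        return 0.0
    w1 = g1.size / values.size
    w2 = 1.0 - w1
    return float(w1 * w2 * (g1.mean() - g2.mean()) ** 2 / total_var)


def iterative_otsu_ld_mask(
    lipid_map: np.ndarray,
    max_iters: int = 5,
    stop_rel_change: float = 0.01,
    n_bins: int = 256,
    min_ld_size: int = 0,
    min_effectiveness: float = 0.75,
) -> SegmentationMask:
    """Segment lipid droplets by repeatedly re-thresholding the upper mode.

    Iteration 1 applies Otsu to the full map; iteration i+1 re-runs Otsu on
    only the pixels above the current threshold, climbing the intensity
    modes (background → cytoplasm → droplets).  Iteration stops when

    * the candidate split of the restricted pixels is no longer a genuine
      mode separation — its between-class variance fraction (Otsu's
      effectiveness η) falls below ``min_effectiveness`` — meaning the
      remaining pixels form a single noise mode that should not be split;
    * the relative change in threshold drops below ``stop_rel_change``;
    * ``max_iters`` passes have run; or
    * (with a warning recorded) the mask would empty or the restriction is
      degenerate, in which case the previous mask is returned.

    ``min_ld_size`` (pixels) optionally removes smaller connected
    components from the final mask; off by default.
    """
    x = np.asarray(lipid_map, dtype=float)
    thresholds: list[float] = []
    warnings: list[str] = []

    t = otsu_threshold(x, n_bins)
    thresholds.append(t)
    for _ in range(1, max_iters):
        above = x[x > t]
        if above.size == 0:
            warnings.append("mask emptied; returning previous iteration's mask")
            break
        try:
            t_new = otsu_threshold(above, n_bins)
        except DegenerateInputError:
            warnings.append("restricted histogram degenerate; stopping early")
            break
        if _split_effectiveness(above, t_new) < min_effectiveness:
            break  # remaining pixels are one mode; do not split further
        if (x > t_new).sum() == 0:
            warnings.append("mask emptied; returning previous iteration's mask")
            break
        rel = abs(t_new - t) / abs(t) if t != 0 else np.inf
        t = t_new
        thresholds.append(t)
        if rel < stop_rel_change:
            break

    mask = x > t
    if min_ld_size > 0:
        labels = skimage.measure.label(mask)
        sizes = np.bincount(labels.ravel())
        mask = mask & (sizes[labels] >= min_ld_size)
    return SegmentationMask(pixels=mask, source="lipid",
                            thresholds_applied=thresholds, warnings=warnings)


def cell_area_mask(protein_map: np.ndarray, n_bins: int = 256,
                   min_effectiveness: float = 0.75) -> SegmentationMask:
    """Cell-area mask: single Otsu pass on the protein concentration map.

    A contrast guard protects negative controls: when the Otsu split is not
    a genuine mode separation (effectiveness η below ``min_effectiveness``,
    as for a pure-noise image, where η ≈ 0.64) the mask is returned empty
    with a warning instead of marking ~half the pixels.
    """
    x = np.asarray(protein_map, dtype=float)
    t = otsu_threshold(x, n_bins)
    if _split_effectiveness(x.ravel(), t) < min_effectiveness:
        return SegmentationMask(
            pixels=np.zeros_like(x, dtype=bool), source="protein",
            thresholds_applied=[t],
            warnings=["no bimodal contrast; returning empty mask"])
    return SegmentationMask(pixels=x > t, source="protein",
                            thresholds_applied=[t])
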