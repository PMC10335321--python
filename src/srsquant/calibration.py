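"""Delay-line → Raman-shift calibration.

Spectral-focusing SRS selects the probed Raman shift through the pump–Stokes
delay, so the delay-line position must be mapped to wavenumbers before any
band can be labelled.  The map is linear; it is recovered daily by scanning
calibrants with known narrow bands (DMSO at 2914 and 2998 cm⁻¹, polystyrene
at 2852 and 2904 cm⁻¹), locating the peaks in the delay-position spectrum
and fitting an ordinary least-squares line through
(peak position, known shift) pairs.  Points from several calibrants may be
pooled into one fit, which constrains the line better than a single
two-point substance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.signal

from .exceptions import SingularFitError, ValidationError

__all__ = ["RamanAxisMap", "detect_peaks", "fit_raman_axis", "apply_axis",
           "invert_axis", "calibrate_from_scans"]


@dataclass
class RamanAxisMap:
    """Linear map shift = slope·position + intercept.

    slope is in cm⁻¹ per delay unit, intercept in cm⁻¹; ``residual_rms``
    is the root-mean-square fit residual in cm⁻¹ over the ``n_points``
    calibration points.
    """

    slope: float
    intercept: float
    residual_rms: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValidationError("slope must be nonzero")
        if self.n_points < 2:
            raise ValidationError("a linear map needs at least 2 points")
        if self.residual_rms < 0:
            raise ValidationError("residual_rms must be >= 0")


def detect_peaks(
    positions: np.ndarray,
    intensities: np.ndarray,
    min_prominence: float = 0.05,
    refine: str = "quadratic",
) -> np.ndarray:
    """Locate peaks in a calibration spectrum with sub-sample refinement.

    Peaks are local maxima whose prominence exceeds ``min_prominence`` times
    the intensity range.  ``refine`` selects the sub-sample refinement:

    ``"quadratic"``
        Parabola through the maximum and its two neighbours (delay sampling
        is coarse relative to the ~28 cm⁻¹-wide peaks, so refinement
        matters).
    ``"lorentzian"``
        Joint least-squares fit of a sum of Lorentzians (plus a constant
        baseline) initialised at the quadratic estimates.  Overlapping peak
        tails pull local maxima toward each other; the joint fit removes
        that bias and is what the Raman-axis calibration uses.

    Returns peak positions sorted ascending; an empty array if no peak
    qualifies.
    """
    positions = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if y.size < 3 or positions.shape != y.shape:
        raise ValidationError("spectrum needs >= 3 samples with matching axes")
    if refine not in ("quadratic", "lorentzian"):
        raise ValidationError(f"unknown refine mode {refine!r}")

    rng_y = y.max() - y.min()
    if rng_y == 0:
        return np.array([])
    idx, props = scipy.signal.find_peaks(y, prominence=min_prominence * rng_y,
                                         width=1)

    refined = []
    for i in idx:
        if 0 < i < y.size - 1:
            ym, y0, yp = y[i - 1], y[i], y[i + 1]
            denom = ym - 2 * y0 + yp
            # parabolic vertex offset in samples, clamped to the cell
            delta = 0.0 if denom == 0 else np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5)
            step = positions[i + 1] - positions[i] if delta >= 0 else positions[i] - positions[i - 1]
            refined.append(positions[i] + delta * abs(step))
        else:
            refined.append(positions[i])
    centers = np.array(refined)

    if refine == "lorentzian" and centers.size:
        centers = _refine_lorentzian(positions, y, centers, idx, props)
    return np.sort(centers)


def _refine_lorentzian(positions, y, centers, idx, props):
    """Joint multi-Lorentzian + constant-baseline fit of the spectrum."""
    step = np.median(np.diff(positions))
    amps0 = y[idx] - y.min()
    gammas0 = np.maximum(props["widths"] * step / 2.0, step)

    def model(x, *params):
        base = params[-1]
        out = np.full_like(x, base)
        for k in range(centers.size):
            a, c, g = params[3 * k:3 * k + 3]
            out = out + a / (1.0 + ((x - c) / g) ** 2)
        return out

    p0 = np.concatenate([np.column_stack([amps0, centers, gammas0]).ravel(),
                         [y.min()]])
    try:
        popt, _ = scipy.optimize.curve_fit(model, positions, y, p0=p0,
                                           maxfev=10_000)
    except RuntimeError:  # no convergence: keep the quadratic estimates
        return centers
    return popt[1:-1:3]


def fit_raman_axis(
    peak_positions: Sequence[float], known_shifts: Sequence[float]
) -> RamanAxisMap:
    """Ordinary least-squares line through (delay position, Raman shift)."""
    x = np.asarray(peak_positions, dtype=float)
    s = np.asarray(known_shifts, dtype=float)
    if x.shape != s.shape or x.ndim != 1:
        raise ValidationError("peak_positions and known_shifts must be equal-length 1-D")
    if x.size < 2:
        raise ValidationError("at least 2 calibration points required")
    if np.ptp(x) == 0:
        raise SingularFitError("all peak positions identical; line is undetermined")

    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, s, rcond=None)
    resid = s - (slope * x + intercept)
    return RamanAxisMap(
        slope=float(slope),
        intercept=float(intercept),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=x.size,
    )


def apply_axis(axis_map: RamanAxisMap, position) -> np.ndarray | float:
    """Map delay-line position(s) to Raman shift(s) in cm⁻¹."""
    return axis_map.slope * np.asarray(position, dtype=float) + axis_map.intercept


def invert_axis(axis_map: RamanAxisMap, shift) -> np.ndarray | float:
    """Map Raman shift(s) back to delay-line position(s)."""
    return (np.asarray(shift, dtype=float) - axis_map.intercept) / axis_map.slope


def calibrate_from_scans(
    scans: Sequence[tuple[np.ndarray, np.ndarray, Sequence[float]]],
    min_prominence: float = 0.05,
    refine: str = "lorentzian",
) -> RamanAxisMap:
    """Detect peaks on each calibrant scan and fit one pooled line.

    Each scan is a ``(positions, intensities, known_shifts)`` triple; the
    number of detected peaks must equal the number of known shifts for that
    substance, and both are paired in ascending order (the delay axis is
    assumed oriented so that shift increases with position).
    """
    pos_all, shift_all = [], []
    for positions, intensities, known in scans:
        peaks = detect_peaks(positions, intensities, min_prominence,
                             refine=refine)
        known = np.sort(np.asarray(known, dtype=float))
        if peaks.size != known.size:
            raise ValidationError(
                f"detected {peaks.size} peaks but expected {known.size}; "
                "adjust min_prominence or check the scan"
            )
        pos_all.append(peaks)
        shift_all.append(known)
    return fit_raman_axis(np.concatenate(pos_all), np.concatenate(shift_all))
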