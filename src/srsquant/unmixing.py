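"""Spectral unmixing of two-band SRS images into lipid and protein maps.

The imaging protocol acquires repeated frames at each Raman band
(2850 cm⁻¹, dominated by the lipid CH₂ stretch, and 2926 cm⁻¹, a mixed
CH₂/CH₃ region with strong protein contribution).  Frames are averaged per
band and the resulting band images are decomposed by multivariate curve
resolution (MCR) into nonnegative per-component concentration maps using
min-max-normalised pure-component reference spectra (oleic acid for lipid,
bovine serum albumin for protein).

Two modes are provided:

``fixed_spectra``
    The reference spectra are held fixed and each pixel is solved by exact
    nonnegative least squares.  With as many bands as components this is the
    only well-posed choice and is the default.

``free_spectra``
    Classical MCR-ALS: alternating nonnegative updates of the concentration
    maps and the spectra, initialised at the reference spectra, with each
    component spectrum rescaled to unit maximum every iteration (the
    compensating scale is absorbed into the concentration maps so the
    residual is untouched).  Useful when more bands than components are
    measured.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import scipy.optimize

from .exceptions import DegenerateInputError, SingularFitError, ValidationError

__all__ = [
    "FrameStack",
    "BandImage",
    "PureSpectra",
    "ConcentrationMaps",
    "average_frames",
    "minmax_normalize",
    "default_pure_spectra",
    "mcr_als_unmix",
    "nnls_pixels",
]

#: Raman bands (cm⁻¹) used throughout the pipeline.
LIPID_BAND = 2850.0
PROTEIN_BAND = 2926.0

#: Tolerance (cm⁻¹) when matching image bands to reference-spectrum bands;
#: generous enough to absorb day-to-day calibration drift.
BAND_MATCH_TOL = 5.0


@dataclass
class FrameStack:
    """Repeated frames acquired at a single Raman band.

    Attributes
    ----------
    frames : ndarray, shape (F, H, W)
        Raw intensity frames.  Negative values are permitted (lock-in noise).
    band : float
        Raman shift of the acquisition, cm⁻¹.
    meta : dict
        Free-form acquisition metadata.
    """

    frames: np.ndarray
    band: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError(
                f"frames must be a (F, H, W) array with F >= 1, got shape {self.frames.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class BandImage:
    """A single (typically frame-averaged) image at one Raman band."""

    pixels: np.ndarray
    band: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("band image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PureSpectra:
    """Min-max-normalised pure-component reference intensities per band.

    ``matrix`` has one row per component and one column per band; values lie
    in [0, 1] because the source spectra are min-max normalised before the
    band intensities are read off.
    """

    components: tuple[str, ...]
    bands: np.ndarray
    matrix: np.ndarray
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        k, b = self.matrix.shape
        if k < 1 or len(self.components) != k:
            raise ValidationError("component names must match matrix rows")
        if self.bands.shape != (b,):
            raise ValidationError("bands must match matrix columns")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValidationError("pure spectra values must lie in [0, 1]")

    @property
    def n_components(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bands(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ConcentrationMaps:
    """Output of unmixing: nonnegative abundance image per component."""

    components: tuple[str, ...]
    maps: np.ndarray  # (K, H, W), >= 0
    spectra: np.ndarray  # (K, B) spectra actually used/fitted
    bands: np.ndarray  # (B,)
    residual: np.ndarray  # (H, W) per-pixel residual 2-norm
    iterations: int
    converged: bool
    warnings: list[str] = field(default_factory=list)

    def component(self, name: str) -> np.ndarray:
        return self.maps[self.components.index(name)]


def default_pure_spectra() -> PureSpectra:
    """Built-in reference intensities at 2850 and 2926 cm⁻¹.

    Oleic acid (lipid analog) peaks at the CH₂ symmetric stretch near
    2850 cm⁻¹ and retains roughly half that intensity at 2926 cm⁻¹; BSA
    (protein analog) peaks near 2930 cm⁻¹ with a weak CH₂ shoulder at
    2850 cm⁻¹.  Values are on the min-max-normalised scale of each full
    spectrum.
    """
    return PureSpectra(
        components=("lipid", "protein"),
        bands=np.array([LIPID_BAND, PROTEIN_BAND]),
        matrix=np.array([[1.00, 0.55], [0.30, 1.00]]),
        sources=("oleic acid", "BSA"),
    )


def average_frames(stack: FrameStack) -> BandImage:
    """Per-pixel arithmetic mean over the frames of a stack."""
    return BandImage(pixels=stack.frames.mean(axis=0), band=stack.band)


def minmax_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Rescale a spectrum to [0, 1] via (x - min) / (max - min)."""
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValidationError("spectrum must have at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateInputError("constant spectrum cannot be min-max normalized")
    return (x - lo) / (hi - lo)


def _active_set_tables(S: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Precompute pseudo-inverses for every nonempty support of components.

    ``S`` is (K, B).  For support J the unconstrained solution restricted to
    J is ``pinv(S[J].T) @ I``; enumerating all 2^K - 1 supports plus the
    empty one yields the exact NNLS minimiser for small K.
    """
    K = S.shape[0]
    tables = []
    for r in range(1, K + 1):
        for J in itertools.combinations(range(K), r):
            idx = np.array(J)
            A = S[idx].T  # (B, r)
            if np.linalg.matrix_rank(A) < len(J):
                continue
            tables.append((idx, np.linalg.pinv(A)))
    return tables


def nnls_pixels(I: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Exact nonnegative least squares for a batch of pixels.

    Solves ``min_{c>=0} ||I_n - S.T c||²`` for every row ``I_n`` of the
    (N, B) intensity matrix by enumerating active sets, which is exact for
    the small K (2 components) used here.

    Returns the (N, K) coefficient matrix.
    """
    I = np.asarray(I, dtype=float)
    K, B = S.shape
    if I.ndim != 2 or I.shape[1] != B:
        raise ValidationError(f"pixel matrix must be (N, {B}), got {I.shape}")
    if np.linalg.matrix_rank(S) < K:
        raise SingularFitError("reference spectra are linearly dependent")

    N = I.shape[0]
    best_c = np.zeros((N, K))
    # empty support: residual ||I||²
    best_r = np.einsum("nb,nb->n", I, I)
    for idx, pinvA in _active_set_tables(S):
        c_sub = I @ pinvA.T  # (N, r)
        feasible = np.all(c_sub >= 0, axis=1)
        if not feasible.any():
            continue
        resid_vec = I - c_sub @ S[idx]
        r = np.einsum("nb,nb->n", resid_vec, resid_vec)
        better = feasible & (r < best_r - 1e-15 * (1 + best_r))
        if better.any():
            best_r[better] = r[better]
            best_c[better] = 0.0
            best_c[np.ix_(better, idx)] = c_sub[better]
    return best_c


def _match_bands(image_bands: np.ndarray, pure: PureSpectra) -> np.ndarray:
    """Column order of ``pure.matrix`` matching the image band order."""
    cols = []
    for b in image_bands:
        d = np.abs(pure.bands - b)
        j = int(np.argmin(d))
        if d[j] > BAND_MATCH_TOL:
            raise ValidationError(
                f"image band {b:.1f} cm⁻¹ has no reference band within "
                f"{BAND_MATCH_TOL:g} cm⁻¹ (reference bands: {pure.bands.tolist()})"
            )
        cols.append(j)
    if len(set(cols)) != len(cols):
        raise ValidationError("two image bands matched the same reference band")
    return np.array(cols)


def mcr_als_unmix(
    images: Sequence[BandImage],
    pure: PureSpectra,
    mode: str = "fixed_spectra",
    max_iter: int = 500,
    tol: float = 1e-8,
) -> ConcentrationMaps:
    """Decompose band images into nonnegative component concentration maps.

    Parameters
    ----------
    images : sequence of BandImage
        One image per Raman band; all must share dimensions.
    pure : PureSpectra
        Reference spectra; bands are matched to the images by nearest
        wavenumber within ±5 cm⁻¹.
    mode : {"fixed_spectra", "free_spectra"}
        ``fixed_spectra`` solves per-pixel NNLS against the references;
        ``free_spectra`` runs alternating least squares refining both the
        maps and the spectra.
    max_iter, tol : ALS controls (free mode); iteration stops when the
        relative change in total squared residual drops below ``tol``.
    """
    if len(images) < 1:
        raise ValidationError("at least one band image required")
    shape = images[0].shape
    for im in images:
        if im.shape != shape:
            raise ValidationError("all band images must share dimensions")
    if mode not in ("fixed_spectra", "free_spectra"):
        raise ValidationError(f"unknown mode {mode!r}")

    image_bands = np.array([im.band for im in images])
    cols = _match_bands(image_bands, pure)
    S = pure.matrix[:, cols]  # (K, B) in image band order
    K, B = S.shape
    if B < K:
        raise ValidationError(f"need at least {K} bands for {K} components, got {B}")

    H, W = shape
    I = np.stack([im.pixels.ravel() for im in images], axis=1)  # (N, B)
    warnings: list[str] = []

    if mode == "fixed_spectra":
        C = nnls_pixels(I, S)
        iterations, converged = 1, True
        S_fit = S
    else:
        S_fit = S.copy()
        C = nnls_pixels(I, S_fit)
        resid_prev = np.sum((I - C @ S_fit) ** 2)
        iterations, converged = 0, False
        for it in range(1, max_iter + 1):
            iterations = it
            # spectral update: per band, s_:b = argmin_{s>=0} ||I_:,b - C s||
            for b in range(B):
                S_fit[:, b], _ = scipy.optimize.nnls(C, I[:, b])
            # renormalise each component to unit max, absorbing scale into C
            for k in range(K):
                m = S_fit[k].max()
                if m > 0:
                    S_fit[k] /= m
                    C[:, k] *= m
            C = nnls_pixels(I, S_fit)
            resid = np.sum((I - C @ S_fit) ** 2)
            rel_change = abs(resid_prev - resid) / max(resid_prev, np.finfo(float).tiny)
            resid_prev = resid
            # converged on relative change, or on an exact (noise-free) fit
            if rel_change < tol or resid <= tol * np.sum(I * I):
                converged = True
                break
        if not converged:
            warnings.append(
                f"free-spectra ALS did not converge in {max_iter} iterations"
            )

    resid_img = np.linalg.norm(I - C @ S_fit, axis=1).reshape(H, W)
    return ConcentrationMaps(
        components=pure.components,
        maps=C.T.reshape(K, H, W),
        spectra=S_fit,
        bands=image_bands,
        residual=resid_img,
        iterations=iterations,
        converged=converged,
        warnings=warnings,
    )
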