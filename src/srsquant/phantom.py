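"""Synthetic phantoms with known ground truth for every pipeline stage.

Three generators are provided:

* :func:`generate_srs_stack` — two-band SRS image stacks of disc-shaped
  cells with concentric nuclei and bright lipid droplets, built from the
  same linear mixing model the unmixing stage inverts, plus per-frame
  additive Gaussian noise (lock-in detection noise is approximately
  Gaussian).
* :func:`generate_calibration_scan` — intensity-versus-delay-line spectra
  with Lorentzian peaks at the positions a known linear Raman-shift map
  sends to the calibrant's reference shifts (DMSO: 2914/2998 cm⁻¹,
  polystyrene: 2852/2904 cm⁻¹).
* :func:`generate_flow_events` — flow-cytometry event tables containing
  debris, singlet and doublet populations with lognormal fluorescence of
  known mean.

Every generator is a pure function of its spec (including the seed):
identical inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import GenerationError, ValidationError
from .unmixing import FrameStack, PureSpectra, default_pure_spectra

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "FlowPhantomSpec",
    "CalibrationScan",
    "generate_srs_stack",
    "generate_calibration_scan",
    "generate_flow_events",
    "CALIBRANT_SHIFTS",
]

#: Reference Raman shifts (cm⁻¹) of the calibration substances.
CALIBRANT_SHIFTS: dict[str, tuple[float, float]] = {
    "DMSO": (2914.0, 2998.0),
    "polystyrene": (2852.0, 2904.0),
}

#: Spectral resolution of the instrument being emulated, cm⁻¹ (FWHM).
SPECTRAL_RESOLUTION_FWHM = 28.0


@dataclass
class PhantomSpec:
    """Parameters of a two-band SRS cell phantom.

    Cells are discs with concentric nuclear discs; lipid droplets are small
    discs confined to the cytoplasmic annulus.  Intensity levels are in the
    arbitrary units of the concentration maps; the nucleus carries no lipid
    signal (nuclei image dark in the lipid channel) and elevated protein.
    """

    image_height: int = 512
    image_width: int = 512
    n_frames: int = 10
    pixel_area: float = 22.5  # μm² per pixel, the pipeline-wide constant
    n_cells: int = 25
    cell_radius_range: tuple[float, float] = (25.0, 35.0)
    nucleus_radius_fraction: float = 0.45
    n_lds_per_cell_range: tuple[int, int] = (3, 8)
    ld_radius_range: tuple[float, float] = (2.0, 4.0)
    lipid_level_cytoplasm: float = 1.0
    lipid_level_ld: float = 5.0
    protein_level_cytoplasm: float = 2.0
    protein_level_nucleus: float = 3.0
    gaussian_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_height, self.image_width, self.n_frames, self.n_cells) < 1:
            raise ValidationError("dimensions, frame count and cell count must be >= 1")
        if self.pixel_area <= 0:
            raise ValidationError("pixel_area must be positive")
        for name in ("cell_radius_range", "ld_radius_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValidationError(f"{name} must satisfy 0 < lo <= hi")
        lo, hi = self.n_lds_per_cell_range
        if lo < 0 or hi < lo:
            raise ValidationError("n_lds_per_cell_range must satisfy 0 <= lo <= hi")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ValidationError("nucleus_radius_fraction must lie in (0, 1)")
        if self.lipid_level_ld <= self.lipid_level_cytoplasm:
            raise ValidationError("lipid_level_ld must exceed lipid_level_cytoplasm")
        if self.gaussian_noise_sd < 0:
            raise ValidationError("gaussian_noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated SRS phantom."""

    components: tuple[str, ...]
    concentration_maps_true: np.ndarray  # (K, H, W), noiseless
    ld_mask_true: np.ndarray  # (H, W) bool
    cell_mask_true: np.ndarray  # (H, W) bool
    n_cells_true: int
    per_cell_ld_area_true: float  # μm²
    pure_spectra: PureSpectra = field(repr=False, default=None)


def _disc_mask(H: int, W: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:H, :W]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def generate_srs_stack(
    spec: PhantomSpec, pure: PureSpectra | None = None
) -> tuple[list[FrameStack], PhantomTruth]:
    """Generate two-band frame stacks and the matching ground truth.

    The noiseless intensity at band b is the linear mixture
    ``sum_k C_k(x) * S[k, b]`` over lipid and protein, with ``S`` the
    min-max-normalised reference spectra; each frame then receives i.i.d.
    Gaussian noise of sd ``spec.gaussian_noise_sd``.

    Returns one :class:`FrameStack` per band (2850 then 2926 cm⁻¹) and a
    :class:`PhantomTruth` carrying the noiseless maps, masks and counts.
    """
    if pure is None:
        pure = default_pure_spectra()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width

    lipid = np.zeros((H, W))
    protein = np.zeros((H, W))
    cell_mask = np.zeros((H, W), dtype=bool)
    ld_mask = np.zeros((H, W), dtype=bool)

    placed: list[tuple[float, float, float]] = []
    max_retries = 200
    for _ in range(spec.n_cells):
        r = rng.uniform(*spec.cell_radius_range)
        if 2 * r >= min(H, W):
            raise GenerationError(
                "cell_radius_range too large for the image dimensions"
            )
        for attempt in range(max_retries):
            cy = rng.uniform(r, H - 1 - r)
            cx = rng.uniform(r, W - 1 - r)
            if all(
                (cy - py) ** 2 + (cx - px) ** 2 > (r + pr) ** 2
                for py, px, pr in placed
            ):
                break
        else:
            raise GenerationError(
                "could not place all cells without overlap; reduce n_cells "
                "or cell_radius_range"
            )
        placed.append((cy, cx, r))

        cell = _disc_mask(H, W, cy, cx, r)
        nucleus = _disc_mask(H, W, cy, cx, spec.nucleus_radius_fraction * r)
        cytoplasm = cell & ~nucleus
        cell_mask |= cell
        lipid[cytoplasm] = spec.lipid_level_cytoplasm
        protein[cytoplasm] = spec.protein_level_cytoplasm
        protein[nucleus] = spec.protein_level_nucleus

        n_lds = int(rng.integers(spec.n_lds_per_cell_range[0],
                                 spec.n_lds_per_cell_range[1] + 1))
        r_nuc = spec.nucleus_radius_fraction * r
        for _ in range(n_lds):
            ld_r = rng.uniform(*spec.ld_radius_range)
            lo = r_nuc + ld_r
            hi = r - ld_r
            if hi <= lo:  # cytoplasmic annulus too thin for this droplet
                continue
            rho = rng.uniform(lo, hi)
            theta = rng.uniform(0, 2 * np.pi)
            ld = _disc_mask(H, W, cy + rho * np.sin(theta),
                            cx + rho * np.cos(theta), ld_r)
            ld_mask |= ld

    lipid[ld_mask] = spec.lipid_level_ld

    maps_true = np.stack([lipid, protein])  # order matches pure.components
    S = pure.matrix  # (K, B)
    noiseless = np.einsum("khw,kb->bhw", maps_true, S)  # (B, H, W)

    stacks = []
    for b, band in enumerate(pure.bands):
        noise = rng.normal(0.0, spec.gaussian_noise_sd,
                           size=(spec.n_frames, H, W)) if spec.gaussian_noise_sd > 0 \
            else np.zeros((spec.n_frames, H, W))
        stacks.append(FrameStack(frames=noiseless[b] + noise,
                                 band=float(band),
                                 meta={"phantom_seed": spec.seed}))

    truth = PhantomTruth(
        components=pure.components,
        concentration_maps_true=maps_true,
        ld_mask_true=ld_mask,
        cell_mask_true=cell_mask,
        n_cells_true=spec.n_cells,
        per_cell_ld_area_true=ld_mask.sum() * spec.pixel_area / spec.n_cells,
        pure_spectra=pure,
    )
    return stacks, truth


@dataclass
class CalibrationScan:
    """A synthetic intensity-vs-delay-position spectrum with known truth."""

    positions: np.ndarray
    intensities: np.ndarray
    substance: str
    known_shifts: tuple[float, ...]
    true_peak_positions: np.ndarray
    true_slope: float
    true_intercept: float


def generate_calibration_scan(
    substance: str,
    true_slope: float,
    true_intercept: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 600,
    peak_fwhm_cm: float = SPECTRAL_RESOLUTION_FWHM,
) -> CalibrationScan:
    """Simulate a calibrant scan under a known delay→shift linear map.

    Lorentzian peaks of FWHM ``peak_fwhm_cm`` (in wavenumbers; mapped to
    delay units through the true slope) are placed at the delay positions
    the inverse map sends the substance's reference shifts to.
    """
    if substance not in CALIBRANT_SHIFTS:
        raise ValidationError(
            f"unknown substance {substance!r}; choose from {sorted(CALIBRANT_SHIFTS)}"
        )
    if true_slope == 0:
        raise ValidationError("true_slope must be nonzero")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")

    shifts = np.array(CALIBRANT_SHIFTS[substance])
    peak_pos = (shifts - true_intercept) / true_slope
    gamma = (peak_fwhm_cm / abs(true_slope)) / 2.0  # HWHM in delay units

    margin = 6 * gamma
    lo, hi = peak_pos.min() - margin, peak_pos.max() + margin
    positions = np.linspace(lo, hi, n_samples)
    intensities = np.zeros_like(positions)
    for p in peak_pos:
        intensities += 1.0 / (1.0 + ((positions - p) / gamma) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, noise_sd, size=n_samples)

    return CalibrationScan(
        positions=positions,
        intensities=intensities,
        substance=substance,
        known_shifts=tuple(shifts),
        true_peak_positions=np.sort(peak_pos),
        true_slope=true_slope,
        true_intercept=true_intercept,
    )


@dataclass
class FlowPhantomSpec:
    """Parameters of a synthetic flow-cytometry event table.

    The singlet fluorescence channel is lognormal with arithmetic mean
    ``singlet_mfi * mfi_shift_factor`` and coefficient of variation
    ``lognormal_cv``; debris sit at low scatter, doublets at roughly twice
    the singlet SSC-A for the same SSC-H.
    """

    n_events: int = 100_000
    fraction_debris: float = 0.05
    fraction_doublets: float = 0.10
    singlet_mfi: float = 100.0
    mfi_shift_factor: float = 1.0
    lognormal_cv: float = 0.6
    seed: int = 0
    condition: str = "0 Gy"
    timepoint: float = 72.0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValidationError("n_events must be >= 0")
        if not (0 <= self.fraction_debris and 0 <= self.fraction_doublets):
            raise ValidationError("population fractions must be >= 0")
        if self.fraction_debris + self.fraction_doublets >= 1:
            raise ValidationError("population fractions must sum to < 1")
        if self.singlet_mfi <= 0 or self.mfi_shift_factor < 0:
            raise ValidationError("singlet_mfi must be > 0 and mfi_shift_factor >= 0")
        if self.lognormal_cv <= 0:
            raise ValidationError("lognormal_cv must be > 0")


def _lognormal_with_mean(rng: np.random.Generator, mean: float, cv: float,
                         n: int) -> np.ndarray:
    """Lognormal draws with a prescribed arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def generate_flow_events(
    spec: FlowPhantomSpec,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Generate a flow event table plus a truth record.

    The returned DataFrame has columns ``FSC-A``, ``SSC-A``, ``SSC-H``,
    ``FL-green``, ``population`` (truth label), ``condition`` and
    ``timepoint``.  The truth dict records both the population-level singlet
    MFI and the realised sample mean of the generated singlet events.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    n_debris = int(round(spec.fraction_debris * n))
    n_doublets = int(round(spec.fraction_doublets * n))
    n_singlets = n - n_debris - n_doublets

    target_mfi = spec.singlet_mfi * spec.mfi_shift_factor

    parts = []
    if n_singlets:
        ssc = _lognormal_with_mean(rng, 3e4, 0.3, n_singlets)
        parts.append(pd.DataFrame({
            "FSC-A": _lognormal_with_mean(rng, 5e4, 0.3, n_singlets),
            "SSC-A": ssc,
            # singlets lie on the SSC-H ≈ SSC-A diagonal up to pulse jitter
            "SSC-H": ssc * rng.normal(1.0, 0.03, n_singlets).clip(0.8, 1.2),
            "FL-green": _lognormal_with_mean(rng, target_mfi,
                                             spec.lognormal_cv, n_singlets),
            "population": "singlet",
        }))
    if n_doublets:
        ssc = _lognormal_with_mean(rng, 6e4, 0.3, n_doublets)
        parts.append(pd.DataFrame({
            "FSC-A": _lognormal_with_mean(rng, 8.5e4, 0.3, n_doublets),
            "SSC-A": ssc,
            # two cells in one pulse: area doubles, height does not
            "SSC-H": ssc / 2 * rng.normal(1.0, 0.05, n_doublets).clip(0.7, 1.3),
            "FL-green": _lognormal_with_mean(rng, 2 * target_mfi,
                                             spec.lognormal_cv, n_doublets),
            "population": "doublet",
        }))
    if n_debris:
        ssc = _lognormal_with_mean(rng, 3e3, 0.5, n_debris)
        parts.append(pd.DataFrame({
            "FSC-A": _lognormal_with_mean(rng, 4e3, 0.5, n_debris),
            "SSC-A": ssc,
            "SSC-H": ssc * rng.normal(1.0, 0.1, n_debris).clip(0.5, 1.5),
            "FL-green": _lognormal_with_mean(rng, 0.2 * target_mfi,
                                             spec.lognormal_cv, n_debris),
            "population": "debris",
        }))

    if parts:
        events = pd.concat(parts, ignore_index=True)
        events = events.sample(frac=1.0, random_state=spec.seed).reset_index(drop=True)
    else:
        events = pd.DataFrame({c: pd.Series(dtype=float)
                               for c in ("FSC-A", "SSC-A", "SSC-H", "FL-green")}
                              ).assign(population=pd.Series(dtype=str))
    events["condition"] = spec.condition
    events["timepoint"] = spec.timepoint

    singlet_fl = events.loc[events["population"] == "singlet", "FL-green"]
    truth = {
        "singlet_mfi_population": target_mfi,
        "singlet_mfi_realized": float(singlet_fl.mean()) if len(singlet_fl) else float("nan"),
        "n_singlets": int(n_singlets),
        "n_doublets": int(n_doublets),
        "n_debris": int(n_debris),
    }
    return events, truth
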