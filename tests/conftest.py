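"""Shared fixtures: small phantoms sized for fast, exact pipeline checks."""

import numpy as np
import pytest

from srsquant.phantom import PhantomSpec, generate_srs_stack
from srsquant.unmixing import average_frames, default_pure_spectra


def small_spec(seed: int = 0, noise_sd: float = 0.0, **overrides) -> PhantomSpec:
    """A 128×128 phantom with a handful of cells; fast enough for loops."""
    params = dict(
        image_height=128, image_width=128, n_frames=10, n_cells=6,
        cell_radius_range=(12.0, 16.0), n_lds_per_cell_range=(3, 6),
        ld_radius_range=(1.5, 3.0), gaussian_noise_sd=noise_sd, seed=seed,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def peak_band_intensity(spec: PhantomSpec) -> float:
    """Max noiseless band intensity of a phantom (for SNR-scaled noise)."""
    noiseless = PhantomSpec(**{**spec.__dict__, "gaussian_noise_sd": 0.0})
    stacks, _ = generate_srs_stack(noiseless)
    return max(s.frames.max() for s in stacks)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def pure():
    return default_pure_spectra()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """(stacks, truth, band images) for a noiseless small phantom."""
    stacks, truth = generate_srs_stack(small_spec(seed=11))
    images = [average_frames(s) for s in stacks]
    return stacks, truth, images
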