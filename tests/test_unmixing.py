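"""Frame averaging, normalisation, and MCR unmixing vs independent oracles."""

import numpy as np
import pytest
import scipy.optimize

from srsquant.exceptions import (DegenerateInputError, SingularFitError,
                                 ValidationError)
from srsquant.unmixing import (BandImage, FrameStack, PureSpectra,
                               average_frames, mcr_als_unmix,
                               minmax_normalize, nnls_pixels)



class TestAverageFrames:
    def test_single_frame_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        out = average_frames(FrameStack(frames=img[None], band=2850.0))
        np.testing.assert_array_equal(out.pixels, img)
        assert out.band == 2850.0

    def test_constant_frames_average(self):
        frames = np.stack([np.full((4, 4), 1.0), np.full((4, 4), 3.0)])
        out = average_frames(FrameStack(frames=frames, band=2926.0))
        np.testing.assert_array_equal(out.pixels, np.full((4, 4), 2.0))

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(size=(10, 16, 16))
        out = average_frames(FrameStack(frames=frames, band=2850.0))
        brute = sum(frames[i] for i in range(10)) / 10
        np.testing.assert_allclose(out.pixels, brute, atol=1e-12)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValidationError):
            FrameStack(frames=np.empty((0, 4, 4)), band=2850.0)


class TestMinMaxNormalize:
    def test_simple_case(self):
        np.testing.assert_allclose(minmax_normalize([2.0, 4.0, 6.0]),
                                   [0.0, 0.5, 1.0])

    def test_idempotent_on_normalized_input(self):
        x = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(minmax_normalize(x), x)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            minmax_normalize([5.0, 5.0, 5.0])


def scipy_nnls_oracle(I, S):
    """Independent per-pixel Lawson–Hanson NNLS (scipy)."""
    return np.array([scipy.optimize.nnls(S.T, row)[0] for row in I])


class TestFixedSpectraUnmixing:
    def test_pure_pixel_recovers_unit_coefficient(self, pure):
        I = pure.matrix[0][None]  # exactly the lipid row
        c = nnls_pixels(I, pure.matrix)
        np.testing.assert_allclose(c, [[1.0, 0.0]], atol=1e-12)

    def test_interior_mixture_recovered_exactly(self, pure):
        c_true = np.array([[2.0, 3.0]])
        I = c_true @ pure.matrix
        c = nnls_pixels(I, pure.matrix)
        np.testing.assert_allclose(c, c_true, atol=1e-9)

    def test_boundary_pixel_matches_active_set_search(self, pure):
        """Negative unconstrained solution → NNLS picks the best boundary case."""
        S = pure.matrix
        I = np.array([[1.0, 0.1]])  # forces protein coefficient negative
        unconstrained = np.linalg.solve(S.T, I[0])
        assert unconstrained.min() < 0  # the interesting case
        # brute force over {lipid only, protein only, both zero}
        candidates = []
        for keep in ([0], [1], []):
            if keep:
                A = S[keep].T
                ck, *_ = np.linalg.lstsq(A, I[0], rcond=None)
                if ck.min() < 0:
                    continue
                full = np.zeros(2)
                full[keep] = ck
            else:
                full = np.zeros(2)
            candidates.append((np.sum((I[0] - full @ S) ** 2), full))
        best = min(candidates, key=lambda t: t[0])[1]
        np.testing.assert_allclose(nnls_pixels(I, S)[0], best, atol=1e-9)

    def test_agrees_with_scipy_nnls_on_random_pixels(self, pure):
        rng = np.random.default_rng(3)
        I = rng.normal(0.5, 1.0, size=(500, 2))
        c = nnls_pixels(I, pure.matrix)
        oracle = scipy_nnls_oracle(I, pure.matrix)
        resid = np.sum((I - c @ pure.matrix) ** 2, axis=1)
        resid_oracle = np.sum((I - oracle @ pure.matrix) ** 2, axis=1)
        np.testing.assert_allclose(resid, resid_oracle, atol=1e-10)

    def test_scaling_equivariance(self, noiseless_phantom, pure):
        _, _, images = noiseless_phantom
        maps1 = mcr_als_unmix(images, pure)
        scaled = [BandImage(pixels=3.5 * im.pixels, band=im.band)
                  for im in images]
        maps2 = mcr_als_unmix(scaled, pure)
        np.testing.assert_allclose(maps2.maps, 3.5 * maps1.maps, rtol=1e-9,
                                   atol=1e-12)

    def test_noiseless_phantom_recovery(self, noiseless_phantom, pure):
        _, truth, images = noiseless_phantom
        maps = mcr_als_unmix(images, pure)
        rel = (np.linalg.norm(maps.maps - truth.concentration_maps_true)
               / np.linalg.norm(truth.concentration_maps_true))
        assert rel < 1e-6
        assert np.all(maps.maps >= 0)

    def test_rank_deficient_spectra_rejected(self):
        bad = PureSpectra(components=("a", "b"),
                          bands=np.array([2850.0, 2926.0]),
                          matrix=np.array([[0.5, 0.5], [1.0, 1.0]]))
        img = BandImage(pixels=np.ones((4, 4)), band=2850.0)
        img2 = BandImage(pixels=np.ones((4, 4)), band=2926.0)
        with pytest.raises(SingularFitError):
            mcr_als_unmix([img, img2], bad)

    def test_band_mismatch_rejected(self, pure):
        img = BandImage(pixels=np.ones((4, 4)), band=2700.0)
        img2 = BandImage(pixels=np.ones((4, 4)), band=2926.0)
        with pytest.raises(ValidationError):
            mcr_als_unmix([img, img2], pure)

    def test_band_matching_tolerates_small_drift(self, pure):
        """Bands within ±5 cm⁻¹ of the references are matched."""
        rng = np.random.default_rng(4)
        c_true = rng.uniform(0, 2, size=(16, 2))
        I = c_true @ pure.matrix
        imgs = [BandImage(pixels=I[:, b].reshape(4, 4), band=float(band + d))
                for b, (band, d) in enumerate(zip(pure.bands, (3.0, -4.0)))]
        maps = mcr_als_unmix(imgs, pure)
        np.testing.assert_allclose(
            maps.maps.reshape(2, 16).T, c_true, atol=1e-8)


class TestFreeSpectraUnmixing:
    def test_residual_monotonically_non_increasing(self, pure):
        rng = np.random.default_rng(5)
        # 3 bands, 2 components: free mode has spectral freedom
        S_true = np.array([[1.0, 0.55, 0.2], [0.3, 1.0, 0.8]])
        pure3 = PureSpectra(components=("lipid", "protein"),
                            bands=np.array([2850.0, 2926.0, 2960.0]),
                            matrix=np.clip(S_true + rng.normal(0, 0.05, S_true.shape), 0, 1))
        C = rng.uniform(0, 3, size=(256, 2))
        I = C @ S_true + rng.normal(0, 0.02, size=(256, 3))
        imgs = [BandImage(pixels=I[:, b].reshape(16, 16), band=bd)
                for b, bd in enumerate(pure3.bands)]

        residuals = []
        for it in range(1, 8):
            m = mcr_als_unmix(imgs, pure3, mode="free_spectra", max_iter=it,
                              tol=0.0)
            residuals.append(float((m.residual.ravel() ** 2).sum()))
        assert all(r2 <= r1 + 1e-9 for r1, r2 in zip(residuals, residuals[1:]))

    def test_free_mode_reports_convergence_and_unit_max_spectra(self, pure):
        rng = np.random.default_rng(6)
        S_true = np.array([[1.0, 0.55, 0.2], [0.3, 1.0, 0.8]])
        pure3 = PureSpectra(components=("lipid", "protein"),
                            bands=np.array([2850.0, 2926.0, 2960.0]),
                            matrix=S_true)
        C = rng.uniform(0, 3, size=(64, 2))
        I = C @ S_true
        imgs = [BandImage(pixels=I[:, b].reshape(8, 8), band=bd)
                for b, bd in enumerate(pure3.bands)]
        m = mcr_als_unmix(imgs, pure3, mode="free_spectra")
        assert m.converged
        np.testing.assert_allclose(m.spectra.max(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            m.maps.reshape(2, 64).T @ m.spectra, I, atol=1e-6)
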