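"""Physics of the projection-space low-dose simulator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erbnet.core import CTVolume
from erbnet.dosesim import (DoseConfig, Sinogram, apply_poisson_noise,
                            dose_to_photon_count, forward_project, hu_to_mu,
                            mu_to_hu, projection_from_counts, raw_to_hu,
                            reconstruct_fbp, simulate_low_dose_volume,
                            transmission_from_projection)
from erbnet.phantom import generate_volume

MU_WATER = 0.0195


class TestHuMuAlgebra:
    @pytest.mark.parametrize("raw, slope, intercept, expected", [
        (0, 1, -1024, -1024),
        (512.5, 1, 0, 512.5),
        (1024, 1, -1024, 0),
        (100, 2.0, 10.0, 210.0),
    ])
    def test_raw_rescale(self, raw, slope, intercept, expected):
        assert raw_to_hu(raw, slope, intercept) == pytest.approx(expected)

    def test_water_and_air_anchors(self):
        assert hu_to_mu(0.0, MU_WATER) == pytest.approx(MU_WATER)
        assert hu_to_mu(-1000.0, MU_WATER) == pytest.approx(0.0)
        assert hu_to_mu(500.0, 0.02) == pytest.approx(0.03)
        assert mu_to_hu(MU_WATER, MU_WATER) == pytest.approx(0.0)
        assert mu_to_hu(0.0, MU_WATER) == pytest.approx(-1000.0)

    def test_negative_attenuation_clipped(self):
        assert hu_to_mu(-2000.0) == 0.0

    @given(hu=st.floats(min_value=-1000.0, max_value=3071.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, hu):
        assert mu_to_hu(hu_to_mu(hu, MU_WATER), MU_WATER) == pytest.approx(hu, abs=1e-9)


class TestPhotonScaling:
    @pytest.mark.parametrize("fraction, expected", [
        (1.0, 10_000), (0.1, 1_000), (0.4, 4_000), (0.2, 2_000), (0.6, 6_000),
    ])
    def test_reference_scaling(self, fraction, expected):
        assert dose_to_photon_count(fraction, 10_000) == expected

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_invalid_fraction(self, fraction):
        with pytest.raises(ValueError):
            dose_to_photon_count(fraction)


class TestForwardProjection:
    def test_zero_slice_gives_zero_sinogram(self):
        sino = forward_project(np.zeros((32, 32)), 1.0)
        assert np.all(sino.values == 0.0)

    def test_empty_slice_rejected(self):
        with pytest.raises(ValueError):
            forward_project(np.zeros((0, 0)), 1.0)

    def test_disk_central_ray_matches_chord_length(self, disk_slice):
        # line integral through the centre of a uniform disk = 2 * r * mu
        sino = forward_project(disk_slice, 1.0)
        central = sino.values[:, sino.values.shape[1] // 2]
        assert np.all(np.abs(central - 0.8) <= 0.02 * 0.8)

    def test_mass_conservation_across_angles(self, disk_slice):
        sino = forward_project(disk_slice, 1.0)
        sums = sino.values.sum(axis=1) * sino.detector_spacing_mm
        expected = disk_slice.sum() * 1.0  # total mu mass * pixel area / spacing
        assert np.all(np.abs(sums - expected) <= 0.01 * expected)


class TestTransmissionAndCounts:
    def test_closed_forms(self):
        sino = Sinogram(np.array([[0.0, np.log(2.0)]]), [0.0], 1.0)
        T = transmission_from_projection(sino)
        assert T[0, 0] == pytest.approx(1.0)
        assert T[0, 1] == pytest.approx(0.5)

    def test_monotone_in_p(self):
        p = np.linspace(0, 5, 50)
        T = transmission_from_projection(p)
        assert np.all(np.diff(T) < 0)

    def test_zero_transmission_gives_zero_counts(self):
        counts = apply_poisson_noise(np.zeros(100), 10_000, seed=0)
        assert np.all(counts == 0)

    def test_seeded_reproducibility(self):
        T = np.full(1000, 0.5)
        assert np.array_equal(apply_poisson_noise(T, 1000, seed=5),
                              apply_poisson_noise(T, 1000, seed=5))

    def test_log_projection_closed_forms(self):
        I0 = 10_000
        assert projection_from_counts(np.array([I0]), I0)[0] == 0.0
        assert projection_from_counts(np.array([I0 / 2]), I0)[0] == pytest.approx(np.log(2))
        # zero counts floored at min_counts before the log
        assert projection_from_counts(np.array([0.0]), I0, min_counts=1)[0] == pytest.approx(np.log(I0))

    def test_counts_above_I0_capped(self):
        p = projection_from_counts(np.array([2 * 10_000]), 10_000)
        assert p[0] == 0.0


class TestFBP:
    def test_zero_sinogram_zero_image(self):
        sino = Sinogram(np.zeros((60, 46)), np.arange(60) * 3.0, 1.0)
        rec = reconstruct_fbp(sino, (32, 32), 1.0)
        assert np.allclose(rec, 0.0)

    def test_too_few_angles_rejected(self):
        sino = Sinogram(np.zeros((1, 46)), [0.0], 1.0)
        with pytest.raises(ValueError):
            reconstruct_fbp(sino, (32, 32), 1.0)

    def test_disk_round_trip_accuracy(self, disk_slice):
        n = disk_slice.shape[0]
        sino = forward_project(disk_slice, 1.0)
        rec = reconstruct_fbp(sino, (n, n), 1.0)
        x = np.arange(n) - n / 2 + 0.5
        xx, yy = np.meshgrid(x, x, indexing="ij")
        interior = np.sqrt(xx**2 + yy**2) <= 18.0  # 2-pixel edge band excluded
        rmse = np.sqrt(np.mean((rec[interior] - disk_slice[interior]) ** 2))
        assert rmse < 0.05 * MU_WATER

    def test_linearity_of_projection_reconstruction(self, disk_slice):
        rng = np.random.default_rng(0)
        g = rng.random((128, 128)) * 0.01
        a = 2.5

        def recon(img):
            sino = forward_project(img, 1.0)
            return reconstruct_fbp(sino, img.shape, 1.0)

        lhs = recon(a * disk_slice + g)
        rhs = a * recon(disk_slice) + recon(g)
        assert np.allclose(lhs, rhs, atol=1e-8)


class TestLowDoseVolume:
    def test_full_dose_returned_untouched(self, lesion_free_config):
        vol, _ = generate_volume(lesion_free_config)
        out = simulate_low_dose_volume(vol, DoseConfig(fraction=1.0, seed=0))
        assert np.array_equal(out.voxels, vol.voxels)

    def test_deterministic_under_seed(self, lesion_free_config):
        vol, _ = generate_volume(lesion_free_config)
        cfg = DoseConfig(fraction=0.2, seed=11, n_angles=60)
        a = simulate_low_dose_volume(vol, cfg)
        b = simulate_low_dose_volume(vol, cfg)
        assert np.array_equal(a.voxels, b.voxels)

    def test_anisotropic_in_plane_rejected(self):
        vol = CTVolume(np.zeros((16, 16, 4)), (1.0, 2.0, 1.0))
        with pytest.raises(ValueError, match="resample"):
            simulate_low_dose_volume(vol, DoseConfig(fraction=0.5))

    def test_noiseless_round_trip_inside_body(self, lesion_free_config):
        # projector + FBP only: interior error well under the dose noise
        # scale; a 2-voxel band around tissue interfaces is excluded
        # (FBP ringing at 1000-HU edges is intrinsic to the method)
        from scipy import ndimage

        vol, _ = generate_volume(lesion_free_config)
        cfg = DoseConfig(fraction=1.0, reprocess_full_dose=True, apply_noise=False)
        out = simulate_low_dose_volume(vol, cfg)
        err = out.voxels - vol.voxels
        body = vol.voxels > -990
        flat = np.ones_like(body)
        for z in range(vol.shape[2]):
            ptp = (ndimage.maximum_filter(vol.voxels[:, :, z], size=5)
                   - ndimage.minimum_filter(vol.voxels[:, :, z], size=5))
            flat[:, :, z] = ptp < 1.0
        mask = body & flat
        assert mask.sum() > 1000
        assert np.sqrt(np.mean(err[mask] ** 2)) < 25.0

    def test_projection_recovered_at_high_flux(self, disk_slice):
        # Poisson counts at very large I0 recover the noiseless projection
        sino = forward_project(disk_slice, 1.0)
        T = transmission_from_projection(sino)
        I0 = 10_000_000
        counts = apply_poisson_noise(T, I0, seed=2)
        p_ld = projection_from_counts(counts, I0)
        sel = sino.values > 0.1
        assert np.all(np.abs(p_ld[sel] - sino.values[sel]) <= 0.01 * sino.values[sel] + 5e-3)
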