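import numpy as np
import pytest

from ctdenoise.geometry import ScanGeometry, desk_geometry
from ctdenoise.metrics import psnr
from ctdenoise.noise import NoiseParams, simulate_noisy_ili
from ctdenoise.phantoms import disc_phantom
from ctdenoise.preprocessing import AbsorptionSinogram, ILISinogram, to_absorption
from ctdenoise.projection import forward_project
from ctdenoise.recon import FilterSpec, circle_mask, fbp, reconstruct_pipeline


def _absorption(values, geometry, provenance="experimental_clean"):
    return AbsorptionSinogram(values=values, geometry=geometry, epsilon=1e-6,
                              provenance=provenance)


class TestFBP:
    def test_zero_sinogram_gives_zero_image(self, geometry48):
        img = fbp(_absorption(np.zeros(geometry48.sinogram_shape), geometry48))
        assert img.values == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_scaling(self, geometry48, disc48):
        y = forward_project(disc48, geometry48)[0]
        a = fbp(_absorption(y, geometry48)).values
        b = fbp(_absorption(2.0 * y, geometry48)).values
        assert b == pytest.approx(2.0 * a, abs=1e-9)

    def test_disc_round_trip_interior_error(self):
        """FBP of the forward projection recovers the disc within 10%."""
        ph = disc_phantom(128, radius=32.0, mu=0.02)
        g = desk_geometry(128, 360)
        y = forward_project(ph, g)[0]
        recon = fbp(_absorption(y, g), g)
        interior = circle_mask(128, shrink=0.9)
        err = np.linalg.norm((recon.values - ph.attenuation)[interior])
        ref = np.linalg.norm(ph.attenuation[interior])
        assert err / ref < 0.10

    def test_deterministic(self, geometry48, disc48):
        y = forward_project(disc48, geometry48)[0]
        a = fbp(_absorption(y, geometry48)).values
        b = fbp(_absorption(y, geometry48)).values
        assert np.array_equal(a, b)

    def test_filter_cutoff_suppresses_noise(self, geometry48, rng):
        """Band-limiting the ramp filter lowers reconstructed noise power."""
        noise = rng.normal(0.0, 0.05, size=geometry48.sinogram_shape)
        y = _absorption(np.abs(noise), geometry48)
        full = fbp(y, geometry48, FilterSpec("ramp", 1.0)).values
        cut = fbp(y, geometry48, FilterSpec("ramp", 0.5)).values
        mask = circle_mask(48, shrink=0.8)
        assert cut[mask].var() < full[mask].var()

    def test_invalid_filter_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec("butterworth")
        with pytest.raises(ValueError):
            FilterSpec("ramp", 0.0)

    def test_shape_mismatch_rejected(self, geometry48):
        with pytest.raises(ValueError, match="shape"):
            fbp(_absorption(np.zeros((10, 10)), desk_geometry(10, 10)), geometry48)

    def test_fan_beam_rebinning_reconstructs_disc(self):
        # detector pitch chosen so the rebinned parallel grid matches the
        # phantom grid (pitch * SOD / SDD = 1); the two-pass linear
        # interpolation blurs edges slightly, hence the relaxed correlation
        ph = disc_phantom(48, radius=12.0, mu=0.03)
        g = ScanGeometry(beam_type="fan", n_detector_pixels=64,
                         detector_pixel_size=1.5, n_projections=180,
                         angular_increment=2.0, sod=120.0, sdd=180.0)
        y = forward_project(ph, g)[0]
        recon = fbp(_absorption(y, g), g, image_size=48)
        mask = circle_mask(48, shrink=0.7)
        r = np.corrcoef(recon.values[mask], ph.attenuation[mask])[0, 1]
        assert r > 0.85
        # attenuation value recovered quantitatively at the disc centre
        assert recon.values[24, 24] == pytest.approx(0.03, rel=0.05)


class TestReconstructPipeline:
    def test_unit_ili_gives_zero_image(self, geometry48):
        ili = ILISinogram(values=np.ones(geometry48.sinogram_shape),
                          geometry=geometry48, provenance="experimental_clean")
        img = reconstruct_pipeline(ili)
        assert img.values == pytest.approx(0.0, abs=1e-12)
        assert img.provenance == "fbp_of_clean"

    def test_matches_explicit_composition(self, mono_dataset):
        ili = mono_dataset[0].clean_ili()
        a = reconstruct_pipeline(ili).values
        b = fbp(to_absorption(ili), ili.geometry).values
        assert np.array_equal(a, b)

    def test_clean_recon_correlates_with_phantom(self, mono_dataset):
        pair = mono_dataset[0]
        recon = reconstruct_pipeline(pair.clean_ili())
        mask = circle_mask(recon.size)
        r = np.corrcoef(recon.values[mask], pair.phantom.attenuation[mask])[0, 1]
        assert r > 0.95

    def test_noisy_recon_has_lower_psnr_than_clean(self, mono_dataset):
        """Parameterized noise always degrades the reconstruction, every seed."""
        pair = mono_dataset[0]
        clean = pair.clean_ili()
        gt = pair.phantom.attenuation
        mask = circle_mask(pair.phantom.size)
        clean_psnr = psnr(gt, reconstruct_pipeline(clean).values, mask=mask)
        for seed in range(10):
            noisy = simulate_noisy_ili(clean, NoiseParams(I0=200.0, seed=seed))
            noisy_psnr = psnr(gt, reconstruct_pipeline(noisy).values, mask=mask)
            assert noisy_psnr < clean_psnr


def test_noise_amplification_ranking_reversal(geometry48, disc48):
    """Sinogram-domain ranking of two corruptions reverses after FBP.

    Candidate A carries white noise (small sinogram error, strongly
    amplified by the ramp filter); candidate B carries a smooth
    low-frequency error (larger sinogram error, barely amplified).  A
    wins in the sinogram domain and loses in the reconstruction domain.
    """
    rng = np.random.default_rng(99)
    y = forward_project(disc48, geometry48)[0]
    clean = ILISinogram(values=np.exp(-y), geometry=geometry48,
                        provenance="experimental_clean")
    white = rng.normal(0.0, 0.01, size=clean.values.shape)
    smooth = 0.02 * np.sin(
        2 * np.pi * np.arange(geometry48.n_detector_pixels) / geometry48.n_detector_pixels
    )[None, :] * np.ones((geometry48.n_projections, 1))
    cand_a = clean.with_values(clean.values + white, "simulated_noisy")
    cand_b = clean.with_values(clean.values + smooth, "simulated_noisy")

    sino_psnr_a = psnr(clean.values, cand_a.values)
    sino_psnr_b = psnr(clean.values, cand_b.values)
    assert sino_psnr_a > sino_psnr_b  # A better in the sinogram domain

    gt = disc48.attenuation
    mask = circle_mask(48)
    recon_psnr_a = psnr(gt, reconstruct_pipeline(cand_a).values, mask=mask)
    recon_psnr_b = psnr(gt, reconstruct_pipeline(cand_b).values, mask=mask)
    assert recon_psnr_a < recon_psnr_b  # ranking reverses after FBP
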