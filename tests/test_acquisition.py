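import numpy as np
import pytest

from ctdenoise.acquisition import (
    acquire,
    default_fields,
    make_paired_dataset,
)
from ctdenoise.geometry import AcquisitionParams, desk_geometry, twodetect_geometry
from ctdenoise.noise import NoiseParams
from ctdenoise.phantoms import ObjectTag, Phantom, PhantomSpec
from ctdenoise.preprocessing import flatfield_correct
from ctdenoise.recon import circle_mask, reconstruct_pipeline


class TestAcquire:
    def test_bench_geometry_output_shape(self):
        """The full bench-preset acquisition is (3601, 956)."""
        g = twodetect_geometry()
        A = np.full(g.sinogram_shape, 5.0)
        dark, flat = default_fields(g.n_detector_pixels, 100.0, seed=0)
        sino = acquire(A, dark, flat, NoiseParams(sigma_crosstalk=0.0), seed=0,
                       geometry=g, flux_in_vacuum=100.0)
        assert sino.counts.shape == (3601, 956)

    @pytest.mark.parametrize("lam", [5.0, 50.0, 500.0])
    def test_poisson_moments_after_correction(self, lam):
        """Counts minus dark have Poisson mean and variance at flat gain."""
        g = desk_geometry(1000, 100)
        A = np.full(g.sinogram_shape, lam)
        n = A.size
        dark = np.zeros(g.n_detector_pixels)
        flat = np.full(g.n_detector_pixels, 1000.0)
        sino = acquire(A, dark, flat, NoiseParams(sigma_crosstalk=0.0), seed=1,
                       geometry=g, flux_in_vacuum=1000.0)
        counts = sino.counts - sino.dark[None, :]
        tol = 4.0 * np.sqrt(lam / n) * max(1.0, np.sqrt(lam))
        assert abs(counts.mean() - lam) < tol
        assert counts.var() == pytest.approx(lam, rel=0.05)

    def test_law_of_large_numbers_limit(self):
        """At enormous flux the corrected counts match expectation closely."""
        g = desk_geometry(64, 60)
        flux = 1e9
        A = np.full(g.sinogram_shape, 0.5 * flux)
        dark, flat = default_fields(g.n_detector_pixels, flux, seed=2)
        sino = acquire(A, dark, flat, NoiseParams(sigma_crosstalk=0.0), seed=2,
                       geometry=g, flux_in_vacuum=flux)
        ili = flatfield_correct(sino)
        assert np.max(np.abs(ili.values - 0.5)) / 0.5 < 1e-3

    def test_negative_expected_counts_rejected(self):
        g = desk_geometry(8, 180)
        dark, flat = default_fields(8, 10.0, seed=0)
        with pytest.raises(ValueError, match="nonnegative"):
            acquire(np.full(g.sinogram_shape, -1.0), dark, flat, NoiseParams(),
                    geometry=g)

    def test_reproducible_per_seed(self):
        g = desk_geometry(16, 180)
        A = np.full(g.sinogram_shape, 50.0)
        dark, flat = default_fields(16, 100.0, seed=3)
        a = acquire(A, dark, flat, NoiseParams(), seed=5, geometry=g)
        b = acquire(A, dark, flat, NoiseParams(), seed=5, geometry=g)
        assert np.array_equal(a.counts, b.counts)


class TestDefaultFields:
    def test_flat_exceeds_dark_with_bounded_gain(self):
        dark, flat = default_fields(64, 200.0, seed=0)
        assert (flat > dark).all()
        gain = (flat - dark) / 200.0
        assert (gain >= 0.9 - 1e-12).all() and (gain <= 1.1 + 1e-12).all()

    def test_dark_is_one_percent_of_flat_level(self):
        dark, _ = default_fields(32, 500.0, seed=1)
        assert dark == pytest.approx(5.0)


class TestMakePairedDataset:
    def test_deterministic_for_fixed_seed(self, geometry48):
        a = make_paired_dataset(3, geometry=geometry48, seed=10)
        b = make_paired_dataset(3, geometry=geometry48, seed=10)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.phantom.attenuation, pb.phantom.attenuation)
            assert np.array_equal(pa.clean.counts, pb.clean.counts)
            assert np.array_equal(pa.noisy.counts, pb.noisy.counts)

    def test_pair_shares_phantom_and_count_ratio(self, mono_dataset):
        """Clean and noisy differ only in dose: mean count ratio ~ 30."""
        for pair in mono_dataset:
            clean = (pair.clean.counts - pair.clean.dark[None, :]).mean()
            noisy = (pair.noisy.counts - pair.noisy.dark[None, :]).mean()
            assert clean / noisy == pytest.approx(30.0, rel=0.05)

    def test_provenance_tags(self, mono_dataset):
        assert mono_dataset[0].clean.provenance == "experimental_clean"
        assert mono_dataset[0].noisy.provenance == "experimental_noisy"

    def test_differing_exposure_rejected(self, geometry48):
        clean = AcquisitionParams(flux_in_vacuum=6000.0)
        noisy = AcquisitionParams(flux_in_vacuum=200.0, tube_current_ua=33.3,
                                  exposure_time_ms=25.0)
        with pytest.raises(ValueError, match="tube current"):
            make_paired_dataset(1, geometry=geometry48, clean_params=clean,
                                noisy_params=noisy)

    def test_zero_slices_rejected(self, geometry48):
        with pytest.raises(ValueError):
            make_paired_dataset(0, geometry=geometry48)

    def test_monochromatic_log_linear_in_thickness(self, geometry48):
        """-log(corrected counts) is linear in object thickness without
        beam hardening, and measurably concave with it."""
        def effective_mu(mode):
            spec = PhantomSpec(matrix=False, n_small_stones=(0, 0))
            mus = []
            for scale in (1.0, 3.0):
                tag = ObjectTag("matrix", (23.5, 23.5), 18.0, 0.03 * scale,
                                1.0 / 3.0)
                grid = np.zeros((48, 48))
                rr, cc = np.mgrid[0:48, 0:48]
                grid[(rr - 23.5) ** 2 + (cc - 23.5) ** 2 <= 18.0**2] = 0.03 * scale
                ph = Phantom(attenuation=grid, content_tags=(tag,))
                from ctdenoise.geometry import SourceSpectrum
                from ctdenoise.projection import expected_counts, forward_project

                spectrum = (SourceSpectrum.two_energy_surrogate()
                            if mode == "surrogate" else SourceSpectrum.monochromatic())
                L = forward_project(ph, geometry48, spectrum)
                A = expected_counts(L, 1.0, spectrum)
                central = A[geometry48.n_projections // 2,
                            geometry48.n_detector_pixels // 2]
                mus.append(-np.log(central) / (2 * 18.0 * scale))
            return mus

        mono = effective_mu("mono")
        hard = effective_mu("surrogate")
        assert mono[0] == pytest.approx(mono[1], rel=1e-6)  # linear: same slope
        assert hard[1] < hard[0] * 0.97  # concave: effective mu drops with thickness

    def test_surrogate_mode_shows_interobject_streak(self, geometry48):
        """Beam hardening darkens the line between grouped dense objects."""
        spec = PhantomSpec(n_small_stones=(0, 0), grouped_stones=True,
                           n_grouped=(2, 2), grouped_radius_frac=(0.09, 0.10))
        recons = {}
        for mode in ("monochromatic", "experimental_surrogate"):
            ds = make_paired_dataset(1, geometry=geometry48, surrogate_mode=mode,
                                     phantom_spec=spec, seed=77,
                                     sigma_electronic=0.0)
            recons[mode] = reconstruct_pipeline(ds[0].clean_ili(), geometry48)
            phantom = ds[0].phantom
        stones = [t for t in phantom.content_tags
                  if t.kind == "stone_large_grouped"][:2]
        mid = tuple(int(round((a + b) / 2))
                    for a, b in zip(stones[0].center, stones[1].center))
        diff = (recons["monochromatic"].values
                - recons["experimental_surrogate"].values)
        # depression at the midpoint between stones exceeds the typical
        # difference elsewhere in the scan circle
        mask = circle_mask(48, shrink=0.9)
        assert diff[mid] > 3.0 * np.abs(diff[mask]).mean()
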