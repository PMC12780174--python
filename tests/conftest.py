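import numpy as np
import pytest

from ctdenoise import desk_geometry, disc_phantom, make_paired_dataset


@pytest.fixture(scope="session")
def geometry48():
    return desk_geometry(48, 60)


@pytest.fixture(scope="session")
def disc48():
    return disc_phantom(48, radius=12.0, mu=0.03)


@pytest.fixture(scope="session")
def mono_dataset(geometry48):
    """Small monochromatic paired dataset shared across tests."""
    return make_paired_dataset(4, geometry=geometry48, surrogate_mode="monochromatic",
                               seed=11)


@pytest.fixture(scope="session")
def surrogate_dataset(geometry48):
    """Small experimental-surrogate paired dataset shared across tests."""
    return make_paired_dataset(4, geometry=geometry48,
                               surrogate_mode="experimental_surrogate", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# Printed cross-evaluation grid of the reference bench study (mean SSIM/PSNR
# per architecture x training data x test data x evaluation domain), used as
# input data for the report-arithmetic worked examples.
_BENCH_CELLS = [
    # (arch, trained-on, domain, ssim_exp, ssim_sim, psnr_exp, psnr_sim)
    ("unet", "experimental_noisy", "sinogram", 0.8126, 0.8167, 18.4966, 19.3181),
    ("unet", "simulated_noisy", "sinogram", 0.8273, 0.8795, 33.4602, 36.6016),
    ("msdnet", "experimental_noisy", "sinogram", 0.8613, 0.8239, 36.2182, 20.4747),
    ("msdnet", "simulated_noisy", "sinogram", 0.7512, 0.8835, 16.3208, 38.0265),
    ("unet", "experimental_noisy", "reconstruction_of_output", 0.6134, 0.6273, 26.7127, 27.5290),
    ("unet", "simulated_noisy", "reconstruction_of_output", 0.5504, 0.6351, 28.3307, 32.5568),
    ("msdnet", "experimental_noisy", "reconstruction_of_output", 0.5984, 0.6152, 30.9185, 28.3031),
    ("msdnet", "simulated_noisy", "reconstruction_of_output", 0.3854, 0.6372, 11.6366, 32.6552),
    ("unet", "experimental_noisy", "reconstruction_direct", 0.8161, 0.7466, 29.8398, 28.0435),
    ("unet", "simulated_noisy", "reconstruction_direct", 0.5957, 0.6693, 26.8841, 28.8134),
    ("msdnet", "experimental_noisy", "reconstruction_direct", 0.7829, 0.7892, 32.0684, 32.0704),
    ("msdnet", "simulated_noisy", "reconstruction_direct", 0.7615, 0.8204, 30.6211, 33.1053),
]


@pytest.fixture(scope="session")
def bench_report():
    """StudyReport populated with the bench study's printed metric grid."""
    from ctdenoise.study import StudyReport

    records = []
    for arch, tdata, domain, ssim_e, ssim_s, psnr_e, psnr_s in _BENCH_CELLS:
        for test, sv, pv in (("experimental_noisy", ssim_e, psnr_e),
                             ("simulated_noisy", ssim_s, psnr_s)):
            records.append({"architecture": arch, "training_data": tdata,
                            "test_data": test, "domain": domain, "metric": "ssim",
                            "mean": sv, "std": float("nan"), "n_slices": 0,
                            "std_defined": False})
            records.append({"architecture": arch, "training_data": tdata,
                            "test_data": test, "domain": domain, "metric": "psnr",
                            "mean": pv, "std": float("nan"), "n_slices": 0,
                            "std_defined": False})
    return StudyReport.from_records(records)
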