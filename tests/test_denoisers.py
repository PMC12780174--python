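import numpy as np
import pytest

from ctdenoise.denoisers import (
    DenoisingModel,
    NetworkSpec,
    TWODETECT_SPLIT_SIZES,
    TrainingConfig,
    build_network,
    denoise_reconstruction,
    denoise_sinogram,
    split_dataset,
)
from ctdenoise.geometry import desk_geometry
from ctdenoise.nn import get_state
from ctdenoise.preprocessing import ILISinogram
from ctdenoise.recon import ReconImage


class TestBuildNetwork:
    def test_msdnet_dilation_cycle(self):
        net = build_network(NetworkSpec(family="msdnet", msd_layers=20,
                                        msd_dilation_cycle=10))
        assert net.dilations == list(range(1, 11)) + list(range(1, 11))

    def test_unet_has_more_parameters_than_msdnet(self):
        unet = build_network(NetworkSpec(family="unet", unet_depth=3,
                                         unet_base_channels=16))
        msd = build_network(NetworkSpec(family="msdnet", msd_layers=30,
                                        msd_dilation_cycle=10))
        assert unet.n_parameters > msd.n_parameters

    def test_same_seed_identical_weights(self):
        spec = NetworkSpec(family="unet", seed=7)
        a, b = build_network(spec), build_network(spec)
        for pa, pb in zip(get_state(a), get_state(b)):
            assert np.array_equal(pa, pb)

    def test_different_seed_different_weights(self):
        a = build_network(NetworkSpec(family="msdnet", seed=1))
        b = build_network(NetworkSpec(family="msdnet", seed=2))
        assert any(not np.array_equal(pa, pb)
                   for pa, pb in zip(get_state(a), get_state(b)))

    def test_output_shape_equals_input_shape(self, rng):
        x = rng.normal(size=(24, 32)).astype(np.float32)
        for family in ("unet", "msdnet"):
            net = build_network(NetworkSpec(family=family))
            assert net.forward(x).shape == (1, 24, 32)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(family="resnet")


class TestSplitDataset:
    def test_exact_fraction_sizes(self):
        s = split_dataset(10, (0.8, 0.1, 0.1), seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (8, 1, 1)

    def test_disjoint_and_exhaustive(self):
        s = split_dataset(37, (0.8, 0.1, 0.1), seed=3)
        joined = np.concatenate([s.train, s.validation, s.test])
        assert sorted(joined) == list(range(37))

    def test_reproducible_and_seed_sensitive(self):
        a = split_dataset(50, seed=4)
        b = split_dataset(50, seed=4)
        c = split_dataset(50, seed=5)
        assert np.array_equal(a.train, b.train)
        assert not np.array_equal(a.train, c.train)

    def test_bench_reference_split_sizes(self):
        assert TWODETECT_SPLIT_SIZES == (3930, 550, 470)
        assert sum(TWODETECT_SPLIT_SIZES) == 4950

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(10, (0.5, 0.2, 0.2), seed=0)


def _toy_sino_pairs(n, geometry, rng, noise=0.1):
    pairs = []
    for _ in range(n):
        clean_vals = np.clip(rng.uniform(0.2, 1.0) * np.ones(geometry.sinogram_shape)
                             - rng.uniform(0, 0.3), 0.05, 1.0)
        clean_vals[:, 8:24] *= rng.uniform(0.4, 0.9)
        noisy_vals = clean_vals + rng.normal(0, noise, size=clean_vals.shape)
        clean = ILISinogram(values=clean_vals, geometry=geometry,
                            provenance="experimental_clean")
        noisy = ILISinogram(values=noisy_vals, geometry=geometry,
                            provenance="experimental_noisy")
        pairs.append((noisy, clean))
    return pairs


class TestTraining:
    GEOM = desk_geometry(32, 32)

    def test_training_descends(self, rng):
        pairs = _toy_sino_pairs(10, self.GEOM, rng)
        cfg = TrainingConfig(domain="sinogram", epochs=5, seed=0)
        model = DenoisingModel(pairs, NetworkSpec(family="msdnet", msd_layers=4,
                                                  msd_dilation_cycle=2, seed=0),
                               cfg).fit()
        h = model.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]

    def test_selected_epoch_is_val_loss_argmin(self, rng):
        pairs = _toy_sino_pairs(10, self.GEOM, rng)
        cfg = TrainingConfig(domain="sinogram", epochs=6, seed=1)
        model = DenoisingModel(pairs, NetworkSpec(family="unet", unet_depth=1,
                                                  unet_base_channels=4, seed=1),
                               cfg).fit()
        h = model.history
        assert model.selected_epoch == int(h["val_loss"].idxmin())
        assert h.loc[model.selected_epoch, "val_loss"] == h["val_loss"].min()

    def test_deterministic_given_seed(self, rng):
        pairs = _toy_sino_pairs(8, self.GEOM, rng)
        cfg = TrainingConfig(domain="sinogram", epochs=3, seed=2)
        spec = NetworkSpec(family="msdnet", msd_layers=3, msd_dilation_cycle=2, seed=2)
        a = DenoisingModel(pairs, spec, cfg).fit()
        b = DenoisingModel(pairs, spec, cfg).fit()
        x = pairs[0][0].values
        assert np.array_equal(a.predict(x), b.predict(x))

    def test_absorption_inputs_rejected(self, rng):
        """The pipeline-order contract: denoisers consume pre-log ILI only."""
        from ctdenoise.preprocessing import to_absorption

        pairs = _toy_sino_pairs(4, self.GEOM, rng)
        bad = [(to_absorption(a), to_absorption(b)) for a, b in pairs]
        with pytest.raises(TypeError, match="ILISinogram"):
            DenoisingModel(bad, NetworkSpec(), TrainingConfig(domain="sinogram"))

    def test_clean_inputs_rejected_for_sinogram_training(self, rng):
        pairs = [(b, b) for _, b in _toy_sino_pairs(4, self.GEOM, rng)]
        with pytest.raises(ValueError, match="noisy"):
            DenoisingModel(pairs, NetworkSpec(), TrainingConfig(domain="sinogram"))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            DenoisingModel([], NetworkSpec(), TrainingConfig())

    def test_summary_mentions_selection(self, rng):
        pairs = _toy_sino_pairs(8, self.GEOM, rng)
        model = DenoisingModel(pairs, NetworkSpec(family="msdnet", msd_layers=3,
                                                  msd_dilation_cycle=3, seed=0),
                               TrainingConfig(epochs=3, seed=0)).fit()
        text = model.summary()
        assert "selected epoch" in text and "msdnet" in text


class TestInference:
    GEOM = desk_geometry(32, 32)

    @pytest.fixture(scope="class")
    def sino_model(self):
        rng = np.random.default_rng(0)
        pairs = _toy_sino_pairs(8, self.GEOM, rng)
        return DenoisingModel(pairs, NetworkSpec(family="msdnet", msd_layers=3,
                                                 msd_dilation_cycle=2, seed=0),
                              TrainingConfig(domain="sinogram", epochs=2, seed=0)).fit()

    def test_denoise_sinogram_shape_and_determinism(self, sino_model, rng):
        noisy = ILISinogram(values=rng.uniform(0, 1, self.GEOM.sinogram_shape),
                            geometry=self.GEOM, provenance="experimental_noisy")
        a = denoise_sinogram(sino_model, noisy)
        b = denoise_sinogram(sino_model, noisy)
        assert a.values.shape == noisy.values.shape
        assert np.array_equal(a.values, b.values)
        assert a.provenance == "denoised_experimental_noisy"

    def test_domain_mismatch_rejected(self, sino_model, rng):
        from ctdenoise.acquisition import make_paired_dataset

        ds = make_paired_dataset(1, geometry=self.GEOM, seed=0)
        with pytest.raises(ValueError, match="domain"):
            denoise_reconstruction(sino_model, ds[0].noisy)

    def test_reconstruction_pipeline_shape_contract(self, rng):
        """(n_proj x n_det) counts in, (N x N) image out."""
        from ctdenoise.acquisition import make_paired_dataset
        from ctdenoise.recon import reconstruct_pipeline

        ds = make_paired_dataset(4, geometry=self.GEOM, seed=1)
        recon_pairs = []
        for p in ds:
            ref = reconstruct_pipeline(p.clean_ili(), self.GEOM)
            noisy = reconstruct_pipeline(p.noisy_ili(), self.GEOM)
            recon_pairs.append((noisy, ref))
        model = DenoisingModel(
            recon_pairs, NetworkSpec(family="msdnet", msd_layers=3,
                                     msd_dilation_cycle=2, seed=0),
            TrainingConfig(domain="reconstruction", epochs=2, seed=0,
                           pipeline_filter="ramp"),
        ).fit()
        out = denoise_reconstruction(model, ds[0].noisy)
        assert out.values.shape == (32, 32)
        assert out.provenance == "fbp_of_denoised"

    def test_identity_task_reproduces_reconstruction(self, rng):
        """A network trained on identical input/target pairs stays near identity."""
        from ctdenoise.acquisition import make_paired_dataset
        from ctdenoise.recon import reconstruct_pipeline

        ds = make_paired_dataset(6, geometry=self.GEOM, seed=2)
        recons = [reconstruct_pipeline(p.clean_ili(), self.GEOM) for p in ds]
        pairs = [(r, r) for r in recons]
        model = DenoisingModel(
            pairs, NetworkSpec(family="msdnet", msd_layers=3, msd_dilation_cycle=2,
                               seed=0),
            TrainingConfig(domain="reconstruction", epochs=3, seed=0,
                           pipeline_filter="ramp"),
        ).fit()
        x = recons[0].values
        rms = np.sqrt(np.mean((model.predict(x) - x) ** 2))
        assert rms < 0.1 * np.sqrt(np.mean(x**2)) + 1e-6
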