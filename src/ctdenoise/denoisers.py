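"""Learned denoisers: U-Net and MSD-Net in two training regimes.

Sinogram-domain models map noisy beam intensity loss images to clean
ones (denoising happens before the negative logarithm — enforced by
type and provenance checks).  Reconstruction-domain ("FBP+") models map
the FBP of a noisy sinogram directly to a clean reconstruction.

The training API follows the model/results convention:
``DenoisingModel(pairs, spec, config).fit()`` returns a
:class:`TrainedDenoiser` carrying the weights of the epoch with minimal
validation loss, the full loss history, and the training provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .preprocessing import ILISinogram, flatfield_correct, to_absorption
from .recon import FilterSpec, ReconImage, fbp

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "TrainedDenoiser",
    "DenoisingModel",
    "build_network",
    "split_dataset",
    "train",
    "denoise_sinogram",
    "denoise_reconstruction",
    "denoise_reconstruction_ili",
    "TWODETECT_SPLIT_SIZES",
]

#: reference split sizes of the full-scale bench dataset (train/val/test)
TWODETECT_SPLIT_SIZES = (3930, 550, 470)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture specification for a denoiser network."""

    family: str = "unet"  # {"unet", "msdnet"}
    unet_depth: int = 2
    unet_base_channels: int = 8
    msd_layers: int = 10
    msd_dilation_cycle: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("unet", "msdnet"):
            raise ValueError(f"unknown network family {self.family!r}")
        if min(self.unet_depth, self.unet_base_channels, self.msd_layers,
               self.msd_dilation_cycle) < 1:
            raise ValueError("network size fields must be positive")


def build_network(spec: NetworkSpec):
    """Instantiate an untrained network with deterministic initialization."""
    if spec.family == "unet":
        return nn.UNet(depth=spec.unet_depth, base_channels=spec.unet_base_channels,
                       seed=spec.seed)
    return nn.MSDNet(n_layers=spec.msd_layers, dilation_cycle=spec.msd_dilation_cycle,
                     seed=spec.seed)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (Adam, MSE loss by default)."""

    domain: str = "sinogram"  # {"sinogram", "reconstruction"}
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 1
    loss: str = "mse"
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    #: FBP filter of the in-pipeline reconstruction of "FBP+" models; an
    #: apodized filter stabilizes the network input at low dose
    pipeline_filter: str = "hann"

    def __post_init__(self) -> None:
        if self.domain not in ("sinogram", "reconstruction"):
            raise ValueError(f"unknown training domain {self.domain!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mse":
            raise ValueError("only the mse loss is implemented")
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def split_dataset(
    n_or_items, fractions: Sequence[float] = (0.8, 0.1, 0.1), seed: int = 0
) -> SplitIndices:
    """Random disjoint, exhaustive train/validation/test index split.

    Sizes follow largest-remainder rounding of the fractions (n = 10 at
    (0.8, 0.1, 0.1) gives 8/1/1); deterministic per seed.
    """
    n = n_or_items if isinstance(n_or_items, (int, np.integer)) else len(n_or_items)
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    counts = np.floor(fractions * n).astype(int)
    for _ in range(n - counts.sum()):  # distribute remainder by largest fractional part
        counts[np.argmax(fractions * n - counts)] += 1
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5B11)))
    perm = rng.permutation(n)
    edges = np.cumsum(counts)[:-1]
    tr, va, te = np.split(perm, edges)
    return SplitIndices(np.sort(tr), np.sort(va), np.sort(te))


class TrainedDenoiser:
    """Results object of a denoiser fit.

    Attributes
    ----------
    history : pandas.DataFrame
        Per-epoch train and validation loss.
    selected_epoch : int
        1-based epoch whose weights are carried (argmin of validation
        loss).
    provenance : dict
        ``training_data`` in {"experimental_noisy", "simulated_noisy"}
        and ``domain`` in {"sinogram", "reconstruction"}.
    """

    def __init__(self, spec, config, state, history, selected_epoch, provenance, scale):
        self.spec = spec
        self.config = config
        self.state = state
        self.history = history
        self.selected_epoch = int(selected_epoch)
        self.provenance = dict(provenance)
        self.scale = float(scale)
        self._net = build_network(spec)
        nn.set_state(self._net, state)

    @property
    def domain(self) -> str:
        return self.provenance["domain"]

    @property
    def n_parameters(self) -> int:
        return self._net.n_parameters

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Denoise one 2-D array (deterministic at inference)."""
        out = self._net.forward(np.asarray(values, dtype=float) * self.scale)
        return out[0] / self.scale

    def summary(self) -> str:
        h = self.history
        lines = [
            f"TrainedDenoiser [{self.spec.family}]",
            f"  domain:           {self.domain}",
            f"  training data:    {self.provenance['training_data']}",
            f"  parameters:       {self.n_parameters}",
            f"  epochs trained:   {len(h)}",
            f"  selected epoch:   {self.selected_epoch} "
            f"(val loss {h['val_loss'].min():.6g})",
            f"  final train loss: {h['train_loss'].iloc[-1]:.6g}",
        ]
        return "\n".join(lines)


class DenoisingModel:
    """Supervised denoiser ready to fit.

    Parameters
    ----------
    pairs : sequence of (input, target)
        Sinogram domain: (noisy :class:`ILISinogram`, clean
        :class:`ILISinogram`).  Reconstruction domain: (noisy
        :class:`ReconImage`, ground-truth :class:`ReconImage`).
        Absorption sinograms are rejected: denoising is defined on the
        pre-log representation.
    """

    def __init__(self, pairs, spec: NetworkSpec, config: TrainingConfig,
                 training_data: str = "experimental_noisy",
                 split: SplitIndices | None = None):
        if len(pairs) == 0:
            raise ValueError("empty dataset")
        self._validate_pairs(pairs, config.domain)
        self.pairs = [(np.asarray(a.values, dtype=float), np.asarray(b.values, dtype=float))
                      for a, b in pairs]
        self.spec = spec
        self.config = config
        self.training_data = training_data
        self.split = split or split_dataset(len(pairs), config.split_fractions, config.seed)
        if len(self.split.train) == 0 or len(self.split.validation) == 0:
            raise ValueError("train and validation splits must be non-empty")

    @staticmethod
    def _validate_pairs(pairs, domain):
        want = ILISinogram if domain == "sinogram" else ReconImage
        for a, b in pairs:
            if not isinstance(a, want) or not isinstance(b, want):
                raise TypeError(
                    f"{domain}-domain training expects {want.__name__} pairs, "
                    f"got ({type(a).__name__}, {type(b).__name__})"
                )
            if domain == "sinogram" and "noisy" not in a.provenance:
                raise ValueError(
                    f"sinogram-domain inputs must be noisy ILI, got {a.provenance!r}"
                )

    def fit(self) -> TrainedDenoiser:
        """Train with Adam/MSE; return the min-validation-loss weights."""
        cfg = self.config
        net = build_network(self.spec)
        opt = nn.Adam(net.params(), lr=cfg.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence((int(cfg.seed), 0x7A11)))
        # normalize targets to O(1) amplitude so one learning rate serves both domains
        tmax = max(float(np.abs(t).max()) for _, t in self.pairs) or 1.0
        scale = 1.0 / tmax
        train_idx = self.split.train.copy()
        history = []
        best = (np.inf, None, -1)
        for epoch in range(1, cfg.epochs + 1):
            rng.shuffle(train_idx)
            losses = []
            for start in range(0, len(train_idx), cfg.batch_size):
                batch = train_idx[start : start + cfg.batch_size]
                opt.zero_grad()
                for i in batch:
                    x, t = self.pairs[i]
                    out = net.forward(x * scale)
                    diff = out - t[None] * scale
                    losses.append(float(np.mean(diff**2)))
                    net.backward(2.0 * diff / (diff.size * len(batch)))
                opt.step()
            val = float(
                np.mean([
                    np.mean((net.forward(self.pairs[i][0] * scale)
                             - self.pairs[i][1][None] * scale) ** 2)
                    for i in self.split.validation
                ])
            )
            history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                            "val_loss": val})
            if val < best[0]:
                best = (val, nn.get_state(net), epoch)
        hist = pd.DataFrame(history).set_index("epoch")
        return TrainedDenoiser(
            spec=self.spec,
            config=cfg,
            state=best[1],
            history=hist,
            selected_epoch=best[2],
            provenance={"training_data": self.training_data, "domain": cfg.domain},
            scale=scale,
        )


def train(spec: NetworkSpec, pairs, config: TrainingConfig,
          training_data: str = "experimental_noisy") -> TrainedDenoiser:
    """Functional wrapper around :class:`DenoisingModel`."""
    return DenoisingModel(pairs, spec, config, training_data).fit()


def denoise_sinogram(model: TrainedDenoiser, ili_noisy: ILISinogram) -> ILISinogram:
    """Apply a sinogram-domain denoiser to a noisy ILI."""
    if model.domain != "sinogram":
        raise ValueError(f"model domain is {model.domain!r}, expected 'sinogram'")
    if not isinstance(ili_noisy, ILISinogram):
        raise TypeError("denoise_sinogram consumes pre-log ILI sinograms")
    out = model.predict(ili_noisy.values)
    return ili_noisy.with_values(out, provenance=f"denoised_{ili_noisy.provenance}")


def denoise_reconstruction_ili(
    model: TrainedDenoiser,
    ili_noisy: ILISinogram,
    filter_spec: FilterSpec | None = None,
    image_size: int | None = None,
) -> ReconImage:
    """Reconstruction-domain denoising starting from a noisy ILI.

    The in-pipeline FBP uses the filter the model was trained with
    (``model.config.pipeline_filter``) unless overridden.
    """
    if model.domain != "reconstruction":
        raise ValueError(f"model domain is {model.domain!r}, expected 'reconstruction'")
    if filter_spec is None:
        filter_spec = FilterSpec(kind=model.config.pipeline_filter)
    noisy_recon = fbp(to_absorption(ili_noisy), ili_noisy.geometry, filter_spec, image_size)
    out = model.predict(noisy_recon.values)
    return ReconImage(values=out, pixel_size=noisy_recon.pixel_size,
                      provenance="fbp_of_denoised")


def denoise_reconstruction(
    model: TrainedDenoiser,
    noisy_counts,
    filter_spec: FilterSpec | None = None,
    image_size: int | None = None,
) -> ReconImage:
    """Full "FBP+" path: flat-field correction, log, FBP, then network."""
    return denoise_reconstruction_ili(
        model, flatfield_correct(noisy_counts), filter_spec, image_size
    )
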