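"""Cross-evaluation study: architectures x training data x test data x domains.

The study trains both denoiser families on both noise types
(experimental-surrogate and simulated) in both optimization domains,
then evaluates every model on both test sets — in the sinogram domain
and as "FBP of model output" for sinogram-domain models, and directly
for reconstruction-domain ("FBP+") models.  Results aggregate to a
mean +/- std grid with named gap statistics: the matched-minus-
mismatched generalization gap of simulated-trained models, and the
improvement from optimizing in the reconstruction domain.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .acquisition import PairedDataset, make_paired_dataset
from .calibration import NoiseLevelCalibration
from .denoisers import (
    DenoisingModel,
    NetworkSpec,
    TrainingConfig,
    denoise_reconstruction_ili,
    denoise_sinogram,
    split_dataset,
)
from .geometry import desk_geometry
from .metrics import psnr, ssim
from .noise import NoiseParams, simulate_noisy_ili
from .phantoms import PhantomSpec
from .preprocessing import ILISinogram
from .recon import FilterSpec, ReconImage, circle_mask, reconstruct_pipeline

__all__ = [
    "EvalSlice",
    "StudyReport",
    "evaluate_study",
    "StudyConfig",
    "StudyResult",
    "run_study",
]

ARCHITECTURES = ("unet", "msdnet")
TRAINING_TYPES = ("experimental_noisy", "simulated_noisy")
TEST_TYPES = ("experimental_noisy", "simulated_noisy")
DOMAINS = ("sinogram", "reconstruction")


@dataclass(frozen=True)
class EvalSlice:
    """One test slice: noisy input, clean sinogram, reference reconstruction.

    ``reference_recon`` is the reconstruction-domain comparison target —
    the reconstruction of the clean acquisition of the same slice (the
    synthetic analogue of a reference reconstruction computed from the
    high-dose scan).
    """

    noisy_ili: ILISinogram
    clean_ili: ILISinogram
    reference_recon: ReconImage


class StudyReport:
    """Metric grid of the cross-evaluation study.

    Cells are indexed by (architecture, training_data, test_data,
    domain, metric) where domain is one of ``sinogram``,
    ``reconstruction_of_output`` or ``reconstruction_direct``.  Gap
    statistics are exact differences of cell means.
    """

    def __init__(self, cells: pd.DataFrame, missing: list | None = None):
        self.cells = cells
        self.missing = missing or []

    _KEY = ["architecture", "training_data", "test_data", "domain", "metric"]

    @classmethod
    def from_records(cls, records, missing=None) -> "StudyReport":
        return cls(pd.DataFrame(records), missing)

    def value(self, architecture, training_data, test_data, domain, metric) -> float:
        sel = self.cells
        for col, v in zip(self._KEY, (architecture, training_data, test_data, domain, metric)):
            sel = sel[sel[col] == v]
        if len(sel) != 1:
            raise KeyError(
                f"no unique cell ({architecture}, {training_data}, {test_data}, "
                f"{domain}, {metric})"
            )
        return float(sel["mean"].iloc[0])

    def gap(self, key_a: dict, key_b: dict) -> float:
        """Exact difference of two cell means, value(a) - value(b)."""
        return self.value(**key_a) - self.value(**key_b)

    def matched_minus_mismatched(self, architecture, metric,
                                 domain="sinogram",
                                 training_data="simulated_noisy") -> float:
        """Generalization gap: matched test set minus the other test set."""
        matched = dict(architecture=architecture, training_data=training_data,
                       test_data=training_data, domain=domain, metric=metric)
        other = [t for t in TEST_TYPES if t != training_data][0]
        mismatched = {**matched, "test_data": other}
        return self.gap(matched, mismatched)

    def domain_optimization_improvement(self, training_data, test_data,
                                        metric="ssim") -> float:
        """Best direct-reconstruction model minus best FBP-of-output model.

        Compares, for a fixed training/testing constellation, the best
        architecture optimized in the reconstruction domain against the
        best architecture optimized in the sinogram domain, both scored
        in the reconstruction domain.
        """
        def best(domain):
            vals = []
            for arch in ARCHITECTURES:
                try:
                    vals.append(self.value(arch, training_data, test_data, domain, metric))
                except KeyError:
                    pass
            if not vals:
                raise KeyError(f"no cells for domain {domain!r}")
            return max(vals)

        return best("reconstruction_direct") - best("reconstruction_of_output")

    def summary(self) -> str:
        lines = ["Cross-evaluation study report", ""]
        for domain in ("sinogram", "reconstruction_of_output", "reconstruction_direct"):
            block = self.cells[self.cells["domain"] == domain]
            if block.empty:
                continue
            lines.append(f"-- evaluation: {domain} --")
            pivot = block.pivot_table(
                index=["architecture", "training_data", "metric"],
                columns="test_data", values="mean",
            )
            lines.append(pivot.to_string(float_format=lambda v: f"{v:.4f}"))
            lines.append("")
        if self.missing:
            lines.append(f"missing cells: {self.missing}")
        return "\n".join(lines)


def _aggregate(values):
    values = [v for v in values]
    mean = float(np.mean(values))
    std = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
    return mean, std, len(values)


def evaluate_study(models, test_sets: dict, geometry=None) -> StudyReport:
    """Evaluate trained models over the full test grid.

    Parameters
    ----------
    models : sequence of TrainedDenoiser
        Should cover architectures x training types x domains; grid
        cells with no model are reported in ``StudyReport.missing``.
    test_sets : dict
        Maps test-data type ("experimental_noisy" / "simulated_noisy")
        to a list of :class:`EvalSlice`.
    """
    records = []
    covered = set()
    for model in models:
        arch = model.spec.family
        tdata = model.provenance["training_data"]
        covered.add((arch, tdata, model.domain))
        for test_name, slices in test_sets.items():
            per_domain: dict[str, dict[str, list]] = {}
            for sl in slices:
                mask = circle_mask(sl.reference_recon.size)
                if model.domain == "sinogram":
                    out = denoise_sinogram(model, sl.noisy_ili)
                    ref = sl.clean_ili.values
                    per_domain.setdefault("sinogram", {"ssim": [], "psnr": []})
                    per_domain["sinogram"]["ssim"].append(ssim(ref, out.values))
                    per_domain["sinogram"]["psnr"].append(psnr(ref, out.values))
                    recon = reconstruct_pipeline(out, out.geometry)
                    gt = sl.reference_recon.values
                    per_domain.setdefault("reconstruction_of_output", {"ssim": [], "psnr": []})
                    per_domain["reconstruction_of_output"]["ssim"].append(
                        ssim(gt, recon.values, mask=mask))
                    per_domain["reconstruction_of_output"]["psnr"].append(
                        psnr(gt, recon.values, mask=mask))
                else:
                    recon = denoise_reconstruction_ili(model, sl.noisy_ili)
                    gt = sl.reference_recon.values
                    per_domain.setdefault("reconstruction_direct", {"ssim": [], "psnr": []})
                    per_domain["reconstruction_direct"]["ssim"].append(
                        ssim(gt, recon.values, mask=mask))
                    per_domain["reconstruction_direct"]["psnr"].append(
                        psnr(gt, recon.values, mask=mask))
            for domain, metrics in per_domain.items():
                for metric, vals in metrics.items():
                    mean, std, n = _aggregate(vals)
                    records.append({
                        "architecture": arch, "training_data": tdata,
                        "test_data": test_name, "domain": domain, "metric": metric,
                        "mean": mean, "std": std, "n_slices": n,
                        "std_defined": n > 1,
                    })
    missing = [
        (a, t, d)
        for a in ARCHITECTURES for t in TRAINING_TYPES for d in DOMAINS
        if (a, t, d) not in covered
    ]
    return StudyReport.from_records(records, missing)


@dataclass(frozen=True)
class StudyConfig:
    """End-to-end study settings (the desk preset is the default)."""

    n_slices: int = 60
    image_size: int = 48
    n_projections: int = 60
    epochs: int = 20
    batch_size: int = 1
    learning_rate: float = 1e-3
    i0_grid: tuple = (150.0, 200.0, 250.0, 300.0)
    split_fractions: tuple = (0.8, 0.1, 0.1)
    sigma_crosstalk: float = 0.05
    pipeline_filter: str = "hann"  # in-pipeline FBP filter of the FBP+ models
    unet: NetworkSpec = field(default_factory=lambda: NetworkSpec(
        family="unet", unet_depth=2, unet_base_channels=8))
    msdnet: NetworkSpec = field(default_factory=lambda: NetworkSpec(
        family="msdnet", msd_layers=20, msd_dilation_cycle=10))

    @classmethod
    def twodetect_like(cls) -> "StudyConfig":
        """Full-scale preset mirroring the bench study's constants."""
        return cls(
            n_slices=sum((3930, 550, 470)) // 50,  # slices per data mode, desk-bounded
            image_size=128,
            n_projections=360,
            epochs=100,
            i0_grid=(200.0, 250.0, 300.0, 350.0),
            unet=NetworkSpec(family="unet", unet_depth=4, unet_base_channels=32),
            msdnet=NetworkSpec(family="msdnet", msd_layers=100, msd_dilation_cycle=10),
        )


@dataclass
class StudyResult:
    report: StudyReport
    calibration: object
    models: list
    manifest: dict


def _prepare_slices(dataset: PairedDataset, i0: float, seed: int, geometry,
                    sigma_crosstalk: float = 0.05):
    """Per-slice (clean, experimental-noisy, simulated-noisy, reference) tuples.

    The reference is the ramp-filtered reconstruction of the clean
    acquisition — the comparison target for every reconstruction-domain
    metric of the study.
    """
    out = []
    for pair in dataset:
        clean = pair.clean_ili()
        exp_noisy = pair.noisy_ili()
        sim_seed = int(
            np.random.SeedSequence((int(seed), pair.index, 0x51D)).generate_state(1)[0]
            % (2**31)
        )
        sim_noisy = simulate_noisy_ili(
            clean,
            NoiseParams(I0=i0, sigma_crosstalk=sigma_crosstalk, seed=sim_seed),
        )
        reference = reconstruct_pipeline(clean, geometry)
        out.append((clean, exp_noisy, sim_noisy, reference))
    return out


def run_study(config: StudyConfig = StudyConfig(), seed: int = 0) -> StudyResult:
    """Execute the full study: simulate, calibrate, train 8 models, evaluate."""
    t_start = time.time()
    geometry = desk_geometry(config.image_size, config.n_projections)
    phantom_spec = PhantomSpec(grouped_stones=True)
    dataset = make_paired_dataset(
        config.n_slices,
        geometry=geometry,
        surrogate_mode="experimental_surrogate",
        seed=int(np.random.SeedSequence((int(seed), 0xDA7A)).generate_state(1)[0] % (2**31)),
        phantom_spec=phantom_spec,
        sigma_crosstalk=config.sigma_crosstalk,
    )
    split = split_dataset(len(dataset), config.split_fractions, seed)

    # calibration on the validation slices, against their reference recons
    clean_val = [dataset[i].clean_ili() for i in split.validation]
    noisy_val = [dataset[i].noisy_ili() for i in split.validation]
    ref_val = [reconstruct_pipeline(c, geometry) for c in clean_val]
    calib = NoiseLevelCalibration(
        clean_val, noisy_val, ref_val, i0_grid=config.i0_grid, geometry=geometry,
        sigma_crosstalk=config.sigma_crosstalk,
    ).fit(seed=seed)
    i0 = calib.selected_i0

    slices = _prepare_slices(dataset, i0, seed, geometry, config.sigma_crosstalk)

    def gt_of(i):
        return slices[i][3]

    # training pair tables per (training_data, domain)
    def sino_pairs(kind):
        src = 1 if kind == "experimental_noisy" else 2
        return [(slices[i][src], slices[i][0]) for i in range(len(slices))]

    pipeline_filter = FilterSpec(kind=config.pipeline_filter)

    def recon_pairs(kind):
        src = 1 if kind == "experimental_noisy" else 2
        out = []
        for i in range(len(slices)):
            noisy_recon = reconstruct_pipeline(slices[i][src], geometry, pipeline_filter)
            out.append((noisy_recon, gt_of(i)))
        return out

    models = []
    for arch_name, spec in (("unet", config.unet), ("msdnet", config.msdnet)):
        for tdata in TRAINING_TYPES:
            for domain in DOMAINS:
                pairs = sino_pairs(tdata) if domain == "sinogram" else recon_pairs(tdata)
                model_seed = int(
                    np.random.SeedSequence(
                        (int(seed), ARCHITECTURES.index(arch_name),
                         TRAINING_TYPES.index(tdata), DOMAINS.index(domain))
                    ).generate_state(1)[0] % (2**31)
                )
                cfg = TrainingConfig(
                    domain=domain, epochs=config.epochs,
                    learning_rate=config.learning_rate,
                    batch_size=config.batch_size, seed=model_seed,
                    split_fractions=config.split_fractions,
                    pipeline_filter=config.pipeline_filter,
                )
                spec_seeded = NetworkSpec(**{**asdict(spec), "seed": model_seed})
                model = DenoisingModel(pairs, spec_seeded, cfg, training_data=tdata,
                                       split=split).fit()
                models.append(model)

    test_sets = {
        "experimental_noisy": [
            EvalSlice(slices[i][1], slices[i][0], gt_of(i)) for i in split.test
        ],
        "simulated_noisy": [
            EvalSlice(slices[i][2], slices[i][0], gt_of(i)) for i in split.test
        ],
    }
    report = evaluate_study(models, test_sets, geometry)

    manifest = {
        "package_version": _pkg_version,
        "seed": int(seed),
        "config": asdict(config),
        "selected_i0": float(i0),
        "split": {
            "train": split.train.tolist(),
            "validation": split.validation.tolist(),
            "test": split.test.tolist(),
        },
        "n_models": len(models),
        "elapsed_s": round(time.time() - t_start, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return StudyResult(report=report, calibration=calib, models=models, manifest=manifest)
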