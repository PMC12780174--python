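"""SSIM and PSNR with an explicit data-range policy.

CT images are unbounded, so the reference range used by both metrics is
a reported choice, not a hidden default: ``gt_range`` (max - min of the
reference image, per slice) or ``fixed(value)``.  Values are never
clipped.  Reconstruction-domain metrics are computed inside the
inscribed reconstruction circle only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricRecord", "psnr", "ssim", "resolve_range"]


@dataclass(frozen=True)
class MetricRecord:
    """One metric evaluation with its full context."""

    metric: str  # {"ssim", "psnr"}
    value: float
    reference_id: str = ""
    test_id: str = ""
    domain: str = ""  # {"sinogram", "reconstruction_of_output", "reconstruction_direct"}
    data_range_policy: str = "gt_range"
    infinite: bool = False


def resolve_range(reference: np.ndarray, data_range_policy) -> float:
    """Resolve a data-range policy against a reference image."""
    if data_range_policy == "gt_range":
        rng = float(reference.max() - reference.min())
    elif isinstance(data_range_policy, tuple) and data_range_policy[0] == "fixed":
        rng = float(data_range_policy[1])
    elif isinstance(data_range_policy, (int, float)):
        rng = float(data_range_policy)
    else:
        raise ValueError(f"unknown data range policy {data_range_policy!r}")
    if rng <= 0:
        raise ValueError("data range must be positive")
    return rng


def psnr(
    reference: np.ndarray,
    test: np.ndarray,
    data_range_policy="gt_range",
    mask: np.ndarray | None = None,
) -> float:
    """Peak signal-to-noise ratio, 20*log10(range / rms error), in dB.

    Identical images give ``math.inf`` (callers flag it rather than
    receiving an arbitrary cap).
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("shape mismatch")
    rng = resolve_range(reference, data_range_policy)
    diff = reference - test
    if mask is not None:
        diff = diff[mask]
    mse = float(np.mean(diff**2))
    if mse == 0.0:
        return math.inf
    return 20.0 * math.log10(rng / math.sqrt(mse))


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    data_range_policy="gt_range",
    win_size: int = 7,
    mask: np.ndarray | None = None,
) -> float:
    """Mean local structural similarity (uniform 7x7 window by default).

    Identical images give exactly 1.0.  With a mask, the local SSIM map
    is averaged over the masked pixels only.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("shape mismatch")
    if win_size > min(reference.shape):
        raise ValueError("window larger than image")
    if np.array_equal(reference, test):
        return 1.0
    rng = resolve_range(reference, data_range_policy)
    mean_ssim, ssim_map = structural_similarity(
        reference,
        test,
        win_size=win_size,
        data_range=rng,
        gaussian_weights=False,
        full=True,
    )
    if mask is None:
        return float(mean_ssim)
    return float(ssim_map[mask].mean())
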