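"""Flat-field correction and Beer-Lambert log transform.

Raw counts S with dark field D and flat field F become the beam
intensity loss image ILI = (S - D) / (F - D), the fraction of beam
intensity surviving along each ray.  The absorption sinogram is
y = -log(ILI).  Denoising operates on the ILI (pre-log) representation:
the logarithm amplifies noise where the signal is low and changes its
distribution, so every denoising path in this package consumes ILI
inputs, never y.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ScanGeometry

__all__ = [
    "ILISinogram",
    "AbsorptionSinogram",
    "flatfield_correct",
    "to_absorption",
    "from_absorption",
]

#: provenance tags for ILI data
ILI_PROVENANCES = ("experimental_clean", "experimental_noisy", "simulated_noisy")


@dataclass(frozen=True)
class ILISinogram:
    """Beam intensity loss image: flat-field-corrected sinogram.

    Values are nominally in [0, 1]; noise may push individual pixels
    slightly outside and those values are retained here (they are only
    clamped at the absorption step, preserving the noise distribution
    the denoisers must learn).
    """

    values: np.ndarray
    geometry: ScanGeometry
    provenance: str

    def __post_init__(self) -> None:
        if self.values.shape != self.geometry.sinogram_shape:
            raise ValueError(
                f"ILI shape {self.values.shape} does not match geometry "
                f"{self.geometry.sinogram_shape}"
            )
        if not self.provenance:
            raise ValueError("provenance tag must be set")

    def with_values(self, values: np.ndarray, provenance: str | None = None) -> "ILISinogram":
        return replace(
            self, values=values, provenance=provenance if provenance else self.provenance
        )


@dataclass(frozen=True)
class AbsorptionSinogram:
    """Negative-log sinogram y = -log(max(ILI, eps)), clamped to y >= 0."""

    values: np.ndarray
    geometry: ScanGeometry
    epsilon: float
    n_clamped: int = 0
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("absorption sinogram must be finite")
        if np.any(self.values < 0):
            raise ValueError("absorption sinogram must be nonnegative")


def flatfield_correct(sinogram) -> ILISinogram:
    """Dark- and flat-field correction, ILI = (S - D) / (F - D).

    ``sinogram`` is a :class:`~ctdenoise.acquisition.PhotonSinogram`;
    D and F are per-detector-pixel and broadcast over projections.
    Raises if any pixel has F <= D.
    """
    D = np.asarray(sinogram.dark, dtype=float)
    F = np.asarray(sinogram.flat, dtype=float)
    if np.any(F <= D):
        raise ValueError("flat field must exceed dark field at every pixel")
    ili = (sinogram.counts - D) / (F - D)
    return ILISinogram(values=ili, geometry=sinogram.geometry, provenance=sinogram.provenance)


def to_absorption(ili: ILISinogram, epsilon: float = 1e-6) -> AbsorptionSinogram:
    """Negative logarithm with floor clamping.

    Pixels with ILI <= epsilon are floored at epsilon before the log
    (photon starvation guard); ILI > 1 passes through the log and the
    resulting small negative absorptions are clamped to zero.  The
    number of clamped pixels is recorded for logging.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    v = ili.values
    floored = np.maximum(v, epsilon)
    y = -np.log(floored)
    n_clamped = int(np.count_nonzero(v < epsilon) + np.count_nonzero(y < 0))
    y = np.maximum(y, 0.0)
    return AbsorptionSinogram(
        values=y,
        geometry=ili.geometry,
        epsilon=epsilon,
        n_clamped=n_clamped,
        provenance=ili.provenance,
    )


def from_absorption(y: AbsorptionSinogram) -> ILISinogram:
    """Inverse log step, ILI = exp(-y); round-trips to_absorption for y >= 0."""
    return ILISinogram(
        values=np.exp(-y.values), geometry=y.geometry, provenance=y.provenance
    )
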