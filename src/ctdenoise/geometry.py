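"""Scan geometry, source spectra and acquisition parameters.

The default ("desk") geometry is a parallel-beam scan whose detector grid
matches the phantom pixel grid, so forward projection and filtered
backprojection share a single sampling lattice.  The fan-beam constants of
the 2DeteCT-style bench acquisition (956 binned detector pixels of
149.6 um, 3601 projections at 0.1 deg, SOD 431.020 mm, SDD 529.000 mm)
are retained as a named preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScanGeometry",
    "SourceSpectrum",
    "AcquisitionParams",
    "desk_geometry",
    "twodetect_geometry",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry of a 2-D CT scan.

    Parameters
    ----------
    beam_type : {"parallel", "fan"}
    n_detector_pixels : int
        Number of (binned) detector pixels along the detector line.
    detector_pixel_size : float
        Detector pixel pitch, in the same length unit as the phantom
        pixel size (the desk preset uses phantom-pixel units).
    n_projections : int
    angular_increment : float
        Angular step between consecutive projections, degrees.
    sod, sdd : float, optional
        Source-object and source-detector distances (fan beam only).
    """

    beam_type: str = "parallel"
    n_detector_pixels: int = 128
    detector_pixel_size: float = 1.0
    n_projections: int = 180
    angular_increment: float = 1.0
    sod: float | None = None
    sdd: float | None = None

    def __post_init__(self) -> None:
        if self.beam_type not in ("parallel", "fan"):
            raise ValueError(f"unknown beam_type {self.beam_type!r}")
        if self.n_detector_pixels < 1 or self.n_projections < 1:
            raise ValueError("detector pixel and projection counts must be positive")
        if self.detector_pixel_size <= 0 or self.angular_increment <= 0:
            raise ValueError("lengths and angular increment must be positive")
        coverage = self.n_projections * self.angular_increment
        required = 180.0 if self.beam_type == "parallel" else 360.0
        if coverage < required - 1e-9:
            raise ValueError(
                f"{self.beam_type} scan covers {coverage:.1f} deg < {required:.0f} deg"
            )
        if self.beam_type == "fan":
            if self.sod is None or self.sdd is None:
                raise ValueError("fan-beam geometry requires sod and sdd")
            if self.sod <= 0 or self.sdd <= self.sod:
                raise ValueError("require 0 < sod < sdd")

    @property
    def angles_deg(self) -> np.ndarray:
        """Projection angles in degrees, starting at zero."""
        return np.arange(self.n_projections) * self.angular_increment

    @property
    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_projections, self.n_detector_pixels)

    def with_projections(self, n_projections: int, angular_increment: float) -> "ScanGeometry":
        return replace(self, n_projections=n_projections, angular_increment=angular_increment)


def desk_geometry(image_size: int = 128, n_projections: int = 180) -> ScanGeometry:
    """Parallel-beam desk preset: detector grid matched to the image grid."""
    return ScanGeometry(
        beam_type="parallel",
        n_detector_pixels=image_size,
        detector_pixel_size=1.0,
        n_projections=n_projections,
        angular_increment=180.0 / n_projections,
    )


def twodetect_geometry() -> ScanGeometry:
    """Fan-beam preset with the 2DeteCT-style bench constants (lengths in mm)."""
    return ScanGeometry(
        beam_type="fan",
        n_detector_pixels=956,
        detector_pixel_size=0.1496,
        n_projections=3601,
        angular_increment=0.1,
        sod=431.020,
        sdd=529.000,
    )


@dataclass(frozen=True)
class SourceSpectrum:
    """X-ray source spectrum as discrete energy bins.

    ``monochromatic`` mode has a single bin and reproduces the standard
    Beer-Lambert/Radon model.  ``two_energy_surrogate`` mode carries two
    bins with different effective attenuation per material, which makes
    beam hardening expressible (the logarithm of the corrected signal is
    no longer linear in object thickness).
    """

    energies: tuple[float, ...] = (60.0,)
    weights: tuple[float, ...] = (1.0,)
    mode: str = "monochromatic"

    def __post_init__(self) -> None:
        if self.mode not in ("monochromatic", "two_energy_surrogate"):
            raise ValueError(f"unknown spectrum mode {self.mode!r}")
        w = np.asarray(self.weights, dtype=float)
        if len(self.energies) != len(w):
            raise ValueError("energies and weights must have equal length")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
        if self.mode == "monochromatic" and len(w) != 1:
            raise ValueError("monochromatic spectrum has exactly one bin")
        if self.mode == "two_energy_surrogate" and len(w) != 2:
            raise ValueError("two_energy_surrogate spectrum has exactly two bins")

    @property
    def n_bins(self) -> int:
        return len(self.energies)

    @classmethod
    def monochromatic(cls, energy: float = 60.0) -> "SourceSpectrum":
        return cls(energies=(energy,), weights=(1.0,), mode="monochromatic")

    @classmethod
    def two_energy_surrogate(
        cls, energies: tuple[float, float] = (40.0, 80.0), weights: tuple[float, float] = (0.5, 0.5)
    ) -> "SourceSpectrum":
        return cls(energies=energies, weights=weights, mode="two_energy_surrogate")


@dataclass(frozen=True)
class AcquisitionParams:
    """Tube and exposure settings of one acquisition.

    ``flux_in_vacuum`` is the expected photon count per detector pixel
    with no object in the beam; paired clean/noisy acquisitions differ
    only in tube current, and flux scales linearly with current.
    """

    tube_voltage_kv: float = 90.0
    tube_current_ua: float = 1000.0
    exposure_time_ms: float = 50.0
    n_proj: int = 3601
    n_avim: int = 1
    flux_in_vacuum: float = 6000.0

    def __post_init__(self) -> None:
        vals = (
            self.tube_voltage_kv,
            self.tube_current_ua,
            self.exposure_time_ms,
            self.n_proj,
            self.n_avim,
            self.flux_in_vacuum,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all acquisition parameters must be positive")

    def with_current(self, tube_current_ua: float) -> "AcquisitionParams":
        """Same acquisition at a different tube current; flux scales with current."""
        scale = tube_current_ua / self.tube_current_ua
        return replace(
            self,
            tube_current_ua=tube_current_ua,
            flux_in_vacuum=self.flux_in_vacuum * scale,
        )

    def noise_factor(self) -> float:
        """Relative quantum-noise factor V^1.3 / sqrt(I * t * n_proj * n_avim)."""
        denom = (
            self.tube_current_ua
            * self.exposure_time_ms
            * self.n_proj
            * self.n_avim
        )
        return self.tube_voltage_kv ** 1.3 / np.sqrt(denom)


def dose_scale_factor(params_a: AcquisitionParams, params_b: AcquisitionParams) -> float:
    """Ratio of relative quantum-noise levels between two acquisitions.

    The noise level in a reconstructed slice scales as
    ``V^1.3 / sqrt(I * t * n_proj * n_avim)``; this returns
    ``factor_a / factor_b``.  A clean scan at 30x the tube current of the
    noisy one yields ``1 / sqrt(30)``.
    """
    return params_a.noise_factor() / params_b.noise_factor()
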