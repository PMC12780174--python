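"""Full-path acquisition simulation and paired clean/noisy datasets.

The detector path follows the simplified energy-integrating detector
model: expected counts A per pixel (Beer-Lambert, per spectrum), a
Poisson draw, additive zero-mean Gaussian electronic noise, detector
cross-talk applied to the full measurement, then dark offset and
per-pixel flat-field gains.  Paired clean/noisy acquisitions share one
phantom and differ only in tube current (hence flux); the default dose
ratio is x30, matching a high-dose/low-dose bench pair.

The "experimental surrogate" mode adds physics the monochromatic
parameterized noise model cannot express — a two-energy spectrum
(beam hardening) and electronic readout noise — so that a simulated-vs-
surrogate-experimental performance gap is observable without any real
measurement data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AcquisitionParams, ScanGeometry, SourceSpectrum, desk_geometry
from .noise import NoiseParams, build_crosstalk_operator
from .phantoms import Phantom, PhantomSpec, generate_phantom
from .preprocessing import ILISinogram, flatfield_correct
from .projection import expected_counts, forward_project

__all__ = [
    "PhotonSinogram",
    "acquire",
    "default_fields",
    "SlicePair",
    "PairedDataset",
    "make_paired_dataset",
]

#: default dose ratio between the clean and noisy member of a pair
DOSE_RATIO = 30.0
#: electronic readout noise (photon-count units) in experimental-surrogate mode
SURROGATE_SIGMA_ELECTRONIC = 5.0


@dataclass(frozen=True)
class PhotonSinogram:
    """Raw detector counts with their calibration fields.

    ``dark`` and ``flat`` are per-detector-pixel (1-D) and broadcast
    over projections.
    """

    counts: np.ndarray
    dark: np.ndarray
    flat: np.ndarray
    geometry: ScanGeometry
    provenance: str = "experimental_clean"

    def __post_init__(self) -> None:
        if self.counts.shape != self.geometry.sinogram_shape:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match geometry "
                f"{self.geometry.sinogram_shape}"
            )
        if np.any(np.asarray(self.flat) <= np.asarray(self.dark)):
            raise ValueError("flat field must exceed dark field per pixel")


def default_fields(
    n_pixels: int, flux_in_vacuum: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Default dark and flat fields.

    Dark: constant offset at 1% of the flat-field level.  Flat: smooth
    per-pixel gain in [0.9, 1.1] (a low-order cosine series with
    seed-dependent phases) times the vacuum flux, plus the dark offset.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xF1A7)))
    x = np.linspace(0.0, 1.0, n_pixels)
    gain = np.ones(n_pixels)
    for k in (1, 2, 3):
        gain += (0.1 / 3.0) * np.cos(2 * np.pi * (k * x + rng.uniform()))
    gain = np.clip(gain, 0.9, 1.1)
    dark = np.full(n_pixels, 0.01 * flux_in_vacuum)
    flat = flux_in_vacuum * gain + dark
    return dark, flat


def acquire(
    counts_expected: np.ndarray,
    dark: np.ndarray,
    flat: np.ndarray,
    noise_params: NoiseParams,
    seed: int | np.random.Generator = 0,
    geometry: ScanGeometry | None = None,
    provenance: str = "experimental_clean",
    flux_in_vacuum: float | None = None,
) -> PhotonSinogram:
    """Simulate one raw acquisition from expected counts.

    ``counts = Gamma[Poisson(A * gain) + N(0, sigma_e)] + dark`` where
    the per-pixel gain is ``(flat - dark) / flux_in_vacuum`` — the flat
    field describes the very pixel sensitivities the measurement is
    subject to, so flat-field correction is nontrivial but consistent.
    If the vacuum flux is not given it is estimated as the mean flat
    level.  Reproducible for a fixed seed.
    """
    A = np.asarray(counts_expected, dtype=float)
    if np.any(A < 0):
        raise ValueError("expected counts must be nonnegative")
    if geometry is None:
        geometry = desk_geometry(A.shape[1], A.shape[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dark = np.asarray(dark, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if flux_in_vacuum is None:
        flux_in_vacuum = float(np.mean(flat - dark))
    gain = (flat - dark) / flux_in_vacuum
    measured = rng.poisson(A * gain[None, :]).astype(float)
    if noise_params.sigma_electronic > 0:
        measured += rng.normal(0.0, noise_params.sigma_electronic, size=measured.shape)
    gamma = build_crosstalk_operator(
        geometry.n_detector_pixels, noise_params.sigma_crosstalk, noise_params.crosstalk_mode
    )
    counts = gamma.apply(measured) + dark[None, :]
    return PhotonSinogram(
        counts=counts, dark=dark, flat=flat, geometry=geometry, provenance=provenance
    )


@dataclass(frozen=True)
class SlicePair:
    """One phantom with its paired clean and noisy acquisitions."""

    phantom: Phantom
    clean: PhotonSinogram
    noisy: PhotonSinogram
    index: int = 0

    def clean_ili(self) -> ILISinogram:
        return flatfield_correct(self.clean)

    def noisy_ili(self) -> ILISinogram:
        return flatfield_correct(self.noisy)


@dataclass(frozen=True)
class PairedDataset:
    """A set of paired clean/noisy acquisitions of the same slices."""

    pairs: tuple[SlicePair, ...]
    geometry: ScanGeometry
    surrogate_mode: str
    clean_params: AcquisitionParams
    noisy_params: AcquisitionParams
    master_seed: int

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i: int) -> SlicePair:
        return self.pairs[i]

    def __iter__(self):
        return iter(self.pairs)


def _slice_rng(master_seed: int, slice_index: int, role: str) -> np.random.Generator:
    """Independent per-slice, per-role RNG stream derived from the master seed."""
    role_code = {"phantom": 0, "clean": 1, "noisy": 2, "fields": 3}[role]
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed), int(slice_index), role_code))
    )


def make_paired_dataset(
    n_slices: int,
    geometry: ScanGeometry | None = None,
    surrogate_mode: str = "monochromatic",
    clean_params: AcquisitionParams | None = None,
    noisy_params: AcquisitionParams | None = None,
    seed: int = 0,
    phantom_spec: PhantomSpec | None = None,
    image_size: int | None = None,
    sigma_crosstalk: float = 0.05,
    sigma_electronic: float | None = None,
) -> PairedDataset:
    """Generate paired clean/noisy acquisitions of shared phantoms.

    Parameters
    ----------
    surrogate_mode : {"monochromatic", "experimental_surrogate"}
        Monochromatic mode uses the single-bin spectrum and no
        electronic noise — the physics the parameterized noise model can
        express exactly.  Experimental-surrogate mode uses the two-energy
        spectrum (beam hardening) and electronic readout noise, standing
        in for a real bench acquisition.
    clean_params, noisy_params : AcquisitionParams, optional
        Must differ only in tube current / flux.  Defaults: clean flux
        6000 photons per pixel, noisy at a x30 lower current (flux 200).

    The whole dataset is a pure function of the arguments and the master
    seed; per-slice clean/noisy draws use independent derived streams.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if surrogate_mode not in ("monochromatic", "experimental_surrogate"):
        raise ValueError(f"unknown surrogate_mode {surrogate_mode!r}")
    geometry = geometry or desk_geometry(image_size or 128)
    if image_size is None:
        image_size = (
            geometry.n_detector_pixels if geometry.beam_type == "parallel" else 128
        )
    clean_params = clean_params or AcquisitionParams(flux_in_vacuum=200.0 * DOSE_RATIO)
    noisy_params = noisy_params or clean_params.with_current(
        clean_params.tube_current_ua / DOSE_RATIO
    )
    _check_only_current_differs(clean_params, noisy_params)

    surrogate = surrogate_mode == "experimental_surrogate"
    spectrum = (
        SourceSpectrum.two_energy_surrogate() if surrogate else SourceSpectrum.monochromatic()
    )
    if sigma_electronic is None:
        sigma_electronic = SURROGATE_SIGMA_ELECTRONIC if surrogate else 0.0
    noise = NoiseParams(
        I0=1.0, sigma_electronic=sigma_electronic, sigma_crosstalk=sigma_crosstalk
    )

    spec = phantom_spec if phantom_spec is not None else PhantomSpec()
    pairs = []
    for i in range(n_slices):
        phantom_seed = int(_slice_rng(seed, i, "phantom").integers(0, 2**31 - 1))
        phantom = generate_phantom(spec, image_size=image_size, seed=phantom_seed)
        L = forward_project(phantom, geometry, spectrum)
        dark, flat = default_fields(
            geometry.n_detector_pixels,
            clean_params.flux_in_vacuum,
            seed=int(_slice_rng(seed, i, "fields").integers(0, 2**31 - 1)),
        )
        # the dark offset is a detector property and does not change with dose;
        # the flat level scales with the tube current
        flux_ratio = noisy_params.flux_in_vacuum / clean_params.flux_in_vacuum
        dark_n, flat_n = dark, dark + (flat - dark) * flux_ratio
        A_clean = expected_counts(L, clean_params.flux_in_vacuum, spectrum)
        A_noisy = expected_counts(L, noisy_params.flux_in_vacuum, spectrum)
        clean = acquire(
            A_clean, dark, flat, noise,
            seed=_slice_rng(seed, i, "clean"), geometry=geometry,
            provenance="experimental_clean",
            flux_in_vacuum=clean_params.flux_in_vacuum,
        )
        noisy = acquire(
            A_noisy, dark_n, flat_n, noise,
            seed=_slice_rng(seed, i, "noisy"), geometry=geometry,
            provenance="experimental_noisy",
            flux_in_vacuum=noisy_params.flux_in_vacuum,
        )
        pairs.append(SlicePair(phantom=phantom, clean=clean, noisy=noisy, index=i))
    return PairedDataset(
        pairs=tuple(pairs),
        geometry=geometry,
        surrogate_mode=surrogate_mode,
        clean_params=clean_params,
        noisy_params=noisy_params,
        master_seed=seed,
    )


def _check_only_current_differs(a: AcquisitionParams, b: AcquisitionParams) -> None:
    same = (
        a.tube_voltage_kv == b.tube_voltage_kv
        and a.exposure_time_ms == b.exposure_time_ms
        and a.n_proj == b.n_proj
        and a.n_avim == b.n_avim
    )
    if not same:
        raise ValueError("paired acquisitions must differ only in tube current")
    ratio_current = a.tube_current_ua / b.tube_current_ua
    ratio_flux = a.flux_in_vacuum / b.flux_in_vacuum
    if not np.isclose(ratio_current, ratio_flux):
        raise ValueError("flux must scale with tube current between paired acquisitions")
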