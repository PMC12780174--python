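"""Synthetic mixed-content phantoms.

Phantoms emulate the scanned-object structure of a bench CT slice: a
low-attenuation circular matrix (the sample container filling) with
embedded high-attenuation "stone" inclusions, either small and isolated
or large and closely grouped.  Grouped large stones are the content
class for which beam hardening produces inter-object streaks in a
polychromatic acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ObjectTag", "Phantom", "PhantomSpec", "generate_phantom"]

#: per-material hardening coefficient h: bin attenuation = mu * (1 + h * delta_k)
#: with delta = (+1, -1) for the (low, high) energy bins of the two-bin
#: surrogate spectrum.  h = 1/3 makes the stone's low-energy attenuation
#: twice its high-energy attenuation while preserving the mean.
DEFAULT_HARDENING = {"matrix": 0.10, "stone_small": 1.0 / 3.0, "stone_large_grouped": 1.0 / 3.0}


@dataclass(frozen=True)
class ObjectTag:
    """Descriptor of one disc-shaped object in a phantom."""

    kind: str  # {"matrix", "stone_small", "stone_large_grouped"}
    center: tuple[float, float]  # (row, col), pixel coordinates
    radius: float  # pixels
    mu: float  # nominal linear attenuation, per unit length
    hardening: float = 0.0  # energy dependence coefficient


@dataclass(frozen=True)
class Phantom:
    """2-D attenuation map with content metadata.

    ``attenuation`` is the nominal (spectrum-averaged) map; per-energy-bin
    maps for a two-bin surrogate spectrum are derived from the object tags
    via their hardening coefficients.
    """

    attenuation: np.ndarray
    pixel_size: float = 1.0
    content_tags: tuple[ObjectTag, ...] = ()

    def __post_init__(self) -> None:
        a = self.attenuation
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("attenuation grid must be 2-D and square")
        if np.any(a < 0):
            raise ValueError("attenuation must be nonnegative")

    @property
    def size(self) -> int:
        return self.attenuation.shape[0]

    def attenuation_for_bins(self, deltas: tuple[float, ...]) -> np.ndarray:
        """Per-energy-bin attenuation maps, shape (n_bins, N, N).

        Bin k scales each object's contribution by ``1 + h * delta_k``;
        with symmetric deltas and equal bin weights the weighted mean map
        equals the nominal map.
        """
        n = self.size
        maps = np.zeros((len(deltas), n, n))
        rr, cc = np.mgrid[0:n, 0:n]
        for tag in self.content_tags:
            mask = (rr - tag.center[0]) ** 2 + (cc - tag.center[1]) ** 2 <= tag.radius**2
            for k, d in enumerate(deltas):
                np.copyto(maps[k], tag.mu * (1.0 + tag.hardening * d), where=mask)
        return maps


@dataclass(frozen=True)
class PhantomSpec:
    """Content specification for the phantom generator.

    Counts are ranges (inclusive); attenuation defaults scale with the
    grid so the central path through the matrix has optical depth ~1.4
    regardless of resolution (mu_matrix = 1.4 / image_size, stones 8x).
    """

    matrix: bool = True
    matrix_radius_frac: float = 0.42  # of image size; keeps content in the scan circle
    matrix_mu: float | None = None
    n_small_stones: tuple[int, int] = (0, 3)
    small_stone_radius_frac: tuple[float, float] = (0.03, 0.06)
    grouped_stones: bool = False
    n_grouped: tuple[int, int] = (2, 3)
    grouped_radius_frac: tuple[float, float] = (0.07, 0.10)
    stone_mu: float | None = None
    hardening: dict = field(default_factory=lambda: dict(DEFAULT_HARDENING))

    def resolved_mus(self, image_size: int) -> tuple[float, float]:
        mu_m = self.matrix_mu if self.matrix_mu is not None else 1.4 / image_size
        mu_s = self.stone_mu if self.stone_mu is not None else 8.0 * mu_m
        return mu_m, mu_s


def _rasterize(tags: list[ObjectTag], image_size: int, pixel_size: float) -> Phantom:
    grid = np.zeros((image_size, image_size))
    rr, cc = np.mgrid[0:image_size, 0:image_size]
    for tag in tags:
        mask = (rr - tag.center[0]) ** 2 + (cc - tag.center[1]) ** 2 <= tag.radius**2
        grid[mask] = tag.mu  # later objects replace earlier ones (stones embedded in matrix)
    return Phantom(attenuation=grid, pixel_size=pixel_size, content_tags=tuple(tags))


def generate_phantom(
    content_spec: PhantomSpec | None = None,
    image_size: int = 128,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> Phantom:
    """Draw a random mixed-content phantom; deterministic for a given seed.

    Raises
    ------
    ValueError
        If the requested objects cannot fit inside the grid.
    """
    spec = content_spec if content_spec is not None else PhantomSpec()
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x9E3779)))
    mu_m, mu_s = spec.resolved_mus(image_size)
    center = (image_size - 1) / 2.0
    tags: list[ObjectTag] = []

    matrix_r = spec.matrix_radius_frac * image_size
    if matrix_r > image_size / 2.0:
        raise ValueError("matrix does not fit the grid")
    if spec.matrix:
        tags.append(
            ObjectTag("matrix", (center, center), matrix_r, mu_m, spec.hardening["matrix"])
        )
    # container radius inside which stones must lie
    host_r = matrix_r if spec.matrix else image_size / 2.0 - 1.0

    def _place(radius: float, near: tuple[float, float] | None = None, spread: float = 0.0):
        max_off = host_r - radius
        if max_off <= 0:
            raise ValueError("stone radius too large for the phantom")
        for _ in range(200):
            if near is None:
                ang = rng.uniform(0.0, 2 * np.pi)
                off = max_off * np.sqrt(rng.uniform(0.0, 1.0))
                pos = (center + off * np.sin(ang), center + off * np.cos(ang))
            else:
                ang = rng.uniform(0.0, 2 * np.pi)
                off = rng.uniform(radius, spread)
                pos = (near[0] + off * np.sin(ang), near[1] + off * np.cos(ang))
            d = np.hypot(pos[0] - center, pos[1] - center)
            if d + radius <= host_r:
                return pos
        raise ValueError("could not place stone inside the phantom")

    n_small = int(rng.integers(spec.n_small_stones[0], spec.n_small_stones[1] + 1))
    for _ in range(n_small):
        r = rng.uniform(*spec.small_stone_radius_frac) * image_size
        pos = _place(r)
        tags.append(ObjectTag("stone_small", pos, r, mu_s, spec.hardening["stone_small"]))

    if spec.grouped_stones:
        n_grp = int(rng.integers(spec.n_grouped[0], spec.n_grouped[1] + 1))
        n_grp = max(n_grp, 2)  # a group is at least two stones
        r0 = rng.uniform(*spec.grouped_radius_frac) * image_size
        anchor = _place(r0)
        tags.append(
            ObjectTag("stone_large_grouped", anchor, r0, mu_s, spec.hardening["stone_large_grouped"])
        )
        for _ in range(n_grp - 1):
            r = rng.uniform(*spec.grouped_radius_frac) * image_size
            # group members stay within 3 radii of the anchor
            pos = _place(r, near=anchor, spread=min(3.0 * r0, host_r - r))
            tags.append(
                ObjectTag("stone_large_grouped", pos, r, mu_s, spec.hardening["stone_large_grouped"])
            )

    return _rasterize(tags, image_size, pixel_size)


def disc_phantom(
    image_size: int, radius: float, mu: float, center: tuple[float, float] | None = None,
    pixel_size: float = 1.0, hardening: float = 0.0,
) -> Phantom:
    """Single uniform disc; the workhorse analytic test object."""
    c = ((image_size - 1) / 2.0,) * 2 if center is None else center
    tag = ObjectTag("matrix", c, radius, mu, hardening)
    return _rasterize([tag], image_size, pixel_size)
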