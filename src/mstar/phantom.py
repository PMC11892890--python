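"""Synthetic ground-truth volumes.

The main object is a *foam phantom*: a solid cylinder of uniform attenuation
``mu_material`` perforated by many non-overlapping spherical bubbles of zero
attenuation, a standard benchmark object for tomographic artifact-reduction
studies.  Voxel values are exactly binary: 0 outside the cylinder and inside
bubbles, ``mu_material`` in the remaining material.

Coordinate convention: voxel index ``i`` maps to physical coordinate
``i - (size - 1) / 2`` (voxel size 1); the cylinder axis runs along Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "FoamSpec",
    "PlacementError",
    "generate_foam_phantom",
    "generate_disk_phantom",
]


class PlacementError(RuntimeError):
    """Raised when bubbles cannot be placed within the attempt budget."""


@dataclass
class Volume:
    """A 3D grid of linear attenuation coefficients, shape (Z, Y, X)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class FoamSpec:
    """Parameters of the foam phantom generator.

    ``bubble_radius_range`` is in voxels; radii are drawn log-uniformly so
    that small bubbles dominate in number, as in physical foams.
    """

    grid_size: int = 64
    cylinder_radius_frac: float = 0.9
    n_bubbles: int = 100
    bubble_radius_range: tuple[float, float] = (2.0, 8.0)
    mu_material: float = 1.0
    seed: int = 0
    max_attempts_per_bubble: int = 1000

    def validate(self) -> None:
        if self.grid_size < 8:
            raise ValueError("grid_size must be at least 8")
        if self.n_bubbles < 0:
            raise ValueError("n_bubbles must be non-negative")
        lo, hi = self.bubble_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("bubble radii must be positive with min <= max")
        if not (0 < self.cylinder_radius_frac <= 1.0):
            raise ValueError("cylinder_radius_frac must lie in (0, 1]")
        if hi >= self.cylinder_radius_frac * self.grid_size / 2:
            raise ValueError("bubble radii must be smaller than the cylinder radius")


def _sample_bubbles(spec: FoamSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping bubbles; rows are (z, y, x, r)."""
    half = (spec.grid_size - 1) / 2.0
    r_cyl = spec.cylinder_radius_frac * spec.grid_size / 2.0
    lo, hi = spec.bubble_radius_range
    placed = np.empty((spec.n_bubbles, 4), dtype=np.float64)
    n_placed = 0
    budget = spec.max_attempts_per_bubble * max(spec.n_bubbles, 1)
    attempts = 0
    while n_placed < spec.n_bubbles:
        if attempts >= budget:
            raise PlacementError(
                f"could not place bubble {n_placed} of {spec.n_bubbles} "
                f"after {attempts} attempts"
            )
        attempts += 1
        r = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        # Uniform in the cylinder cross-section, radially contained.
        rho = (r_cyl - r) * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2 * np.pi)
        y = rho * np.sin(phi)
        x = rho * np.cos(phi)
        z = rng.uniform(-half + r, half - r)
        if n_placed:
            prev = placed[:n_placed]
            d2 = (prev[:, 0] - z) ** 2 + (prev[:, 1] - y) ** 2 + (prev[:, 2] - x) ** 2
            if np.any(d2 <= (prev[:, 3] + r) ** 2):
                continue
        placed[n_placed] = (z, y, x, r)
        n_placed += 1
    return placed


def generate_foam_phantom(spec: FoamSpec) -> Volume:
    """Generate a cylindrical foam phantom with non-overlapping bubbles.

    Deterministic for a given ``spec.seed``.  Raises :class:`PlacementError`
    (naming the bubble index reached) if the requested bubble count cannot be
    placed within ``max_attempts_per_bubble * n_bubbles`` attempts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_size
    half = (n - 1) / 2.0
    r_cyl = spec.cylinder_radius_frac * n / 2.0

    coords = np.arange(n, dtype=np.float64) - half
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    cylinder = (yy**2 + xx**2) <= r_cyl**2
    mask = np.broadcast_to(cylinder, (n, n, n)).copy()

    bubbles = _sample_bubbles(spec, rng) if spec.n_bubbles else np.empty((0, 4))
    for z0, y0, x0, r in bubbles:
        zi = int(np.floor(z0 + half))
        lo = max(0, zi - int(np.ceil(r)) - 1)
        hi = min(n, zi + int(np.ceil(r)) + 2)
        zz = coords[lo:hi][:, None, None]
        inside = (zz - z0) ** 2 + (yy - y0) ** 2 + (xx - x0) ** 2 <= r**2
        mask[lo:hi] &= ~inside

    data = np.where(mask, np.float32(spec.mu_material), np.float32(0.0))
    vol = Volume(data)
    vol.bubbles = bubbles  # (z, y, x, r) rows, for geometric checks
    return vol


def generate_disk_phantom(grid_size: int, radius: float, mu: float) -> Volume:
    """Uniform disk of value ``mu``, replicated along Z (unit-test fixture)."""
    if grid_size < 2 or radius <= 0 or radius >= grid_size / 2:
        raise ValueError("need 0 < radius < grid_size / 2")
    half = (grid_size - 1) / 2.0
    coords = np.arange(grid_size, dtype=np.float64) - half
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    disk = (yy**2 + xx**2) <= radius**2
    slice_ = np.where(disk, np.float32(mu), np.float32(0.0))
    return Volume(np.broadcast_to(slice_, (grid_size,) + slice_.shape).copy())
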