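"""Parallel-beam CT pipeline: projection, sinogram and reconstruction domains.

Conventions
-----------
* A volume is (Z, Y, X) with square slices; the detector has M = Z rows and
  N = X columns, so no magnification (parallel beam).
* Acquisition angles are equally spaced on [0, pi), endpoint excluded,
  starting at 0.  A low-quality scan with ``N_a`` angles shares its grid with
  a high-quality scan of ``factor * N_a`` angles: LQ angle ``i`` is HQ angle
  ``i * factor``.
* Projections hold post-log line integrals of attenuation (Beer-Lambert):
  a point at slice coordinates (x0, y0) relative to the rotation center
  traces the sinusoid ``t(theta) = x0 cos(theta) + y0 sin(theta)`` on the
  detector.
* Reconstruction is filtered back projection with a Ram-Lak (ramp) filter in
  its standard discretization and linear-interpolation back projection,
  scaled by ``pi / (2 N_a)`` so amplitudes round-trip.  No circular mask is
  applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform

from .phantom import Volume

__all__ = [
    "make_angles",
    "ProjectionStack",
    "SinogramStack",
    "forward_project",
    "rearrange",
    "inverse_rearrange",
    "angle_upsample",
    "fbp_reconstruct",
]


def make_angles(n_angles: int) -> np.ndarray:
    """Equally spaced angles in radians on [0, pi), endpoint excluded."""
    if n_angles < 1:
        raise ValueError("need at least one angle")
    return np.linspace(0.0, np.pi, n_angles, endpoint=False)


def _check_angles(angles: np.ndarray) -> np.ndarray:
    angles = np.asarray(angles, dtype=np.float64)
    if angles.ndim != 1 or angles.size == 0:
        raise ValueError("angles must be a non-empty 1D array")
    if np.any(np.diff(angles) <= 0):
        raise ValueError("angles must be strictly increasing")
    if angles[0] < 0 or angles[-1] >= np.pi:
        raise ValueError("angles must lie in [0, pi)")
    return angles


@dataclass
class ProjectionStack:
    """(N_a, M, N) attenuation-domain projection images plus their angles."""

    data: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.angles = _check_angles(self.angles)
        if self.data.ndim != 3:
            raise ValueError("projection data must be (N_a, M, N)")
        if self.data.shape[0] != self.angles.size:
            raise ValueError("first axis must match the number of angles")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("projections contain non-finite values")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]


@dataclass
class SinogramStack:
    """(M, N_a, N) per-detector-row sinograms plus their angles."""

    data: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.angles = _check_angles(self.angles)
        if self.data.ndim != 3:
            raise ValueError("sinogram data must be (M, N_a, N)")
        if self.data.shape[1] != self.angles.size:
            raise ValueError("second axis must match the number of angles")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinograms contain non-finite values")

    @property
    def n_angles(self) -> int:
        return self.data.shape[1]


def forward_project(vol: Volume, angles: np.ndarray) -> ProjectionStack:
    """Slice-wise 2D parallel-beam line integrals of a volume.

    For each angle the volume is rotated about the slice center (linear
    interpolation, zero outside) and summed along the beam axis; detector
    width equals the slice width.  Pure geometry: no noise of any kind.
    """
    angles = _check_angles(angles)
    data = np.asarray(vol.data, dtype=np.float64)
    nz, ny, nx = data.shape
    if ny != nx:
        raise ValueError("volume slices must be square (Y == X)")
    c = (nx - 1) / 2.0
    out = np.empty((angles.size, nz, nx), dtype=np.float32)
    for a, theta in enumerate(angles):
        ct, st = np.cos(theta), np.sin(theta)
        # out grid (z, u, t) -> input (z, y, x): y = t st + u ct, x = t ct - u st
        matrix = np.array([[1.0, 0.0, 0.0], [0.0, ct, st], [0.0, -st, ct]])
        offset = np.array([0.0, c - (ct * c + st * c), c - (-st * c + ct * c)])
        rotated = affine_transform(
            data, matrix, offset=offset, order=1, mode="constant", cval=0.0
        )
        out[a] = rotated.sum(axis=1)
    return ProjectionStack(out, angles)


def rearrange(p: ProjectionStack) -> SinogramStack:
    """(N_a, M, N) -> (M, N_a, N); lossless axis permutation."""
    return SinogramStack(np.ascontiguousarray(p.data.transpose(1, 0, 2)), p.angles)


def inverse_rearrange(s: SinogramStack) -> ProjectionStack:
    """(M, N_a, N) -> (N_a, M, N); inverse of :func:`rearrange`."""
    return ProjectionStack(np.ascontiguousarray(s.data.transpose(1, 0, 2)), s.angles)


def angle_upsample(s: SinogramStack, factor: int) -> SinogramStack:
    """Linearly interpolate a sinogram to ``factor`` times as many angles.

    The output grid is equally spaced on [0, pi) sharing angle 0 with the
    input.  Interpolation past the last measured angle wraps through the
    half-turn identity ``s(theta + pi, n) = s(theta, N - 1 - n)``.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    if factor == 1:
        return SinogramStack(s.data.copy(), s.angles.copy())
    n_a = s.n_angles
    # Extend by the flipped first angle, valid at theta = pi.
    ext = np.concatenate([s.data, s.data[:, :1, ::-1]], axis=1)
    pos = np.arange(n_a * factor, dtype=np.float64) / factor
    i0 = np.floor(pos).astype(np.intp)
    frac = (pos - i0).astype(np.float32)[None, :, None]
    out = ext[:, i0] * (1.0 - frac) + ext[:, i0 + 1] * frac
    return SinogramStack(out, make_angles(n_a * factor))


def _ramp_filter(size: int) -> np.ndarray:
    """Ram-Lak frequency response from the standard real-space kernel."""
    n = np.concatenate(
        (np.arange(1, size // 2 + 1, 2), np.arange(size // 2 - 1, 0, -2))
    )
    f = np.zeros(size)
    f[0] = 0.25
    f[1::2] = -1.0 / (np.pi * n) ** 2
    return 2.0 * np.real(np.fft.fft(f))


def fbp_reconstruct(s: SinogramStack) -> Volume:
    """Slice-by-slice filtered back projection; output shape (M, N, N).

    Linear in its input (each step — filtering, interpolation, summation —
    is linear), which is what lets additive projection-domain artifacts be
    analyzed as additive reconstruction-domain artifacts.
    """
    if s.n_angles < 2:
        raise ValueError("need at least 2 angles to reconstruct")
    data = np.asarray(s.data, dtype=np.float64)
    m, n_a, n = data.shape
    pad = max(64, int(2 ** np.ceil(np.log2(2 * n))))
    filt = _ramp_filter(pad)
    spec = np.fft.fft(data, pad, axis=2) * filt
    q = np.real(np.fft.ifft(spec, axis=2))[:, :, :n]

    c = (n - 1) / 2.0
    coords = np.arange(n, dtype=np.float64) - c
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    acc = np.zeros((m, n * n), dtype=np.float64)
    for a, theta in enumerate(s.angles):
        t = (xx * np.cos(theta) + yy * np.sin(theta) + c).ravel()
        i0 = np.floor(t).astype(np.intp)
        valid = (t >= 0.0) & (t <= n - 1)
        i0c = np.clip(i0, 0, n - 2)
        frac = t - i0c
        rows = q[:, a, :]
        contrib = rows[:, i0c] * (1.0 - frac) + rows[:, i0c + 1] * frac
        contrib[:, ~valid] = 0.0
        acc += contrib
    recon = acc.reshape(m, n, n) * (np.pi / (2.0 * s.n_angles))
    return Volume(recon.astype(np.float32))
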