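"""Acquisition-artifact simulation: Poisson noise, ring offsets, zingers.

All corruption happens in the projection domain and is additive or
count-statistical on top of clean post-log line integrals:

* **Poisson noise** — projections are converted to expected photon counts
  ``I0 * exp(-p)``, Poisson-sampled, clipped below at one count, and logged
  back.  Severity is set by the incident count ``I0`` after the projections
  have been scaled so the object absorbs a target fraction ``gamma`` of
  photons on average.
* **Ring offsets** — a fixed fraction ``P_ring`` of detector pixels receives
  a Gaussian additive offset (std ``sigma_ring``) that is identical in every
  projection; constant detector offsets become straight angle-axis lines in
  sinograms and concentric rings after reconstruction.
* **Zingers** — a fraction ``P_proj`` of projections gets a fraction
  ``P_zinger`` of its pixels overwritten with a saturation value ``v``,
  modelling stray high-energy photon hits; they reconstruct into crossing
  streaks.

Affected-pixel counts are exact (``round(P * count)`` draws without
replacement), not Bernoulli, so corruption is exactly countable; "percentage"
parameters are fractions in [0, 1] (``P_ring = 0.1`` means 10% of pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pipeline import ProjectionStack

__all__ = [
    "ArtifactConfig",
    "RingPattern",
    "calibrate_absorption",
    "apply_poisson",
    "make_ring_pattern",
    "apply_ring",
    "apply_zinger",
    "corrupt",
]


@dataclass
class ArtifactConfig:
    """All corruption parameters for one simulated low-quality scan."""

    I0: float = 100.0
    gamma_target: float = 0.5
    P_ring: float = 0.1
    sigma_ring: float = 0.005
    P_proj: float = 0.1
    P_zinger: float = 0.001
    v: float = 5.0
    seed: int = 0
    noise_enabled: bool = True
    ring_enabled: bool = True
    zinger_enabled: bool = True

    def validate(self) -> None:
        for name in ("P_ring", "P_proj", "P_zinger"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.noise_enabled and self.I0 <= 0:
            raise ValueError("I0 must be positive when noise is enabled")
        if self.sigma_ring < 0:
            raise ValueError("sigma_ring must be non-negative")
        if not np.isfinite(self.v):
            raise ValueError("zinger value v must be finite")
        if not (0.0 < self.gamma_target < 1.0):
            raise ValueError("gamma_target must lie in (0, 1)")


@dataclass
class RingPattern:
    """Per-detector-pixel additive offsets and the mask of affected pixels."""

    offsets: np.ndarray  # (M, N) float, zero off-mask
    mask: np.ndarray  # (M, N) bool

    def __post_init__(self) -> None:
        if self.offsets.shape != self.mask.shape:
            raise ValueError("offsets and mask shapes differ")
        if np.any(self.offsets[~self.mask] != 0):
            raise ValueError("offsets must be zero where mask is false")


def calibrate_absorption(
    p: ProjectionStack, gamma_target: float = 0.5, tol: float = 1e-6
) -> tuple[ProjectionStack, float]:
    """Scale projections so the object absorbs ``gamma_target`` on average.

    Finds the single global factor ``c`` (by bisection) such that the mean of
    ``1 - exp(-c * p)`` over object-intersecting rays (``p > 0``) equals
    ``gamma_target``, and returns the scaled stack together with ``c``.
    """
    vals = p.data[p.data > 0]
    if vals.size == 0:
        raise ValueError("cannot calibrate an all-zero projection stack")
    if not (0.0 < gamma_target < 1.0):
        raise ValueError("gamma_target must lie in (0, 1)")
    vals = vals.astype(np.float64)

    def absorbed(c: float) -> float:
        return float(np.mean(1.0 - np.exp(-c * vals)))

    lo, hi = 0.0, 1.0
    while absorbed(hi) < gamma_target:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("absorption calibration failed to bracket")
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if absorbed(mid) < gamma_target:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    return ProjectionStack(p.data * np.float32(c), p.angles.copy()), c


def apply_poisson(p: ProjectionStack, I0: float, seed: int) -> ProjectionStack:
    """Poisson photon-count noise at incident count ``I0`` per pixel.

    Counts ``k ~ Poisson(I0 * exp(-p))`` are clipped below at 1 (a zero count
    has no defined log-transmission) and converted back with
    ``p' = -ln(k / I0)``.  Deterministic given ``seed``.
    """
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    if np.any(p.data < 0):
        raise ValueError("projections must be non-negative (calibrate first)")
    rng = np.random.default_rng(seed)
    lam = I0 * np.exp(-p.data.astype(np.float64))
    counts = np.maximum(rng.poisson(lam), 1)
    return ProjectionStack(
        (-np.log(counts / I0)).astype(np.float32), p.angles.copy()
    )


def make_ring_pattern(
    m: int, n: int, P_ring: float, sigma_ring: float, seed: int
) -> RingPattern:
    """Draw ``round(P_ring * M * N)`` affected pixels without replacement."""
    if not (0.0 <= P_ring <= 1.0):
        raise ValueError("P_ring must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(round(P_ring * m * n))
    flat = rng.choice(m * n, size=k, replace=False)
    mask = np.zeros(m * n, dtype=bool)
    mask[flat] = True
    offsets = np.zeros(m * n, dtype=np.float32)
    offsets[flat] = rng.normal(0.0, sigma_ring, size=k)
    return RingPattern(offsets.reshape(m, n), mask.reshape(m, n))


def apply_ring(p: ProjectionStack, pattern: RingPattern) -> ProjectionStack:
    """Add the identical offset image to every projection."""
    if pattern.offsets.shape != p.data.shape[1:]:
        raise ValueError(
            f"ring pattern shape {pattern.offsets.shape} does not match "
            f"detector shape {p.data.shape[1:]}"
        )
    return ProjectionStack(p.data + pattern.offsets[None], p.angles.copy())


def apply_zinger(
    p: ProjectionStack, P_proj: float, P_zinger: float, v: float, seed: int
) -> ProjectionStack:
    """Overwrite random pixels with the saturation value ``v``.

    Exactly ``round(P_proj * N_a)`` projections are selected without
    replacement; within each, exactly ``round(P_zinger * M * N)`` pixels
    (independent positions per projection) are set to ``v``.
    """
    for name, val in (("P_proj", P_proj), ("P_zinger", P_zinger)):
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_a, m, n = p.data.shape
    out = p.data.copy()
    n_proj = int(round(P_proj * n_a))
    n_pix = int(round(P_zinger * m * n))
    hit = np.sort(rng.choice(n_a, size=n_proj, replace=False))
    for a in hit:
        flat = rng.choice(m * n, size=n_pix, replace=False)
        img = out[a].reshape(-1)
        img[flat] = v
    return ProjectionStack(out, p.angles.copy())


def _subseeds(seed: int, n: int) -> list[int]:
    """Derive independent per-component seeds from one master seed."""
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def corrupt(p_clean: ProjectionStack, cfg: ArtifactConfig) -> ProjectionStack:
    """Compose the three artifact models on a calibrated clean stack.

    Order: Poisson noise, then ring offsets, then zingers (zingers model
    saturation and overwrite whatever is underneath).  Disabled components
    are skipped; sub-seeds derive deterministically from ``cfg.seed``.
    """
    cfg.validate()
    seeds = _subseeds(cfg.seed, 3)
    p = ProjectionStack(p_clean.data.copy(), p_clean.angles.copy())
    if cfg.noise_enabled:
        p = apply_poisson(p, cfg.I0, seeds[0])
    if cfg.ring_enabled:
        pattern = make_ring_pattern(
            p.data.shape[1], p.data.shape[2], cfg.P_ring, cfg.sigma_ring, seeds[1]
        )
        p = apply_ring(p, pattern)
    if cfg.zinger_enabled:
        p = apply_zinger(p, cfg.P_proj, cfg.P_zinger, cfg.v, seeds[2])
    return p


def with_seed(cfg: ArtifactConfig, seed: int) -> ArtifactConfig:
    """Copy of ``cfg`` with a different seed (convenience for sweeps)."""
    return replace(cfg, seed=seed)
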