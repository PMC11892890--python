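"""Classical artifact-reduction operators and their SSIM-driven tuning.

Two standard pre-processing steps are provided:

* **Median zinger removal** (projection domain): a pixel whose value
  exceeds its local median by more than ``dif`` is treated as a stray
  high-energy hit and replaced by that median.  One-sided on purpose:
  zingers are saturation events, always positive.
* **Wavelet-Fourier ring suppression** (sinogram domain, Muench-style):
  each sinogram is decomposed with a 2D multilevel DWT; in every level the
  vertical-stripe detail band is Fourier-transformed along the angle axis
  and multiplied by ``g(k) = 1 - exp(-k^2 / (2 sigma^2))``, which removes
  the angle-constant components that become rings after reconstruction.

``grid_search`` tunes both operators jointly by exhaustively reconstructing
every parameter combination and picking the highest mean SSIM against a
clean reference, mirroring how such parameters are chosen in practice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pywt
from scipy.ndimage import median_filter

from .phantom import Volume
from .pipeline import ProjectionStack, SinogramStack, fbp_reconstruct, rearrange
from .metrics import evaluate_volume

__all__ = [
    "ClassicalParams",
    "remove_zinger_median",
    "remove_ring_wavelet_fft",
    "grid_search",
]


@dataclass(frozen=True)
class ClassicalParams:
    """Joint parameter set of the two classical operators."""

    dif: float = 0.5
    size: int = 3
    level: int = 4
    wname: str = "sym5"
    sigma: float = 8.0

    def validate(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("median window size must be odd and >= 3")
        if self.level < 1:
            raise ValueError("wavelet level must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.dif <= 0:
            raise ValueError("dif must be positive")
        if self.wname not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet {self.wname!r}")


def remove_zinger_median(
    p: ProjectionStack, dif: float = 0.5, size: int = 3
) -> ProjectionStack:
    """Replace positive outliers above the local median in each projection."""
    if size % 2 == 0 or size < 3:
        raise ValueError("median window size must be odd and >= 3")
    if dif <= 0:
        raise ValueError("dif must be positive")
    out = p.data.copy()
    for a in range(out.shape[0]):
        med = median_filter(out[a], size=size, mode="reflect")
        hit = out[a] - med > dif
        out[a][hit] = med[hit]
    return ProjectionStack(out, p.angles.copy())


def _damp_stripes(band: np.ndarray, sigma: float) -> np.ndarray:
    """Suppress angle-constant components of one detail band.

    ``band`` has the (angle-like, detector-like) orientation of a sinogram;
    the FFT runs along the angle axis and low angular frequencies are damped
    by ``1 - exp(-k^2 / (2 sigma^2))``.
    """
    ny = band.shape[0]
    k = np.fft.fftshift(np.fft.fftfreq(ny, d=1.0 / ny))
    if sigma > 0:
        g = 1.0 - np.exp(-(k**2) / (2.0 * sigma**2))
    else:
        g = np.ones_like(k)
        g[np.abs(k) < 0.5] = 0.0  # sigma -> 0: remove only the DC component
    spec = np.fft.fftshift(np.fft.fft(band, axis=0), axes=0)
    spec *= g[:, None]
    return np.real(np.fft.ifft(np.fft.ifftshift(spec, axes=0), axis=0))


def remove_ring_wavelet_fft(
    s: SinogramStack, level: int = 4, wname: str = "sym5", sigma: float = 8.0
) -> SinogramStack:
    """Wavelet-Fourier stripe suppression, applied per detector row."""
    if s.n_angles < 2**level:
        raise ValueError("too few angles for the requested decomposition level")
    if wname not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet {wname!r}")
    out = np.empty_like(s.data)
    for m in range(s.data.shape[0]):
        sino = s.data[m].astype(np.float64)
        coeffs = pywt.wavedec2(sino, wname, level=level)
        damped = [coeffs[0]] + [
            (ch, _damp_stripes(cv, sigma), cd) for ch, cv, cd in coeffs[1:]
        ]
        rec = pywt.waverec2(damped, wname)
        out[m] = rec[: sino.shape[0], : sino.shape[1]].astype(np.float32)
    return SinogramStack(out, s.angles.copy())


def grid_search(
    p_corrupt: ProjectionStack,
    reference: Volume,
    grid: dict[str, list],
) -> tuple[ClassicalParams, list[dict]]:
    """Exhaustive SSIM-maximizing search over classical parameters.

    ``grid`` maps each :class:`ClassicalParams` field name to its candidate
    values; missing fields use the defaults.  Every combination is applied
    (zinger removal, then ring removal, then FBP), scored by mean SSIM
    against ``reference``, and the first-encountered argmax is returned
    together with the full score table.
    """
    names = list(grid.keys())
    if not names or any(len(v) == 0 for v in grid.values()):
        raise ValueError("parameter grid must be non-empty")
    unknown = set(names) - set(ClassicalParams.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown grid parameters: {sorted(unknown)}")
    table: list[dict] = []
    best: ClassicalParams | None = None
    best_score = -np.inf
    for combo in itertools.product(*grid.values()):
        params = ClassicalParams(**dict(zip(names, combo)))
        params.validate()
        cleaned = remove_zinger_median(p_corrupt, params.dif, params.size)
        s = remove_ring_wavelet_fft(
            rearrange(cleaned), params.level, params.wname, params.sigma
        )
        report = evaluate_volume(fbp_reconstruct(s), reference)
        entry = asdict(params)
        entry["mean_ssim"] = report.mean_ssim
        entry["mean_psnr"] = report.mean_psnr
        table.append(entry)
        if report.mean_ssim > best_score:
            best_score = report.mean_ssim
            best = params
    return best, table
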