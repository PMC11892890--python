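"""PSNR and SSIM with the reference-range convention.

Both metrics are computed against a high-quality reference and use the
*reference volume's* global ``max - min`` as the data range: per-slice
values therefore share one common scale across a volume.  SSIM uses the
Wang-2004 settings (11x11 Gaussian window, sigma 1.5, C1 = (0.01 R)^2,
C2 = (0.03 R)^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.metrics import structural_similarity

from .phantom import Volume

__all__ = ["psnr", "ssim", "evaluate_volume", "EvalReport", "PSNR_INF"]

#: Sentinel reported when MSE is exactly zero (identical images).
PSNR_INF = float("inf")


def _check_pair(x: np.ndarray, ref: np.ndarray, data_range: float) -> None:
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {ref.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")


def psnr(x: np.ndarray, ref: np.ndarray, data_range: float) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(range^2 / MSE)."""
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    _check_pair(x, ref, data_range)
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return PSNR_INF
    return 10.0 * np.log10(data_range**2 / mse)


def ssim(x: np.ndarray, ref: np.ndarray, data_range: float) -> float:
    """Mean local structural similarity (Gaussian 11x11 window, sigma 1.5)."""
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    _check_pair(x, ref, data_range)
    return float(
        structural_similarity(
            ref,
            x,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


@dataclass
class EvalReport:
    """Per-slice metrics of a reconstruction against a reference volume."""

    psnr_per_slice: list[float]
    ssim_per_slice: list[float]
    mean_psnr: float
    mean_ssim: float
    data_range: float
    reference_id: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls(**json.loads(text))


def evaluate_volume(r: Volume, r_hq: Volume, reference_id: str = "") -> EvalReport:
    """Slice-wise PSNR/SSIM of ``r`` against ``r_hq``, averaged along Z.

    The data range is the global max - min of the reference volume.
    """
    if r.data.shape != r_hq.data.shape:
        raise ValueError("volumes must share a shape")
    ref = r_hq.data.astype(np.float64)
    data_range = float(ref.max() - ref.min())
    if data_range <= 0:
        raise ValueError("reference volume has zero range")
    ps, ss = [], []
    for z in range(ref.shape[0]):
        ps.append(psnr(r.data[z], ref[z], data_range))
        ss.append(ssim(r.data[z], ref[z], data_range))
    return EvalReport(
        psnr_per_slice=ps,
        ssim_per_slice=ss,
        mean_psnr=float(np.mean(ps)),
        mean_ssim=float(np.mean(ss)),
        data_range=data_range,
        reference_id=reference_id,
    )
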