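"""Chained multi-stage inference across projection, sinogram and
reconstruction domains.

The chain applies one 2D network per domain, slice-by-slice:

1. **Projection stage** — each raw projection image is enhanced
   individually.
2. **Sinogram stage** — raw and enhanced projections are rearranged into
   per-row sinograms and angle-upsampled to the high-quality angle count;
   with bypass connections the network sees both as a 2-channel input, so
   errors introduced by stage 1 can still be corrected from the raw data.
3. **Reconstruction stage** — the raw-derived, stage-1-derived and
   stage-2-derived sinograms are each FBP-reconstructed onto one common
   grid; with bypass the network sees all three reconstructions per slice.

The no-bypass variant links stages directly (1 channel everywhere), which
is the ablation showing why the raw-data bypass matters.  All stage inputs
are built by pure functions so training can reuse exactly the inference
data path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import Volume
from .pipeline import (
    ProjectionStack,
    SinogramStack,
    angle_upsample,
    fbp_reconstruct,
    rearrange,
)

__all__ = [
    "PipelineModels",
    "enhance",
    "enhance_no_bypass",
    "stage2_inputs",
    "stage3_inputs",
    "apply_stage",
]


@dataclass
class PipelineModels:
    """The three stage models plus the LQ-to-HQ angle upsampling factor."""

    f_p: object
    f_s: object
    f_r: object
    upsample_factor: int = 4

    def check_bypass(self) -> None:
        if (self.f_p.c_in, self.f_s.c_in, self.f_r.c_in) != (1, 2, 3):
            raise ValueError(
                "bypass chain needs stage input channels (1, 2, 3), got "
                f"({self.f_p.c_in}, {self.f_s.c_in}, {self.f_r.c_in})"
            )

    def check_no_bypass(self) -> None:
        if (self.f_p.c_in, self.f_s.c_in, self.f_r.c_in) != (1, 1, 1):
            raise ValueError(
                "no-bypass chain needs stage input channels (1, 1, 1), got "
                f"({self.f_p.c_in}, {self.f_s.c_in}, {self.f_r.c_in})"
            )


def apply_stage(model, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Apply a stage network to (K, C, H, W) in memory-bounded batches."""
    out = np.empty((images.shape[0], 1) + images.shape[2:], dtype=np.float32)
    for lo in range(0, images.shape[0], batch_size):
        out[lo : lo + batch_size] = model.predict(images[lo : lo + batch_size])
    return out


def stage2_inputs(
    p_raw: ProjectionStack, p_hat: ProjectionStack, factor: int
) -> tuple[np.ndarray, SinogramStack, SinogramStack]:
    """Two-channel sinogram-stage input [raw, enhanced], angle-upsampled.

    Returns the (M, 2, N_a_hq, N) batch plus the two upsampled sinogram
    stacks (reused by the reconstruction stage).
    """
    s_raw = angle_upsample(rearrange(p_raw), factor)
    s_hat = angle_upsample(rearrange(p_hat), factor)
    batch = np.stack([s_raw.data, s_hat.data], axis=1)
    return batch, s_raw, s_hat


def stage3_inputs(
    s_raw_up: SinogramStack, s_phat_up: SinogramStack, s_hat: SinogramStack
) -> tuple[np.ndarray, Volume, Volume, Volume]:
    """Three-channel reconstruction-stage input, all on one grid.

    Channels are FBP reconstructions of the raw sinogram, the stage-1
    enhanced sinogram and the stage-2 output, in that order.
    """
    r_raw = fbp_reconstruct(s_raw_up)
    r_phat = fbp_reconstruct(s_phat_up)
    r_shat = fbp_reconstruct(s_hat)
    batch = np.stack([r_raw.data, r_phat.data, r_shat.data], axis=1)
    return batch, r_raw, r_phat, r_shat


def enhance(
    p_raw: ProjectionStack, models: PipelineModels, batch_size: int = 8
) -> tuple[ProjectionStack, SinogramStack, Volume]:
    """Run the full bypass chain; returns (p_hat, s_hat, r_hat).

    Never mutates its inputs; every stage consumes freshly built batches.
    """
    models.check_bypass()
    factor = models.upsample_factor
    p_hat_img = apply_stage(models.f_p, p_raw.data[:, None], batch_size)
    p_hat = ProjectionStack(p_hat_img[:, 0], p_raw.angles.copy())

    batch2, s_raw_up, s_phat_up = stage2_inputs(p_raw, p_hat, factor)
    s_hat_img = apply_stage(models.f_s, batch2, batch_size)
    s_hat = SinogramStack(s_hat_img[:, 0], s_raw_up.angles.copy())

    batch3, _, _, _ = stage3_inputs(s_raw_up, s_phat_up, s_hat)
    r_hat_img = apply_stage(models.f_r, batch3, batch_size)
    return p_hat, s_hat, Volume(r_hat_img[:, 0])


def enhance_no_bypass(
    p_raw: ProjectionStack, models: PipelineModels, batch_size: int = 8
) -> tuple[ProjectionStack, SinogramStack, Volume]:
    """Run the chain without bypass: each stage sees only its predecessor."""
    models.check_no_bypass()
    factor = models.upsample_factor
    p_hat_img = apply_stage(models.f_p, p_raw.data[:, None], batch_size)
    p_hat = ProjectionStack(p_hat_img[:, 0], p_raw.angles.copy())

    s_phat_up = angle_upsample(rearrange(p_hat), factor)
    s_hat_img = apply_stage(models.f_s, s_phat_up.data[:, None], batch_size)
    s_hat = SinogramStack(s_hat_img[:, 0], s_phat_up.angles.copy())

    r_shat = fbp_reconstruct(s_hat)
    r_hat_img = apply_stage(models.f_r, r_shat.data[:, None], batch_size)
    return p_hat, s_hat, Volume(r_hat_img[:, 0])
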