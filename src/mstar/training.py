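"""Sequential per-stage supervised training.

One corrupted low-quality (LQ) scan and one clean high-quality (HQ) scan of
the same object supply supervised pairs for every stage: the LQ angles are
an exact subsequence of the HQ angles (LQ angle ``i`` is HQ angle
``i * factor``), so HQ projections can be selected directly as stage-1
targets, the HQ sinogram is the stage-2 target and the HQ reconstruction
the stage-3 target.

Stages are trained strictly in order 1 -> 2 -> 3 and **independently**: a
stage is frozen before the next stage's input pairs are computed from it,
and no gradient ever crosses a stage boundary.  Each stage minimizes
mean-squared error with Adam, tracks a held-out validation loss every
epoch, stops early after ``early_stop_patience`` epochs without
improvement, and keeps the best-validation parameters.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .network import Adam, NetworkSpec, StageModel
from .phantom import Volume
from .pipeline import (
    ProjectionStack,
    angle_upsample,
    fbp_reconstruct,
    rearrange,
)
from .multistage import (
    PipelineModels,
    apply_stage,
    stage2_inputs,
    stage3_inputs,
)

__all__ = [
    "TrainingConfig",
    "PairedScan",
    "StageHistory",
    "build_pairs",
    "build_single_stage_pairs",
    "train_stage",
    "train_all",
]


@dataclass
class TrainingConfig:
    """Hyperparameters shared by all stages.

    Defaults follow the reference protocol (Adam, initial learning rate
    1e-3, L2 loss, early stopping after ten stalled epochs); the per-stage
    epoch budget defaults to (200, 200, 500) — the reconstruction stage
    sees richer image content and trains longest.  ``max_duration_s``
    bounds wall-clock time per stage for scaled-down runs.
    """

    epochs: tuple[int, int, int] = (200, 200, 500)
    learning_rate: float = 1e-3
    batch_size: int = 4
    val_fraction: float = 0.1
    early_stop_patience: int = 10
    seed: int = 0
    max_duration_s: float | None = None

    def validate(self) -> None:
        if any(e <= 0 for e in self.epochs):
            raise ValueError("epoch budgets must be positive")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class PairedScan:
    """One corrupted LQ scan and one clean HQ scan of the same object."""

    p_lq: ProjectionStack
    p_hq: ProjectionStack
    r_hq: Volume | None = None

    def __post_init__(self) -> None:
        if self.p_hq.n_angles % self.p_lq.n_angles != 0:
            raise ValueError("HQ angle count must be a multiple of the LQ count")
        factor = self.factor
        if not np.allclose(self.p_hq.angles[::factor], self.p_lq.angles, atol=1e-9):
            raise ValueError("LQ angles must be the subsequence i*factor of HQ angles")
        if self.r_hq is None:
            self.r_hq = fbp_reconstruct(rearrange(self.p_hq))

    @property
    def factor(self) -> int:
        return self.p_hq.n_angles // self.p_lq.n_angles


@dataclass
class StageHistory:
    """Per-epoch loss curves and the epoch whose parameters were kept."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False


def build_pairs(
    scan: PairedScan,
    stage: int,
    models_so_far: dict | None = None,
    bypass: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Supervised (input, target) image pairs for one stage.

    Inputs for stages 2 and 3 are computed with the frozen earlier-stage
    models, exactly as inference would compute them.  Returns arrays of
    shape (K, c_in, H, W) and (K, 1, H, W).
    """
    models_so_far = models_so_far or {}
    factor = scan.factor
    if stage == 1:
        inputs = scan.p_lq.data[:, None]
        targets = scan.p_hq.data[::factor][:, None]
        return inputs.copy(), targets.copy()

    if "f_p" not in models_so_far:
        raise ValueError("stage >= 2 requires the trained projection model f_p")
    f_p = models_so_far["f_p"]
    p_hat_img = apply_stage(f_p, scan.p_lq.data[:, None])
    p_hat = ProjectionStack(p_hat_img[:, 0], scan.p_lq.angles.copy())
    s_hq = rearrange(scan.p_hq)

    if stage == 2:
        if bypass:
            inputs, _, _ = stage2_inputs(scan.p_lq, p_hat, factor)
        else:
            inputs = angle_upsample(rearrange(p_hat), factor).data[:, None]
        return inputs, s_hq.data[:, None].copy()

    if stage == 3:
        if "f_s" not in models_so_far:
            raise ValueError("stage 3 requires the trained sinogram model f_s")
        f_s = models_so_far["f_s"]
        targets = scan.r_hq.data[:, None].copy()
        if bypass:
            batch2, s_raw_up, s_phat_up = stage2_inputs(scan.p_lq, p_hat, factor)
            s_hat_img = apply_stage(f_s, batch2)
            from .pipeline import SinogramStack

            s_hat = SinogramStack(s_hat_img[:, 0], s_raw_up.angles.copy())
            inputs, _, _, _ = stage3_inputs(s_raw_up, s_phat_up, s_hat)
        else:
            s_phat_up = angle_upsample(rearrange(p_hat), factor)
            s_hat_img = apply_stage(f_s, s_phat_up.data[:, None])
            from .pipeline import SinogramStack

            s_hat = SinogramStack(s_hat_img[:, 0], s_phat_up.angles.copy())
            inputs = fbp_reconstruct(s_hat).data[:, None]
        return inputs, targets

    raise ValueError(f"stage must be 1, 2 or 3, got {stage}")


def build_single_stage_pairs(
    scan: PairedScan, domain: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs for a single-domain model (ablation): no earlier stages.

    ``domain`` is "projection", "sinogram" or "reconstruction"; inputs are
    derived from the raw LQ data alone.
    """
    factor = scan.factor
    if domain == "projection":
        return build_pairs(scan, 1)
    s_raw_up = angle_upsample(rearrange(scan.p_lq), factor)
    if domain == "sinogram":
        return s_raw_up.data[:, None].copy(), rearrange(scan.p_hq).data[:, None].copy()
    if domain == "reconstruction":
        r_raw = fbp_reconstruct(s_raw_up)
        return r_raw.data[:, None].copy(), scan.r_hq.data[:, None].copy()
    raise ValueError(f"unknown domain {domain!r}")


def _norm_stats(arr: np.ndarray, axis) -> tuple[np.ndarray, np.ndarray]:
    mean = arr.mean(axis=axis)
    std = np.maximum(arr.std(axis=axis), 1e-6)
    return mean, std


def train_stage(
    pairs: tuple[np.ndarray, np.ndarray],
    spec: NetworkSpec,
    cfg: TrainingConfig,
    epochs: int | None = None,
) -> tuple[StageModel, StageHistory]:
    """Train one stage on (inputs, targets) image pairs.

    Normalization constants come from the training split; the returned
    model carries the lowest-validation-loss parameters.  Deterministic for
    a fixed ``cfg.seed``.
    """
    cfg.validate()
    inputs, targets = pairs
    k = inputs.shape[0]
    if k < 2:
        raise ValueError("need at least 2 pairs to hold out a validation image")
    if inputs.shape[1] != spec.c_in:
        raise ValueError(
            f"pairs have {inputs.shape[1]} channels but spec.c_in = {spec.c_in}"
        )
    epochs = int(epochs if epochs is not None else cfg.epochs[0])
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(k)
    n_val = max(1, int(round(cfg.val_fraction * k)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_tr, y_tr = inputs[train_idx], targets[train_idx]
    x_val, y_val = inputs[val_idx], targets[val_idx]

    mean_in, std_in = _norm_stats(x_tr.astype(np.float64), axis=(0, 2, 3))
    mean_out, std_out = _norm_stats(y_tr.astype(np.float64), axis=None)
    model = StageModel(
        spec,
        norm_in=np.stack([mean_in, std_in]),
        norm_out=(float(mean_out), float(std_out)),
    )
    opt = Adam(lr=cfg.learning_rate)
    hist = StageHistory()
    best_val = np.inf
    best_params = model.copy_params()
    stall = 0
    t0 = time.monotonic()
    n_tr = x_tr.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n_tr)
        losses = []
        for lo in range(0, n_tr, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            losses.append(model.training_step(x_tr[sel], y_tr[sel], opt))
        val = model.loss(x_val, y_val)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_params = model.copy_params()
            hist.best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.early_stop_patience:
                hist.stopped_early = True
                break
        if cfg.max_duration_s is not None and time.monotonic() - t0 > cfg.max_duration_s:
            hist.stopped_early = True
            break
    model.set_params(best_params)
    return model, hist


def train_all(
    scan: PairedScan,
    specs: tuple[NetworkSpec, NetworkSpec, NetworkSpec],
    cfg: TrainingConfig,
    bypass: bool = True,
) -> tuple[PipelineModels, dict]:
    """Train the three stages sequentially; earlier stages are frozen.

    Returns the trained chain and a log dict with per-stage histories and
    the ordered event list (pair building strictly follows the completion
    of every earlier stage).
    """
    cfg.validate()
    expected = (1, 2, 3) if bypass else (1, 1, 1)
    if tuple(s.c_in for s in specs) != expected:
        raise ValueError(f"stage specs must have c_in {expected}")
    events: list[str] = []
    log: dict = {"events": events, "histories": {}}
    models: dict = {}

    events.append("build_pairs:stage1")
    pairs = build_pairs(scan, 1, models, bypass)
    events.append("train:stage1")
    models["f_p"], log["histories"]["stage1"] = train_stage(
        pairs, specs[0], cfg, cfg.epochs[0]
    )
    events.append("frozen:stage1")

    events.append("build_pairs:stage2")
    pairs = build_pairs(scan, 2, models, bypass)
    events.append("train:stage2")
    models["f_s"], log["histories"]["stage2"] = train_stage(
        pairs, specs[1], cfg, cfg.epochs[1]
    )
    events.append("frozen:stage2")

    events.append("build_pairs:stage3")
    pairs = build_pairs(scan, 3, models, bypass)
    events.append("train:stage3")
    models["f_r"], log["histories"]["stage3"] = train_stage(
        pairs, specs[2], cfg, cfg.epochs[2]
    )
    events.append("frozen:stage3")

    chain = PipelineModels(
        models["f_p"], models["f_s"], models["f_r"], upsample_factor=scan.factor
    )
    return chain, log
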