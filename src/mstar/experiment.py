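"""End-to-end experiment orchestration: simulate, corrupt, train, enhance,
evaluate.

One :class:`ExperimentConfig` describes a complete scaled synthetic study:
a foam phantom pair (train/test), paired LQ/HQ scans, sequential stage
training, multi-stage inference and metric reports.  A single global seed
deterministically spawns every sub-seed, so a manifest plus its seed
reproduces the run exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .artifacts import ArtifactConfig, calibrate_absorption, corrupt
from .metrics import evaluate_volume
from .multistage import PipelineModels, enhance, enhance_no_bypass
from .network import NetworkSpec
from .phantom import FoamSpec, Volume, generate_foam_phantom
from .pipeline import ProjectionStack, fbp_reconstruct, make_angles, forward_project, rearrange, angle_upsample
from .training import PairedScan, TrainingConfig, train_all
from . import io as mio

__all__ = ["ExperimentConfig", "simulate_paired_scan", "run_experiment"]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class ExperimentConfig:
    """Everything needed to run one scaled synthetic experiment."""

    foam: FoamSpec = field(default_factory=FoamSpec)
    n_angles_lq: int = 32
    upsample_factor: int = 4
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    depth: int = 20
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0
    ablation: bool = False
    out_dir: str = "mstar_run"

    def validate(self) -> None:
        self.foam.validate()
        self.artifacts.validate()
        self.training.validate()
        if self.n_angles_lq < 2 or self.upsample_factor < 1:
            raise ValueError("need >= 2 LQ angles and a factor >= 1")


def simulate_paired_scan(
    foam: FoamSpec,
    n_angles_lq: int,
    factor: int,
    artifacts: ArtifactConfig,
) -> tuple[PairedScan, Volume]:
    """Simulate one paired LQ/HQ acquisition of a fresh foam phantom.

    The HQ scan has ``factor * n_angles_lq`` clean angles; the LQ scan takes
    every ``factor``-th angle and is corrupted per ``artifacts`` after the
    global absorption calibration.  Returns the scan and the ground-truth
    volume.
    """
    vol = generate_foam_phantom(foam)
    p_hq = forward_project(vol, make_angles(n_angles_lq * factor))
    p_hq, _ = calibrate_absorption(p_hq, artifacts.gamma_target)
    p_lq_clean = ProjectionStack(
        p_hq.data[::factor].copy(), p_hq.angles[::factor].copy()
    )
    p_lq = corrupt(p_lq_clean, artifacts)
    return PairedScan(p_lq=p_lq, p_hq=p_hq), vol


def _stage_specs(depth: int, seeds: list[int], bypass: bool) -> tuple:
    chans = (1, 2, 3) if bypass else (1, 1, 1)
    return tuple(
        NetworkSpec(c_in=c, depth=depth, seed=s) for c, s in zip(chans, seeds)
    )


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the full synthetic protocol and write a result manifest.

    Trains on one phantom, evaluates on a second, independently drawn one;
    writes models, reconstructions and metric reports under
    ``cfg.out_dir`` and returns the manifest dict.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(cfg.seed, 8)
    foam_train = replace(cfg.foam, seed=seeds[0])
    foam_test = replace(cfg.foam, seed=seeds[1])
    art_train = replace(cfg.artifacts, seed=seeds[2])
    art_test = replace(cfg.artifacts, seed=seeds[3])
    train_cfg = replace(cfg.training, seed=seeds[4])

    scan_train, _ = simulate_paired_scan(
        foam_train, cfg.n_angles_lq, cfg.upsample_factor, art_train
    )
    scan_test, _ = simulate_paired_scan(
        foam_test, cfg.n_angles_lq, cfg.upsample_factor, art_test
    )

    manifest: dict = {
        "config": {
            "foam": asdict(cfg.foam),
            "n_angles_lq": cfg.n_angles_lq,
            "upsample_factor": cfg.upsample_factor,
            "artifacts": asdict(cfg.artifacts),
            "depth": cfg.depth,
            "training": asdict(cfg.training),
            "seed": cfg.seed,
            "ablation": cfg.ablation,
        },
        "files": {},
        "metrics": {},
    }

    r_corrupt = fbp_reconstruct(
        angle_upsample(rearrange(scan_test.p_lq), cfg.upsample_factor)
    )
    manifest["metrics"]["corrupted"] = _report(r_corrupt, scan_test.r_hq)

    variants = [("bypass", True)] + ([("no_bypass", False)] if cfg.ablation else [])
    for name, bypass in variants:
        specs = _stage_specs(cfg.depth, seeds[5:8], bypass)
        chain, log = train_all(scan_train, specs, train_cfg, bypass=bypass)
        run = enhance if bypass else enhance_no_bypass
        _, _, r_hat = run(scan_test.p_lq, chain)
        manifest["metrics"][name] = _report(r_hat, scan_test.r_hq)
        mdir = out / f"models_{name}"
        mdir.mkdir(exist_ok=True)
        for stage, model in (("f_p", chain.f_p), ("f_s", chain.f_s), ("f_r", chain.f_r)):
            path = mdir / f"{stage}.npz"
            model.save(path)
            manifest["files"][f"{name}/{stage}"] = str(path)
        rec_path = out / f"recon_{name}.tif"
        mio.write_volume(rec_path, r_hat)
        manifest["files"][f"{name}/recon"] = str(rec_path)
        manifest["metrics"][f"{name}_val_loss"] = {
            stage: hist.val_loss[-1] if hist.val_loss else None
            for stage, hist in log["histories"].items()
        }

    ref_path = out / "recon_reference.tif"
    mio.write_volume(ref_path, scan_test.r_hq)
    manifest["files"]["reference"] = str(ref_path)
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


def _report(r: Volume, r_hq: Volume) -> dict:
    rep = evaluate_volume(r, r_hq)
    return {"mean_psnr": rep.mean_psnr, "mean_ssim": rep.mean_ssim}
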