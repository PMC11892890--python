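# mstar — multi-stage artifact reduction for parallel-beam CT

Synchrotron-style tomography pipelines process data in three
representations: projection images, sinograms, and reconstructed slices.
Acquisition artifacts corrupt all three, each in its own characteristic
way — Poisson photon noise is local everywhere, a miscalibrated detector
pixel becomes a straight line in the sinogram and a concentric *ring* in
the reconstruction, and a stray high-energy hit (*zinger*) becomes a
crossing streak.  A CNN applied only to reconstructed slices struggles
with the non-local ring and streak artifacts, because by then the damage
has been smeared across the whole image.

`mstar` implements a multi-stage alternative: three small 2D mixed-scale
dense (MS-D) networks, one per representation, applied in sequence

    p̂ = f_p(p̃)                                  (projection stage)
    ŝ = f_s([ℛ(p̃)↑, ℛ(p̂)↑])                     (sinogram stage)
    r̂ = f_r([FBP(ℛ(p̃)↑), FBP(ℛ(p̂)↑), FBP(ŝ)])   (reconstruction stage)

where ℛ is the projection↔sinogram rearrangement, ↑ is angular
upsampling to the high-quality angle count and FBP is filtered back
projection.  The extra input channels are *bypass connections*: every
stage also sees the raw data, so an earlier stage's mistake cannot wipe
out information downstream.  Stages are trained sequentially and
independently (MSE loss, Adam), never end-to-end — each stage is a 2D
problem, which is what makes the approach tractable for volumes that
exceed GPU or RAM budgets as a 3D problem.

The package is self-contained: it generates its own ground truth (foam
phantoms — a cylinder with many non-overlapping zero-attenuation
bubbles), simulates paired corrupted low-quality / clean high-quality
scans, trains and evaluates the chain, and compares against classical
pre-processing (median zinger removal plus Münch-style wavelet-Fourier
ring suppression, with an SSIM-maximizing grid search for their
parameters).  A depth-`d` MS-D stage with `c` input channels has exactly
`Σ_{i=1..d} [9·(c+i−1)+1] + (c+d) + 1` trainable parameters — 45652 /
46553 / 47454 for the three depth-100 stages, 146972 for the depth-180
single-network post-processing baseline.

## Worked example

```python
from mstar import *
from mstar.experiment import simulate_paired_scan
from mstar.training import TrainingConfig, train_all
from mstar.network import NetworkSpec

foam = FoamSpec(grid_size=64, n_bubbles=120, bubble_radius_range=(2, 8), seed=101)
art = ArtifactConfig(I0=30.0, P_ring=0.1, P_zinger=0.001, seed=202)
scan, _ = simulate_paired_scan(foam, n_angles_lq=32, factor=4, artifacts=art)

specs = tuple(NetworkSpec(c_in=c, depth=20, seed=c) for c in (1, 2, 3))
cfg = TrainingConfig(epochs=(30, 30, 45), batch_size=4, seed=7)
chain, log = train_all(scan, specs, cfg)

test_scan, _ = simulate_paired_scan(
    FoamSpec(grid_size=64, n_bubbles=120, bubble_radius_range=(2, 8), seed=303),
    32, 4, ArtifactConfig(I0=30.0, P_ring=0.1, P_zinger=0.001, seed=404))
_, _, r_hat = enhance(test_scan.p_lq, chain)

corrupted = evaluate_volume(
    fbp_reconstruct(angle_upsample(rearrange(test_scan.p_lq), 4)), test_scan.r_hq)
enhanced = evaluate_volume(r_hat, test_scan.r_hq)
print(f"corrupted: {corrupted.mean_psnr:.2f} dB   enhanced: {enhanced.mean_psnr:.2f} dB")
```

At this desk scale (64³ phantom, 32 corrupted angles at I₀ = 30 with
rings and zingers, depth-20 networks) the run above prints

```
corrupted: 2.69 dB   enhanced: 18.59 dB
```

i.e. the three-stage chain recovers ~16 dB over the corrupted
reconstruction.  The same script with single-stage variants reproduces
the characteristic ordering: projection-only (15.51) ≤ sinogram-only
(15.86) ≤ reconstruction-only (16.21) ≤ multi-stage without bypass
(17.81) ≤ multi-stage with bypass (18.59 dB).

A command-line interface mirrors the library:

```
mstar simulate phantom --size 64 --bubbles 120 --seed 1 --out foam.tif
mstar project --volume foam.tif --angles 128 --out proj.tif
mstar corrupt --config artifacts.yaml --in proj.tif --out proj_lq.tif
mstar enhance --models models/ --in proj_lq.tif --out recon.tif
mstar evaluate --recon recon.tif --ref ref.tif --out report.json
```

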