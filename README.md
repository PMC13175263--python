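# petrestore

Quantification of radiotracer uptake in small lung tumours on PET images is
limited by image noise and the partial volume effect: reconstruction with
resolution (PSF) modelling sharpens small lesions but adds Gibbs-like edge
overshoot that inflates SUV_max, while medians are depressed by spill-out.
`petrestore` implements a fully simulated study of a deep-learning fix for
this: tumours with known ("ground truth") activity distributions are placed
in the left lung of a digital torso, realistic PET raw data are generated
and reconstructed, and a 3D convolutional network is trained to restore the
ground-truth activity from the reconstructed image.  It is aimed at
researchers in PET quantification and image reconstruction who want a
self-contained, reproducible sandbox for restoration methods.

The pipeline, all driven by seeds and configs:

1. **phantom** — procedural torso (lungs, heart, spine/ribs) plus tumours of
   0.01–200 ml with three activity patterns (uniform, split in halves,
   hollow with a necrotic core; shell thickness = half the equivalent
   radius); tumour-to-background ratio fixed at 10.
2. **projector** — analytic simulator: image-space Gaussian PSF (default
   FWHM (4.5, 4.5, 4.0) mm), attenuated parallel-beam line integrals,
   scaling to a target prompt count with a uniform scatter+randoms
   background (NEC = T²/P; 100M prompts ↔ 12.4M NEC), Poisson noise.
3. **osem** — ordinary-Poisson OSEM, 6 iterations × 21 subsets, image-based
   PSF modelling, no post-filter.
4. **cnn** — 7-layer 3D CNN (32 filters of 3×3×3, batch-norm, two dropout
   layers at rate 0.3, final linear layer), MSE loss, Adam at 0.001,
   implemented directly on NumPy with analytic gradients.
5. **quantify** — recovery coefficients RC_max, RC_median, RC_peak (ratios
   of each statistic to its ground-truth value inside the tumour mask),
   SUV_peak in a 1 cm³ spherical VOI, 3D MSSIM over 7×7×7 windows,
   mesh-based sphericity (36π V²)^{1/3}/A, half-activity ratios,
   volume-binned cohort tables.
6. **experiments** — the three studies: (1) train/test with one PSF,
   (2) apply the trained network to data with PSFs drawn from
   N(4.5, 0.2²) mm, (3) apply it to hollow tumours at 0.5× and 2× prompts.

## Worked example

Run experiment 1 at the reduced scale used by the test-suite (72 cases on a
48×48×28 grid, 2M prompts, 24³ crops, 10 epochs):

```python
import numpy as np
import petrestore as pr
from petrestore import experiments

cfg = pr.ExperimentConfig(
    grid_shape=(48, 48, 28), n_angles=42, total_prompts=2e6,
    crop_shape=(24, 24, 24),
    composition={"uniform": 24, "halves": 24, "hollow": 24},
    small_volume_range=(0.8, 5.0), large_volume_range=(5.0, 7.0),
    epochs=10, master_seed=20,
)
result = experiments.run_experiment(cfg, outdir="exp1")
print(result.tables["recon_large"])   # reconstructed PET, tumours >= 5 ml
print(result.tables["pred_large"])    # CNN predictions
```

which prints (reconstruction first, prediction second):

```
               mean        sd    n
rc_max     2.295724  0.274192  7.0
rc_median  0.794529  0.073691  5.0
rc_peak    1.062308  0.051113  7.0
               mean        sd    n
rc_max     1.582274  0.190039  7.0
rc_median  0.936744  0.081150  5.0
rc_peak    1.258172  0.071984  7.0
```

Read this as: on held-out tumours larger than 5 ml the PSF reconstruction
overshoots the true maximum by ~2.3× (Gibbs artefact) and under-recovers
the median (0.79); the network pulls RC_max down to 1.58 and the median up
to 0.94.  Mean MSSIM against the ground truth rises from 0.63
(reconstruction) to 0.67 (prediction).  At full protocol scale (344×344×127 grid, 100M prompts,
2110 cases, 500 epochs) the same directions hold with tighter values; that
preset (`experiments.full_scale(1)`) is cluster-scale.

A CLI mirrors the library (`petrestore phantom | simulate | reconstruct |
train | predict | evaluate | experiment`); volumes are exchanged as NIfTI,
sinograms as HDF5, metrics as CSV.

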