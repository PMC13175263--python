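# Methods

`petrestore` reproduces, end to end and at configurable scale, a
simulation study of deep-learning-based restoration of PET lung-tumour
images: ground-truth tumours with known activity are embedded in a digital
torso, turned into realistic PET raw data and reconstructed with a
clinical-style protocol, and a 3D CNN is trained to recover the ground
truth from the reconstruction.  This note documents the models, the
numerical choices, and what the synthetic data do and do not show.

## Ground-truth phantom

The torso is procedural: an elliptic-cylinder body of soft tissue, two lung
ellipsoids, a heart with elevated uptake, and spine/rib structures with
bone attenuation adjacent to the left lung.  Attenuation defaults are
standard 511 keV values (soft tissue 0.0096/mm, lung 0.0026/mm, bone
0.0150/mm); organ activities are relative levels, because the whole
background field is rescaled per case (below).  The torso stands in for an
anthropomorphic phantom only as a realistic background — it is not
anatomically faithful, and no motion or kinetics are modelled.

Tumours are sampled as ellipsoids with a volume-preserving axis ratio set
by an elongation parameter (larger elongation, lower sphericity), deformed
by a smooth random radial perturbation, randomly oriented, and voxelized; a
bisection on the global scale factor matches the voxel count to the target
volume (0.01–200 ml) to within about one surface layer.  Three activity
patterns are supported:

* **uniform** — one activity over the whole mask;
* **halves** — the mask is split by a random plane through its centroid and
  the two sides receive different activities; the ratio between them is
  drawn uniformly from [1.2, 3.0] by the experiment driver (the
  distribution of this ratio is a package choice; only its variability is
  prescribed by the study design);
* **hollow** — voxels deeper than half the equivalent-sphere radius
  (Euclidean distance transform with physical voxel spacing) form a
  necrotic core at background activity; the shell keeps the tumour
  activity.  For spheres this reduces exactly to "shell thickness equals
  half the radius".

Tumour activities are drawn uniformly from 6–35 kBq/ml.  At assembly the
torso activity field is rescaled so the lung background equals one tenth of
the maximum tumour activity: every ground-truth image has a
tumour-to-background ratio of exactly 10.  Placement is uniform over all
positions at which the tumour lies entirely inside the left lung
(admissibility computed by FFT correlation of the mask with the lung
complement).  Everything is deterministic given the spec and seeds.

## Raw-data simulation

The simulator is analytic, not Monte Carlo.  The resolution kernel is an
anisotropic, spatially invariant Gaussian PSF applied in image space
(sigma = FWHM / 2sqrt(2 ln 2); transaxial FWHM in x, y and axial in z;
default FWHM (4.5, 4.5, 4.0) mm).  Projection is slice-wise 2D
parallel-beam: volumes are padded to the grid diagonal and rotated
(bilinear), and line integrals are taken along one axis.  Because both
annihilation photons traverse the full line of response, attenuation enters
as a single per-LOR factor exp(-integral of mu), independent of the
emission point.  The scanner's 3D geometry, detector normalisation, dead
time and time-of-flight are all out of scope; the simplified projector
preserves the noise and partial-volume phenomenology the method depends on.

The trues sinogram is scaled so its expected total equals
`trues_fraction x total_prompts`; a spatially uniform background supplies
the remaining prompts, modelling scatter plus randoms (their true spatial
distribution is not modelled).  With NEC defined as T^2/P — the study never
separates scatter from randoms, so the T^2/(T+S+2R) form is not
identifiable — the default trues fraction 0.352 makes 100M prompts
correspond to 12.4M noise-equivalent counts.  Counts are independent
Poisson draws per bin, seeded.

For the cross-scanner dataset the per-case PSF is drawn with transaxial
FWHM ~ N(4.5, 0.2^2) mm and axial = transaxial / 1.125, matched between
simulation and reconstruction.

## Reconstruction

Ordinary-Poisson OSEM with image-based PSF modelling: the subset forward
model is `s * att * R(G(x)) + b` with G the image-space PSF, R the
projector, att the attenuation factors, s the simulation's trues scale and
b the known background expectation (included additively, keeping the
Poisson model exact rather than pre-subtracting).  Updates multiply the
current image by the PSF-adjoint backprojection of the count ratio,
normalised by the subset sensitivity (PSF-adjoint backprojection of the
attenuation factors).  Defaults follow the protocol: 6 iterations, 21
interleaved angle subsets (subset k takes angles k, k+21, ...), no
post-filter.  Numerical guards: epsilon 1e-12 in denominators; voxels with
sensitivity below 1e-8 of its maximum are frozen at zero; the initial image
is one inside the support.  With a single subset each iteration is exactly
the classical MLEM update, which the tests verify update-by-update, along
with the ML fixed point (a noiseless cylinder re-projects to its own
sinogram) and the characteristic Gibbs overshoot of PSF reconstruction
(reconstructed maxima above truth for uniform spheres of 5 ml and more).

The backprojector uses rotation by the negative angle as the adjoint of the
bilinear rotation; this is the usual slightly unmatched adjoint and is
accurate to interpolation error.

## Restoration network

Seven 3x3x3 convolutions (same padding), 32 filters in the hidden layers,
ReLU activations, batch normalisation after every convolution except the
last, dropout 0.3 directly after the first and second batch-norms, and a
final single-filter linear convolution so the output matches the input
shape — 140,545 parameters in total (140,161 convolutional plus 384
batch-norm).  The final layer has one filter
because the output must be a single-channel volume; with inverted dropout
and non-negative masks, dropout and ReLU commute, so placing dropout
directly after batch-norm is equivalent to placing it after the activation.

The network and its training loop are implemented directly on NumPy
(channels-last float32).  Convolutions run as 27 shifted GEMMs (one per
kernel offset), which keeps every BLAS operand contiguous; backpropagation
uses the exact analytic gradients, which the test-suite checks against
finite differences.  The optimiser is Adam at learning rate 0.001 and the
loss is voxel-wise MSE.

Each training pair is min-max scaled with the reconstructed crop's minimum
and maximum; the same record scales the ground-truth target and is inverted
on the prediction before any quantitative analysis, so all reported
activities are in kBq/ml.  (Scaling the target with the input's record —
rather than its own — is the package's resolution of an ambiguity in the
protocol; it makes the inverse transform well defined at inference, when
only the input is available.)  Training data are augmented by spatially
shrinking larger tumours with factors in [0.5, 0.8] (volumes scale with the
cube of the factor), increasing the number of small tumours.

## Evaluation metrics

* **SUV** = concentration (kBq/ml) / (injected MBq / body weight kg), unit
  tissue density.
* **Recovery coefficients**: ratios of maximum, median and peak uptake
  inside the ground-truth tumour mask (mask applied to both images).  The
  median RC is skipped for halves tumours, whose in-mask histogram is
  bimodal.
* **Peak** uptake: the highest mean over 1 cm^3 spherical VOIs
  (radius 6.204 mm) centred on mask voxels whose full sphere lies inside
  the image; computed by convolution and verified against exhaustive
  enumeration.
* **MSSIM**: mean SSIM over all fully interior 7x7x7 windows, stride 1,
  unit exponents, constants C1=(0.01 L)^2, C2=(0.03 L)^2, C3=C2/2 with L
  the joint data range of the pair (joint, so the measure stays symmetric);
  sample (n-1) covariance normalisation, matching the scikit-image
  reference against which it is tested.
* **Sphericity** = (36 pi V^2)^(1/3) / A with V from the voxel count and A
  from a marching-cubes isosurface of the binary mask at level 0.5, clipped
  to 1.  Voxel-face counting is rejected (it overestimates A badly), but
  the marching-cubes area on a binary mask still carries a bounded
  staircase bias of roughly 8%, so digital spheres measure ~0.92 rather
  than 1 at any resolution; the closed-form route gives exactly 1.  The
  metric is used comparatively (elongated vs round tumours), where the
  shared bias cancels.
* **Halves ratio**: median-activity ratio between the two halves, high/low
  ordering fixed on the ground truth, with an underestimation flag.
* **Cohort summaries**: volume >= 5 ml, plain mean +/- SD per RC; volume
  1–2 ml, four 0.25 ml segments averaged per segment and then equally
  weighted (empty segments are excluded with a warning).
* **Detectability**: in-mask maximum above 1.5x the known background.

## Experiments and scale

Experiment 1 trains and tests (80/20 split, 20% of training for
validation) on data with the fixed PSF; experiment 2 applies the
experiment-1 network, never retrained, to data with sampled PSFs;
experiment 3 applies it to hollow tumours above 5 ml simulated at half and
twice the nominal prompts.

The `full` preset records the full protocol (344x344x127 voxel grid at
[2.09, 2.09, 2.03] mm, 100M prompts, 2110 cases, 50^3 crops, 500 epochs,
batch 50) — it is cluster-scale and not exercised by the test-suite.  The
`desk` preset (96x96x48 grid, 2M prompts, 60 cases, 32^3 crops, 30 epochs)
runs on a workstation.  The acceptance suite runs a further reduced
configuration chosen to keep the whole chain tractable on a single CPU
while preserving the phenomenology: 48x48x28 grid at the reference voxel
size, 42 projection angles (still 21 subsets, 6 iterations), 2M prompts,
72 cases (24 per pattern, half of them above 5 ml), 24^3 crops and 10
epochs.  At this scale the reconstructed images show the expected
behaviour (RC_max well above 1 from Gibbs overshoot, RC_median below 1 from
partial volume), and the trained network moves every one of these
statistics toward 1 and raises MSSIM on held-out cases — the directional
claims are scale-free, while the absolute table values depend on scanner
geometry and statistics and are not expected to reproduce numerically at
reduced scale.

## Known limitations

* The projector is 2D slice-wise with a uniform contamination model; axial
  blur enters only through the image-space PSF.
* Marching-cubes surface areas on binary masks are biased high (see above).
* Batch normalisation statistics come from small batches at desk scale;
  training is reproducible given the seed, but parallel BLAS reductions may
  introduce tiny run-to-run differences on other platforms.
* The synthetic torso lacks anatomical variability, organ texture and
  motion, so passing tests demonstrate correctness of the pipeline and the
  direction of the restoration effect — not clinical performance.
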