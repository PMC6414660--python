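# Methods

`renoquant` implements an automated pipeline for measuring glomerular
filtration rate (GFR) from quantitative 99mTc-DTPA SPECT/CT: a 3D
convolutional network segments the renal parenchyma on CT, the resulting
volume of interest (VOI) is applied to the co-registered quantitative
SPECT volume to obtain the percent injected dose (%ID), and an affine
calibration converts %ID to per-kidney GFR, with the bilateral sum
normalized to body surface area.  Because no clinical images ship with
the package, every component is exercised end-to-end on digital kidney
phantoms with known ground truth.

## Coordinate and data model

Volumes are axis-aligned 3D lattices (`VolumeGrid`) with positive voxel
spacing, a voxel-center world mapping `world = origin + index * spacing`,
and a closed unit enumeration (HU, Bq/ml, counts, probability, binary).
Array axis 0 runs right→left, axis 1 anterior→posterior, axis 2
inferior→superior; a coronal slice is a fixed index along axis 1.
NIfTI-1 is the on-disk format; unit tags travel in JSON sidecars.
Laterality of a binary VOI is assigned per connected component from the
centroid relative to the mid-sagittal plane; when exactly two components
fall on one side, relative order decides.

Resampling is trilinear, about the shared volume center, so a coarser
target grid trims the field of view symmetrically (the clinical
preprocessing maps CT 512×512×161 @ 0.977×0.977×2.5 mm and SPECT 128³ @
3.452 mm onto a common 256×256×232 @ 1.726 mm grid, then crops a
192×128×96 window for training).  Binary masks are resampled by
trilinear interpolation followed by a 0.5 threshold, which implements
the intended sub-voxel smoothness better than nearest-neighbour
lookup.  Crops keep their inverse mapping in metadata, so predictions
made on a window can be placed back on the uncropped grid exactly.

### Mask smoothing

`smooth_mask` regularizes VOIs assembled from 2D ROIs.  A plain
"Gaussian-blur the indicator and re-threshold at 0.5" erodes a convex
VOI by roughly σ²·curvature per application, which is a substantial
fraction of a kidney's boundary at coarse grids.  We therefore smooth
the *signed distance field* and re-threshold at the level that conserves
the VOI volume (clipped to ±0.3σ so gross under/over-segmentation is
not frozen in), followed by morphological closing (cubic element,
radius 1 voxel by default).  This keeps the operator nearly idempotent
(Dice ≥ 0.99 against its own output) while still bridging inter-slice
discontinuities.

## Digital phantoms

Each phantom subject comprises a CT-like volume, a SPECT-like volume, a
ground-truth parenchyma VOI and per-kidney ground-truth %ID.  The
anatomy is deliberately minimal:

* **Kidneys** — tilted ellipsoids (long axis inferior–superior, coronal
  tilt up to ±12°), lateral offset and semi-axes sampled per subject.
  A medially offset inner ellipsoid carves out the renal pelvis/hilum,
  yielding the bean shape and, crucially, a non-parenchymal compartment
  directly adjacent to parenchyma.
* **Lesions** — spherical cysts (0–2 per kidney), an optional tumor,
  renal stones at the parenchyma/pelvis interface and ureter stones
  inferomedial to the kidney.  All lesions and the pelvis are *excluded*
  from the ground-truth VOI by construction.
* **CT appearance** — compartment means (soft tissue ≈ 40 HU, parenchyma
  ≈ 35 HU, cyst ≈ 10 HU, non-contrast pelvis ≈ 15 HU, stones ≥ 300 HU,
  contrast-filled pelvis ≥ 150 HU, air −1000 HU) keep the
  parenchyma/soft-tissue/cyst contrast weak, as on non-contrast CT.  In
  22.6% of subjects (configurable) the pelvis is contrast-enhanced.
  The configured noise SDs describe the native CT grid (voxel volume
  ≈ 2.39 mm³); per-voxel noise is scaled by √(V_ref/V_voxel) so coarser
  analysis grids carry proportionally less noise, as in real
  reconstruction.  Subjects have a single kidney with probability 0.01.
* **SPECT** — uniform tracer concentration over each kidney's
  parenchyma, scaled so the sampled target %ID of the 370 MBq injection
  is met; excluded structures carry zero activity.  The map is blurred
  with an isotropic Gaussian PSF (default FWHM 6 mm, standing for the
  post-reconstruction resolution of an OSEM chain with resolution
  modelling) and corrupted with Poisson count noise at the calibrated
  system sensitivity (152.5 cpm/μCi, 1-minute acquisition).

**Ground-truth %ID definition.** The recorded ground truth is the
fraction of injected activity inside the parenchyma VOI of the *ideal
noise-free post-PSF* activity map — the quantity a perfect VOI
measurement on a perfect reconstruction would return.  A pre-blur
definition would make even a perfect measurement biased by the PSF
spill-out (order σ·S/V ≈ 5–15% for kidney-sized VOIs), an effect the
clinical %ID→GFR calibration absorbs empirically and which this package
deliberately does not re-derive.  The pre-blur sampled target is kept in
the cohort manifest (`target_pid_*`) for reference.

Status labels follow the clinical grouping: kidney donors are `normal`;
a ureter stone of any size or a renal stone > 10 mm makes a kidney
`symptomatic`; a small renal stone or the contralateral kidney of a
unilateral stone patient is `asymptomatic`.  Symptomatic kidneys sample
their target %ID from a lowered range (factor 0.5 by default), giving
the cohort a known between-group GFR decrement.

The generator is fully deterministic given `(seed, subject_index)`.

### Manual-VOI emulation

Clinical reference VOIs were drawn as 2D coronal ROIs on every 2nd–3rd
slice (up to 30 per kidney) and interpolated in between.
`emulate_manual_voi` reproduces this error source: it keeps the true
per-slice ROIs on the sampled slices (optionally shifted by one in-plane
voxel to emulate drawing error), reconstructs intervening slices by
linear interpolation of per-slice signed distance fields, and applies a
mild `smooth_mask` (σ = 0.5 voxel, no closing — closing would refill the
pelvis notch the ROIs deliberately exclude).  With dense sampling the
emulator degenerates to the ground truth; with sparse sampling it
inherits the characteristic failures of interpolated manual references,
including stones that lie wholly between drawn slices and therefore
survive inside the interpolated VOI.

### What the phantoms do not emulate

No projection-domain SPECT simulation (the phantom emits
already-reconstructed quantitative volumes), no scatter/attenuation
artifacts, no anatomically realistic organs or texture, no breathing or
registration error.  Tests passing on phantoms therefore demonstrate
the correctness of the pipeline's bookkeeping, geometry and learning
machinery — not clinical-grade segmentation performance.

## Segmentation network

A modified 3D U-net (see `renoquant.segnet` for the full wiring):
per-level pre-activation residual blocks of two 3×3×3 convolutions with
leaky-ReLU (slope 0.01), 2×2×2 stride-2 convolutions for downsampling
(the strided output is element-wise summed with the next block's
convolution output via the block's projection shortcut), spatial
dropout (rate 0.3) after each contraction block, and an expansion path
of leaky-ReLU → 3×3×3 convolution → 1×1×1 convolution → 2×2×2
transposed convolution with copy-and-concatenate skips.  The outputs of
the last three expansion-path 3×3×3 convolutions are projected to one
channel, upsampled and summed immediately before the sigmoid; the
projection biases start at −1 so the initial output sits near the
background prior.  Channel widths double per level from
`base_channels`.  Input CT is windowed to the soft-tissue range
(clip [−30, 100] HU, center 35, scale 30) — the standard viewing window
for this contrast regime.

The network, its convolutions and the optimizer are implemented in a
small reverse-mode autodiff engine over numpy arrays
(`renoquant.nn.autodiff`), verified against finite differences in the
test suite.  Tensors are channels-first with an implicit batch of one.

**Training.** Soft-Dice loss `1 − (2Σpt+ε)/(Σp+Σt+ε)` with ε = 1 voxel
(configurable), Adam with β₁ = 0.9, β₂ = 0.999, ε = 0 (updates with a
still-zero second moment are skipped to keep 0/0 at 0), initial learning
rate 5·10⁻⁴ halved when the mean epoch loss has not improved by a
relative 10⁻⁴ within a 10-epoch patience window.  The full-scale
schedule is 80 epochs × 272 iterations at batch size 1; the test-scale
default is 12 × 60.  Training is deterministic given the seed.

**Inference.** Probability ≥ 0.5 → keep at most the two largest
connected components → assign laterality by centroid → map back to the
uncropped grid.  An all-background prediction returns an empty mask
with a warning rather than an error (single-kidney inputs are a known
hard case).

**Scales.** Two built-in configurations: `test` (window 48×32×32 @
3.5 mm, 3 levels, 8 base channels, ~110k parameters) for CPU-scale
experiments, and `clinical` (window 192×128×96 @ 1.726 mm, 5 levels, 32
base channels) matching the clinical geometry.  The window is
anisotropic because the two kidneys span widest along the left–right
axis.  The ablation flags (`use_residual_blocks`, `use_elementwise_sum`,
`use_skip_connections`) reproduce the architecture-variant arms as
configurations; only their parameter-count ordering is asserted in
tests, since performance differences are data-scale effects.

## Quantification

For each labeled side, activity = Σ(value · voxel volume) for
concentration input, or counts / acquisition-minutes / 152.5 cpm/μCi
for counts input; %ID = 100 · activity / injected activity.  No decay
correction is applied (the acquisition starts ~2 min after injection;
with the 6.01 h half-life of 99mTc the effect is < 0.6%).  Per kidney,

    GFR (ml/min) = %ID × 9.1462 + 23.0653

applied individually to each kidney (the calibration is a per-kidney
regression; the intercept is included per kidney).  Body surface area
uses the Dubois formula `0.007184 · W^0.425 · H^0.725` (W in kg, H in
cm) and the bilateral total is `Σ GFR × 1.73 / BSA` in ml/min/1.73 m².
%ID values above 100 (possible under noise) raise a warning, not an
error.

## Evaluation harness

* Dice = 2|A∩B|/(|A|+|B|); two empty masks are defined to agree
  (Dice 1).
* MAPE: mean ± SD of 100·|test−ref|/ref over pairs.
* Agreement: R² from ordinary least squares of the test method on the
  reference (identical to squared Pearson r for simple OLS);
  Bland–Altman bias = mean difference with 1.96·SD normal limits.
* k-fold cross-validation: seed-reproducible partition balanced within
  one subject; each fold trains on the rest and reports held-out Dice
  and GFR agreement.  Both methods are quantified through the identical
  VOI→SPECT route, so a perfect segmenter scores MAPE exactly 0; a
  failing fold is recorded and skipped rather than aborting the run.
* Group report: per-status-group GFR summaries per method, with
  delegated scipy tests (Kruskal–Wallis, one-way ANOVA, Wilcoxon)
  surfaced as report fields only.

## Numerical choices and degenerate inputs

* Mask resampling threshold 0.5; binarization threshold 0.5 (sigmoid
  midpoint); at most two retained components (at most two kidneys).
* Soft-Dice ε = 1.0 voxel: stabilizes the empty-mask case and keeps the
  loss bounded.
* Adam with ε = 0 exactly as specified; the 0/0 guard only affects
  parameters whose gradient has been identically zero so far.
* Empty VOI side → %ID 0 with a warning; empty mask into `smooth_mask`
  → returned unchanged with a warning.
* Checkpoints are single-file `.npz` with a versioned schema; loading
  re-instantiates the graph and restores weights bit-exactly.

## Problem sizes

The desk-scale study used throughout the tests and the reproduction
script generates test-scale phantoms (CT 56×40×40 @ 3.5 mm, SPECT
48×36×36 @ 4 mm), trains the 3-level network on 20 subjects for
16 × 70 = 1120 iterations and evaluates on 5 held-out subjects;
property checks use cohorts of 20–60 phantoms.  These sizes were chosen
so the full study runs on a single CPU core in minutes while every
pipeline stage is exercised at full fidelity.

## Known limitations

* Phantom realism is validated by properties, not by matching clinical
  intensity distributions; no claim is made about clinical Dice or GFR
  accuracy.
* The expansion-path sum-junction wiring and per-level channel widths
  are declared design choices where the architecture description leaves
  them open.
* The %ID→GFR calibration constants are taken as given (they originate
  in a scanner-specific clinical regression) and are not re-derived.
* Registration between CT and SPECT is assumed perfect, as on a hybrid
  scanner.
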