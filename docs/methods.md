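# Methods

This note documents the models and procedures `stimpat` implements, the
choices made where the designs were genuinely open, and the limits of what
the synthetic fixtures can show.

## Image representation

All models consume `LuminanceImage`: a 2-D grid of intensities in [0, 1],
indexed (row, column) with row 0 at the top. RGB input is collapsed with
ITU-R BT.601 luma weights (0.299, 0.587, 0.114) — the most common raster
convention. Resampling is bilinear. Both filter-bank models process images
at a fixed working size of 256×256 px: a power of two keeps the FFT-based
convolution exact, and 256 divides evenly into the 10×10 jet grid
(25.6 px spacing, grid centres at round(12.8 + 25.6·k)).

## GaborJet

The descriptor samples complex Gabor responses ("jets") at a coarse grid.
Kernels are defined directly in the frequency domain with the classic
dynamic-link-architecture parameterisation: centre frequency
k_ν = (π/2)/√2^ν for ν = 0…4, orientations μ·45° for μ = 0…7, Gaussian
envelope parameter σ = 2π, and the DC response subtracted so that constant
images yield zero output (this also makes magnitudes exactly invariant to
global intensity offsets). The image spectrum is multiplied by each kernel,
inverse-transformed, and the complex response is read out at the 100 grid
points, giving 100 × 5 × 8 = 4000 magnitudes and phases. Element ordering
is position-major, then frequency (low→high), then orientation.

Comparison uses the angular distance between magnitude vectors,
arccos of the cosine similarity (in radians; for nonnegative magnitudes the
range is [0, π/2]). `1 − cos` is not used; the arccos reading is the
literal one and the cosine itself is recoverable from it. Note that arccos
is ill-conditioned near zero distance: nearly identical descriptors carry
angle noise of order √ε ≈ 1e−8, which the tests tolerate explicitly.

## HMAX

A four-layer feedforward stack with fixed (not learned) intermediate
features:

* **S1** — absolute values of valid-mode correlations with zero-mean,
  unit-norm Gabor kernels at 4 orientations (0°, 45°, 90°, 135°, named by
  the preferred stimulus orientation) and 12 sizes 7, 9, …, 29 px. Per-size
  parameters follow the standard published recipe:
  σ = 0.0036·s² + 0.35·s + 0.18, wavelength λ = σ/0.8, aspect ratio 0.3.
  Absolute values make responses nonnegative so that max pooling is
  meaningful.
* **C1** — sizes are grouped into 4 consecutive-triplet scale bands
  {7,9,11}, {13,15,17}, {19,21,23}, {25,27,29}. Per band and orientation,
  grids are centre-cropped to a common extent, the elementwise max over the
  three sizes is taken, then local spatial max pooling with neighbourhoods
  of 8, 10, 12, 14 px and stride half the neighbourhood.
* **S2** — at every 2×2 neighbourhood of C1 positions, all 4⁴ = 256 ordered
  assignments of orientations to the four cells are formed; the four
  selected C1 responses are combined by their arithmetic mean (the
  scale-preserving choice; product and Gaussian-match combinations would be
  drop-in alternatives).
* **C2** — global max over positions and the four bands per configuration:
  a 256-element vector, tolerant to translation up to roughly the C1
  pooling stride (measured relative change for a 2 px shift of a bar
  stimulus: a few percent; the test bound is 0.15).
* **VTU** — optional view-tuned units: activation exp(−‖c2 − w‖²/(2σ²))
  against each stored training C2 vector, computed on unit-normalised C2
  with σ = 1 by default (fixed, documented; activations are in (0, 1] and
  equal 1 iff the test C2 matches a prototype).

HMAX dissimilarity uses Euclidean distance on C2, mirroring the pixelwise
convention. Minimum input size for the full stack is about 96 px; below
that the coarsest band's C1 grid cannot support the 2×2 S2 neighbourhoods.

## MVPA

Both analyses operate on one dataset per participant per region of
interest: a samples × voxels matrix with condition and run labels. The
entry points require every run to contain every condition; splits of a
valid dataset may transiently violate this, so the check lives at the
analysis entry rather than in the container.

* **Normalization.** For correlations: per run, each voxel is centred over
  the run's samples (removes run-level offsets voxel by voxel). For SVM:
  per (run, condition) group, one scalar — the group mean over samples and
  voxels — is subtracted. Both are idempotent.
* **Split-half correlations.** Per iteration, samples are randomly split in
  half, stratified by condition (odd counts send the extra sample to a
  uniformly random half); condition averages of half A are correlated with
  those of half B for all ordered pairs; the matrix is symmetrised by
  averaging (i,j) with (j,i). Iterations (default 100) are averaged through
  Fisher's z-transform (plain averaging by flag). Correlations are clipped
  to ±(1 − 1e−15) before arctanh so that a perfect correlation survives the
  round trip as exactly 1.0 rather than producing an infinity. The output
  includes the diagonal pairs — the split-half reliability of each
  condition.
* **Pairwise nu-SVM decoding.** Per unordered condition pair and iteration
  (default 100), a 75/25 train/test split stratified by condition, a fresh
  linear nu-SVM (ν = 0.5 by default) fit on the training samples, the test
  samples averaged into one pattern per condition, and both averages
  classified — iteration accuracy is 0, 0.5 or 1; the table reports the
  per-pair mean. Diagonal pairs are excluded (self-decoding is undefined).
* **Splitting unit.** Splits are sample-level by default; `split_unit="run"`
  assigns whole runs instead.

### Run-correlated noise and sample-level splits

Two leakage effects of sample-level splitting on data with run structure
are worth knowing (both were measured on the simulator):

1. With run-level noise, a condition's train and test sets have
   complementary run compositions, so run offsets learned by the classifier
   *anti*-predict the held-out averages — label-shuffled accuracy drops
   systematically below 0.5 (≈0.44 at the simulator's default noise
   levels).
2. With condition signal present, a within-run label shuffle leaves a
   run-consistent label-to-template mapping that sample-level splits can
   partially exploit — accuracy rises above 0.5 (≈0.55).

Consequently the chance-calibration tests use exchangeable data (no
condition signal, no run noise), where sample-level splits are guaranteed
to sit at chance, and each Monte-Carlo replication draws a fresh dataset so
replication means are independent and their empirical standard error is
valid. Run-level splits remove both leak paths and stay at chance even
with full signal and strong run noise, which a dedicated test demonstrates.

### Pattern simulator

`simulate_patterns` draws one template per condition
(Normal(0, signal_sd) per voxel), adds a per-run offset
(Normal(0, run_noise_sd) per voxel, shared by all samples of the run) and
independent per-sample noise (Normal(0, sample_noise_sd)). Defaults — 4
conditions, 4 runs, 2 samples per condition per run, 50 voxels,
signal 1.0, run noise 0.5, sample noise 1.0 — give a moderate-SNR regime
typical of a single-subject ROI: decodable but not at ceiling. The
simulator emulates the covariance structure the analyses assume
(condition × run × sample over voxels) but none of the spatial smoothness,
temporal autocorrelation or hemodynamic confounds of real BOLD data, so
passing tests certify the analysis machinery, not performance on real
scans. A NIfTI-volume adapter was deliberately left out of the core; the
CSV dataset format (matrix + sidecar labels) keeps everything
self-contained.

## Aggregation statistics

`aggregate` groups a long-format table by up to three plotting factors plus
one error-bar unit (typically the participant) and reduces the value column
(mean by default, any pandas reducer name or callable). Cells with no
matching records stay missing — they are never zero-filled, which would
silently bias means. `error_bars` computes mean and SEM (sample sd, n−1
denominator, over non-missing units; SEM is reported absent for a single
unit). `significance_stars` runs a one-sample t-test against a reference
or a two-sample test; the two-sample test is paired when both inputs are
Series with identical indexes (matching error-bar units, the typical
repeated-measures case) and an independent pooled-variance test otherwise,
overridable with `paired=`. Star levels: `*` for p < 0.05, `**` for
p < 0.01; a third level (`***`, p < 0.001) exists but is off by default.

## Problem sizes in tests

The test suite and the acceptance script run at desk scale: 256×256 model
inputs, pattern datasets of 16–48 samples × 30–60 voxels, 10–100 split
iterations, and 1000 total decoding iterations (20 replications × 50
iterations) for the chance calibration. These sizes were chosen so that
every statistical check retains adequate power while the whole suite runs
in well under a minute on one CPU.

## Known limitations

* The GaborJet kernel family and grid placement follow one published
  parameterisation; the model family has several variants and the constants
  live in `stimpat.models` for inspection.
* HMAX here is the classic fixed-feature variant; modern descendants learn
  the S2 dictionary and are substantially more powerful.
* Group-level fMRI statistics, preprocessing and searchlight analyses are
  out of scope; analyses are strictly per participant per ROI.
* Sample-level splits leak run structure as described above; prefer
  `split_unit="run"` when run noise is substantial.
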