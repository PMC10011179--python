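# Methods

## Problem and pipeline

Tomato plants under progressive water deficit are graded into three
classes by soil relative humidity: well-watered (60–80 %),
reduced-watered (40–60 %) and deficient-watered (20–40 %). The
observable is a 272-band reflectance cube (400–1000 nm) of a single
leaf, acquired by a push-broom imager, with one young and one mature
leaf sampled per plant and replicate. The pipeline estimates the class
from (i) the leaf's mean reflectance spectrum restricted to selected
effective wavelengths (EWs), (ii) convolutional image features of a
small set of weakly correlated band images (the reflectance-image set,
RIS), and (iii) the fusion of the young and mature leaf vectors of the
same plant.

## Synthetic leaf model

The generator emulates the spectral phenomenology that drives the
classification, not leaf optics from first principles. A noiseless
spectrum is a sum of smooth terms:

* a flat visible baseline (default 0.06 reflectance),
* a Gaussian green peak at 560 nm (width 28 nm) whose amplitude is
  `green_peak_amp + level * green_peak_gain_per_level` — reflectance at
  560 nm therefore increases strictly with stress level,
* a logistic red edge centred at `730 − level * 8` nm (width 12 nm)
  rising to a flat NIR plateau (default 0.55) — the red-edge inflection
  blue-shifts linearly with stress,
* for mature leaves, a damped green peak (×0.7) plus a fixed smooth
  sinusoidal perturbation (amplitude `stage_offset`, default 0.02), so
  the two stages carry genuinely different spectral signatures.

Cubes paint this spectrum into an elliptical leaf (default 40×24 px in
a 64×64 frame; tests use smaller frames) over a dark background
(< 0.05 NIR reflectance), with i.i.d. Gaussian pixel noise
(`pixel_noise_sd`, default 0.01) and, when `blue_light=False`,
additional band-uncorrelated noise (`blue_noise_sd`, default 0.05)
restricted to bands below 500 nm. This reproduces, qualitatively, the
poor blue-region signal-to-noise ratio of halogen-only illumination;
the Savitzky–Golay deviation RMS over 400–500 nm is the metric that
detects it. Per-pair biological variation is a shared multiplicative
gain (sd 0.03) applied to both stages of a pair.

What the generator does *not* emulate: leaf venation, specular
highlights, spatial noise correlation, petioles, instrument keystone,
or any temporal dynamics of drought progression. Passing tests
demonstrate that the algorithms behave as specified on data with the
assumed statistical structure — not that the assumed structure matches
any particular instrument or cultivar.

Two auxiliary feature-matrix generators support method studies:
`make_band_signal_dataset` (class signal confined to a few known bands
among pure-noise bands, for band-selection recovery) and
`make_disjoint_stage_dataset` (young separates class 0, mature
separates class 2, so neither stage alone suffices but their fusion
does — the cleanest possible test of the fusion principle).

## Calibration and extraction

Reflectance is `(I_r − I_d)/(I_w − I_d)` with per-column white/dark
reference spectra broadcast along the scan axis (3-D reference scans
are averaged over lines first — the usual push-broom convention).
Values outside [0, 1.2] are clipped and counted in a QC field; the
ceiling tolerates mild specular excursions above the white board.
Clipped reflectance is stored as float32; unclipped diagnostic output
stays float64.

Segmentation thresholds the band nearest 800 nm at 0.35 reflectance —
NIR maximises leaf/background contrast — and keeps the largest
connected component; masks covering > 90 % of the frame trigger a
warning (threshold almost certainly too low), and masks under 50 px are
rejected. The leaf spectrum is the per-band arithmetic mean over the
mask. The Savitzky–Golay defaults are window 11, order 2.

## Effective-wavelength selection

A chromosome is a binary band mask (initial inclusion density 0.3;
empty chromosomes are repaired by switching on one random bit). Fitness
is mean stratified k-fold CV accuracy (default 5-fold) of an RBF SVM
(C = 1, gamma = `scale`) with per-band standardisation fitted on
training folds only; fold assignments are fixed per protocol so fitness
values are comparable and memoisable across restarts. Operators:
tournament selection of size 2, uniform crossover applied with
probability 0.5, and individual-level mutation — with probability 0.1 a
child flips each bit with probability 1/n_bands. (A per-bit flip rate
of 0.1 was evaluated and rejected: ~10 flips per child on a 100-band
problem randomises the population faster than selection can exploit it,
roughly doubling runtime while recovering fewer informative bands.)
One elite survives unchanged, which makes the best-fitness trace
non-decreasing by construction.

The full protocol reruns the GA from scratch: the first run sets the
reference fitness; every strictly better rerun replaces it and resets
the stall counter; after `stall_limit` consecutive non-improving runs
the best subset is returned. The reference-scale stall limit is 1000;
desk-scale studies use 5–20. Strict `>` comparison is used, so
plateaus terminate rather than cycle.

## Reflectance-image set

ReliefF (k = 10 neighbours, all samples as anchors, min-max scaled
features, Manhattan neighbourhoods, class-prior-weighted misses) ranks
the EWs on the calibration spectra; the top EW's band image is the
reference. Pearson correlations between in-leaf pixel vectors of EW
band-image pairs form the correlation matrix — averaged over all
calibration leaves by default (a single randomly chosen leaf is
available via `single_sample`, but one leaf makes the matrix noticeably
noisier). The container scan admits EWs in ascending index order iff
|r| ≤ 0.3 against the reference *and* every image already admitted,
capped at four members; admitted members are then ranked by |r| with
the reference, ascending, ties to the smaller index. Superposition
search stacks the candidates one by one as CNN input channels, trains a
LeNet-5 per depth on the calibration split, scores EW-spectra + image
features by SVM CV accuracy, and keeps the smallest depth achieving the
maximum.

## Image features, combination, fusion

RIS stacks are ROI bounding-box crops with background zeroed, resized
bilinearly to 32×32. LeNet-5 (conv 5×5×6 → avgpool 2×2 → conv 5×5×16 →
avgpool → FC 120 → FC 84 → FC 3, ReLU activations, He initialisation,
Adam 1e-3, softmax cross-entropy) is trained as a stress classifier on
the calibration stacks only, then frozen. Image features are the FC-84
layer's *pre-activation* outputs (84-d); the 3-d output-layer
pre-activation is available by configuration. One network is trained
per leaf stage, since the stages have different RIS wavelengths.

Combination standardises the EW-spectrum block and the image block
separately (statistics from the calibration set; zero-variance
coordinates map to 0 with a QC flag) and concatenates spectral-first.
Fusion concatenates the combined young vector then the combined mature
vector of one (plant, replicate); label, plant and replicate must
match, enforced at the type level.

## Models, splitting, evaluation

* SVM: standardised RBF, C = 1, one-vs-rest decision scores.
* Random forest: 500 trees, sqrt-features per split.
* 1-D DenseNet: stem conv (kernel 3, 16 channels), one dense block of
  4 layers with growth rate 12 (layer ℓ sees 16 + (ℓ−1)·12 channels),
  global average pooling, linear head; Adam 1e-3, softmax
  cross-entropy. Batch normalisation is deliberately omitted — at
  desk-scale batch sizes it adds variance without benefit and would
  complicate bit-reproducibility.

The 7:3 calibration/prediction split is stratified by treatment and
grouped by plant (all leaves of a plant stay on one side, preventing
plant-level leakage; a flag disables grouping). Fused samples split at
the pair level, and single-stage experiments in the pipeline reuse the
same pair-level split so all strategies see identical calibration
plants. Accuracies and per-class precision/recall/F1 are reported in
percent; a class absent from the prediction set yields `None` metrics
plus a flag rather than a silent zero. ROC is one-vs-rest per class
from decision scores.

## Determinism and numerics

Every stochastic stage derives its seed from the global run seed via a
CRC-tagged affine map, so a rerun with the same config reproduces the
summary table exactly; this is asserted in the test suite. All CNN
randomness flows through explicit numpy generators. Convolution is
im2col with einsum contractions; gradients of every layer are verified
against central differences to < 1e-7 in the tests.

## Problem sizes

Desk-scale studies in the tests and the acceptance script use: 128-band
32×32 cubes for simulator properties; a 100-band, 150-sample,
5-informative-band benchmark with a reduced GA (population 40, 60
generations, stall limit 5) for selection recovery; designs of 6–8
pairs per class for end-to-end runs. These sizes were chosen so the
statistical effects under study (band recovery, the blue-light RMS gap,
the fusion gain) are comfortably detectable while a full run stays in
the minutes range on one CPU. The reference-scale defaults (design
108/105/102, population 100, 400 generations, stall 1000, RF 500
trees) remain the package defaults.

## Known limitations

* The synthetic within-class spectral variance is not calibrated to any
  real instrument; absolute accuracies on synthetic data say nothing
  about field performance.
* The GA fitness is the CV mean, and the restart protocol compares CV
  means; a held-out-test-set variant can be emulated by splitting
  before selection (the pipeline already selects on the calibration
  split only).
* LeNet-5 and DenseNet training on tiny designs underfits; deep-model
  rows in small-run summaries are reported as computed, not tuned.
* ENVI support covers the header dialect written here (BIL/BIP/BSQ,
  types 1/2/4/5/12, single wavelength block); vendor extensions are out
  of scope.
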