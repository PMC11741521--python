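# Methods

## Problem setting

High-content "cell painting" experiments stain generic organelles with a
small dye panel and image each field in several fluorescence channels; the
goal is to predict each cell's type from its morphology alone. Ground-truth
labels come *after* morphological imaging, either from cyclic
immunofluorescence (quench, restain with class-specific markers, re-image)
or from replication pre-labelling, and are assigned by intensity gating.
Classification can operate on handcrafted features (shape, intensity,
texture per region and channel) with a random forest, or directly on image
crops with a CNN. The central methodological question this package
operationalizes is *how the crop is defined*: whole-cell crops (60 µm,
outside-mask zeroed) and nuclear crops (18 µm, outside-mask zeroed) depend
on segmentation quality, which degrades in dense cultures, whereas
**nucleocentric crops** (18 µm centred on the nuclear centroid, background
preserved) only require nuclear detection and therefore stay reliable at
high confluency.

## Synthetic scenes

All experiments run on a seeded scene generator with exact ground truth.

* **Geometry.** Nuclei are noisy ellipses (eccentricity sampled uniformly
  in [0, 0.8], area-preserving parametrization, low-order harmonic boundary
  perturbation); the cytoplasm is an angularly perturbed hull extending a
  sampled radial distance beyond the nucleus. Contested pixels go to the
  nearest centre; distinct touching nuclei keep a 1-px separation so
  instances remain resolvable. Overlap policies: `none` (disjoint
  footprints), `allow` (cytoplasm may overlap, nuclei disjoint), `crowded`
  (nuclei may touch).
* **Channels.** Channel 0 is nuclear; channels 1–3 are cytoplasmic with a
  perinuclear radial falloff. Texture is band-limited multiplicative noise
  with a class-specific correlation length (grain, µm) and per-channel
  gain. Textures are drawn **per cell**, not per field: cells are
  independent biological units, and a shared field texture would give every
  field a fingerprint that classifiers memorize, contaminating null
  experiments with well-identity signal. Additive Gaussian noise
  (`noise_floor`, default 0.02) is the only field-wide stochastic component.
* **Ground-truth round.** A second image (DAPI-like channel + one channel
  per marker) is rendered from the same masks; per-nucleus marker intensity
  is Normal around the class mean (default CV 8%), and the whole round is
  displaced by a configurable stage shift such that registration reports
  exactly that shift.
* **Defaults.** Pixel size 0.325 µm/pixel; two classes differing only in
  nuclear radius (base 4 µm, ratio configurable — ratio 1.0 is the
  morphological null) with swapped marker means 1000 vs 100 a.u.; GT DAPI
  ≈ 800 a.u. The generator does **not** model PSF blur, bleed-through,
  3-D structure, replicate batch effects, uneven illumination, or true cell
  overlap, so green tests bound pipeline correctness on idealized data, not
  performance on real microscopy.

## Pre-processing and ground truth

Channels are windowed to the 1st–99th intensity quantile (numpy linear
quantile convention) and clipped to [0, 1]; z-stacks are maximum-projected
first. Cyclic rounds are registered by Fourier phase cross-correlation on
the nuclear channel, integer-pixel by default (stage displacements are
linear translations; subpixel upsampling is available but off), and
re-aligned with zero-filled borders so wrapped content never enters gating.
Marker gating: single-marker logic (exactly one marker above threshold →
that class; zero or several → undefined) or two-marker quadrant logic
(A−/B+ → neuron, A+/B− → NPC, else undefined). Thresholds are data
dependent; `propose_thresholds` suggests the midpoint of per-monoculture
medians and the value actually used is recorded in the run config. Three
discard rules: (1) no ground-truth DAPI signal (detachment; floor defaults
to the rule-3 DAPI threshold since no separate constant is standard),
(2) undefined gate, (3) mean nuclear DAPI ≤ 500 or nuclear area ≤ 160
native pixels. The rules are independent predicates, so their order is
irrelevant; each discard is logged with its rule id.

## Segmentation

StarDist (nuclei; probability 0.6, overlap 0.3) and Cellpose (cells; four
cyto2 models averaged on the composite of all channels) are recorded as
backend parameters and used when installed. The hermetic `baseline`
backend needs no model downloads: nuclei by Otsu threshold on a lightly
smoothed nuclear channel, hole filling, then a distance-transform watershed
seeded at per-component cores (pixels above 70% of the component's peak
distance, small-dilation-bridged so an eccentric nucleus contributes one
seed); cells by a nucleus-seeded watershed over the channel composite, so
each cell inherits its nucleus' label. The cytoplasm region is cell minus
nucleus after maximal-overlap matching; unmatched nuclei are excluded from
whole-cell/cytoplasm features but keep their nucleocentric crops.

## Crops

Window extent is the nearest odd pixel count to patch_size/pixel_size
(odd ⇒ the centroid maps exactly to the central pixel); windows below 3 px
are rejected, which makes the 0.6 µm end of the patch sweep degenerate by
design. Defaults: cell 60 µm, nucleus 18 µm, nucleocentric 18 µm. Cell and
nucleus modes zero everything outside their mask; nucleocentric keeps all
pixels. Border-crossing windows are zero-padded and the record carries an
edge flag. Per-channel crop normalization is a z-score within the crop
(configurable to dataset statistics); a speckled-background control
replaces zeroed background with seeded draws from the in-mask intensity
distribution at a configured density.

## Handcrafted features

Per region (nucleus, cytoplasm, cell): 14 shape features (area, convex and
filled area, axis lengths, eccentricity, equivalent diameter, extent, Feret
diameter, orientation, perimeter, Crofton perimeter, solidity, and the
centroid encoded as distance from the field centre — raw coordinates would
leak field position); per region × channel: intensity max/mean/min/std and
six GLCM statistics (contrast, dissimilarity, homogeneity, energy,
correlation, ASM). GLCM construction, recorded in the extraction metadata
because values depend on it: intensities quantized to 32 gray levels over
the region's min–max, symmetric co-occurrence at 1 px offset for 0°, 45°,
90°, 135°, pairs leaving the region excluded, properties averaged over the
four directions. Redundancy pruning removes columns whose absolute Pearson
correlation with an earlier kept column exceeds 0.95 (greedy keep-first,
deterministic). Standardization z-scores each feature per group with
statistics **fit on the training subset only** — fitting on all rows makes
the held-out wells' group-centered values anti-correlate with the training
wells through the zero-sum constraint, a transductive leak this package
explicitly avoids. Grouping by replicate is supported for data with real
between-replicate shifts; the synthetic pipeline defaults to a single
global group because the generator has no replicate effects and group-wise
estimation noise is then pure well-fingerprint signal for a forest to
overfit (measurably inverting null predictions).

## Classification

* **Split.** 60/10/30 train/validation/test at the *well* level, optionally
  stratified by culture class so monoculture designs keep both classes in
  every subset; largest-remainder allocation of well counts, seeded random
  assignment. Training asserts train/test well disjointness at fit time.
* **Balancing.** Each class downsampled without replacement to the minority
  count (training subset).
* **Random forest.** 30 trees by default (10–150 all reasonable; accuracy
  saturates near 30), mean-decrease-in-impurity importances normalized to
  1.
* **CNN.** The engine is a compact NumPy implementation (im2col + BLAS
  convolutions, BatchNorm with running statistics, residual blocks, global
  average pooling, linear head, Adam). BatchNorm matters beyond speed: it
  gives the small nets the memorization capacity of their full-scale
  counterparts, without which label-shuffled training collapses to a
  constant predictor instead of chance-level noise. The full-scale recipe
  is the default `TrainConfig`: 50 epochs, batches of 100, lr 1e-4 reduced
  ×0.1 after 10 epochs without validation improvement, ≥5000 inputs per
  class, horizontal/vertical flips and random rotation (implemented as 90°
  multiples to avoid interpolation artifacts on masked crops), best
  checkpoint by validation accuracy with earliest-epoch tie-break.
  Desk-scale experiments use the narrow variant ("resnet18_small": widths
  16/32/64, one residual block per stage) with 10–15 epochs, lr 1e-3 and
  relaxed per-class minimum; "resnet50" builds the wider/deeper member of
  the same family. Channel-subset experiments zero deselected channels at
  the loader so one architecture serves all subsets.
* **Evaluation.** Macro F = unweighted mean of per-class F1 (symmetric for
  class-equalized data). Density stratification uses the six confluency
  bins (0–20, 20–40, 40–60, 60–80, 80–95, 95–100], half-open on the left;
  confluency = percent of the field covered by the cell mask (a count-based
  score is available). Per-bin macro F averages over the classes present in
  the bin, with an `insufficient` flag below a minimum n. Model comparison
  uses the two-sided Mann-Whitney U (exact enumeration for groups ≤ 8
  without ties, normal approximation with midranks otherwise).

## Degradation

Pixel binning averages factor×factor blocks (edge blocks average what is
available; pixel size scales by the factor); composing two ×2 binnings
equals one ×4 binning exactly on divisible extents, and the global mean is
conserved. Noise injection targets an SNR under the amplitude convention
20·log10(RMS_signal/σ_noise), chosen because it makes the add/measure pair
self-consistent; the convention travels in the output metadata. The
add→measure round-trip is exact to ~0.1 dB pre-clipping; with the default
clip-at-zero, low targets on dim images read high because clipping removes
noise power. Degradation is applied to full fields before cropping,
matching the pipeline order.

## Experiment designs and desk-scale conditions

`run_experiment` drives Mono2Mono (monoculture wells, culture-level
labels), Co2Co (co-culture wells, labels gated from the simulated marker
round after registration), and Mono2Co (monoculture training, gated
co-culture testing, optional finetuning on monoculture data of the held-out
replicate with a fresh learning-rate schedule). Every run persists the
resolved config with a content hash, the split, the per-epoch training log
and the metrics. `run_sweep` varies patch size, density, bin factor or SNR
and emits one row per (value, seed), marking per-point failures instead of
aborting.

Problem sizes used by the acceptance experiments, chosen to keep every
property measurable on a single CPU: parameter recovery uses 12 wells × 3
fields × 32 cells (≈1150 cells, ≥500 per class) at 0.325 µm/px with 18 µm
nucleocentric crops (55 px) and 15 training epochs; the SNR sweep and the
mask-corruption comparison image at 0.65 µm/px (nucleocentric 27 px,
whole-cell 93 px) so that the 40 and 6 CNN trainings they require stay
cheap. The SNR grid (30, −14, −19, −24, −40 dB) spans saturation →
transition → chance for this synthetic task; it reaches much lower than
the published ranges for real data because a two-fold nuclear-size
contrast on clean synthetic scenes survives far more noise than subtle
real phenotypes. Mask corruption merges 70% of cell labels into a
neighbour in dense fields (under-segmentation); whole-cell crops inherit
the damage while nucleocentric crops, which never consult the cell mask,
isolate the density effect itself.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` generators
  derived from explicit seeds; training is bit-reproducible at fixed seed
  (single-threaded NumPy).
* The conv engine trains in float32; gradient checks run the same code in
  float64 against central differences (including the BatchNorm train-mode
  path).
* Quantile convention, GLCM parameters, SNR convention and segmentation
  backend parameters are all recorded in outputs because downstream values
  depend on them.
* Best-model ties break toward the earlier epoch; density bin edges are
  half-open (lo, hi] with 100 included in the last bin; validation
  monitoring uses accuracy.
* Known limitations: integer-pixel registration only (no rotation/affine);
  the UMAP projection is seeded and deterministic but not exactly
  permutation-equivariant (neighbour search depends on row order); the
  baseline segmenter is tuned for the generator's morphology scale and is
  not a StarDist/Cellpose replacement on real data; marker measurement
  region defaults to the nucleus (configurable per marker, e.g. whole-cell
  for cytoplasmic markers).
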