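# nucleoprofile

Nucleocentric morphological profiling: single-cell type prediction from
multi-channel "cell painting" microscopy, exercised end-to-end on synthetic
scenes with exact ground truth.

High-content imaging labels generic organelles with a handful of dyes and
asks whether a cell's type can be read from its morphology alone. True
labels arrive only *after* morphological imaging — via cyclic
immunofluorescence or replication pre-labelling — and are assigned by
intensity gating. Classification then runs either on handcrafted features
(shape + intensity + GLCM texture per region and channel) with a random
forest, or directly on image crops with a CNN. The crop definition is the
crux: whole-cell (60 µm) and nuclear (18 µm) crops zero everything outside
a segmentation mask and therefore inherit segmentation errors, which
multiply in dense cultures; a **nucleocentric** crop (18 µm centred on the
nuclear centroid, surroundings preserved) needs only nuclear detection and
stays reliable at high confluency.

The package implements the full pipeline for audiences who want to test,
extend or benchmark it without proprietary imaging data:

* `nucleoprofile.simulate` — seeded multi-channel scene generator with
  exact masks, class-dependent nuclear size/texture, adjustable confluency,
  and a translated ground-truth round with class-dependent marker levels;
* `nucleoprofile.imaging` — TIFF I/O, max projection, 1st–99th quantile
  normalization, phase-correlation registration of cyclic rounds;
* `nucleoprofile.segment` — nuclear/whole-cell instance masks behind a
  backend contract (StarDist/Cellpose settings recorded; hermetic
  watershed baseline included);
* `nucleoprofile.crops` — the three crop regimes, patch-size sweeps,
  speckled-background controls;
* `nucleoprofile.gating` — marker measurement, single- and two-marker
  gates, the three discard rules;
* `nucleoprofile.features` — per-region × channel shape/intensity/GLCM
  features, 0.95-correlation pruning, leak-free standardization;
* `nucleoprofile.classify` — well-stratified 60/10/30 splits, class
  balancing, random forest and CNN training (compact NumPy conv-net
  engine: residual blocks, BatchNorm, Adam, plateau LR schedule,
  best-on-validation), density-stratified evaluation, embeddings,
  finetuning, Mann-Whitney model comparison;
* `nucleoprofile.degrade` — pixel binning and SNR-controlled Gaussian
  noise (amplitude convention 20·log10(RMS/σ));
* `nucleoprofile.interpret` — GradCAM saliency, seeded example selection,
  UMAP projections;
* `nucleoprofile.pipeline` — Mono2Mono / Co2Co / Mono2Co designs, sweep
  drivers, mask-corruption robustness experiments, full run provenance.

## Worked example

Train the small residual CNN on 18 µm nucleocentric crops of a two-class
synthetic experiment (nuclear radius ratio 2), with monoculture wells and
a well-stratified split:

```bash
python examples/train_cnn_nucleocentric.py
```

```
trained 10 epochs; best validation accuracy 0.988 at epoch 8
test macro F-score: 0.987 over 80 cells (160 training crops)
   bin  n  macro_f
  0-20 20 1.000000
 20-40 20 1.000000
 40-60 40 0.987342
 60-80  0      NaN
 80-95  0      NaN
95-100  0      NaN
```

The macro F-score of 0.987 on held-out wells shows the network recovered
the planted class effect (a two-fold nuclear-radius difference); the
per-density-bin rows report the same score stratified by field confluency,
with NaN for bins that contain no test cells. The other scripts in
`examples/` walk through scene simulation, cyclic-round registration and
gating, the feature/forest route, degradation, and GradCAM/UMAP
interpretation, each printing the quantities it computes.

A thin CLI wraps the common steps (`nucleoprofile simulate | segment |
degrade | run | sweep`); see `nucleoprofile --help`.

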