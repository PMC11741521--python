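"""Handcrafted features + random forest on a small two-class experiment.

Extracts the full shape/intensity/texture matrix per region and channel,
prunes redundant columns (|r| > 0.95), standardizes, and trains a
30-tree forest with a well-stratified split.
"""

from nucleoprofile.classify import TrainConfig
from nucleoprofile.pipeline import ExperimentConfig, run_experiment

config = ExperimentConfig(
    model="rf",
    radius_ratio=2.0,
    n_wells=8,
    fields_per_well=2,
    cells_per_field=20,
    field_size=(384, 384),
    train=TrainConfig(epochs=1, min_per_class=1, seed=0),
)
result = run_experiment(config)
report = result["report"]
print(f"test macro F-score: {report.macro_f:.3f} over {report.n} held-out cells")
for cls, p, r in zip(report.classes, report.precision, report.recall):
    print(f"  {cls}: precision {p:.3f} recall {r:.3f}")
print("confusion matrix (rows = truth):")
print(report.confusion)
# near-perfect recovery is expected: a 2x nuclear-radius ratio gives a 4x
# area difference that the shape features encode directly
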