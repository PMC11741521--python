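"""Train the small residual CNN on nucleocentric crops (Mono2Mono design).

Monoculture wells provide culture-level labels; 18 µm crops centred on each
nuclear centroid keep their surroundings (no whole-cell mask needed); the
split is stratified per well so no well leaks between subsets.
"""

from nucleoprofile.classify import TrainConfig
from nucleoprofile.pipeline import ExperimentConfig, run_experiment

config = ExperimentConfig(
    design="mono2mono",
    crop_mode="nucleocentric",
    radius_ratio=2.0,
    n_wells=8,
    fields_per_well=2,
    cells_per_field=20,
    field_size=(384, 384),
    train=TrainConfig(epochs=10, lr0=1e-3, min_per_class=1, seed=0),
)
result = run_experiment(config)
report = result["report"]
log = result["training_log"]
print(f"trained {len(log)} epochs; best validation accuracy "
      f"{log['val_acc'].max():.3f} at epoch {result['model'].best_epoch}")
print(f"test macro F-score: {report.macro_f:.3f} over {report.n} cells "
      f"({result['n_train']} training crops)")
print(report.per_bin[["bin", "n", "macro_f"]].to_string(index=False))
# per-density-bin rows with too few test cells are reported as NaN
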