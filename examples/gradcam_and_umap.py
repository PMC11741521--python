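"""Interpretability: GradCAM saliency and a UMAP of CNN embeddings.

After training, GradCAM shows which part of a crop drives the class
decision, and the penultimate-layer embeddings are projected to 2-D.
Example crops are drawn with a recorded seed so panels are reproducible.
"""

import numpy as np

from nucleoprofile.classify import TrainConfig, embed
from nucleoprofile.crops import CropSpec
from nucleoprofile.interpret import gradcam, project_2d, select_examples
from nucleoprofile.pipeline import ExperimentConfig, assemble_crops, run_experiment, simulate_wells

config = ExperimentConfig(
    radius_ratio=2.0, n_wells=6, fields_per_well=1, cells_per_field=16,
    field_size=(320, 320),
    train=TrainConfig(epochs=8, lr0=1e-3, min_per_class=1, seed=0),
)
result = run_experiment(config)
model = result["model"]

fields = simulate_wells(config)
data = assemble_crops(fields, CropSpec())
chosen, seed_used = select_examples(list(data["roi_id"]), n=3, seed=42)
print(f"example crops {chosen} (selection seed {seed_used})")
for roi_id in chosen:
    crop = data.loc[data["roi_id"] == roi_id, "crop"].iloc[0]
    pred_class = int(model.predict(crop[None])[0])
    sal = gradcam(model, crop, target_class=pred_class, roi_id=roi_id)
    h = sal.heatmap
    inner = h[h.shape[0] // 4 : -h.shape[0] // 4, h.shape[1] // 4 : -h.shape[1] // 4]
    print(f"  {roi_id}: predicted {model.class_names[pred_class]}, saliency peak "
          f"{h.max():.2f}, central-mass fraction {inner.sum() / max(h.sum(), 1e-9):.2f}")

X = np.stack(data["crop"].to_list())
emb = embed(model, X)
coords = project_2d(emb, mode="unsupervised", seed=0)
print(f"embeddings {emb.shape} -> 2-D layout {coords.shape}")
from sklearn.metrics import silhouette_score

print(f"silhouette of true classes in the 2-D layout: "
      f"{silhouette_score(coords, data['label']):.2f}")
# a clearly positive silhouette means the embedding separates the classes
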