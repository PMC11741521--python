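"""Model interpretability: GradCAM saliency over crops and 2-D embeddings.

GradCAM weights the activation maps of a designated convolutional layer by
the spatially averaged gradient of the target-class logit, rectifies, and
max-normalizes; the resulting heatmap shows which part of a crop drives the
class decision (nucleus vs perinuclear region vs neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .nn import Conv2d, ConvNet, Residual

__all__ = ["SaliencyMap", "gradcam", "select_examples", "project_2d", "default_cam_layer"]


@dataclass
class SaliencyMap:
    """P×P heatmap in [0,1] (all-zero when the class gradient vanishes)."""

    heatmap: np.ndarray
    roi_id: str
    target_class: int
    layer: int

    def __post_init__(self) -> None:
        if self.heatmap.ndim != 2:
            raise ValueError("heatmap must be 2-D")
        if self.heatmap.size and (self.heatmap.min() < 0 or self.heatmap.max() > 1):
            raise ValueError("heatmap must lie in [0,1]")


def default_cam_layer(model: ConvNet) -> int:
    """Index of the last convolutional block in the model body."""
    for i in range(len(model.body) - 1, -1, -1):
        if isinstance(model.body[i], (Conv2d, Residual)):
            return i
    raise ValueError("model has no convolutional layer")


def gradcam(
    model: ConvNet, crop: np.ndarray, target_class: int, layer: int | None = None,
    roi_id: str = "",
) -> SaliencyMap:
    """Class-activation map for one crop (C,H,W) at `layer` (default: last
    conv block), upsampled to the crop extent."""
    if not 0 <= target_class < model.n_classes:
        raise ValueError(f"invalid class index {target_class}")
    layer = default_cam_layer(model) if layer is None else layer
    x = np.asarray(crop, dtype=np.float64)[None]
    logits = model.forward(x, record_layer=layer)
    acts = model._recorded  # (1, C, h, w)
    g = np.zeros_like(logits)
    g[0, target_class] = 1.0
    model.zero_grad()
    grads = model.backward(g, capture_layer=layer)
    weights = grads[0].mean(axis=(1, 2))  # (C,)
    cam = np.maximum((weights[:, None, None] * acts[0]).sum(axis=0), 0.0)
    P = crop.shape[-1]
    cam = resize(cam, (P, P), order=1, preserve_range=True, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    m = cam.max()
    if m > 0:
        cam = cam / m
    return SaliencyMap(cam, roi_id, target_class, layer)


def select_examples(roi_ids, n: int, seed: int) -> tuple[list, int]:
    """Seeded uniform sample of ROI ids without replacement; the seed is
    echoed so reported example panels are reproducible, not cherry-picked."""
    ids = list(roi_ids)
    if n > len(ids):
        raise ValueError(f"requested {n} examples from {len(ids)} ROIs")
    rng = np.random.default_rng(seed)
    sel = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sel], seed


def project_2d(
    matrix: np.ndarray, mode: str = "unsupervised", labels=None, seed: int = 0
) -> np.ndarray:
    """2-D UMAP layout of a feature or embedding matrix (default
    hyperparameters; supervised mode feeds the class labels as the target)."""
    X = np.asarray(matrix, dtype=np.float64)
    if X.ndim != 2 or len(X) < 10:
        raise ValueError("need a 2-D matrix with at least 10 rows")
    if mode not in ("unsupervised", "supervised"):
        raise ValueError(f"unknown mode {mode!r}")
    y = None
    if mode == "supervised":
        if labels is None:
            raise ValueError("supervised projection requires labels")
        _, y = np.unique(np.asarray(labels), return_inverse=True)
        if len(y) != len(X):
            raise ValueError("labels must match matrix rows")
    import warnings

    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2, random_state=seed, n_neighbors=min(15, len(X) - 1)
        )
        return np.asarray(reducer.fit_transform(X, y=y), dtype=np.float64)
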