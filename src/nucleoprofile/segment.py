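"""Nuclear and whole-cell instance segmentation behind a pluggable backend
contract.

The deep-learning backends used in high-content screening (StarDist for
nuclei, Cellpose for cells) are recorded in :class:`BackendParams` with their
standard settings, but run only when those packages are importable. The
``baseline`` backend — Otsu threshold followed by a distance-transform
watershed (nuclei) or a nucleus-seeded watershed over the cytoplasmic
composite (cells) — has no model downloads and is the hermetic default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .imaging import MultiChannelImage

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMask",
    "BackendParams",
    "segment_nuclei",
    "segment_cells",
    "match_nuclei_to_cells",
]


@dataclass
class LabelMask:
    """Instance mask: H×W integer grid, 0 = background; label ids are
    arbitrary positive integers (not necessarily contiguous)."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMask expects a 2-D grid")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def shape(self):
        return self.labels.shape


@dataclass(frozen=True)
class BackendParams:
    """Segmentation backend selection and its recorded hyperparameters.

    probability/overlap are the StarDist settings (0.6 / 0.3);
    n_models_averaged and model_name record the Cellpose recipe (four cyto2
    models averaged). diameter_hint (µm) optionally guides cell detection.
    """

    backend: str = "baseline"
    probability: float = 0.6
    overlap: float = 0.3
    n_models_averaged: int = 4
    model_name: str = "cyto2"
    diameter_hint: float | None = None
    min_area_px: int = 40

    def __post_init__(self) -> None:
        if not (0 < self.probability < 1 and 0 < self.overlap < 1):
            raise ValueError("probability and overlap must lie in (0,1)")
        if self.backend not in ("baseline", "stardist", "cellpose"):
            raise ValueError(f"unknown backend {self.backend!r}")


def _require_backend(name: str):
    try:
        return __import__(name)
    except ImportError as exc:  # pragma: no cover - exercised only without the package
        raise ImportError(
            f"segmentation backend {name!r} requested but the package is not "
            "installed; use backend='baseline' or install it"
        ) from exc


def _nuclear_plane(img: MultiChannelImage, channel) -> np.ndarray:
    plane = img.channel(channel)
    if plane.ndim != 2:
        raise ValueError("segment on a projected (single-plane) image")
    return plane.astype(np.float64)


def segment_nuclei(
    img: MultiChannelImage,
    params: BackendParams = BackendParams(),
    channel: int | str = 0,
) -> LabelMask:
    """Instance-segment nuclei from the nuclear channel.

    The baseline backend thresholds (Otsu), splits touching nuclei with a
    smoothed distance-transform watershed, and drops specks below
    ``min_area_px``.
    """
    if params.backend == "stardist":
        _require_backend("stardist")
    if params.backend == "cellpose":
        raise ValueError("cellpose backend targets whole cells; use stardist or baseline")
    plane = _nuclear_plane(img, channel)
    if np.ptp(plane) == 0:
        return LabelMask(np.zeros(plane.shape, dtype=np.int32), _prov("nuclei", params))
    plane_s = gaussian(plane, sigma=1.0)
    thr = threshold_otsu(plane_s)
    fg = ndi.binary_fill_holes(plane_s > thr)
    fg = _drop_small(ndi.label(fg)[0], params.min_area_px) > 0
    if not fg.any():
        return LabelMask(np.zeros(plane.shape, dtype=np.int32), _prov("nuclei", params))
    dist = ndi.distance_transform_edt(fg)
    # seed at the distance-map core of each object: pixels above 70% of the
    # component's peak distance form one marker per (touching) nucleus
    comp, n_comp = ndi.label(fg)
    peak = np.zeros(n_comp + 1)
    peak[1:] = ndi.maximum(dist, comp, index=np.arange(1, n_comp + 1))
    seed_mask = fg & (dist >= 0.7 * peak[comp])
    # bridge fragmented cores of one (eccentric) nucleus without joining the
    # well-separated cores of touching neighbours
    seed_mask = ndi.binary_dilation(seed_mask, iterations=5) & fg
    seeds, _ = ndi.label(seed_mask)
    labels = watershed(-gaussian(dist, sigma=1.0), seeds, mask=fg)
    labels = _drop_small(labels, params.min_area_px)
    return LabelMask(labels.astype(np.int32), _prov("nuclei", params))


def segment_cells(
    img: MultiChannelImage,
    params: BackendParams = BackendParams(),
    nuclei: LabelMask | None = None,
) -> LabelMask:
    """Instance-segment whole cells on the composite of all channels.

    Baseline: threshold the composite, then grow a watershed from nuclear
    seeds (computed on the fly when not supplied) so each cell inherits its
    nucleus' label id.
    """
    if params.backend == "cellpose":
        _require_backend("cellpose")
    if params.backend == "stardist":
        raise ValueError("stardist backend targets nuclei; use cellpose or baseline")
    if img.pixels.ndim != 3:
        raise ValueError("segment on a projected (single-plane) image")
    composite = img.pixels.astype(np.float64).sum(axis=-1)
    if np.ptp(composite) == 0:
        return LabelMask(np.zeros(composite.shape, dtype=np.int32), _prov("cells", params))
    if nuclei is None:
        nuclei = segment_nuclei(img, params)
    thr = threshold_otsu(composite)
    fg = composite > thr * 0.5
    fg |= nuclei.labels > 0
    labels = watershed(-gaussian(composite, 1.0), nuclei.labels, mask=fg)
    return LabelMask(labels.astype(np.int32), _prov("cells", params))


def match_nuclei_to_cells(nuclei: LabelMask, cells: LabelMask) -> dict[int, int | None]:
    """Map each nuclear label to the cell label with maximal pixel overlap.

    Nuclei overlapping only background map to ``None`` (flagged unmatched).
    """
    if nuclei.shape != cells.shape:
        raise ValueError("masks must share a shape")
    n, c = nuclei.labels.ravel(), cells.labels.ravel()
    sel = n > 0
    pairs, counts = np.unique(np.stack([n[sel], c[sel]]), axis=1, return_counts=True)
    mapping: dict[int, int | None] = {int(i): None for i in nuclei.ids}
    best: dict[int, int] = {}
    for (ni, ci), cnt in zip(pairs.T, counts):
        ni = int(ni)
        if cnt > best.get(ni, 0) and ci > 0:
            best[ni] = int(cnt)
            mapping[ni] = int(ci)
    return mapping


def _drop_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    areas = np.bincount(labels.ravel())
    kill = np.nonzero(areas < min_area)[0]
    out = labels.copy()
    if len(kill):
        out[np.isin(out, kill[kill > 0])] = 0
    return out


def _prov(target: str, params: BackendParams) -> dict:
    return {
        "target": target,
        "backend": params.backend,
        "probability": params.probability,
        "overlap": params.overlap,
        "n_models_averaged": params.n_models_averaged,
        "model_name": params.model_name,
        "diameter_hint": params.diameter_hint,
    }
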