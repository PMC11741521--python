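"""Per-cell records and model-ready crops under three regional regimes.

``cell``          60 µm window, pixels outside the cell mask zeroed.
``nucleus``       18 µm window, pixels outside the nuclear mask zeroed.
``nucleocentric`` 18 µm window centred on the nuclear centroid with the
                  surroundings preserved — classification then no longer
                  depends on whole-cell segmentation quality, which is the
                  point of the nucleocentric regime in dense cultures.

Windows use an odd pixel extent so the nuclear centroid maps exactly onto
the central pixel; border-crossing windows are zero-padded and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .imaging import MultiChannelImage
from .segment import LabelMask, match_nuclei_to_cells

logger = logging.getLogger(__name__)

__all__ = [
    "RoiRecord",
    "CropSpec",
    "CropTensor",
    "extract_rois",
    "patch_pixels",
    "crop_roi",
    "crop_all",
    "speckle_background",
    "patch_size_sweep",
]

PATCH_RANGE_UM = (0.6, 150.0)


@dataclass
class RoiRecord:
    """Identity and geometry of one detected cell."""

    roi_id: str
    label: int
    field: int | str
    well: str
    replicate: str
    nuclear_centroid: tuple[float, float]  # (row, col) px
    nuclear_area: int  # px
    mean_nuclear_dapi: float
    cell_label: int | None = None
    edge_contact: bool = False

    def __post_init__(self) -> None:
        if self.nuclear_area <= 0:
            raise ValueError("nuclear_area must be positive")


@dataclass(frozen=True)
class CropSpec:
    """Crop regime: mode, window size in µm and background policy."""

    mode: str = "nucleocentric"
    patch_size: float | None = None  # µm; default per mode
    background: str | None = None

    DEFAULT_SIZE = {"cell": 60.0, "nucleus": 18.0, "nucleocentric": 18.0}

    def __post_init__(self) -> None:
        if self.mode not in ("cell", "nucleus", "nucleocentric"):
            raise ValueError(f"unknown crop mode {self.mode!r}")
        if self.patch_size is None:
            object.__setattr__(self, "patch_size", self.DEFAULT_SIZE[self.mode])
        if not (PATCH_RANGE_UM[0] <= self.patch_size <= PATCH_RANGE_UM[1]):
            raise ValueError(f"patch_size {self.patch_size} µm outside {PATCH_RANGE_UM}")
        if self.background is None:
            bg = "preserved" if self.mode == "nucleocentric" else "zeroed"
            object.__setattr__(self, "background", bg)
        if self.mode == "nucleocentric" and self.background != "preserved":
            raise ValueError("nucleocentric crops keep their background")
        if self.mode in ("cell", "nucleus") and self.background not in ("zeroed", "speckled"):
            raise ValueError(f"mode {self.mode} requires zeroed (or speckled) background")


@dataclass
class CropTensor:
    """C×P×P crop, optionally per-channel normalized."""

    values: np.ndarray
    roi_id: str
    spec: CropSpec
    mask: np.ndarray | None = None  # P×P indicator of the in-regime region

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("crop must be C×P×P")
        if not np.isfinite(self.values).all():
            raise ValueError("crop contains non-finite values")


def patch_pixels(patch_size_um: float, pixel_size_um: float) -> int:
    """Window extent in pixels: nearest odd integer to patch/pixel size.

    Odd extents give exact centering. Raises when the window degenerates
    (P < 3), which happens at the 0.6 µm end of the patch sweep.
    """
    if patch_size_um <= 0 or pixel_size_um <= 0:
        raise ValueError("sizes must be positive")
    p = patch_size_um / pixel_size_um
    P = int(2 * round((p - 1) / 2) + 1)  # nearest odd
    if P < 3:
        raise ValueError(f"patch of {patch_size_um} µm at {pixel_size_um} µm/px gives P={P} < 3")
    return P


def extract_rois(
    nuclei: LabelMask,
    cells: LabelMask | None,
    img: MultiChannelImage,
    dapi_channel: int | str = 0,
) -> list[RoiRecord]:
    """One record per nuclear label: centroid, area, mean DAPI, matched cell."""
    if nuclei.shape != img.pixels.shape[:2]:
        raise ValueError("mask and image shapes differ")
    if cells is not None and cells.shape != nuclei.shape:
        raise ValueError("mask shapes differ")
    from scipy import ndimage as ndi

    ids = nuclei.ids
    if len(ids) == 0:
        return []
    mapping = match_nuclei_to_cells(nuclei, cells) if cells is not None else {}
    dapi = img.channel(dapi_channel).astype(np.float64)
    coms = ndi.center_of_mass(np.ones(nuclei.shape), nuclei.labels, index=ids)
    means = ndi.mean(dapi, nuclei.labels, index=ids)
    areas = np.bincount(nuclei.labels.ravel())
    md = img.metadata
    H, W = nuclei.shape
    out = []
    slices = ndi.find_objects(nuclei.labels)
    for lab, com, mean in zip(ids, coms, means):
        sl = slices[lab - 1] if lab - 1 < len(slices) and slices[lab - 1] else None
        edge = bool(
            sl
            and (sl[0].start == 0 or sl[1].start == 0 or sl[0].stop == H or sl[1].stop == W)
        )
        out.append(
            RoiRecord(
                roi_id=f"{md.get('well', 'w')}_{md.get('field', 0)}_{int(lab)}",
                label=int(lab),
                field=md.get("field", 0),
                well=md.get("well", "w"),
                replicate=md.get("replicate", "r"),
                nuclear_centroid=(float(com[0]), float(com[1])),
                nuclear_area=int(areas[lab]),
                mean_nuclear_dapi=float(mean),
                cell_label=mapping.get(int(lab)),
                edge_contact=edge,
            )
        )
    return out


def _window(
    arr: np.ndarray, center: tuple[float, float], P: int
) -> np.ndarray:
    """P×P window centred on the rounded centroid, zero-padded at borders."""
    cy, cx = int(round(center[0])), int(round(center[1]))
    h = (P - 1) // 2
    H, W = arr.shape[:2]
    out = np.zeros((P, P) + arr.shape[2:], dtype=arr.dtype)
    y0, y1 = cy - h, cy + h + 1
    x0, x1 = cx - h, cx + h + 1
    sy0, sy1 = max(y0, 0), min(y1, H)
    sx0, sx1 = max(x0, 0), min(x1, W)
    out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = arr[sy0:sy1, sx0:sx1]
    return out


def crop_roi(
    img: MultiChannelImage,
    roi: RoiRecord,
    nuclei: LabelMask,
    cells: LabelMask | None,
    spec: CropSpec,
    normalize: str = "crop",
) -> CropTensor | None:
    """Cut one crop for `roi` under `spec`; returns None (with a logged
    reason) for a cell-mode crop whose ROI has no matched cell label.

    normalize: "crop" z-scores each channel within the crop (constant
    channels become 0); "none" keeps raw intensities.
    """
    P = patch_pixels(spec.patch_size, img.pixel_size)
    if spec.mode == "cell":
        if roi.cell_label is None:
            logger.info("roi %s skipped: no matched cell label for cell-mode crop", roi.roi_id)
            return None
        if cells is None:
            raise ValueError("cell-mode crops need a cell mask")
        region = cells.labels == roi.cell_label
    elif spec.mode == "nucleus":
        region = nuclei.labels == roi.label
    else:
        region = None

    win = _window(img.pixels, roi.nuclear_centroid, P)  # P×P×C
    mwin = _window(region.astype(np.uint8), roi.nuclear_centroid, P) if region is not None else None
    if mwin is not None:
        win = win * mwin[..., None]
    vals = np.moveaxis(win.astype(np.float32), -1, 0)  # C×P×P
    if normalize == "crop":
        vals = _zscore_channels(vals)
    return CropTensor(vals, roi.roi_id, spec, mask=mwin)


def _zscore_channels(vals: np.ndarray) -> np.ndarray:
    mu = vals.mean(axis=(1, 2), keepdims=True)
    sd = vals.std(axis=(1, 2), keepdims=True)
    out = np.where(sd > 0, (vals - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out.astype(np.float32)


def crop_all(img, rois, nuclei, cells, spec, normalize="crop") -> tuple[list[CropTensor], list]:
    """Crop every ROI; returns (crops, skipped_roi_ids)."""
    crops, skipped = [], []
    for roi in rois:
        c = crop_roi(img, roi, nuclei, cells, spec, normalize=normalize)
        (crops if c is not None else skipped).append(c if c is not None else roi.roi_id)
    return crops, skipped


def speckle_background(
    crop: CropTensor, seed: int, density: float = 0.5
) -> CropTensor:
    """Replace zeroed background with seeded speckle drawn from the in-mask
    intensity distribution; in-mask pixels are untouched.

    Used as the control showing that masked-crop classifiers exploit cell
    shape rather than background statistics.
    """
    if crop.mask is None:
        raise ValueError("speckling requires a masked (zeroed-background) crop")
    rng = np.random.default_rng(seed)
    vals = crop.values.copy()
    bg = crop.mask == 0
    n_bg = int(bg.sum())
    if n_bg == 0:
        return CropTensor(vals, crop.roi_id, crop.spec, crop.mask)
    lit = rng.random(n_bg) < density
    for c in range(vals.shape[0]):
        inside = vals[c][crop.mask > 0]
        if inside.size == 0:
            continue
        draw = rng.choice(inside, size=n_bg, replace=True)
        plane = vals[c]
        bg_vals = np.zeros(n_bg, dtype=plane.dtype)
        bg_vals[lit] = draw[lit]
        plane[bg] = bg_vals
    return CropTensor(vals, crop.roi_id, crop.spec, crop.mask)


def patch_size_sweep(
    img: MultiChannelImage,
    rois: list[RoiRecord],
    nuclei: LabelMask,
    cells: LabelMask | None,
    sizes: list[float],
    mode: str = "nucleocentric",
    normalize: str = "crop",
) -> dict[float, list[CropTensor]]:
    """One crop set per patch size (µm), same ROI ordering for every size.

    Sizes whose window degenerates below 3 px at this pixel size are skipped
    with a log message (the 0.6 µm end of the sweep is degenerate by design).
    """
    out: dict[float, list[CropTensor]] = {}
    for s in sizes:
        if not (PATCH_RANGE_UM[0] <= s <= PATCH_RANGE_UM[1]):
            raise ValueError(f"sweep size {s} outside {PATCH_RANGE_UM}")
        try:
            patch_pixels(s, img.pixel_size)
        except ValueError as exc:
            logger.warning("patch size %s µm skipped: %s", s, exc)
            continue
        spec = CropSpec(mode=mode, patch_size=s)
        crops, _ = crop_all(img, rois, nuclei, cells, spec, normalize=normalize)
        out[s] = crops
    return out
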