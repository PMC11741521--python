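"""Handcrafted per-ROI features: shape, intensity and GLCM texture per
region (nucleus, cytoplasm, cell) and channel, with redundancy pruning and
replicate-grouped standardization for shallow learning.

Shape features are geometric and computed once per region; intensity
(max/mean/min/std) and texture statistics are computed per region × channel.
GLCM construction: region intensities quantized to 32 gray levels over the
region's min–max, symmetric co-occurrence at offset 1 px for 0°, 45°, 90°
and 135°, properties averaged over the four directions. Pixel pairs leaving
the region are excluded. These choices are recorded in the extraction
metadata because the texture values depend on them.

The raw centroid would leak field position into the classifier, so the
matrix carries distance-from-field-centre instead (raw centroids remain
available on the RoiRecord).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import graycomatrix
from skimage.measure import regionprops

from .imaging import MultiChannelImage
from .segment import LabelMask

__all__ = [
    "GLCM_PROPS",
    "SHAPE_FEATURES",
    "INTENSITY_FEATURES",
    "compute_features",
    "glcm_features",
    "drop_redundant",
    "standardize",
    "extraction_metadata",
]

GLCM_PROPS = ["contrast", "dissimilarity", "homogeneity", "energy", "correlation", "ASM"]
SHAPE_FEATURES = [
    "area",
    "area_convex",
    "area_filled",
    "axis_major_length",
    "axis_minor_length",
    "centroid_dist",
    "eccentricity",
    "equivalent_diameter_area",
    "extent",
    "feret_diameter_max",
    "orientation",
    "perimeter",
    "perimeter_crofton",
    "solidity",
]
INTENSITY_FEATURES = ["intensity_max", "intensity_mean", "intensity_min", "intensity_std"]

GLCM_LEVELS = 32
GLCM_DISTANCES = (1,)
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def extraction_metadata() -> dict:
    return {
        "glcm_levels": GLCM_LEVELS,
        "glcm_distances": list(GLCM_DISTANCES),
        "glcm_angles_deg": [0, 45, 90, 135],
        "glcm_symmetric": True,
        "glcm_averaged_over_angles": True,
        "centroid_encoding": "distance from field centre (px)",
    }


def _quantize(patch: np.ndarray, mask: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Quantize in-mask intensities to 1..levels (0 = outside region)."""
    vals = patch[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        q = np.ones(patch.shape, dtype=np.uint8)
    else:
        q = np.clip(((patch - lo) / (hi - lo) * levels).astype(np.int64), 0, levels - 1) + 1
    q = q.astype(np.uint8)
    q[~mask] = 0
    return q


def _glcm_props_from_matrix(P: np.ndarray) -> dict[str, float]:
    """Texture properties of a normalized co-occurrence matrix (levels×levels)."""
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    out = {}
    out["contrast"] = float((P * (i - j) ** 2).sum())
    out["dissimilarity"] = float((P * np.abs(i - j)).sum())
    out["homogeneity"] = float((P / (1.0 + (i - j) ** 2)).sum())
    asm = float((P**2).sum())
    out["ASM"] = asm
    out["energy"] = float(np.sqrt(asm))
    mu_i = float((P * i).sum())
    mu_j = float((P * j).sum())
    var_i = float((P * (i - mu_i) ** 2).sum())
    var_j = float((P * (j - mu_j) ** 2).sum())
    if var_i * var_j > 0:
        out["correlation"] = float((P * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    else:
        out["correlation"] = 1.0
    return out


def glcm_features(patch: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Angle-averaged GLCM statistics over the masked region of `patch`.

    Builds the co-occurrence matrix with the quantized background held at
    level 0 and then discards all pairs touching level 0, so only pairs with
    both pixels inside the region contribute.
    """
    if mask.sum() < 2:
        return {p: np.nan for p in GLCM_PROPS}
    q = _quantize(patch, mask)
    glcm = graycomatrix(
        q,
        distances=list(GLCM_DISTANCES),
        angles=list(GLCM_ANGLES),
        levels=GLCM_LEVELS + 1,
        symmetric=True,
        normed=False,
    )
    acc = {p: 0.0 for p in GLCM_PROPS}
    n_used = 0
    for ai in range(glcm.shape[3]):
        M = glcm[1:, 1:, 0, ai].astype(np.float64)
        tot = M.sum()
        if tot == 0:
            continue
        props = _glcm_props_from_matrix(M / tot)
        for p in GLCM_PROPS:
            acc[p] += props[p]
        n_used += 1
    if n_used == 0:
        return {p: np.nan for p in GLCM_PROPS}
    return {p: acc[p] / n_used for p in GLCM_PROPS}


def _shape_features(region_mask: np.ndarray, field_center: tuple[float, float]) -> dict:
    props = regionprops(region_mask.astype(np.uint8))
    if not props:
        return {f: np.nan for f in SHAPE_FEATURES}
    p = props[0]
    cy, cx = p.centroid
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # feret on 1-px regions
        return {
            "area": float(p.area),
            "area_convex": float(p.area_convex),
            "area_filled": float(p.area_filled),
            "axis_major_length": float(p.axis_major_length),
            "axis_minor_length": float(p.axis_minor_length),
            "centroid_dist": float(np.hypot(cy - field_center[0], cx - field_center[1])),
            "eccentricity": float(p.eccentricity),
            "equivalent_diameter_area": float(p.equivalent_diameter_area),
            "extent": float(p.extent),
            "feret_diameter_max": float(p.feret_diameter_max),
            "orientation": float(p.orientation),
            "perimeter": float(p.perimeter),
            "perimeter_crofton": float(p.perimeter_crofton),
            "solidity": float(p.solidity),
        }


def compute_features(
    img: MultiChannelImage,
    nuclei: LabelMask,
    cells: LabelMask | None = None,
    mapping: dict[int, int | None] | None = None,
) -> pd.DataFrame:
    """Full feature matrix: one row per nuclear label.

    Columns are named ``{region}_{feature}`` for shape and
    ``{region}_ch{c}_{feature}`` for intensity/texture. Rows whose cytoplasm
    region is undefined (unmatched nucleus) carry NaNs in cell/cytoplasm
    columns and are flagged in the boolean ``incomplete`` column.
    """
    from .segment import match_nuclei_to_cells

    if nuclei.shape != img.pixels.shape[:2]:
        raise ValueError("mask and image shapes differ")
    if cells is not None and mapping is None:
        mapping = match_nuclei_to_cells(nuclei, cells)
    H, W = nuclei.shape
    center = ((H - 1) / 2, (W - 1) / 2)
    n_ch = img.n_channels
    slices = ndi.find_objects(nuclei.labels)
    cell_slices = ndi.find_objects(cells.labels) if cells is not None else None
    rows = []
    for lab in nuclei.ids:
        lab = int(lab)
        row: dict = {"label": lab}
        regions: dict[str, np.ndarray | None] = {}
        sl = slices[lab - 1]
        pad = 2
        sl = (slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, H)),
              slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, W)))
        nuc_local = nuclei.labels[sl] == lab
        regions["nucleus"] = (sl, nuc_local)
        cell_lab = mapping.get(lab) if mapping else None
        if cells is not None and cell_lab is not None:
            csl = cell_slices[cell_lab - 1]
            csl = (slice(max(csl[0].start - pad, 0), min(csl[0].stop + pad, H)),
                   slice(max(csl[1].start - pad, 0), min(csl[1].stop + pad, W)))
            cell_local = cells.labels[csl] == cell_lab
            cyto_local = cell_local & (nuclei.labels[csl] != lab)
            regions["cell"] = (csl, cell_local)
            regions["cytoplasm"] = (csl, cyto_local if cyto_local.any() else None)
        else:
            regions["cell"] = (None, None)
            regions["cytoplasm"] = (None, None)
        incomplete = False
        for rname, (rsl, rmask) in regions.items():
            if rmask is None or not rmask.any():
                for f in SHAPE_FEATURES:
                    row[f"{rname}_{f}"] = np.nan
                for c in range(n_ch):
                    for f in INTENSITY_FEATURES + GLCM_PROPS:
                        row[f"{rname}_ch{c}_{f}"] = np.nan
                incomplete = True
                continue
            off = (rsl[0].start, rsl[1].start)
            local_center = (center[0] - off[0], center[1] - off[1])
            for f, v in _shape_features(rmask, local_center).items():
                row[f"{rname}_{f}"] = v
            for c in range(n_ch):
                patch = img.pixels[rsl[0], rsl[1], c].astype(np.float64)
                vals = patch[rmask]
                row[f"{rname}_ch{c}_intensity_max"] = float(vals.max())
                row[f"{rname}_ch{c}_intensity_mean"] = float(vals.mean())
                row[f"{rname}_ch{c}_intensity_min"] = float(vals.min())
                row[f"{rname}_ch{c}_intensity_std"] = float(vals.std())
                for f, v in glcm_features(patch, rmask).items():
                    row[f"{rname}_ch{c}_{f}"] = v
        row["incomplete"] = incomplete
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("label")
    return df


def drop_redundant(
    features: pd.DataFrame, r_max: float = 0.95
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy keep-first pruning of feature pairs with |Pearson r| > r_max."""
    if len(features) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    num = features.select_dtypes(include=[np.number])
    cols = list(num.columns)
    X = num.to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(X, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    kept: list[int] = []
    dropped: list[str] = []
    for j in range(len(cols)):
        if any(corr[j, i] > r_max for i in kept):
            dropped.append(cols[j])
        else:
            kept.append(j)
    keep_names = [cols[j] for j in kept] + [
        c for c in features.columns if c not in cols
    ]
    return features[keep_names], dropped


def standardize(
    features: pd.DataFrame,
    groups: pd.Series | None = None,
    fit_on: pd.Index | None = None,
) -> pd.DataFrame:
    """Z-score each numeric feature within each replicate group (population
    sd). Zero-variance columns within a group become 0 with a warning.

    When `fit_on` is given, group means and sds are estimated from those
    rows only (the training subset) and applied to the whole group — using
    held-out rows to fit the statistics would leak test-well information
    into the transform.
    """
    num = features.select_dtypes(include=[np.number])
    out = features.copy()
    if groups is None:
        groups = pd.Series("all", index=features.index)
    groups = groups.reindex(features.index)
    warned = False
    for _, idx in groups.groupby(groups).groups.items():
        block = num.loc[idx]
        fit_block = block
        if fit_on is not None:
            fit_idx = idx.intersection(fit_on)
            if len(fit_idx) >= 2:
                fit_block = num.loc[fit_idx]
        mu = fit_block.mean(axis=0)
        sd = fit_block.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any() and not warned:
            warnings.warn("zero-variance feature(s) within a group set to 0")
            warned = True
        sd = sd.where(~zero, 1.0)
        z = (block - mu) / sd
        z.loc[:, zero] = 0.0
        out.loc[idx, num.columns] = z
    return out
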