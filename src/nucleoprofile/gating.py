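"""Class labels from aligned ground-truth rounds, plus the three discard rules.

Post-hoc ground truth: after morphological imaging, the same cells are
re-imaged with class-specific markers (immunostaining or EdU/BrdU
pre-labelling). Per-ROI mean marker intensities are gated against manually
set thresholds (in practice chosen from monoculture controls; a midpoint
helper is provided) and cells outside the gate stay ``undefined``.

ROIs are then discarded on three conditions:
  rule 1 — detachment: no DAPI signal in the ground-truth round;
  rule 2 — ambiguity: gate produced no class (undefined);
  rule 3 — faulty detection: mean nuclear DAPI ≤ 500 or nuclear area ≤ 160
           (native pixels at the acquisition pixel size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .crops import RoiRecord
from .imaging import MultiChannelImage
from .segment import LabelMask

__all__ = [
    "GateSpec",
    "FilterSpec",
    "UNDEFINED",
    "measure_markers",
    "propose_thresholds",
    "gate_single",
    "gate_two_marker",
    "apply_filters",
]

UNDEFINED = "undefined"


@dataclass(frozen=True)
class GateSpec:
    """Per-marker intensity thresholds and the gate logic to apply."""

    thresholds: dict = field(default_factory=dict)
    logic: str = "single"  # "single" (one marker per class) or "two_marker"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds.values()):
            raise ValueError("thresholds must be positive")
        if self.logic not in ("single", "two_marker"):
            raise ValueError(f"unknown gate logic {self.logic!r}")


@dataclass(frozen=True)
class FilterSpec:
    """Discard-rule parameters (defaults follow the standard pipeline)."""

    min_mean_dapi: float = 500.0
    min_nuclear_area: int = 160
    require_gt_dapi: bool = True
    gt_dapi_floor: float | None = None  # default: min_mean_dapi

    def __post_init__(self) -> None:
        if self.min_mean_dapi < 0 or self.min_nuclear_area < 0:
            raise ValueError("filter thresholds must be non-negative")


def measure_markers(
    gt_img_aligned: MultiChannelImage,
    nuclei: LabelMask,
    rois: list[RoiRecord] | None = None,
    region_masks: dict[str, LabelMask] | None = None,
    dapi_channel: int | str = 0,
) -> pd.DataFrame:
    """Per-ROI mean intensity of each ground-truth channel.

    By default every marker is measured over the nucleus; `region_masks`
    maps a marker name to an alternative mask (e.g. the cell mask for a
    cytoplasmic marker such as TUBB3). Output columns: one per marker plus
    ``gt_dapi``; index = roi_id (or nuclear label when rois is None).
    """
    ids = nuclei.ids
    if len(ids) == 0:
        return pd.DataFrame(columns=["gt_dapi"])
    names = list(gt_img_aligned.channel_names)
    dapi_idx = dapi_channel if isinstance(dapi_channel, int) else names.index(dapi_channel)
    cols: dict[str, np.ndarray] = {}
    for ci, name in enumerate(names):
        mask = nuclei
        if region_masks and name in region_masks:
            mask = region_masks[name]
        plane = gt_img_aligned.channel(ci).astype(np.float64)
        vals = ndi.mean(plane, mask.labels, index=ids)
        # a label absent from the measuring mask yields NaN → omitted later
        present = np.isin(ids, mask.ids)
        vals = np.where(present, vals, np.nan)
        cols["gt_dapi" if ci == dapi_idx else name] = vals
    index = (
        pd.Index([r.roi_id for r in sorted(rois, key=lambda r: r.label)], name="roi_id")
        if rois is not None
        else pd.Index(ids, name="label")
    )
    if rois is not None:
        by_label = {r.label: r.roi_id for r in rois}
        keep = [i for i, lab in enumerate(ids) if lab in by_label]
        index = pd.Index([by_label[ids[i]] for i in keep], name="roi_id")
        cols = {k: v[keep] for k, v in cols.items()}
    table = pd.DataFrame(cols, index=index)
    return table.dropna(how="any")


def propose_thresholds(
    mono_tables: dict[str, pd.DataFrame], markers: list[str]
) -> dict[str, float]:
    """Midpoint between per-monoculture median intensities for each marker.

    A starting point for the manual threshold choice; the value finally used
    should be recorded in the run config.
    """
    out = {}
    for m in markers:
        medians = sorted(t[m].median() for t in mono_tables.values() if m in t)
        if len(medians) < 2:
            raise ValueError(f"need ≥2 monocultures measuring marker {m!r}")
        out[m] = float((medians[0] + medians[-1]) / 2)
    return out


def gate_single(table: pd.DataFrame, spec: GateSpec) -> pd.Series:
    """One marker per class (e.g. EdU vs BrdU): class = argmax marker among
    those above threshold; none or several above → undefined."""
    markers = list(spec.thresholds)
    missing = [m for m in markers if m not in table.columns]
    if missing:
        raise KeyError(f"marker columns missing from table: {missing}")
    above = pd.DataFrame(
        {m: table[m] > spec.thresholds[m] for m in markers}, index=table.index
    )
    n_above = above.sum(axis=1)
    winner = table[markers].idxmax(axis=1)
    labels = winner.where(n_above == 1, UNDEFINED)
    # with exactly one marker above threshold, that marker wins by definition
    one = n_above == 1
    labels[one] = above[one].idxmax(axis=1)
    return labels.rename("label")


def gate_two_marker(
    table: pd.DataFrame,
    spec: GateSpec,
    marker_a: str = "Ki67",
    marker_b: str = "TUBB3",
    class_a_neg_b_pos: str = "neuron",
    class_a_pos_b_neg: str = "NPC",
) -> pd.Series:
    """Two-marker quadrant gate: A−/B+ → neuron, A+/B− → NPC, else undefined."""
    for m in (marker_a, marker_b):
        if m not in table.columns:
            raise KeyError(f"marker column {m!r} missing from table")
        if m not in spec.thresholds:
            raise KeyError(f"no threshold for marker {m!r}")
    a_pos = table[marker_a] > spec.thresholds[marker_a]
    b_pos = table[marker_b] > spec.thresholds[marker_b]
    labels = pd.Series(UNDEFINED, index=table.index, name="label")
    labels[(~a_pos) & b_pos] = class_a_neg_b_pos
    labels[a_pos & (~b_pos)] = class_a_pos_b_neg
    return labels


def apply_filters(
    records: list[RoiRecord],
    table: pd.DataFrame,
    labels: pd.Series,
    spec: FilterSpec = FilterSpec(),
) -> tuple[list[RoiRecord], pd.DataFrame]:
    """Apply the three discard rules; returns (retained records, discard log).

    The discard log has one row per discarded ROI with every rule it
    violated (rules are independent, so their order cannot matter).
    """
    floor = spec.gt_dapi_floor if spec.gt_dapi_floor is not None else spec.min_mean_dapi
    retained, log_rows = [], []
    for rec in records:
        rules = []
        in_table = rec.roi_id in table.index
        gt_dapi = float(table.at[rec.roi_id, "gt_dapi"]) if in_table and "gt_dapi" in table else np.nan
        if spec.require_gt_dapi and (not in_table or not (gt_dapi > floor)):
            rules.append(1)  # detachment: no ground-truth DAPI signal
        lab = labels.get(rec.roi_id, UNDEFINED)
        if lab == UNDEFINED or pd.isna(lab):
            rules.append(2)  # ambiguous gate
        if not (rec.mean_nuclear_dapi > spec.min_mean_dapi) or not (
            rec.nuclear_area > spec.min_nuclear_area
        ):
            rules.append(3)  # faulty ROI detection
        if rules:
            log_rows.append({"roi_id": rec.roi_id, "rules": tuple(rules)})
        else:
            retained.append(rec)
    log = pd.DataFrame(log_rows, columns=["roi_id", "rules"])
    return retained, log
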