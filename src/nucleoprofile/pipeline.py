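"""End-to-end experiment designs on synthetic scenes, from one config.

Designs (train → test):
  mono2mono — monoculture wells with culture-level labels on both sides;
  co2co     — co-culture wells with cell-level labels from the gated
              ground-truth round on both sides;
  mono2co   — trained on monoculture wells (culture label), tested on
              co-culture wells (cell-level gated label), optionally
              finetuned on monoculture data from the held-out replicate.

The sweep driver varies one axis (patch_size, density, bin_factor, snr)
and reports a tidy macro-F table suitable for ribbon plots.

Every run writes its resolved config (with a content hash), split
assignment, per-epoch training log and metrics into the run directory, so
any reported number traces back to a logged field or seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import gating
from .classify import (
    TrainConfig,
    balance_classes,
    confluency_score,
    evaluate,
    evaluate_by_density,
    finetune,
    split_by_well,
    train_cnn,
    train_rf,
)
from .crops import CropSpec, crop_all, extract_rois, patch_pixels
from .degrade import add_noise, bin_pixels
from .features import compute_features, drop_redundant, standardize
from .imaging import apply_shift, estimate_shift, normalize_channels
from .segment import BackendParams, LabelMask, segment_cells, segment_nuclei
from .simulate import (
    SceneConfig,
    render_ground_truth_round,
    render_scene,
    two_class_profiles,
)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "FieldData", "simulate_wells", "assemble_crops",
           "build_feature_table", "run_experiment", "run_sweep",
           "density_robustness_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one synthetic experiment."""

    design: str = "mono2mono"
    radius_ratio: float = 2.0
    texture_contrast: bool = False
    n_wells: int = 12
    fields_per_well: int = 3
    cells_per_field: int = 30
    field_size: tuple = (448, 448)
    pixel_size: float = 0.325  # µm/pixel
    overlap_policy: str = "allow"
    replicates: tuple = ("rep1", "rep2", "rep3")
    crop_mode: str = "nucleocentric"
    patch_size: float | None = None
    segmentation: str = "truth"  # truth | baseline
    # The synthetic generator has no replicate-level batch effects, so the
    # default standardizes features globally (fit on the training subset);
    # per-replicate grouping is for data with real between-replicate shifts,
    # where its estimation noise is small against the batch effect it removes.
    standardize_per_replicate: bool = False
    gt_shift_max: int = 8
    marker_threshold: float = 400.0
    filter_spec: gating.FilterSpec = field(
        default_factory=lambda: gating.FilterSpec(min_mean_dapi=0.0, min_nuclear_area=60)
    )
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            epochs=15, batch_size=100, lr0=1e-3, min_per_class=1, seed=0
        )
    )
    model: str = "cnn"  # cnn | rf
    finetune_replicate: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("mono2mono", "co2co", "mono2co"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.segmentation not in ("truth", "baseline"):
            raise ValueError(f"unknown segmentation source {self.segmentation!r}")

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter_spec"] = dataclasses.asdict(self.filter_spec)
        d["train"] = dataclasses.asdict(self.train)
        return d


@dataclass
class FieldData:
    """One simulated field after the pre-processing stages."""

    img: object
    truth: object
    nuclei: LabelMask
    cells: LabelMask
    records: list
    labels: pd.Series  # roi_id -> class label
    well: str
    replicate: str
    density: float


def simulate_wells(cfg: ExperimentConfig) -> list[FieldData]:
    """Render all fields of the experiment with their labels.

    Monoculture wells alternate classes; co-culture wells mix both. Cell
    labels come from the gated ground-truth round for co-culture wells (the
    round is rendered with a random stage shift, registered and re-aligned
    first) and from the culture identity for monoculture wells.
    """
    profiles = two_class_profiles(cfg.radius_ratio, texture_contrast=cfg.texture_contrast)
    markers = sorted({m for p in profiles for m in p.marker_means})
    fields: list[FieldData] = []
    rng = np.random.default_rng(cfg.seed)
    for wi in range(cfg.n_wells):
        well = f"W{wi:02d}"
        replicate = cfg.replicates[wi % len(cfg.replicates)]
        mono_class = profiles[wi % 2]
        for fi in range(cfg.fields_per_well):
            mono = cfg.design != "co2co" and _is_mono_well(cfg.design, wi, cfg.n_wells)
            classes = (mono_class,) if mono else profiles
            scfg = SceneConfig(
                field_size=cfg.field_size,
                pixel_size=cfg.pixel_size,
                classes=classes,
                target_count=cfg.cells_per_field,
                overlap_policy=cfg.overlap_policy,
                seed=int(rng.integers(2**31)),
                well=well,
                replicate=replicate,
                field_id=fi,
            )
            img, truth = render_scene(scfg)
            nuclei, cells = _masks_for(cfg, img, truth)
            img_n = normalize_channels(img)
            records = extract_rois(nuclei, cells, img_n)
            if mono:
                labels = pd.Series(
                    mono_class.name, index=[r.roi_id for r in records], name="label"
                )
            else:
                labels, records = _labels_from_gt_round(
                    cfg, scfg, truth, nuclei, records, markers,
                    round1_dapi=img_n.channel(0), shift_rng=rng,
                )
            density = confluency_score(cells.labels)
            fields.append(
                FieldData(img_n, truth, nuclei, cells, records, labels, well, replicate, density)
            )
    return fields


def _is_mono_well(design: str, well_index: int, n_wells: int) -> bool:
    if design == "mono2mono":
        return True
    if design == "mono2co":
        # last third of wells are co-cultures (the test side)
        return well_index < (2 * n_wells) // 3
    return False


def _masks_for(cfg, img, truth) -> tuple[LabelMask, LabelMask]:
    if cfg.segmentation == "truth":
        return (
            LabelMask(truth.nuclei_mask, {"backend": "truth"}),
            LabelMask(truth.cells_mask, {"backend": "truth"}),
        )
    params = BackendParams(backend="baseline")
    img_n = normalize_channels(img)
    nuclei = segment_nuclei(img_n, params)
    cells = segment_cells(img_n, params, nuclei=nuclei)
    return nuclei, cells


def _labels_from_gt_round(cfg, scfg, truth, nuclei, records, markers, round1_dapi, shift_rng):
    """Render the cyclic round, register, align, measure, gate, filter."""
    dy = int(shift_rng.integers(-cfg.gt_shift_max, cfg.gt_shift_max + 1))
    dx = int(shift_rng.integers(-cfg.gt_shift_max, cfg.gt_shift_max + 1))
    gt = render_ground_truth_round(truth, scfg, shift=(dy, dx), markers=markers)
    est = estimate_shift(round1_dapi, gt.channel(0))
    gt_aligned = apply_shift(gt, est)
    table = gating.measure_markers(gt_aligned, nuclei, rois=records)
    spec = gating.GateSpec(thresholds={m: cfg.marker_threshold for m in markers})
    marker_labels = gating.gate_single(table, spec)
    class_of_marker = {"markerA": "alpha", "markerB": "beta"}
    labels = marker_labels.map(lambda m: class_of_marker.get(m, gating.UNDEFINED))
    retained, _log = gating.apply_filters(records, table, labels, cfg.filter_spec)
    ids = [r.roi_id for r in retained]
    return labels.loc[ids], retained


def assemble_crops(
    fields: list[FieldData],
    spec: CropSpec,
    degrade_mode: str | None = None,
    degrade_value: float | None = None,
    degrade_seed: int = 0,
    corrupt_cell_masks_above: float | None = None,
    corrupt_seed: int = 0,
) -> pd.DataFrame:
    """Crop every retained ROI of every field into one dataset table with
    columns crop (C×P×P array), label, well, replicate, density, roi_id.

    Optional full-field degradation (``bin``/``snr``) is applied before
    cropping. ``corrupt_cell_masks_above`` simulates whole-cell segmentation
    failure in dense fields (density percent above the cutoff): each cell
    label is merged with a neighbouring cell, as happens when a segmenter
    under-segments touching cells.
    """
    rows = []
    for fd in fields:
        img = fd.img
        if degrade_mode == "bin":
            img = bin_pixels(img, int(degrade_value))
        elif degrade_mode == "snr":
            img = add_noise(img, float(degrade_value), seed=degrade_seed)
        elif degrade_mode is not None:
            raise ValueError(f"unknown degradation axis {degrade_mode!r}")
        cells = fd.cells
        if (
            corrupt_cell_masks_above is not None
            and fd.density > corrupt_cell_masks_above
        ):
            cells = LabelMask(
                _merge_neighbours(fd.cells.labels, corrupt_seed),
                {**fd.cells.provenance, "corrupted": True},
            )
        crops, _ = crop_all(img, fd.records, fd.nuclei, cells, spec)
        for roi, crop in zip([r for r in fd.records if _croppable(r, spec)], crops):
            rows.append(
                dict(
                    roi_id=crop.roi_id,
                    crop=crop.values,
                    label=fd.labels.get(crop.roi_id),
                    well=fd.well,
                    replicate=fd.replicate,
                    density=fd.density,
                )
            )
    df = pd.DataFrame(rows)
    return df[df["label"].notna()] if len(df) else df


def _croppable(rec, spec) -> bool:
    return not (spec.mode == "cell" and rec.cell_label is None)


def _merge_neighbours(labels: np.ndarray, seed: int, fraction: float = 0.7) -> np.ndarray:
    """Merge a fraction of cell labels into an adjacent label (simulated
    under-segmentation)."""
    from scipy.ndimage import maximum_filter

    rng = np.random.default_rng(seed)
    out = labels.copy()
    ids = np.unique(out)
    ids = ids[ids > 0]
    # adjacency from dilation overlap
    grown = maximum_filter(out, size=5)
    for lab in ids:
        if rng.random() > fraction:
            continue
        neigh = np.unique(grown[(out == lab)])
        neigh = neigh[(neigh != lab) & (neigh > 0)]
        if len(neigh):
            out[out == lab] = int(rng.choice(neigh))
    return out


def _dataset_arrays(df: pd.DataFrame):
    X = np.stack(df["crop"].to_list()).astype(np.float64)
    y = df["label"].to_numpy()
    return X, y


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run one full design; returns a dict with the report, model, split and
    run-directory path (when out_dir is given, everything is persisted)."""
    fields = simulate_wells(cfg)
    spec = CropSpec(mode=cfg.crop_mode, patch_size=cfg.patch_size)
    data = assemble_crops(fields, spec)
    if cfg.design in ("mono2mono", "co2co"):
        split = split_by_well(_records_df(data), seed=cfg.seed, strata=_well_strata(data))
        train_ids, val_ids, test_ids = _split_ids(data, split)
    else:  # mono2co: train on mono wells, test on co wells
        mono = data[data["well"].isin(_mono_wells(cfg))]
        co = data[~data["well"].isin(_mono_wells(cfg))]
        split = split_by_well(
            _records_df(mono), fractions=(0.85, 0.15, 0.0), seed=cfg.seed,
            strata=_well_strata(mono),
        )
        train_ids = [i for i in mono.index if split.assignment[mono.at[i, "roi_id"]] == "train"]
        val_ids = [i for i in mono.index if split.assignment[mono.at[i, "roi_id"]] == "val"]
        test_ids = list(co.index)
    labels_s = pd.Series(data["label"].to_numpy(), index=data.index)
    train_ids = balance_classes(train_ids, labels_s, seed=cfg.seed)
    val_ids = _balance_if_possible(val_ids, labels_s, cfg.seed)
    report, model, log = _fit_eval(cfg, data, train_ids, val_ids, test_ids, fields=fields)
    result = {
        "report": report,
        "model": model,
        "split": split,
        "training_log": log,
        "n_train": len(train_ids),
        "n_test": len(test_ids),
    }
    if cfg.design == "mono2co" and cfg.finetune_replicate and cfg.model == "cnn":
        extra = data.loc[train_ids]
        extra = extra[extra["replicate"] == cfg.finetune_replicate]
        if len(extra):
            Xe, ye = _dataset_arrays(extra)
            ft_cfg = replace(cfg.train, epochs=max(cfg.train.epochs // 3, 1))
            tuned, _ = finetune(model, Xe, ye, ft_cfg)
            Xt, yt = _dataset_arrays(data.loc[test_ids])
            result["report_finetuned"] = evaluate(tuned, Xt, yt)
    if out_dir is not None:
        _persist(cfg, result, Path(out_dir))
    return result


def _well_strata(data: pd.DataFrame) -> dict:
    """Stratum per well: its single culture class for monoculture wells,
    "mixed" for co-culture wells."""
    out = {}
    for well, sub in data.groupby("well"):
        labs = sub["label"].dropna().unique()
        out[str(well)] = str(labs[0]) if len(labs) == 1 else "mixed"
    return out


def _balance_if_possible(ids, labels_s, seed):
    """Class-equalize a subset; a constant model then cannot outscore a
    non-degenerate one on validation by exploiting class imbalance."""
    try:
        return balance_classes(ids, labels_s, seed=seed)
    except ValueError:
        return ids


def _mono_wells(cfg) -> set:
    return {
        f"W{wi:02d}" for wi in range(cfg.n_wells) if _is_mono_well(cfg.design, wi, cfg.n_wells)
    }


def _records_df(data: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"well": data["well"].to_numpy()}, index=data["roi_id"].to_numpy())


def _split_ids(data: pd.DataFrame, split) -> tuple[list, list, list]:
    out = {"train": [], "val": [], "test": []}
    for i in data.index:
        out[split.assignment[data.at[i, "roi_id"]]].append(i)
    return out["train"], out["val"], out["test"]


def _fit_eval(cfg, data, train_ids, val_ids, test_ids, fields=None):
    train_wells = set(data.loc[train_ids, "well"])
    test_wells = set(data.loc[test_ids, "well"])
    dens = data.loc[test_ids, "density"].to_numpy()
    if cfg.model == "cnn":
        Xt, yt = _dataset_arrays(data.loc[test_ids])
        X, y = _dataset_arrays(data.loc[train_ids])
        Xv, yv = (
            _dataset_arrays(data.loc[val_ids]) if len(val_ids) else (None, None)
        )
        model, log = train_cnn(
            X, y, cfg.train, Xv, yv, train_wells=train_wells, test_wells=test_wells
        )
        report = evaluate_by_density(model, Xt, yt, dens)
    else:
        if fields is None:
            raise ValueError("the random-forest route needs the rendered fields")
        feats = build_feature_table(fields)
        labels = pd.Series(
            data["label"].to_numpy(), index=data["roi_id"].to_numpy()
        )
        feats = feats.loc[feats.index.intersection(labels.index)]
        feats, _dropped = drop_redundant(feats)
        groups = None
        if cfg.standardize_per_replicate:
            groups = pd.Series(
                data["replicate"].to_numpy(), index=data["roi_id"].to_numpy()
            ).loc[feats.index]
        feats = standardize(
            feats.select_dtypes(include=[np.number]),
            groups=groups,
            fit_on=pd.Index(data.loc[train_ids, "roi_id"]),
        )
        Xtr = feats.loc[data.loc[train_ids, "roi_id"]]
        model, _imp = train_rf(
            Xtr, labels, seed=cfg.train.seed,
            train_wells=train_wells, test_wells=test_wells,
        )
        Xte = feats.loc[data.loc[test_ids, "roi_id"]]
        report = evaluate_by_density(model, Xte, labels.loc[Xte.index], dens)
        log = pd.DataFrame()
    return report, model, log


def build_feature_table(fields: list[FieldData]) -> pd.DataFrame:
    """Handcrafted features for every retained ROI of every field, indexed by
    roi_id; rows with undefined cytoplasm are dropped."""
    parts = []
    for fd in fields:
        df = compute_features(fd.img, fd.nuclei, fd.cells)
        if not len(df):
            continue
        by_label = {r.label: r.roi_id for r in fd.records}
        df = df.loc[df.index.isin(by_label)]
        df.index = [by_label[lab] for lab in df.index]
        parts.append(df[~df["incomplete"]])
    out = pd.concat(parts) if parts else pd.DataFrame()
    return out.dropna(axis=0)


def run_sweep(
    cfg: ExperimentConfig,
    axis: str,
    values: list,
    seeds: list[int] = (0,),
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """One row per (axis value, seed): macro-F of the re-trained model.

    axis ∈ {patch_size, density, bin_factor, snr}. Per-point failures are
    recorded as rows with status="failed" instead of aborting the sweep.
    """
    if axis not in ("patch_size", "density", "bin_factor", "snr"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    fields = None
    if axis in ("bin_factor", "snr"):
        # degradation sweeps reuse one rendering of the fields
        fields = simulate_wells(cfg)
    rows = []
    for v in values:
        for s in seeds:
            row = dict(axis=axis, value=v, seed=s, macro_f=np.nan, status="ok")
            try:
                row["macro_f"] = _sweep_point(cfg, axis, v, s, fields=fields)
            except Exception as exc:  # per-point failure stays a row
                logger.warning("sweep point %s=%s seed=%s failed: %s", axis, v, s, exc)
                row["status"] = "failed"
            rows.append(row)
    df = pd.DataFrame(rows, columns=["axis", "value", "seed", "macro_f", "status"])
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df


def _sweep_point(cfg: ExperimentConfig, axis: str, value, seed: int, fields=None) -> float:
    cfg = replace(cfg, seed=cfg.seed, train=replace(cfg.train, seed=seed))
    if axis == "patch_size":
        patch_pixels(float(value), cfg.pixel_size)  # propagate degenerate-size errors
        cfg = replace(cfg, patch_size=float(value))
        res = run_experiment(cfg)
        return res["report"].macro_f
    if axis == "density":
        cfg = replace(cfg, cells_per_field=int(value), overlap_policy="crowded")
        res = run_experiment(cfg)
        return res["report"].macro_f
    # degradation axes: same fields, degraded before cropping
    if fields is None:
        fields = simulate_wells(cfg)
    spec = CropSpec(mode=cfg.crop_mode, patch_size=cfg.patch_size)
    mode = "bin" if axis == "bin_factor" else "snr"
    data = assemble_crops(fields, spec, degrade_mode=mode, degrade_value=value,
                          degrade_seed=seed)
    split = split_by_well(_records_df(data), seed=cfg.seed, strata=_well_strata(data))
    train_ids, val_ids, test_ids = _split_ids(data, split)
    labels_s = pd.Series(data["label"].to_numpy(), index=data.index)
    train_ids = balance_classes(train_ids, labels_s, seed=cfg.seed)
    val_ids = _balance_if_possible(val_ids, labels_s, cfg.seed)
    report, _, _ = _fit_eval(cfg, data, train_ids, val_ids, test_ids)
    return report.macro_f


def density_robustness_experiment(
    cfg: ExperimentConfig,
    seeds=(0, 1, 2),
    low_count: int = 18,
    high_count: int = 55,
    corrupt_fraction: float = 0.7,
) -> pd.DataFrame:
    """Whole-cell vs nucleocentric robustness to segmentation failure in
    dense cultures.

    Trains each crop regime on sparse fields, then evaluates on sparse
    held-out wells (F_low) and on dense fields whose whole-cell masks are
    corrupted by merging a fraction of touching cells (F_high), emulating
    under-segmentation at high confluency. Nucleocentric crops never consult
    the cell mask, so their drop isolates the density effect itself.

    Returns one row per (mode, seed) with f_low, f_high and drop.
    """
    rows = []
    for seed in seeds:
        base = replace(cfg, seed=cfg.seed + 97 * seed, train=replace(cfg.train, seed=seed))
        low_cfg = replace(base, cells_per_field=low_count, overlap_policy="allow")
        high_cfg = replace(
            base,
            cells_per_field=high_count,
            overlap_policy="crowded",
            seed=base.seed + 1,
        )
        low_fields = simulate_wells(low_cfg)
        high_fields = simulate_wells(high_cfg)
        for fd in high_fields:  # distinct well ids: the dense plate is separate
            fd.well = "H" + fd.well
            for r in fd.records:
                r.well = fd.well
        for mode in ("cell", "nucleocentric"):
            spec = CropSpec(mode=mode)
            low = assemble_crops(low_fields, spec)
            high = assemble_crops(
                high_fields, spec,
                corrupt_cell_masks_above=0.0, corrupt_seed=seed,
            )
            split = split_by_well(_records_df(low), seed=base.seed, strata=_well_strata(low))
            tr, va, te = _split_ids(low, split)
            labels_s = pd.Series(low["label"].to_numpy(), index=low.index)
            tr = balance_classes(tr, labels_s, seed=base.seed)
            va = _balance_if_possible(va, labels_s, base.seed)
            X, y = _dataset_arrays(low.loc[tr])
            Xv, yv = _dataset_arrays(low.loc[va]) if len(va) else (None, None)
            model, _ = train_cnn(
                X, y, base.train, Xv, yv,
                train_wells=set(low.loc[tr, "well"]),
                test_wells=set(low.loc[te, "well"]) | set(high["well"]),
            )
            Xl, yl = _dataset_arrays(low.loc[te])
            f_low = evaluate(model, Xl, yl).macro_f
            Xh, yh = _dataset_arrays(high)
            f_high = evaluate(model, Xh, yh).macro_f
            rows.append(
                dict(mode=mode, seed=seed, f_low=f_low, f_high=f_high, drop=f_low - f_high)
            )
    return pd.DataFrame(rows)


def _persist(cfg: ExperimentConfig, result: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    resolved = cfg.resolved()
    blob = json.dumps(resolved, sort_keys=True, default=str).encode()
    resolved["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    (out_dir / "config.json").write_text(json.dumps(resolved, indent=2, default=str))
    (out_dir / "metrics.json").write_text(
        json.dumps(
            {
                "report": result["report"].to_dict(),
                **(
                    {"report_finetuned": result["report_finetuned"].to_dict()}
                    if "report_finetuned" in result
                    else {}
                ),
                "n_train": result["n_train"],
                "n_test": result["n_test"],
            },
            indent=2,
        )
    )
    pd.Series(result["split"].assignment, name="subset").rename_axis("roi_id").to_csv(
        out_dir / "split.csv"
    )
    if len(result["training_log"]):
        result["training_log"].to_csv(out_dir / "training_log.csv", index=False)
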