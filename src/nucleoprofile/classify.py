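"""Well-stratified splitting, class balancing, random-forest and CNN
training, overall and density-stratified evaluation, embeddings, finetuning
and nonparametric model comparison.

Leakage control is structural: the 60/10/30 split assigns whole wells to
subsets, so technical replicates of one well can never straddle train and
test; training asserts the well-disjointness at fit time.

"F-score" throughout is the macro-averaged F1 (unweighted mean of per-class
F1), the symmetric choice for class-equalized data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score, precision_recall_fscore_support

from .nn import Adam, ConvNet, build_model, cross_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "SplitAssignment",
    "TrainConfig",
    "EvalReport",
    "DensityBinning",
    "split_by_well",
    "balance_classes",
    "train_rf",
    "train_cnn",
    "finetune",
    "evaluate",
    "confluency_score",
    "evaluate_by_density",
    "embed",
    "compare_models",
    "apply_channel_subset",
    "augment_batch",
]


@dataclass
class SplitAssignment:
    """roi_id → subset, derived from a well-level partition."""

    assignment: dict[str, str]  # roi_id -> train|val|test
    wells: dict[str, str]  # well -> subset
    seed: int

    def subset_ids(self, subset: str) -> list[str]:
        return [r for r, s in self.assignment.items() if s == subset]

    def well_sets(self) -> dict[str, set]:
        out: dict[str, set] = {"train": set(), "val": set(), "test": set()}
        for w, s in self.wells.items():
            out[s].add(w)
        return out


@dataclass(frozen=True)
class TrainConfig:
    """CNN training recipe. Defaults are the full-scale recipe (50 epochs,
    batches of 100, lr 1e-4 reduced ×0.1 after 10 epochs without validation
    improvement, ≥5000 inputs per class); desk-scale runs relax epochs and
    min_per_class and use the narrow residual architecture."""

    epochs: int = 50
    batch_size: int = 100
    lr0: float = 1e-4
    lr_factor: float = 0.1
    lr_patience: int = 10
    min_per_class: int = 5000
    augment: tuple = ("hflip", "vflip", "rot90")
    seed: int = 0
    arch: str = "resnet18_small"
    input_channels: int = 4

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.lr_patience, self.input_channels) <= 0:
            raise ValueError("epochs, batch_size, lr_patience, input_channels must be positive")
        if self.lr0 <= 0 or not (0 < self.lr_factor <= 1):
            raise ValueError("invalid learning-rate settings")
        bad = set(self.augment) - {"hflip", "vflip", "rot90"}
        if bad:
            raise ValueError(f"unsupported augmentations: {sorted(bad)}")


@dataclass
class EvalReport:
    """Per-class precision/recall/F1, macro F, confusion matrix, optional
    per-density-bin breakdown."""

    classes: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f: float
    confusion: np.ndarray
    n: int
    per_bin: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "classes": [str(c) for c in self.classes],
            "precision": [float(x) for x in self.precision],
            "recall": [float(x) for x in self.recall],
            "f1": [float(x) for x in self.f1],
            "macro_f": float(self.macro_f),
            "confusion": self.confusion.tolist(),
            "n": int(self.n),
        }
        if self.per_bin is not None:
            d["per_bin"] = self.per_bin.to_dict(orient="records")
        return d


@dataclass(frozen=True)
class DensityBinning:
    """Confluency bins, half-open on the left: (lo, hi]; the last bin
    includes 100%."""

    edges: tuple = (0.0, 20.0, 40.0, 60.0, 80.0, 95.0, 100.0)
    min_n: int = 10

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if not (np.all(np.diff(e) > 0) and e[0] == 0.0 and e[-1] == 100.0):
            raise ValueError("edges must increase strictly and cover (0,100]")

    @property
    def labels(self) -> list[str]:
        e = self.edges
        return [f"{e[i]:g}-{e[i+1]:g}" for i in range(len(e) - 1)]

    def assign(self, scores: np.ndarray) -> np.ndarray:
        """Bin index per score; scores must lie in (0, 100]."""
        s = np.asarray(scores, dtype=float)
        idx = np.searchsorted(self.edges, s, side="left") - 1
        return np.clip(idx, 0, len(self.edges) - 2)


def split_by_well(
    records, fractions=(0.60, 0.10, 0.30), seed: int = 0, strata: dict | None = None
) -> SplitAssignment:
    """Partition wells into train/val/test so ROI fractions approximate the
    targets; well counts per subset come from largest-remainder allocation
    and wells are assigned in seeded random order.

    `strata` optionally maps well → stratum (e.g. the culture class of a
    monoculture well); allocation then runs within each stratum so every
    subset samples all strata whenever counts permit.
    """
    wells_of = _well_of(records)
    wells = sorted(set(wells_of.values()))
    if len(wells) < 3:
        raise ValueError("need at least 3 wells for a well-stratified split")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]]
    if strata is None:
        groups = {"all": wells}
    else:
        groups = {}
        for w in wells:
            groups.setdefault(str(strata.get(w, "all")), []).append(w)
    well_map: dict[str, str] = {}
    subset_names = ["train", "val", "test"]
    for group_wells in groups.values():
        counts = _largest_remainder(len(group_wells), fractions)
        shuffled = list(rng.permutation(group_wells))
        pos = 0
        for name, c in zip(subset_names, counts):
            for w in shuffled[pos : pos + c]:
                well_map[str(w)] = name
            pos += c
    assignment = {rid: well_map[str(w)] for rid, w in wells_of.items()}
    return SplitAssignment(assignment, well_map, seed)


def _largest_remainder(n: int, fractions) -> np.ndarray:
    raw = np.array(fractions) * n
    counts = np.floor(raw).astype(int)
    # non-empty subsets where a share was requested, remainder by largest
    # fractional part
    counts = np.where(np.array(fractions) > 0, np.maximum(counts, 1), 0)
    while counts.sum() > n:
        counts[counts.argmax()] -= 1
    rem = raw - np.floor(raw)
    eligible = [i for i in range(len(fractions)) if fractions[i] > 0]
    order = sorted(eligible, key=lambda i: -rem[i])
    i = 0
    while counts.sum() < n:
        counts[order[i % len(order)]] += 1
        i += 1
    return counts


def _well_of(records) -> dict[str, str]:
    if isinstance(records, pd.DataFrame):
        return dict(zip(records.index.astype(str), records["well"].astype(str)))
    return {r.roi_id: str(r.well) for r in records}


def balance_classes(roi_ids, labels: pd.Series, seed: int = 0) -> list[str]:
    """Downsample every class (without replacement) to the minority count."""
    labels = labels.loc[list(roi_ids)]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes to balance")
    if (counts == 0).any():
        raise ValueError("a class has no instances")
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    for cls in sorted(counts.index):
        ids = [i for i in labels.index[labels == cls]]
        sel = rng.choice(len(ids), size=m, replace=False)
        kept.extend(ids[j] for j in sorted(sel))
    return kept


def _assert_no_leakage(train_wells: set, test_wells: set) -> None:
    inter = set(train_wells) & set(test_wells)
    if inter:
        raise ValueError(f"train/test wells overlap: {sorted(inter)}")


def train_rf(
    features: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 30,
    seed: int = 0,
    train_wells: set | None = None,
    test_wells: set | None = None,
) -> tuple[RandomForestClassifier, pd.Series]:
    """Fit a random forest on the standardized feature matrix.

    Returns the fitted model and the mean-decrease-in-impurity importances
    (summing to 1). Tree counts of 10–150 are all reasonable; accuracy
    typically saturates around 30 trees.
    """
    if train_wells is not None and test_wells is not None:
        _assert_no_leakage(train_wells, test_wells)
    X = features.select_dtypes(include=[np.number])
    bad = X.columns[X.isna().any()].tolist()
    if bad:
        raise ValueError(f"NaN feature columns: {bad}")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(X.to_numpy(), labels.loc[X.index].to_numpy())
    imp = pd.Series(model.feature_importances_, index=X.columns, name="importance")
    return model, imp


def augment_batch(x: np.ndarray, rng: np.random.Generator, ops=("hflip", "vflip", "rot90")) -> np.ndarray:
    """Seeded flips and 90°-multiple rotations applied per sample (N,C,H,W).

    Axis-aligned rotations avoid interpolation artifacts on masked crops.
    """
    out = x.copy()
    n = len(out)
    if "hflip" in ops:
        flip = rng.random(n) < 0.5
        out[flip] = out[flip, :, :, ::-1]
    if "vflip" in ops:
        flip = rng.random(n) < 0.5
        out[flip] = out[flip, :, ::-1, :]
    if "rot90" in ops:
        ks = rng.integers(0, 4, n)
        for k in (1, 2, 3):
            sel = ks == k
            if sel.any():
                out[sel] = np.rot90(out[sel], k=k, axes=(2, 3))
    return out


def apply_channel_subset(x: np.ndarray, keep: list[int]) -> np.ndarray:
    """Zero deselected channels, preserving input shape, so one architecture
    serves every channel-subset experiment."""
    out = np.zeros_like(x)
    out[:, keep] = x[:, keep]
    return out


def train_cnn(
    crops: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    val_crops: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    train_wells: set | None = None,
    test_wells: set | None = None,
    model: ConvNet | None = None,
) -> tuple[ConvNet, pd.DataFrame]:
    """Train (or continue training) a conv net with the standard recipe.

    Each epoch the model is scored on the validation set; the checkpoint with
    the best validation accuracy (earliest epoch on ties) is returned. The
    learning rate is multiplied by ``lr_factor`` when validation accuracy has
    not improved for ``lr_patience`` epochs. The training log has one row per
    epoch: loss, train/val accuracy, lr.
    """
    x = np.asarray(crops, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 4:
        raise ValueError("crops must be (N, C, H, W)")
    if len(np.unique([c.shape for c in x], axis=0)) != 1:
        raise ValueError("inconsistent crop shapes")
    class_names, y_idx = np.unique(y, return_inverse=True)
    if len(class_names) < 2:
        raise ValueError("need at least 2 classes in the training set")
    counts = np.bincount(y_idx)
    if counts.min() < config.min_per_class:
        logger.warning(
            "smallest class has %d < min_per_class=%d training inputs",
            counts.min(), config.min_per_class,
        )
    if train_wells is not None and test_wells is not None:
        _assert_no_leakage(train_wells, test_wells)
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = build_model(config.arch, config.input_channels, len(class_names), rng)
    model.class_names = class_names
    opt = Adam(model.parameters(), lr=config.lr0)
    has_val = val_crops is not None and len(val_crops) > 0
    if has_val:
        xv = np.asarray(val_crops, dtype=np.float64)
        yv_idx = np.searchsorted(class_names, np.asarray(val_labels))
    best_state, best_acc, best_epoch = model.state_dict(), -np.inf, -1
    since_improve = 0
    log_rows = []
    n = len(x)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = augment_batch(x[idx], rng, config.augment)
            logits = model.forward(xb, train=True)
            loss, g = cross_entropy(logits, y_idx[idx])
            model.zero_grad()
            model.backward(g)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y_idx[idx]).sum())
        train_acc = correct / n
        if has_val:
            val_acc = float((model.predict(xv) == yv_idx).mean())
        else:
            val_acc = train_acc
        if val_acc > best_acc:  # strict: ties keep the earlier epoch
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.lr_patience:
                opt.lr *= config.lr_factor
                since_improve = 0
                logger.info("epoch %d: lr reduced to %g", epoch, opt.lr)
        log_rows.append(
            dict(epoch=epoch, loss=float(np.mean(losses)), train_acc=train_acc,
                 val_acc=val_acc, lr=opt.lr)
        )
    model.load_state_dict(best_state)
    model.trained = True
    model.best_epoch = best_epoch
    return model, pd.DataFrame(log_rows)


def finetune(
    model: ConvNet,
    extra_crops: np.ndarray,
    extra_labels: np.ndarray,
    config: TrainConfig,
    val_crops=None,
    val_labels=None,
) -> tuple[ConvNet, pd.DataFrame]:
    """Continue optimization from a trained checkpoint on additional data
    with a fresh learning-rate schedule (e.g. monoculture data from the test
    replicate in a Mono2Co design)."""
    if not getattr(model, "trained", False):
        raise ValueError("finetune requires a trained model")
    if len(extra_crops) == 0:
        return model.clone(), pd.DataFrame(columns=["epoch", "loss", "train_acc", "val_acc", "lr"])
    new_classes = set(np.unique(extra_labels)) - set(model.class_names)
    if new_classes:
        raise ValueError(f"classes {sorted(new_classes)} unknown to the model head")
    tuned = model.clone()
    tuned.class_names = model.class_names
    tuned, log = train_cnn(
        extra_crops, extra_labels, config, val_crops, val_labels, model=tuned
    )
    return tuned, log


def _predict_any(model, inputs) -> np.ndarray:
    if isinstance(model, ConvNet):
        idx = model.predict(np.asarray(inputs, dtype=np.float64))
        return np.asarray(model.class_names)[idx]
    X = inputs.select_dtypes(include=[np.number]) if isinstance(inputs, pd.DataFrame) else inputs
    return model.predict(np.asarray(X))


def evaluate(model, inputs, labels, class_order=None) -> EvalReport:
    """Held-out evaluation: per-class precision/recall/F1, macro F and the
    confusion matrix in fixed class order."""
    y = np.asarray(labels)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = _predict_any(model, inputs)
    classes = list(class_order) if class_order is not None else sorted(set(y) | set(pred))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, pred, labels=classes, zero_division=0
    )
    cm = confusion_matrix(y, pred, labels=classes)
    return EvalReport(
        classes=classes,
        precision=prec,
        recall=rec,
        f1=f1,
        macro_f=float(f1.mean()),
        confusion=cm,
        n=len(y),
    )


def confluency_score(cells_mask: np.ndarray | None = None, *, coverage: float | None = None,
                     nuclear_count: int | None = None, count_at_confluency: int | None = None) -> float:
    """Field confluency in (0,100]: cell-mask coverage percent by default, or
    nuclear count scaled by a configured count-at-confluency."""
    if coverage is not None:
        return float(np.clip(coverage * 100.0, 0.0, 100.0))
    if cells_mask is not None:
        m = np.asarray(cells_mask)
        return float(100.0 * np.count_nonzero(m) / m.size)
    if nuclear_count is not None:
        if not count_at_confluency:
            raise ValueError("nuclear-count scoring needs count_at_confluency")
        return float(np.clip(100.0 * nuclear_count / count_at_confluency, 0.0, 100.0))
    raise ValueError("provide cells_mask, coverage or nuclear_count")


def evaluate_by_density(
    model, inputs, labels, densities, binning: DensityBinning = DensityBinning(),
    class_order=None,
) -> EvalReport:
    """Overall report plus per-density-bin macro F.

    Bins with fewer than ``binning.min_n`` test ROIs are reported with
    ``insufficient=True`` and a NaN F-score.
    """
    report = evaluate(model, inputs, labels, class_order=class_order)
    y = np.asarray(labels)
    pred = _predict_any(model, inputs)
    bins = binning.assign(np.asarray(densities, dtype=float))
    rows = []
    for b, lab in enumerate(binning.labels):
        sel = bins == b
        n = int(sel.sum())
        if n < binning.min_n:
            rows.append(dict(bin=lab, n=n, macro_f=np.nan, insufficient=True))
            continue
        # average only over classes present in the bin: dense and sparse
        # fields need not contain every class
        present = sorted(set(y[sel]))
        f = f1_score(y[sel], pred[sel], labels=present, average="macro", zero_division=0)
        rows.append(dict(bin=lab, n=n, macro_f=float(f), insufficient=False))
    report.per_bin = pd.DataFrame(rows)
    return report


def embed(model: ConvNet, crops: np.ndarray) -> np.ndarray:
    """Penultimate-layer (global-average-pool) embedding per crop."""
    if not getattr(model, "trained", False):
        raise ValueError("embed requires a trained model")
    return model.embed(np.asarray(crops, dtype=np.float64))


def compare_models(f_scores_a, f_scores_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two groups of model F-scores.

    Exact null enumeration for groups of ≤ 8 without ties; normal
    approximation with midrank tie correction otherwise.
    """
    a, b = np.asarray(f_scores_a, float), np.asarray(f_scores_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per group")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
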