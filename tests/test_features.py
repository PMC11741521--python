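"""Handcrafted features: GLCM against a brute-force co-occurrence oracle,
shape features against closed forms, pruning and standardization."""

import numpy as np
import pandas as pd
import pytest

from nucleoprofile.features import (
    GLCM_LEVELS,
    GLCM_PROPS,
    compute_features,
    drop_redundant,
    glcm_features,
    standardize,
)
from nucleoprofile.imaging import MultiChannelImage
from nucleoprofile.segment import LabelMask

# offsets (dr, dc) for 0°, 45°, 90°, 135° at distance 1; with symmetric
# counting the sign convention is irrelevant
OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]


def brute_force_glcm(patch, mask, levels=GLCM_LEVELS):
    """Independent pair-counting implementation of the masked, symmetric,
    angle-averaged co-occurrence statistics."""
    vals = patch[mask]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        q = np.zeros(patch.shape, dtype=int)
    else:
        q = np.clip(((patch - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    H, W = patch.shape
    acc = {p: 0.0 for p in GLCM_PROPS}
    n_used = 0
    for dr, dc in OFFSETS:
        M = np.zeros((levels, levels))
        for r in range(H):
            for c in range(W):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W and mask[r, c] and mask[r2, c2]:
                    M[q[r, c], q[r2, c2]] += 1
                    M[q[r2, c2], q[r, c]] += 1  # symmetric
        tot = M.sum()
        if tot == 0:
            continue
        P = M / tot
        i = np.arange(levels)[:, None]
        j = np.arange(levels)[None, :]
        acc["contrast"] += (P * (i - j) ** 2).sum()
        acc["dissimilarity"] += (P * np.abs(i - j)).sum()
        acc["homogeneity"] += (P / (1 + (i - j) ** 2)).sum()
        asm = (P**2).sum()
        acc["ASM"] += asm
        acc["energy"] += np.sqrt(asm)
        mi, mj = (P * i).sum(), (P * j).sum()
        vi, vj = (P * (i - mi) ** 2).sum(), (P * (j - mj) ** 2).sum()
        acc["correlation"] += (
            (P * (i - mi) * (j - mj)).sum() / np.sqrt(vi * vj) if vi * vj > 0 else 1.0
        )
        n_used += 1
    return {p: acc[p] / n_used for p in GLCM_PROPS}


class TestGLCM:
    def test_matches_brute_force_on_random_patches(self, rng):
        """All six statistics agree with the oracle to 1e-9 on ≥50 patches."""
        for trial in range(50):
            patch = rng.random((8, 8))
            mask = rng.random((8, 8)) < 0.8
            if mask.sum() < 4:
                mask[:] = True
            got = glcm_features(patch, mask)
            want = brute_force_glcm(patch, mask)
            for p in GLCM_PROPS:
                assert got[p] == pytest.approx(want[p], abs=1e-9), (trial, p)

    def test_uniform_texture_limits(self):
        patch = np.full((9, 9), 3.7)
        mask = np.ones((9, 9), dtype=bool)
        props = glcm_features(patch, mask)
        assert props["energy"] == pytest.approx(1.0)
        assert props["ASM"] == pytest.approx(1.0)
        assert props["contrast"] == pytest.approx(0.0)
        assert props["dissimilarity"] == pytest.approx(0.0)

    def test_tiny_region_flagged_nan(self):
        props = glcm_features(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))
        assert all(np.isnan(v) for v in props.values())


def _rect_image():
    """Single-channel scene with one 10×20 solid rectangle."""
    labels = np.zeros((40, 60), dtype=int)
    labels[10:20, 15:35] = 1
    pix = np.zeros((40, 60, 1))
    pix[labels == 1, 0] = 5.0
    return MultiChannelImage(pix, ["x"], 1.0), LabelMask(labels)


class TestShapeAndIntensity:
    def test_rectangle_closed_forms(self):
        img, nuclei = _rect_image()
        df = compute_features(img, nuclei)
        row = df.loc[1]
        assert row["nucleus_area"] == 200.0
        assert row["nucleus_extent"] == 1.0
        assert row["nucleus_solidity"] == 1.0
        assert row["nucleus_area_filled"] == 200.0
        assert row["nucleus_ch0_intensity_std"] == 0.0
        assert row["nucleus_ch0_intensity_mean"] == 5.0
        assert row["nucleus_ch0_ASM"] == pytest.approx(1.0)
        assert row["nucleus_ch0_contrast"] == pytest.approx(0.0)

    def test_circle_eccentricity_near_zero(self):
        yy, xx = np.mgrid[:64, :64]
        labels = (np.hypot(yy - 32, xx - 32) <= 20).astype(int)
        pix = labels[..., None].astype(float)
        df = compute_features(MultiChannelImage(pix, ["x"], 1.0), LabelMask(labels))
        assert df.loc[1, "nucleus_eccentricity"] < 0.05

    def test_translation_invariance_of_shape(self):
        img, nuclei = _rect_image()
        shifted = np.roll(nuclei.labels, (7, 9), axis=(0, 1))
        pix = np.zeros(img.pixels.shape)
        pix[shifted == 1, 0] = 5.0
        a = compute_features(img, nuclei).loc[1]
        b = compute_features(MultiChannelImage(pix, ["x"], 1.0), LabelMask(shifted)).loc[1]
        for f in ("area", "extent", "solidity", "perimeter", "eccentricity",
                  "axis_major_length"):
            assert a[f"nucleus_{f}"] == pytest.approx(b[f"nucleus_{f}"])

    def test_intensity_ignores_outside_region(self):
        img, nuclei = _rect_image()
        noisy = img.pixels.copy()
        noisy[nuclei.labels == 0] = 99.0
        a = compute_features(img, nuclei).loc[1]
        b = compute_features(MultiChannelImage(noisy, ["x"], 1.0), nuclei).loc[1]
        for f in ("intensity_max", "intensity_mean", "intensity_min", "intensity_std"):
            assert a[f"nucleus_ch0_{f}"] == b[f"nucleus_ch0_{f}"]

    def test_full_matrix_on_scene(self, small_scene):
        _, img, truth = small_scene
        df = compute_features(img, LabelMask(truth.nuclei_mask), LabelMask(truth.cells_mask))
        assert len(df) == len(truth.table)
        # 3 regions × (14 shape + 4 channels × (4 intensity + 6 texture)) + flag
        assert df.shape[1] == 3 * (14 + 4 * 10) + 1
        complete = df[~df["incomplete"]]
        assert len(complete) > 0
        assert not complete.drop(columns="incomplete").isna().any().any()


class TestDropRedundant:
    def test_duplicate_and_negation_dropped(self, rng):
        x = rng.random(50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": -x, "d": rng.random(50)})
        out, dropped = drop_redundant(df)
        assert list(out.columns) == ["a", "d"]
        assert set(dropped) == {"b", "c"}

    def test_three_mutually_correlated_keep_first(self, rng):
        base = rng.random(200)
        noise = lambda: rng.normal(0, 0.04, 200)  # noqa: E731 - test-local helper
        df = pd.DataFrame({"f1": base, "f2": base + noise(), "f3": base + noise()})
        corr = df.corr().abs()
        assert (corr.to_numpy()[np.triu_indices(3, 1)] > 0.95).all()
        out, dropped = drop_redundant(df)
        assert list(out.columns) == ["f1"] and dropped == ["f2", "f3"]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            drop_redundant(pd.DataFrame({"a": [1.0]}))


class TestStandardize:
    def test_groupwise_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame({"f": rng.normal(5, 3, 60), "g": rng.normal(-2, 0.5, 60)})
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=df.index)
        out = standardize(df, groups)
        for g in ("a", "b"):
            block = out[groups == g]
            assert abs(block["f"].mean()) < 1e-9
            assert block["f"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_groups_centered_independently(self, rng):
        df = pd.DataFrame({"f": np.r_[rng.normal(0, 1, 40), rng.normal(100, 1, 40)]})
        groups = pd.Series(["a"] * 40 + ["b"] * 40)
        out = standardize(df, groups)
        assert abs(out.loc[groups == "b", "f"].mean()) < 1e-9

    def test_single_group_is_global_zscore(self, rng):
        df = pd.DataFrame({"f": rng.normal(7, 2, 50)})
        out = standardize(df)
        want = (df["f"] - df["f"].mean()) / df["f"].std(ddof=0)
        assert np.allclose(out["f"], want)

    def test_zero_variance_column_warns(self):
        df = pd.DataFrame({"f": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning):
            out = standardize(df)
        assert np.all(out["f"] == 0.0)

    def test_train_fit_statistics_apply_to_held_out(self, rng):
        df = pd.DataFrame({"f": rng.normal(10, 2, 100)})
        fit_idx = df.index[:60]
        out = standardize(df, fit_on=fit_idx)
        mu = df.loc[fit_idx, "f"].mean()
        sd = df.loc[fit_idx, "f"].std(ddof=0)
        assert np.allclose(out["f"], (df["f"] - mu) / sd)
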