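"""ROI records and the three crop regimes (cell / nucleus / nucleocentric)."""

import numpy as np
import pytest

from nucleoprofile.crops import (
    CropSpec,
    RoiRecord,
    crop_all,
    crop_roi,
    extract_rois,
    patch_pixels,
    patch_size_sweep,
    speckle_background,
)
from nucleoprofile.segment import LabelMask


@pytest.fixture(scope="module")
def scene_rois(small_scene):
    _, img, truth = small_scene
    nuclei = LabelMask(truth.nuclei_mask)
    cells = LabelMask(truth.cells_mask)
    rois = extract_rois(nuclei, cells, img)
    return img, truth, nuclei, cells, rois


class TestPatchPixels:
    @pytest.mark.parametrize(
        "patch,px,expected",
        [
            (18.0, 0.325, 55),  # 18/0.325 = 55.38 → nearest odd 55
            (60.0, 0.3125, 193),  # 192 px rounded up to odd
            (60.0, 0.325, 185),
        ],
    )
    def test_nearest_odd(self, patch, px, expected):
        assert patch_pixels(patch, px) == expected

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            patch_pixels(0.6, 0.325)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            patch_pixels(0.0, 0.325)


class TestExtractRois:
    def test_records_match_truth(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        assert len(rois) == len(truth.table)
        truth_by_label = truth.table.set_index("label")
        for r in rois:
            row = truth_by_label.loc[r.label]
            assert abs(r.nuclear_centroid[0] - row.centroid_y) <= 1
            assert abs(r.nuclear_centroid[1] - row.centroid_x) <= 1
            # area equals the pixel count of the label (counting oracle)
            assert r.nuclear_area == int(np.sum(nuclei.labels == r.label))
            assert r.cell_label == r.label  # truth masks share ids

    def test_empty_mask_gives_empty_list(self, small_scene):
        _, img, _ = small_scene
        empty = LabelMask(np.zeros(img.pixels.shape[:2], dtype=int))
        assert extract_rois(empty, None, img) == []

    def test_shape_mismatch_rejected(self, small_scene):
        _, img, _ = small_scene
        bad = LabelMask(np.zeros((10, 10), dtype=int))
        with pytest.raises(ValueError):
            extract_rois(bad, None, img)


class TestCropSpec:
    def test_defaults_per_mode(self):
        assert CropSpec(mode="cell").patch_size == 60.0
        assert CropSpec(mode="nucleus").patch_size == 18.0
        assert CropSpec(mode="nucleocentric").background == "preserved"

    def test_nucleocentric_cannot_zero_background(self):
        with pytest.raises(ValueError):
            CropSpec(mode="nucleocentric", background="zeroed")

    def test_patch_range_enforced(self):
        with pytest.raises(ValueError):
            CropSpec(mode="nucleus", patch_size=200.0)


class TestCropRoi:
    def test_centering_and_shape(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        spec = CropSpec(mode="nucleocentric")
        P = patch_pixels(spec.patch_size, img.pixel_size)
        crop = crop_roi(img, rois[0], nuclei, cells, spec, normalize="none")
        assert crop.values.shape == (img.n_channels, P, P)
        # the centroid pixel lands on the central index
        cy, cx = (int(round(c)) for c in rois[0].nuclear_centroid)
        h = (P - 1) // 2
        assert crop.values[0, h, h] == img.pixels[cy, cx, 0]

    def test_nucleus_mode_zeroes_outside(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        crop = crop_roi(img, rois[0], nuclei, cells, CropSpec(mode="nucleus"), normalize="none")
        assert np.all(crop.values[:, crop.mask == 0] == 0)

    def test_mode_nesting(self, scene_rois):
        """nucleus crop = nucleocentric crop × nuclear-mask indicator."""
        img, truth, nuclei, cells, rois = scene_rois
        roi = rois[1]
        nc = crop_roi(img, roi, nuclei, cells, CropSpec(mode="nucleocentric"), normalize="none")
        nu = crop_roi(img, roi, nuclei, cells, CropSpec(mode="nucleus"), normalize="none")
        assert np.array_equal(nu.values, nc.values * nu.mask[None])

    def test_nucleocentric_preserves_neighbors(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        # pick a roi with another cell inside its window, if any
        spec = CropSpec(mode="nucleocentric", patch_size=60.0)
        for roi in rois:
            crop = crop_roi(img, roi, nuclei, cells, spec, normalize="none")
            P = crop.values.shape[-1]
            win = _window_of(cells.labels, roi, P)
            others = set(np.unique(win)) - {0, roi.label}
            if others:
                other = others.pop()
                assert np.any(crop.values[0][win == other] >= 0)  # pixels present, not zeroed
                inten = img.pixels[..., 1][cells.labels == other].mean()
                assert crop.values[1][win == other].mean() == pytest.approx(inten, rel=0.5)
                return
        pytest.skip("no neighbour inside any window for this fixture")

    def test_corner_centroid_zero_padded(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        roi = RoiRecord(
            roi_id="corner", label=rois[0].label, field=0, well="w", replicate="r",
            nuclear_centroid=(1.0, 1.0), nuclear_area=10, mean_nuclear_dapi=1.0,
        )
        crop = crop_roi(img, roi, nuclei, cells, CropSpec(mode="nucleocentric"), normalize="none")
        P = crop.values.shape[-1]
        h = (P - 1) // 2
        # index bookkeeping oracle: rows above the image edge are zero padding
        assert np.all(crop.values[:, : h - 1, :] == 0)
        assert np.array_equal(crop.values[0, h, h], img.pixels[1, 1, 0])

    def test_cell_mode_without_match_skipped(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        orphan = RoiRecord(
            roi_id="orphan", label=rois[0].label, field=0, well="w", replicate="r",
            nuclear_centroid=rois[0].nuclear_centroid, nuclear_area=5,
            mean_nuclear_dapi=1.0, cell_label=None,
        )
        assert crop_roi(img, orphan, nuclei, cells, CropSpec(mode="cell")) is None
        crops, skipped = crop_all(img, [orphan], nuclei, cells, CropSpec(mode="cell"))
        assert crops == [] and skipped == ["orphan"]


def _window_of(arr, roi, P):
    cy, cx = (int(round(c)) for c in roi.nuclear_centroid)
    h = (P - 1) // 2
    out = np.zeros((P, P), dtype=arr.dtype)
    y0, x0 = cy - h, cx - h
    sy0, sy1 = max(y0, 0), min(cy + h + 1, arr.shape[0])
    sx0, sx1 = max(x0, 0), min(cx + h + 1, arr.shape[1])
    out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = arr[sy0:sy1, sx0:sx1]
    return out


class TestSpeckle:
    def test_in_mask_untouched_and_seeded(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        crop = crop_roi(img, rois[0], nuclei, cells, CropSpec(mode="nucleus"), normalize="none")
        a = speckle_background(crop, seed=5)
        b = speckle_background(crop, seed=5)
        c = speckle_background(crop, seed=6)
        inside = crop.mask > 0
        assert np.array_equal(a.values[:, inside], crop.values[:, inside])
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_speckle_density(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        crop = crop_roi(img, rois[0], nuclei, cells, CropSpec(mode="nucleus"), normalize="none")
        out = speckle_background(crop, seed=1, density=0.5)
        bg = crop.mask == 0
        frac = np.mean(out.values[0][bg] != 0)
        assert frac == pytest.approx(0.5, abs=0.02 + 3 / np.sqrt(bg.sum()))

    def test_requires_masked_crop(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        nc = crop_roi(img, rois[0], nuclei, cells, CropSpec(mode="nucleocentric"))
        with pytest.raises(ValueError):
            speckle_background(nc, seed=0)


class TestSweep:
    def test_aligned_sets_and_nesting(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        out = patch_size_sweep(img, rois, nuclei, cells, [12.0, 18.0, 60.0], normalize="none")
        assert sorted(out) == [12.0, 18.0, 60.0]
        assert {len(v) for v in out.values()} == {len(rois)}
        # 18 µm crop is the centered sub-window of the 60 µm crop
        big = out[60.0][0].values
        small = out[18.0][0].values
        Pb, Ps = big.shape[-1], small.shape[-1]
        off = (Pb - Ps) // 2
        assert np.array_equal(small, big[:, off : off + Ps, off : off + Ps])

    def test_degenerate_size_skipped(self, scene_rois, caplog):
        img, truth, nuclei, cells, rois = scene_rois
        out = patch_size_sweep(img, rois, nuclei, cells, [0.6, 18.0])
        assert list(out) == [18.0]

    def test_empty_sizes(self, scene_rois):
        img, truth, nuclei, cells, rois = scene_rois
        assert patch_size_sweep(img, rois, nuclei, cells, []) == {}
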