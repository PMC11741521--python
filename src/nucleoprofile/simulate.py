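"""Seeded generator of multi-channel cell-painting-like scenes with exact truth.

Each scene holds a configurable number of cells from two or more classes.
Nuclei are noisy ellipses (eccentricity ≤ 0.8); cytoplasm is an angularly
perturbed hull dilated around the nucleus. Channel 0 is nuclear; channels
1..3 carry cytoplasmic/perinuclear texture with class-specific correlation
length (grain) and gain, emulating the organelle dyes of a cell-painting
panel. A second "ground-truth" imaging round renders a DAPI-like channel
plus marker channels whose per-nucleus intensity depends on the class, and
is displaced by a stage shift, emulating cyclic immunofluorescence.

All randomness flows through one numpy Generator derived from the config
seed; identical configs render bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import MultiChannelImage, ShiftVector, apply_shift

__all__ = [
    "ClassProfile",
    "SceneConfig",
    "SceneTruth",
    "PlacementError",
    "render_scene",
    "render_ground_truth_round",
    "density_series",
    "two_class_profiles",
    "DEFAULT_CHANNELS",
]

DEFAULT_CHANNELS = ["DAPI", "FITC", "Cy3", "Cy5"]


class PlacementError(RuntimeError):
    """Raised when the requested cell count cannot be placed in the field."""


@dataclass(frozen=True)
class ClassProfile:
    """Morphological and marker phenotype of one cell class.

    Radii and extents are in µm; channel_gains are relative intensities, one
    per morphological channel; marker_means are mean ground-truth marker
    intensities in arbitrary units.
    """

    name: str
    nuclear_radius_mean: float = 5.0
    nuclear_radius_sd: float = 0.5
    cyto_extent_mean: float = 3.0
    cyto_extent_sd: float = 0.8
    texture_grain: float = 1.0
    channel_gains: tuple = (1.0, 1.0, 1.0, 1.0)
    marker_means: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nuclear_radius_mean <= 0 or self.cyto_extent_mean <= 0:
            raise ValueError("radii and extents must be strictly positive")
        if self.texture_grain <= 0:
            raise ValueError("texture_grain must be strictly positive")


@dataclass(frozen=True)
class SceneConfig:
    """One synthetic field of view."""

    field_size: tuple = (512, 512)
    pixel_size: float = 0.325  # µm/pixel
    classes: tuple = ()
    target_count: int = 50
    overlap_policy: str = "none"  # none | allow | crowded
    noise_floor: float = 0.02
    seed: int = 0
    well: str = "A1"
    replicate: str = "rep1"
    field_id: int = 0

    def __post_init__(self) -> None:
        if self.target_count < 0:
            raise ValueError("target_count must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.overlap_policy not in ("none", "allow", "crowded"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")
        if not self.classes:
            object.__setattr__(self, "classes", two_class_profiles())


@dataclass
class SceneTruth:
    """Exact per-scene ground truth: instance masks and a per-cell table."""

    nuclei_mask: np.ndarray
    cells_mask: np.ndarray
    table: pd.DataFrame  # label, class_name, centroid_y/x, nuclear_area_px, well, replicate, field

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.table["label"])


def two_class_profiles(
    radius_ratio: float = 2.0,
    base_radius: float = 4.0,
    texture_contrast: bool = False,
    n_channels: int = 4,
) -> tuple:
    """Two classes differing in nuclear size by `radius_ratio` (and optionally
    texture grain), with swapped marker intensities for intensity gating.

    radius_ratio=1.0 yields morphologically identical classes (the null)."""
    gains = tuple(1.0 for _ in range(n_channels))
    return (
        ClassProfile(
            name="alpha",
            nuclear_radius_mean=base_radius,
            nuclear_radius_sd=0.1 * base_radius,
            texture_grain=1.0,
            channel_gains=gains,
            marker_means={"markerA": 1000.0, "markerB": 100.0},
        ),
        ClassProfile(
            name="beta",
            nuclear_radius_mean=base_radius * radius_ratio,
            nuclear_radius_sd=0.1 * base_radius * radius_ratio,
            texture_grain=1.8 if texture_contrast else 1.0,
            channel_gains=gains,
            marker_means={"markerA": 100.0, "markerB": 1000.0},
        ),
    )


# ---------------------------------------------------------------------------
# geometry helpers

def _radial_profile(rng: np.random.Generator, n_harmonics: int = 4, amp: float = 0.25):
    """Random smooth angular perturbation r(θ)/r0 built from low-order harmonics."""
    ks = np.arange(2, 2 + n_harmonics)
    amps = rng.uniform(0, amp / n_harmonics, n_harmonics)
    phases = rng.uniform(0, 2 * np.pi, n_harmonics)

    def profile(theta):
        return 1.0 + sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, ks, phases))

    return profile


def _sample_cells(rng: np.random.Generator, config: SceneConfig) -> list[dict]:
    """Sample class, geometry and position for each cell; raise PlacementError
    if the requested count cannot be placed under the overlap policy."""
    H, W = config.field_size
    px = config.pixel_size
    cells: list[dict] = []
    max_attempts = 200 * max(config.target_count, 1)
    attempts = 0
    while len(cells) < config.target_count:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed {len(cells)}/{config.target_count} cells after "
                f"{attempts} attempts (policy={config.overlap_policy!r})"
            )
        attempts += 1
        cls_idx = int(rng.integers(len(config.classes)))
        cls = config.classes[cls_idx]
        r_nuc = max(rng.normal(cls.nuclear_radius_mean, cls.nuclear_radius_sd), 0.5) / px
        ext = max(rng.normal(cls.cyto_extent_mean, cls.cyto_extent_sd), 0.5) / px
        r_cell = r_nuc + ext
        margin = 2.0
        if 2 * (r_cell + margin) > min(H, W):
            raise PlacementError(
                f"field {config.field_size} too small for cell radius {r_cell:.1f} px"
            )
        cy = rng.uniform(r_nuc + margin, H - r_nuc - margin)
        cx = rng.uniform(r_nuc + margin, W - r_nuc - margin)
        ok = True
        for other in cells:
            d = np.hypot(cy - other["cy"], cx - other["cx"])
            if config.overlap_policy == "none":
                if d < r_cell + other["r_cell"] + 1:
                    ok = False
                    break
            elif config.overlap_policy == "allow":
                # cytoplasm may overlap but nuclei stay disjoint
                if d < r_nuc + other["r_nuc"] + 2:
                    ok = False
                    break
            else:  # crowded: nuclei may touch, centres must stay distinct
                if d < 0.8 * max(r_nuc, other["r_nuc"]):
                    ok = False
                    break
        if not ok:
            continue
        ecc = rng.uniform(0.0, 0.8)
        cells.append(
            dict(
                cls_idx=cls_idx,
                cy=cy,
                cx=cx,
                r_nuc=r_nuc,
                r_cell=r_cell,
                ecc=ecc,
                phi=rng.uniform(0, np.pi),
                nuc_profile=_radial_profile(rng, amp=0.15),
                cell_profile=_radial_profile(rng, amp=0.5),
            )
        )
    return cells


def _rasterize(cells: list[dict], shape) -> tuple[np.ndarray, np.ndarray]:
    """Paint nuclei and cell footprints; contested pixels go to the nearest
    centre, and touching nuclei are separated by a 1-px gap so instances stay
    resolvable."""
    H, W = shape
    nuclei = np.zeros((H, W), dtype=np.int32)
    cells_mask = np.zeros((H, W), dtype=np.int32)
    depth_nuc = np.full((H, W), np.inf)
    depth_cell = np.full((H, W), np.inf)
    for i, c in enumerate(cells, start=1):
        R = int(np.ceil(c["r_cell"] * 1.6)) + 2
        y0, y1 = max(0, int(c["cy"]) - R), min(H, int(c["cy"]) + R + 1)
        x0, x1 = max(0, int(c["cx"]) - R), min(W, int(c["cx"]) + R + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - c["cy"], xx - c["cx"]
        theta = np.arctan2(dy, dx)
        # anisotropic (elliptical) radius for the nucleus, area-preserving
        q = (1 - c["ecc"] ** 2) ** 0.25
        ca, sa = np.cos(c["phi"]), np.sin(c["phi"])
        u = dx * ca + dy * sa
        v = -dx * sa + dy * ca
        r_ell = np.hypot(u * q, v / q)  # a = r/q, b = r*q
        nuc_r = c["r_nuc"] * c["nuc_profile"](theta)
        cell_r = c["r_cell"] * np.maximum(c["cell_profile"](theta), 0.2)
        rel_nuc = r_ell / np.maximum(nuc_r, 1e-6)
        rel_cell = np.hypot(dy, dx) / np.maximum(cell_r, 1e-6)
        # nucleus must sit inside its cell footprint
        rel_cell = np.minimum(rel_cell, rel_nuc)
        in_nuc = rel_nuc <= 1.0
        in_cell = rel_cell <= 1.0
        win_nuc = in_nuc & (rel_nuc < depth_nuc[y0:y1, x0:x1])
        win_cell = in_cell & (rel_cell < depth_cell[y0:y1, x0:x1])
        nuclei[y0:y1, x0:x1][win_nuc] = i
        cells_mask[y0:y1, x0:x1][win_cell] = i
        depth_nuc[y0:y1, x0:x1][win_nuc] = rel_nuc[win_nuc]
        depth_cell[y0:y1, x0:x1][win_cell] = rel_cell[win_cell]
    _separate_touching(nuclei)
    return nuclei, cells_mask


def _separate_touching(labels: np.ndarray) -> None:
    """Carve a 1-px background gap between distinct touching labels, in place."""
    from scipy.ndimage import maximum_filter

    pos = labels > 0
    mx = maximum_filter(labels, size=3)
    mn = -maximum_filter(np.where(pos, -labels, -(2**30)), size=3)
    contested = pos & (mx != labels)
    contested |= pos & (mn != labels) & (mn < 2**30)
    labels[contested] = 0


def _cell_texture(rng, shape, grain_px: float) -> np.ndarray:
    """Band-limited multiplicative texture patch for one cell and channel.

    Per-cell draws keep cells statistically independent: no field- or
    well-level texture fingerprint exists for a classifier to latch onto,
    so class information flows only through the profile parameters.
    """
    noise = gaussian_filter(rng.standard_normal(shape), max(grain_px, 0.5))
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    return np.clip(1.0 + 0.45 * noise, 0.05, None)


def render_scene(config: SceneConfig) -> tuple[MultiChannelImage, SceneTruth]:
    """Render one field and its exact truth.

    The image has one channel per morphological channel (channel 0 nuclear).
    Identical configs (including seed) give bit-identical pixels and tables.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.field_size
    n_ch = len(config.classes[0].channel_gains)
    cells = _sample_cells(rng, config)
    nuclei, cells_mask = _rasterize(cells, (H, W))

    img = np.zeros((H, W, n_ch), dtype=np.float64)
    dist_weight = _perinuclear_weight(nuclei, cells_mask)
    from scipy.ndimage import find_objects

    slices = find_objects(cells_mask)
    for i, c in enumerate(cells, start=1):
        sl = slices[i - 1] if i - 1 < len(slices) else None
        if sl is None:
            continue
        cls = config.classes[c["cls_idx"]]
        grain_px = cls.texture_grain / config.pixel_size
        local_shape = (sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
        nuc_px = nuclei[sl] == i
        cell_px = cells_mask[sl] == i
        tex0 = _cell_texture(rng, local_shape, grain_px)
        img[sl + (0,)][nuc_px] += 0.85 * cls.channel_gains[0] * tex0[nuc_px]
        for ch in range(1, n_ch):
            tex = _cell_texture(rng, local_shape, grain_px)
            body = 0.55 * cls.channel_gains[ch] * tex
            img[sl + (ch,)][cell_px] += (body * (0.4 + 0.6 * dist_weight[sl]))[cell_px]
    img += rng.normal(0.0, config.noise_floor, img.shape)
    img = np.clip(img, 0.0, None).astype(np.float32)

    areas = np.bincount(nuclei.ravel(), minlength=len(cells) + 1)
    from scipy.ndimage import center_of_mass

    coms = center_of_mass(np.ones_like(nuclei), nuclei, index=range(1, len(cells) + 1))
    rows = []
    for i, c in enumerate(cells, start=1):
        area = int(areas[i])
        cy, cx = (float(coms[i - 1][0]), float(coms[i - 1][1])) if area else (c["cy"], c["cx"])
        rows.append(
            dict(
                label=i,
                class_name=config.classes[c["cls_idx"]].name,
                centroid_y=cy,
                centroid_x=cx,
                nuclear_area_px=area,
                well=config.well,
                replicate=config.replicate,
                field=config.field_id,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "class_name", "centroid_y", "centroid_x",
            "nuclear_area_px", "well", "replicate", "field",
        ],
    )
    mci = MultiChannelImage(
        img,
        DEFAULT_CHANNELS[:n_ch] if n_ch <= 4 else [f"ch{i}" for i in range(n_ch)],
        config.pixel_size,
        {"well": config.well, "replicate": config.replicate, "field": config.field_id},
    )
    return mci, SceneTruth(nuclei, cells_mask, table)


def _perinuclear_weight(nuclei: np.ndarray, cells_mask: np.ndarray) -> np.ndarray:
    """Weight in [0,1] decaying away from the nuclear rim, for perinuclear dyes."""
    from scipy.ndimage import distance_transform_edt

    dist = distance_transform_edt(nuclei == 0)
    w = np.exp(-dist / 8.0)
    w[nuclei > 0] = 1.0
    return w


def render_ground_truth_round(
    scene: SceneTruth,
    config: SceneConfig,
    shift: tuple[int, int] = (0, 0),
    markers: list[str] | None = None,
    marker_cv: float = 0.08,
    seed_offset: int = 1,
) -> MultiChannelImage:
    """Render the post-hoc staining round: DAPI-like channel + marker channels.

    Per-nucleus marker intensity is drawn around the class marker_mean with
    coefficient of variation `marker_cv`. The rendered round is displaced so
    that registering it against round 1 reports exactly `shift` — i.e.
    ``apply_shift(gt_round, ShiftVector(*shift))`` re-aligns it.
    """
    class_by_name = {c.name: c for c in config.classes}
    if markers is None:
        markers = sorted({m for c in config.classes for m in c.marker_means})
    for m in markers:
        if any(m not in c.marker_means for c in config.classes):
            raise ValueError(f"marker {m!r} missing from a class profile")
    rng = np.random.default_rng(config.seed + seed_offset)
    H, W = scene.nuclei_mask.shape
    img = np.zeros((H, W, 1 + len(markers)), dtype=np.float64)
    from scipy.ndimage import find_objects

    slices = find_objects(scene.nuclei_mask)
    for _, row in scene.table.iterrows():
        cls = class_by_name[row["class_name"]]
        lbl = int(row["label"])
        sl = slices[lbl - 1] if lbl - 1 < len(slices) else None
        if sl is None:
            continue
        nuc = scene.nuclei_mask[sl] == lbl
        img[sl + (0,)][nuc] = rng.normal(800.0, 40.0)
        for mi, m in enumerate(markers, start=1):
            mean = cls.marker_means[m]
            img[sl + (mi,)][nuc] = max(rng.normal(mean, marker_cv * mean), 0.0)
    img += np.abs(rng.normal(0.0, 8.0, img.shape))
    mci = MultiChannelImage(
        np.clip(img, 0.0, None).astype(np.float32),
        ["DAPI_gt"] + list(markers),
        config.pixel_size,
        {"well": config.well, "replicate": config.replicate, "field": config.field_id},
    )
    dy, dx = int(shift[0]), int(shift[1])
    if (dy, dx) != (0, 0):
        mci = apply_shift(mci, ShiftVector(-dy, -dx))
    return mci


def density_series(
    config: SceneConfig, levels: list[int]
) -> list[tuple[MultiChannelImage, SceneTruth]]:
    """Render one scene per confluency level (ascending target counts)."""
    if list(levels) != sorted(levels):
        raise ValueError("levels must be sorted ascending")
    out = []
    for i, n in enumerate(levels):
        cfg = replace(config, target_count=int(n), seed=config.seed + 1000 * i, field_id=config.field_id + i)
        out.append(render_scene(cfg))
    return out
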