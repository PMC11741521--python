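"""Input-quality erosion: spatial pixel binning and SNR-controlled Gaussian
noise, applied to full fields before cropping (matching the pipeline order).

SNR uses the amplitude convention ``20·log10(RMS_signal / σ_noise)``, which
makes :func:`add_noise` and :func:`measure_snr` a self-consistent pair; the
convention is recorded in every output's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import MultiChannelImage

__all__ = ["DegradationSpec", "bin_pixels", "add_noise", "measure_snr", "SNR_CONVENTION"]

SNR_CONVENTION = "amplitude: 20*log10(rms_signal/sigma_noise)"


@dataclass(frozen=True)
class DegradationSpec:
    """One degradation step: spatial binning or additive Gaussian noise."""

    mode: str  # "bin" | "noise"
    bin_factor: int | None = None
    target_snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("bin", "noise"):
            raise ValueError(f"unknown degradation mode {self.mode!r}")
        if self.mode == "bin" and (self.bin_factor is None or self.bin_factor < 1):
            raise ValueError("bin mode needs an integer factor >= 1")
        if self.mode == "noise" and (
            self.target_snr_db is None or not np.isfinite(self.target_snr_db)
        ):
            raise ValueError("noise mode needs a finite target SNR (dB)")


def bin_pixels(img: MultiChannelImage, factor: int) -> MultiChannelImage:
    """Average non-overlapping factor×factor blocks; edge blocks average the
    available pixels. Output extent is ⌈n/factor⌉ and pixel_size scales by
    `factor`, emulating acquisition at a coarser pixel pitch."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    H, W = img.pixels.shape[-3], img.pixels.shape[-2]
    if factor > max(H, W):
        raise ValueError(f"factor {factor} exceeds image extent {(H, W)}")
    if factor == 1:
        return img.with_pixels(img.pixels.copy())
    arr = img.pixels.astype(np.float64)
    idx_h = np.arange(0, H, factor)
    idx_w = np.arange(0, W, factor)
    sums = np.add.reduceat(np.add.reduceat(arr, idx_h, axis=-3), idx_w, axis=-2)
    ch = np.add.reduceat(np.ones(H), idx_h)
    cw = np.add.reduceat(np.ones(W), idx_w)
    out = sums / (ch[:, None, None] * cw[None, :, None])
    # float64 output: block averaging conserves the global mean exactly on
    # divisible extents
    return img.with_pixels(
        out,
        pixel_size=img.pixel_size * factor,
        metadata={"binned_by": factor},
    )


def add_noise(
    img: MultiChannelImage, target_snr_db: float, seed: int = 0, clip: bool = True
) -> MultiChannelImage:
    """Add zero-mean Gaussian noise with σ = RMS(img) / 10^(SNR_dB/20).

    Negative intensities are clipped to the valid range by default; the
    add/measure round-trip identity holds pre-clipping (``clip=False``), and
    clipping biases the measured SNR upward once a noticeable fraction of
    pixels clips (low targets on dim images)."""
    if not np.isfinite(target_snr_db):
        raise ValueError("target SNR must be finite")
    arr = img.pixels.astype(np.float64)
    rms = float(np.sqrt(np.mean(arr**2)))
    if rms <= 0:
        raise ValueError("image RMS is non-positive; SNR undefined")
    sigma = rms / 10.0 ** (target_snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noisy = arr + rng.normal(0.0, sigma, arr.shape)
    if clip:
        noisy = np.clip(noisy, 0.0, None)
    return img.with_pixels(
        noisy.astype(np.float32),
        metadata={"target_snr_db": float(target_snr_db), "snr_convention": SNR_CONVENTION},
    )


def measure_snr(clean: MultiChannelImage | np.ndarray, noisy: MultiChannelImage | np.ndarray) -> float:
    """20·log10(RMS(clean) / SD(noisy − clean)); +inf for identical images."""
    a = (clean.pixels if isinstance(clean, MultiChannelImage) else np.asarray(clean)).astype(np.float64)
    b = (noisy.pixels if isinstance(noisy, MultiChannelImage) else np.asarray(noisy)).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    resid_sd = float((b - a).std())
    if resid_sd == 0:
        return float("inf")
    rms = float(np.sqrt(np.mean(a**2)))
    return 20.0 * np.log10(rms / resid_sd)
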