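"""Convert a raw fluorescence video into an SNR video.

Three steps: a spatial homomorphic filter removes multiplicative,
spatially broad illumination/background structure; a temporal matched
filter shaped like a calcium transient boosts transient SNR; per-pixel
whitening (subtract the temporal median, divide by the quantile-based
standard deviation) expresses every pixel in noise units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .datatypes import VideoStack
from .noise_stats import _NORMAL_Q75

__all__ = [
    "FilterKernel",
    "SnrParams",
    "homomorphic_filter",
    "build_matched_kernel",
    "apply_matched_filter",
    "whiten_pixels",
    "generate_snr_video",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
_WHITEN_EPS = 1e-9


@dataclass
class FilterKernel:
    """Temporal matched-filter taps (the transient template, unit L2
    norm) and the frame rate they were sampled at."""

    taps: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=np.float64)
        if self.taps.ndim != 1 or self.taps.size == 0:
            raise ValueError("kernel taps must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.taps)) or np.any(self.taps < 0):
            raise ValueError("kernel taps must be finite and non-negative")
        norm = np.linalg.norm(self.taps)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("kernel taps must have unit L2 norm")

    def __len__(self) -> int:
        return self.taps.size


@dataclass
class SnrParams:
    """Settings for SNR-video generation; FWHM and pixel size in microns,
    transient time constants in seconds."""

    spatial_fwhm_um: float = 50.0
    pixel_size_um: float = 1.0
    decay_s: float = 0.2
    rise_s: float = 0.0
    log_offset: float = 1.0


def homomorphic_filter(
    video: VideoStack,
    spatial_fwhm_um: float,
    pixel_size_um: float,
    log_offset: float = 1.0,
) -> VideoStack:
    """Remove multiplicative, spatially broad background per frame.

    Each frame is log-transformed (with an additive offset so zeros are
    defined), a Gaussian low-pass of the log image is subtracted, and the
    result is exponentiated.  Adding back the per-frame mean of the
    low-pass preserves the overall intensity scale, so a spatially
    uniform frame passes through unchanged.
    """
    if spatial_fwhm_um <= 0:
        raise ValueError("spatial_fwhm must be positive")
    if spatial_fwhm_um <= pixel_size_um:
        raise ValueError("spatial_fwhm must exceed the pixel size")
    if video.kind != "raw":
        raise ValueError("homomorphic filtering expects a raw-kind video")
    sigma_px = spatial_fwhm_um / pixel_size_um * _FWHM_TO_SIGMA
    log_img = np.log(video.data.astype(np.float64) + log_offset)
    lowpass = gaussian_filter(log_img, sigma=(0.0, sigma_px, sigma_px), mode="reflect")
    out = np.exp(log_img - lowpass + lowpass.mean(axis=(1, 2), keepdims=True)) - log_offset
    np.clip(out, 0.0, None, out=out)
    return VideoStack(out.astype(np.float32), video.frame_rate, kind="raw")


def build_matched_kernel(decay_s: float, rise_s: float, frame_rate: float) -> FilterKernel:
    """Sample a difference-of-exponentials transient template.

    The template ``exp(-t/decay) - exp(-t/rise)`` (pure decay when
    ``rise_s == 0``) is peak-normalized, truncated once the tail falls
    below 1% of the peak, and L2-normalized.  Matched filtering is
    cross-correlation with these taps.
    """
    if decay_s <= 0:
        raise ValueError("decay_s must be positive")
    if rise_s < 0:
        raise ValueError("rise_s must be >= 0")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    # sample generously, then truncate at 1% of the peak
    n = max(int(np.ceil(10.0 * decay_s * frame_rate)), 2)
    t = np.arange(n) / frame_rate
    template = np.exp(-t / decay_s)
    if rise_s > 0:
        template = template - np.exp(-t / rise_s)
    peak = template.max()
    if peak <= 0:
        raise ValueError("degenerate template (rise >= decay?)")
    template = template / peak
    ipeak = int(np.argmax(template))
    below = np.flatnonzero(template[ipeak:] < 0.01)
    if below.size:
        template = template[: ipeak + below[0]]
    template = np.clip(template, 0.0, None)
    template /= np.linalg.norm(template)
    return FilterKernel(template, frame_rate)


def apply_matched_filter(x: np.ndarray, kernel: FilterKernel) -> np.ndarray:
    """Cross-correlate a time series with the transient template.

    The template is anchored at the current frame (``y[t] = sum_k
    w[k] x[t+k]``) so the response peaks at the transient onset and event
    timing is not shifted.  The series is extended by edge replication so
    every output frame sees a full-length kernel: this keeps the baseline
    level consistent across the whole trace (a partial-kernel
    renormalization would step the DC level near the end); the last
    ``len(kernel)-1`` frames are edge-affected.
    """
    x = np.asarray(x, dtype=np.float64)
    w = kernel.taps
    k = w.size
    if x.ndim != 1:
        raise ValueError("apply_matched_filter expects a 1-D series")
    if k == 1:
        return x * np.sign(w[0])
    padded = np.concatenate([x, np.full(k - 1, x[-1])])
    return fftconvolve(padded, w[::-1], mode="full")[k - 1 : k - 1 + x.size]


def whiten_pixels(video: VideoStack) -> VideoStack:
    """Whiten each pixel's time series to noise units.

    Subtracts the temporal median and divides by the quantile-based
    standard deviation (floored at 1e-9 so dead pixels map to zero).
    """
    if video.n_frames < 2:
        raise ValueError("whitening needs at least 2 frames")
    data = video.data.astype(np.float64)
    q25, q50 = np.quantile(data, [0.25, 0.5], axis=0)
    noise = (q50 - q25) / _NORMAL_Q75
    out = (data - q50) / np.maximum(noise, _WHITEN_EPS)
    return VideoStack(out.astype(np.float32), video.frame_rate, kind="snr")


def generate_snr_video(video: VideoStack, params: SnrParams | None = None) -> VideoStack:
    """Full raw→SNR conversion: homomorphic filter, temporal matched
    filter, per-pixel whitening."""
    if params is None:
        params = SnrParams()
    if video.kind != "raw":
        raise ValueError("generate_snr_video expects a raw-kind video")
    filtered = homomorphic_filter(
        video, params.spatial_fwhm_um, params.pixel_size_um, params.log_offset
    )
    kernel = build_matched_kernel(params.decay_s, params.rise_s, video.frame_rate)
    data = filtered.data.astype(np.float64)
    flat = data.reshape(data.shape[0], -1)
    # correlate all pixels at once along the time axis, edge-replicated
    w = kernel.taps
    k = w.size
    padded = np.concatenate([flat, np.repeat(flat[-1:], k - 1, axis=0)], axis=0)
    out_flat = fftconvolve(padded, w[::-1, None], mode="full", axes=0)[
        k - 1 : k - 1 + flat.shape[0]
    ]
    stage = VideoStack(
        out_flat.reshape(data.shape).astype(np.float32), video.frame_rate, kind="raw"
    )
    return whiten_pixels(stage)
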