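"""Transient detection by SNR thresholding.

Experimental traces are first matched-filtered (unless they came from an
SNR video, which is already filtered), then normalized to noise units by
subtracting the kernel-density baseline and dividing by the
PSD-estimated noise.  Frames above th_SNR are grouped into candidate
periods; a period is kept if it contains a peak with prominence at
least th_SNR/3, and split at the local minima between multiple
prominent peaks.  Ground-truth transients for simulated clean traces use
the same machinery with a data-derived threshold: half of the typical
single-event peak height (the mode of the peak-height density).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .datatypes import DetectionConfig, Transient
from .noise_stats import kde_baseline, psd_noise
from .snr_video import apply_matched_filter, build_matched_kernel

__all__ = [
    "snr_normalize_trace",
    "detect_transients",
    "gt_transients_from_clean_trace",
]

_NOISE_EPS = 1e-9


def snr_normalize_trace(
    trace: np.ndarray, frame_rate: float, cfg: DetectionConfig
) -> np.ndarray:
    """Convert a trace to SNR units.

    Matched-filter first when ``cfg.apply_temporal_filter`` (traces from
    raw videos), then subtract the density-mode baseline and divide by
    the high-frequency PSD noise estimate.
    """
    x = np.asarray(trace, dtype=np.float64)
    if x.size < 16:
        raise ValueError("snr_normalize_trace needs at least 16 frames")
    # noise from the unfiltered series: the matched kernel has unit L2
    # norm, so white-noise variance is preserved through the filter while
    # the high-frequency PSD band of the *filtered* series would be
    # biased low by the kernel's low-pass response
    noise = psd_noise(x, frame_rate)
    if cfg.apply_temporal_filter:
        kernel = build_matched_kernel(cfg.decay_s, cfg.rise_s, frame_rate)
        x = apply_matched_filter(x, kernel)
    baseline = kde_baseline(x)
    return (x - baseline) / max(noise, _NOISE_EPS)


def _prominent_peaks(x: np.ndarray, prominence: float) -> np.ndarray:
    """Peak frames with at least the given topographic prominence;
    plateau peaks report their leftmost frame."""
    _, props = find_peaks(x, prominence=prominence, plateau_size=(1, None))
    return props["left_edges"].astype(int)


def _segment_active_periods(x: np.ndarray, th: float, prominence: float) -> list[Transient]:
    """Shared period/peak/split logic.

    Active frames are those strictly above ``th``; runs of consecutive
    active frames form candidate periods.  A period with no prominent
    peak is discarded; with one peak it becomes a single transient; with
    several it is split at the (leftmost) local minimum between each
    consecutive peak pair — the frame before a boundary minimum ends the
    preceding transient and the frame after it starts the next.
    """
    active = x > th
    if not active.any():
        return []
    peaks = _prominent_peaks(x, prominence)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    out: list[Transient] = []
    for s, e_excl in zip(edges[::2], edges[1::2]):
        e = int(e_excl) - 1
        s = int(s)
        in_period = peaks[(peaks >= s) & (peaks <= e)]
        if in_period.size == 0:
            continue
        if in_period.size == 1:
            out.append(Transient(s, e, int(in_period[0])))
            continue
        start = s
        for p1, p2 in zip(in_period[:-1], in_period[1:]):
            m = int(p1) + int(np.argmin(x[p1 : p2 + 1]))  # leftmost minimum
            m = min(max(m, start + 1), int(p2) - 1)  # keep one frame per side
            out.append(Transient(start, m - 1, int(p1)))
            start = m + 1
        out.append(Transient(start, e, int(in_period[-1])))
    return out


def detect_transients(snr_trace: np.ndarray, cfg: DetectionConfig) -> list[Transient]:
    """Detect transients on an SNR-normalized trace.

    Threshold ``cfg.th_snr`` defines activity (strictly above); peak
    prominence must reach ``cfg.th_snr * cfg.prominence_factor``.
    """
    x = np.asarray(snr_trace, dtype=np.float64)
    return _segment_active_periods(x, cfg.th_snr, cfg.th_snr * cfg.prominence_factor)


def gt_transients_from_clean_trace(
    gt_trace: np.ndarray, frame_rate: float, cfg: DetectionConfig
) -> list[Transient]:
    """Ground-truth transients from a noiseless simulated trace.

    The clean trace is temporally filtered like experimental traces
    (when ``cfg.apply_temporal_filter``), peaks with prominence of at
    least the trace's standard deviation are collected, and the typical
    single-event height ĥ is the mode of the kernel density of peak
    heights.  Both the activity threshold and the minimum prominence are
    then ĥ/2, and the standard period/peak/split processing applies.
    """
    x = np.asarray(gt_trace, dtype=np.float64)
    if cfg.apply_temporal_filter:
        kernel = build_matched_kernel(cfg.decay_s, cfg.rise_s, frame_rate)
        x = apply_matched_filter(x, kernel)
    sd = float(x.std())
    if sd == 0:
        return []
    peaks = _prominent_peaks(x, sd)
    if peaks.size == 0:
        return []
    heights = x[peaks]
    if heights.size < 2 or np.ptp(heights) == 0:
        h_typ = float(heights[0])
    else:
        h_typ = kde_baseline(heights)  # density mode of the peak heights
    th = h_typ / 2.0
    return _segment_active_periods(x, th, th)
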