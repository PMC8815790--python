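"""Robust estimators shared across the pipeline.

Calcium traces are dominated by a quiet baseline interrupted by sparse
positive transients, so the usual mean/std are biased upward by activity.
The estimators here look only at the lower half of the distribution
(quantile-based spread), the density mode (baseline), or the
high-frequency band of the spectrum (noise), all of which are blind to
sparse transients.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.stats import gaussian_kde

__all__ = ["quantile_std", "kde_baseline", "psd_noise"]

#: (Q75 - Q50) of a unit normal; rescales the Q25..Q50 gap to a standard
#: deviation.
_NORMAL_Q75 = 0.6745

#: fraction of the Nyquist range treated as "high frequency" (top half).
_HF_CUTOFF_FRACTION = 0.5


def quantile_std(x: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Quantile-based standard deviation: (median - Q25) / 0.6745.

    For a Gaussian this equals the standard deviation; sparse positive
    transients only affect quantiles above the median, so the estimate
    reflects baseline noise.  Quantiles use linear interpolation.  A
    constant series returns 0.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[axis] if axis is not None else x.size
    if n < 2:
        raise ValueError("quantile_std needs at least 2 samples")
    q25, q50 = np.quantile(x, [0.25, 0.5], axis=axis)
    out = (q50 - q25) / _NORMAL_Q75
    return float(out) if np.ndim(out) == 0 else out


def kde_baseline(x: np.ndarray) -> float:
    """Baseline of a trace as the mode of a Gaussian kernel density.

    Silverman's rule sets the bandwidth; the argmax is taken over a
    256-point grid spanning [min, max].  Because the baseline occupies
    most frames, the density peaks there even with frequent transients.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("kde_baseline needs at least 2 samples")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return lo
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(lo, hi, 256)
    return float(grid[int(np.argmax(kde(grid)))])


def psd_noise(x: np.ndarray, frame_rate: float = 1.0) -> float:
    """Noise level from the high-frequency band of the power spectrum.

    Welch's method estimates the one-sided power spectral density; the
    mean density over frequencies above half of Nyquist is converted back
    to a standard deviation (white noise of std sigma returns ~sigma).
    Calcium transients are slow, so their energy stays below the band.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 16:
        raise ValueError("psd_noise needs at least 16 samples")
    nyquist = frame_rate / 2.0
    freqs, pxx = signal.welch(x, fs=frame_rate, nperseg=min(256, x.size))
    band = freqs >= _HF_CUTOFF_FRACTION * nyquist
    return float(np.sqrt(np.mean(pxx[band]) * nyquist))
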