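"""Core containers shared across the pipeline.

All arrays are numpy; videos are stored (T, H, W) with frame index on
axis 0 and 0-based (row, column) coordinates.  Intermediate computation
is done in float32 or wider.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VideoStack",
    "NeuronMasks",
    "RunConfig",
    "RegionSet",
    "TraceBundle",
    "TraceMatrix",
    "UnmixResult",
    "Transient",
    "DetectionConfig",
    "EvalScores",
    "MaskMatch",
]


@dataclass
class VideoStack:
    """A fluorescence video: raw intensities or SNR (whitened) values.

    Parameters
    ----------
    data
        (T, H, W) array, frame index first.
    frame_rate
        Acquisition rate in frames/s.
    kind
        ``"raw"`` (non-negative intensities) or ``"snr"`` (real-valued,
        noise-normalized).
    """

    data: np.ndarray
    frame_rate: float
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"video dataset not 3-D (got ndim={self.data.ndim})")
        if self.data.size == 0:
            raise ValueError("empty video")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("video contains non-finite values")
        if self.kind not in ("raw", "snr"):
            raise ValueError(f"unknown video kind {self.kind!r}")
        if self.kind == "raw" and self.data.min() < 0:
            raise ValueError("raw-kind video contains negative values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_spatial(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class NeuronMasks:
    """Binary neuron footprints sharing one spatial grid.

    ``masks`` is an (N, H, W) boolean array; ``ids`` are stable integer
    labels in storage order.
    """

    masks: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (N, H, W)")
        areas = self.masks.sum(axis=(1, 2))
        if np.any(areas == 0):
            bad = int(np.flatnonzero(areas == 0)[0])
            raise ValueError(f"empty mask at index {bad}")
        if self.ids is None:
            self.ids = np.arange(self.masks.shape[0])
        else:
            self.ids = np.asarray(self.ids, dtype=int)
            if self.ids.shape[0] != self.masks.shape[0]:
                raise ValueError("ids length must match mask count")

    def __len__(self) -> int:
        return self.masks.shape[0]

    @property
    def shape_spatial(self) -> tuple[int, int]:
        return self.masks.shape[1:]


@dataclass
class RunConfig:
    """Pipeline settings; defaults match the reference method's settings
    (l1 ratio 0.5, at most 20,000 NMF iterations, tolerance 1e-4)."""

    alpha_initial: float = 1.0
    l1_ratio: float = 0.5
    th_snr: float = 4.0
    downsample_ratio: int = 1
    use_snr_video: bool = False
    workers: int = 1
    seed: int = 0
    max_iter: int = 20000
    tol: float = 1e-4
    alpha_floor: float = 1e-4
    epsilon_zero: float = 1e-9

    def __post_init__(self) -> None:
        if self.alpha_initial < 0:
            raise ValueError("alpha_initial must be >= 0")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must lie in [0, 1]")
        if self.downsample_ratio < 1:
            raise ValueError("downsample_ratio must be a positive integer")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass
class RegionSet:
    """Auxiliary regions for one neuron: the background disk, the
    neuron-free outside region, and neighbor ids (ascending)."""

    neuron_id: int
    background_mask: np.ndarray
    outside_mask: np.ndarray
    neighbor_ids: list[int]
    bg_radius_px: float
    outside_radius_px: float


@dataclass
class TraceBundle:
    """Per-neuron raw and background-subtracted traces.

    ``background`` is the median over the background disk; subtracting it
    from the neuron and outside means gives the background-subtracted
    traces fed to the unmixer.
    """

    neuron_id: int
    raw_neuron: np.ndarray
    raw_outside: np.ndarray
    background: np.ndarray
    bg_sub_neuron: np.ndarray = field(init=False)
    bg_sub_outside: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.bg_sub_neuron = self.raw_neuron - self.background
        self.bg_sub_outside = self.raw_outside - self.background


@dataclass
class TraceMatrix:
    """The measured matrix F_meas for one target neuron.

    Rows: target neuron first, then its neighbors in ascending id order,
    then the outside region last — (k+2) × T.
    """

    rows: np.ndarray
    row_labels: list[str]
    neuron_id: int
    neighbor_ids: list[int]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if self.rows.ndim != 2:
            raise ValueError("F_meas must be 2-D")
        if len(self.row_labels) != self.rows.shape[0]:
            raise ValueError("row_labels length mismatch")

    @property
    def n_components(self) -> int:
        return self.rows.shape[0]

    @property
    def n_frames(self) -> int:
        return self.rows.shape[1]


@dataclass
class UnmixResult:
    """Output of targeted NMF on one F_meas: separated traces F_sep
    (rows matched to the input rows), mixing matrix M with unit diagonal,
    and the regularization weight actually used."""

    F_sep: np.ndarray
    M: np.ndarray
    alpha_final: float
    alpha_initial: float
    n_iterations: int
    converged: bool


@dataclass(frozen=True, order=True)
class Transient:
    """One detected calcium transient, 0-based inclusive frame indices."""

    start_frame: int
    end_frame: int
    peak_frame: int

    def __post_init__(self) -> None:
        if not self.start_frame <= self.peak_frame <= self.end_frame:
            raise ValueError(
                f"transient frames out of order: start={self.start_frame}, "
                f"peak={self.peak_frame}, end={self.end_frame}"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class DetectionConfig:
    """Transient-detection settings.

    ``th_snr`` thresholds the SNR trace; peaks must be prominent by at
    least ``th_snr * prominence_factor``.  ``apply_temporal_filter``
    should be True for traces extracted from raw videos (SNR videos are
    already matched-filtered).
    """

    th_snr: float = 4.0
    prominence_factor: float = 1.0 / 3.0
    apply_temporal_filter: bool = True
    decay_s: float = 0.2
    rise_s: float = 0.0

    def __post_init__(self) -> None:
        if self.th_snr <= 0:
            raise ValueError("th_snr must be > 0")


@dataclass
class EvalScores:
    """Precision/recall/F1 with the underlying counts."""

    precision: float
    recall: float
    f1: float
    tp: int
    n_detected: int
    n_gt: int
    degenerate: bool = False


@dataclass
class MaskMatch:
    """One-to-one mask pairing at IoU >= 0.5."""

    pairs: list[tuple[int, int]]
    unmatched_a: list[int]
    unmatched_b: list[int]
    ious: list[float]
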