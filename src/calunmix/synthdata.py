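"""Seeded synthetic fluorescence data with known ground truth.

Two generators: a trace-level fixture exercising the linear mixing model
F_meas = M_true·F_true + noise directly, and a full video generator that
places overlapping disk neurons and thin dendrite segments on a
spatially broad, temporally fluctuating background.  Calcium activity is
a Poisson spike train convolved with a fast-rise/exponential-decay
transient template.  Ground-truth transients are recorded from the spike
times used, never re-detected.

Defaults mirror the simulated-video study conditions at desk scale:
90×90 px, 3000 frames at 30 Hz, 20 neurons of mean radius 5.9 px at
least 12 px apart, spiking at 0.05/s, with dendrites numbering 20% of
the neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import NeuronMasks, Transient, VideoStack

__all__ = ["SynthConfig", "SynthTruth", "generate_traces_fixture", "generate_video"]

#: fraction of the transient peak that still counts as "active" when
#: converting spike times into ground-truth transient extents
_GT_ACTIVE_FRACTION = 0.2

_MAX_PLACEMENT_TRIES = 10_000


@dataclass
class SynthConfig:
    """Synthetic-scene settings; lengths in pixels, times in seconds."""

    H: int = 90
    W: int = 90
    T: int = 3000
    frame_rate: float = 30.0
    n_neurons: int = 20
    neuron_radius_px: float = 5.9
    neuron_radius_jitter_px: float = 0.6
    # close enough that radius ~6 px somata can partially overlap
    min_centroid_distance_px: float = 8.0
    spike_rate: float = 0.05
    rise_s: float = 0.02
    decay_s: float = 0.2
    amplitude: float = 1.0
    n_dendrites: int = 4
    background_fwhm_px: float = 40.0
    background_amplitude: float = 0.0
    baseline: float = 10.0
    noise_sigma: float = 0.1
    crosstalk_range: tuple[float, float] = (0.2, 0.5)
    crosstalk_density: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.H, self.W, self.T, self.n_neurons) < 1:
            raise ValueError("sizes must be positive")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")


@dataclass
class SynthTruth:
    """Everything the generator knows: masks, clean traces, the spike-
    derived transients, the mixing matrix used (identity-based for trace
    fixtures, None for rendered videos), and the background traces."""

    masks: NeuronMasks | None
    clean_traces: np.ndarray
    gt_transients: list[list[Transient]]
    M_true: np.ndarray | None
    background_field: np.ndarray | None = None
    spike_frames: list[np.ndarray] = field(default_factory=list)


def _transient_template(cfg: SynthConfig) -> np.ndarray:
    """Peak-normalized difference-of-exponentials transient, truncated
    at 1% of the peak."""
    n = max(int(np.ceil(10.0 * cfg.decay_s * cfg.frame_rate)), 2)
    t = np.arange(n) / cfg.frame_rate
    h = np.exp(-t / cfg.decay_s)
    if cfg.rise_s > 0:
        h = h - np.exp(-t / cfg.rise_s)
    h = h / h.max()
    ipeak = int(np.argmax(h))
    below = np.flatnonzero(h[ipeak:] < 0.01)
    if below.size:
        h = h[: ipeak + below[0]]
    return np.clip(h, 0.0, None)


def _spike_train(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    """Frame indices of Poisson spikes (at most one per frame)."""
    p = min(cfg.spike_rate / cfg.frame_rate, 1.0)
    return np.flatnonzero(rng.random(cfg.T) < p)


def _clean_trace(spikes: np.ndarray, template: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    train = np.zeros(cfg.T)
    train[spikes] = cfg.amplitude
    return np.convolve(train, template)[: cfg.T]


def _gt_transients(spikes: np.ndarray, template: np.ndarray, T: int) -> list[Transient]:
    """Transients from spike times: one transient per spike, spanning
    the frames where its template exceeds 20% of the peak but truncated
    at the next spike (a detector splits summed events at the dip, so
    per-spike extents keep ground truth and detection consistent)."""
    if spikes.size == 0:
        return []
    support = int(np.flatnonzero(template >= _GT_ACTIVE_FRACTION)[-1])
    ipeak = int(np.argmax(template))
    out = []
    for idx, s in enumerate(spikes):
        s = int(s)
        end = min(s + support, T - 1)
        if idx + 1 < spikes.size:
            end = min(end, int(spikes[idx + 1]) - 1)
        peak = min(s + ipeak, end)
        out.append(Transient(s, end, peak))
    return out


def generate_traces_fixture(
    cfg: SynthConfig, n_sources: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[list[Transient]]]:
    """Trace-level fixture for the mixing model.

    Returns ``(F_true, M_true, F_meas, gt_transients)`` where F_true
    rows are independent transient trains and F_meas = M_true·F_true
    plus Gaussian noise.  M_true is the identity plus non-negative
    off-diagonal crosstalk drawn uniformly from ``cfg.crosstalk_range``:
    the target row (row 0) is always contaminated by every other source
    (that is what makes it a decontamination fixture), other entries are
    present with probability ``cfg.crosstalk_density`` — contamination
    is pairwise overlap, not all-to-all.  Rows whose off-diagonal sum
    exceeds 0.9 are rescaled so the diagonal stays dominant, mirroring
    physical mixing where a trace is mostly its own neuron.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_neurons if n_sources is None else n_sources
    template = _transient_template(cfg)
    F_true = np.zeros((n, cfg.T))
    gt: list[list[Transient]] = []
    for i in range(n):
        spikes = _spike_train(rng, cfg)
        F_true[i] = _clean_trace(spikes, template, cfg)
        gt.append(_gt_transients(spikes, template, cfg.T))
    lo, hi = cfg.crosstalk_range
    present = (rng.random((n, n)) < cfg.crosstalk_density) & ~np.eye(n, dtype=bool)
    present[0, 1:] = True
    M_true = np.eye(n)
    M_true[present] = rng.uniform(lo, hi, int(present.sum()))
    off_diag = ~np.eye(n, dtype=bool)
    for i in range(n):
        row_sum = M_true[i, off_diag[i]].sum()
        if row_sum > 0.9:
            M_true[i, off_diag[i]] *= 0.9 / row_sum
    F_meas = M_true @ F_true
    if cfg.noise_sigma > 0:
        # background-subtracted measured traces are real-valued: the noise
        # is left unclipped so quiet-frame statistics stay Gaussian
        F_meas = F_meas + rng.normal(0.0, cfg.noise_sigma, F_meas.shape)
    return F_true, M_true, F_meas, gt


def _place_centers(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    """Rejection-sample neuron centers at the minimum pairwise distance."""
    margin = cfg.neuron_radius_px + 1
    centers: list[tuple[float, float]] = []
    for _ in range(_MAX_PLACEMENT_TRIES):
        if len(centers) == cfg.n_neurons:
            break
        cand = (
            rng.uniform(margin, cfg.H - margin),
            rng.uniform(margin, cfg.W - margin),
        )
        if all(
            np.hypot(cand[0] - c[0], cand[1] - c[1]) >= cfg.min_centroid_distance_px
            for c in centers
        ):
            centers.append(cand)
    if len(centers) < cfg.n_neurons:
        raise ValueError("too dense: could not place all neurons")
    return np.array(centers)


def _disk_mask(center: tuple[float, float], radius: float, H: int, W: int) -> np.ndarray:
    yy = np.arange(H)[:, None] - center[0]
    xx = np.arange(W)[None, :] - center[1]
    return yy * yy + xx * xx <= radius * radius


def _dendrite_mask(rng: np.random.Generator, H: int, W: int) -> np.ndarray:
    """Thin elongated segment: a 1-px-wide line of ~15-25 px length."""
    length = int(rng.integers(15, 26))
    y0, x0 = rng.uniform(2, H - 2), rng.uniform(2, W - 2)
    theta = rng.uniform(0, np.pi)
    t = np.linspace(0, length, 2 * length)
    ys = np.clip(np.round(y0 + t * np.sin(theta)).astype(int), 0, H - 1)
    xs = np.clip(np.round(x0 + t * np.cos(theta)).astype(int), 0, W - 1)
    mask = np.zeros((H, W), dtype=bool)
    mask[ys, xs] = True
    return mask


def _background_field(
    rng: np.random.Generator, cfg: SynthConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Three broad Gaussian blobs with independent slow random-walk
    amplitudes; returns (T, H, W) field and the (3, T) amplitude traces."""
    sigma = cfg.background_fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    yy = np.arange(cfg.H)[:, None]
    xx = np.arange(cfg.W)[None, :]
    blobs = []
    for _ in range(3):
        cy, cx = rng.uniform(0, cfg.H), rng.uniform(0, cfg.W)
        blobs.append(np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    walks = np.cumsum(rng.normal(0.0, 1.0, (3, cfg.T)), axis=1)
    walks -= walks.mean(axis=1, keepdims=True)
    walks *= cfg.background_amplitude / max(np.abs(walks).max(), 1e-12)
    field = np.einsum("bt,bhw->thw", walks, np.array(blobs))
    return field, walks


def generate_video(cfg: SynthConfig) -> tuple[VideoStack, SynthTruth]:
    """Render a synthetic raw video and export its ground truth.

    Frame(t) = Σ_i footprint_i · (baseline + trace_i(t)) + dendrites +
    background_field(t) + Gaussian noise, clipped at zero.
    """
    rng = np.random.default_rng(cfg.seed)
    template = _transient_template(cfg)
    centers = _place_centers(rng, cfg)
    radii = np.maximum(
        cfg.neuron_radius_px + rng.normal(0, cfg.neuron_radius_jitter_px, cfg.n_neurons),
        1.5,
    )
    masks = np.stack(
        [_disk_mask(tuple(c), r, cfg.H, cfg.W) for c, r in zip(centers, radii)]
    )
    clean = np.zeros((cfg.n_neurons, cfg.T))
    gt: list[list[Transient]] = []
    spike_frames: list[np.ndarray] = []
    for i in range(cfg.n_neurons):
        spikes = _spike_train(rng, cfg)
        clean[i] = _clean_trace(spikes, template, cfg)
        gt.append(_gt_transients(spikes, template, cfg.T))
        spike_frames.append(spikes)

    video = np.zeros((cfg.T, cfg.H, cfg.W))
    for i in range(cfg.n_neurons):
        video[:, masks[i]] += (cfg.baseline + clean[i])[:, None]
    for _ in range(cfg.n_dendrites):
        dmask = _dendrite_mask(rng, cfg.H, cfg.W)
        dtrace = _clean_trace(_spike_train(rng, cfg), template, cfg)
        video[:, dmask] += (0.5 * cfg.baseline + dtrace)[:, None]

    bg_traces = None
    if cfg.background_amplitude > 0:
        field, bg_traces = _background_field(rng, cfg)
        video += field
    video += cfg.baseline  # ambient floor so noise rarely clips
    if cfg.noise_sigma > 0:
        video += rng.normal(0.0, cfg.noise_sigma, video.shape)
    np.clip(video, 0.0, None, out=video)

    truth = SynthTruth(
        masks=NeuronMasks(masks),
        clean_traces=clean,
        gt_transients=gt,
        M_true=None,
        background_field=bg_traces,
        spike_frames=spike_frames,
    )
    return VideoStack(video.astype(np.float32), cfg.frame_rate, kind="raw"), truth
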