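"""Trace calculation and background subtraction (unmixing stages 2-3).

Each neuron gets three raw traces: the mean over its own mask, the mean
over its outside region, and the median over its background disk.  The
background trace is subtracted from the other two, and the
background-subtracted neuron trace of the target, its neighbors (each
minus its own background), and the target's outside trace are stacked
into the measured matrix F_meas fed to the unmixer.
"""

from __future__ import annotations

import numpy as np

from .datatypes import NeuronMasks, RegionSet, TraceBundle, TraceMatrix, VideoStack

__all__ = [
    "extract_mean_trace",
    "extract_background_trace",
    "compute_trace_bundles",
    "assemble_F_meas",
]


def extract_mean_trace(video: VideoStack, mask: np.ndarray) -> np.ndarray:
    """Per-frame arithmetic mean of the pixels inside ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != video.shape_spatial:
        raise ValueError("mask grid does not match the video")
    if not mask.any():
        raise ValueError("empty mask")
    return video.data[:, mask].mean(axis=1, dtype=np.float64)


def extract_background_trace(video: VideoStack, background_mask: np.ndarray) -> np.ndarray:
    """Per-frame median of the pixels inside the background disk."""
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != video.shape_spatial:
        raise ValueError("mask grid does not match the video")
    if not background_mask.any():
        raise ValueError("empty background mask")
    return np.median(video.data[:, background_mask].astype(np.float64), axis=1)


def compute_trace_bundles(
    video: VideoStack, masks: NeuronMasks, regions: list[RegionSet]
) -> dict[int, TraceBundle]:
    """TraceBundle per neuron id.  Overlapping mask pixels contribute to
    every owner's mean; only the outside region excludes all neurons."""
    bundles: dict[int, TraceBundle] = {}
    for i, region in enumerate(regions):
        bundles[region.neuron_id] = TraceBundle(
            neuron_id=region.neuron_id,
            raw_neuron=extract_mean_trace(video, masks.masks[i]),
            raw_outside=extract_mean_trace(video, region.outside_mask),
            background=extract_background_trace(video, region.background_mask),
        )
    return bundles


def assemble_F_meas(
    regions: list[RegionSet],
    bundles: dict[int, TraceBundle],
    i: int,
) -> TraceMatrix:
    """Stack the measured traces for target neuron index ``i``.

    Row 0: target neuron minus its own background.  Middle rows: each
    neighbor's neuron trace minus that neighbor's own background disk, in
    ascending id order.  Last row: the target's outside trace minus the
    target's background.
    """
    region = regions[i]
    target = bundles[region.neuron_id]
    rows = [target.bg_sub_neuron]
    labels = [f"neuron_{region.neuron_id}"]
    for j in sorted(region.neighbor_ids):
        rows.append(bundles[j].bg_sub_neuron)
        labels.append(f"neighbor_{j}")
    rows.append(target.bg_sub_outside)
    labels.append("outside")
    return TraceMatrix(
        rows=np.vstack(rows),
        row_labels=labels,
        neuron_id=region.neuron_id,
        neighbor_ids=sorted(region.neighbor_ids),
    )
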