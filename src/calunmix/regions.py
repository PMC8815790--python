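"""Auxiliary mask generation (unmixing stage 1).

For each neuron we build a background disk centered at its centroid with
radius 2.5x the radius of a circle whose area equals the mean neuron
area, list the neighbors whose centroids fall inside that disk, and form
the outside region: disk pixels belonging to no neuron mask.  If the
outside region is smaller than half of the mean neuron area, its disk
radius grows one pixel at a time until the area clears the threshold.
"""

from __future__ import annotations

import numpy as np

from .datatypes import NeuronMasks, RegionSet

__all__ = [
    "average_neuron_radius",
    "centroid",
    "background_mask",
    "neighbors",
    "outside_mask",
    "build_regions",
]

BACKGROUND_RADIUS_FACTOR = 2.5


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Unweighted mean (row, col) of the mask's true pixels."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(rows.mean()), float(cols.mean())


def average_neuron_radius(masks: NeuronMasks) -> float:
    """Radius of the circle whose area equals the mean mask area."""
    areas = masks.masks.sum(axis=(1, 2))
    return float(np.sqrt(areas.mean() / np.pi))


def _disk(center: tuple[float, float], radius: float, shape: tuple[int, int]) -> np.ndarray:
    cy, cx = center
    yy = np.arange(shape[0])[:, None] - cy
    xx = np.arange(shape[1])[None, :] - cx
    return yy * yy + xx * xx <= radius * radius


def background_mask(masks: NeuronMasks, i: int) -> tuple[np.ndarray, float]:
    """Background disk for neuron ``i`` (clipped to the frame) and its
    radius in pixels."""
    radius = BACKGROUND_RADIUS_FACTOR * average_neuron_radius(masks)
    c = centroid(masks.masks[i])
    return _disk(c, radius, masks.shape_spatial), radius


def neighbors(masks: NeuronMasks, i: int, bg_radius: float) -> list[int]:
    """Indices j != i whose centroids lie within the background disk of
    neuron ``i`` (center-to-centroid distance <= radius), ascending."""
    ci = np.array(centroid(masks.masks[i]))
    out = []
    for j in range(len(masks)):
        if j == i:
            continue
        cj = np.array(centroid(masks.masks[j]))
        if np.hypot(*(cj - ci)) <= bg_radius:
            out.append(j)
    return out


def outside_mask(
    masks: NeuronMasks, i: int, bg_radius: float, union_all: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Neuron-free disk pixels around neuron ``i``; grows if starved.

    Starts from the background disk minus the union of ALL neuron masks.
    While the area is below half of the mean neuron area the disk radius
    increases by one pixel (re-clipping and re-subtracting each time).
    Only this outside disk grows; the background disk itself is fixed.
    """
    if union_all is None:
        union_all = np.any(masks.masks, axis=0)
    threshold = masks.masks.sum(axis=(1, 2)).mean() / 2.0
    c = centroid(masks.masks[i])
    shape = masks.shape_spatial
    max_radius = float(np.hypot(*shape))
    radius = bg_radius
    while True:
        out = _disk(c, radius, shape) & ~union_all
        if out.sum() >= threshold:
            return out, radius
        if radius > max_radius:
            raise ValueError(
                f"field too crowded: outside region of neuron {i} stays below "
                f"{threshold:.1f} px even at radius {radius:.1f}"
            )
        radius += 1.0


def build_regions(masks: NeuronMasks) -> list[RegionSet]:
    """One RegionSet per neuron; deterministic in the mask order."""
    if len(masks) < 1:
        raise ValueError("need at least one neuron mask")
    union_all = np.any(masks.masks, axis=0)
    bg_radius = BACKGROUND_RADIUS_FACTOR * average_neuron_radius(masks)
    regions = []
    for i in range(len(masks)):
        bg, _ = background_mask(masks, i)
        nbrs = neighbors(masks, i, bg_radius)
        out, out_radius = outside_mask(masks, i, bg_radius, union_all)
        regions.append(
            RegionSet(
                neuron_id=int(masks.ids[i]),
                background_mask=bg,
                outside_mask=out,
                neighbor_ids=[int(masks.ids[j]) for j in nbrs],
                bg_radius_px=bg_radius,
                outside_radius_px=out_radius,
            )
        )
    return regions
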