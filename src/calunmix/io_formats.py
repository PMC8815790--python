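"""Readers and writers for videos, masks, traces, transients, configs.

Videos come in as multipage TIFF or HDF5 (any single 3-D dataset,
frames on axis 0); masks as an HDF5 (N, H, W) boolean array (dataset
``FinalMasks`` preferred) or a 2-D integer label image.  Per-neuron
results go to one HDF5 file (traces, mixing matrix, final α) with an
optional CSV export; transients to CSV; run configuration to YAML/JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import NeuronMasks, RunConfig, Transient, VideoStack
from .unmix import NeuronUnmix

__all__ = [
    "read_video",
    "read_masks",
    "write_traces",
    "read_traces",
    "write_transients_csv",
    "read_transients_csv",
    "load_config",
    "write_video_h5",
]

MASK_DATASET_NAME = "FinalMasks"


def _find_dataset(handle: h5py.File, ndim: int) -> h5py.Dataset:
    """Locate the unique dataset of the requested rank in an HDF5 file."""
    found: list[h5py.Dataset] = []

    def visit(_name: str, obj: object) -> None:
        if isinstance(obj, h5py.Dataset) and obj.ndim == ndim:
            found.append(obj)

    handle.visititems(visit)
    if not found:
        raise ValueError(f"dataset not {ndim}-D: no {ndim}-D dataset in file")
    if len(found) > 1:
        raise ValueError(f"ambiguous file: multiple {ndim}-D datasets")
    return found[0]


def read_video(path: str | Path, frame_rate: float = 30.0, kind: str = "raw") -> VideoStack:
    """Read a multipage TIFF or HDF5 video as (T, H, W) float frames in
    acquisition order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        with h5py.File(path, "r") as fh:
            data = _find_dataset(fh, 3)[:]
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"dataset not 3-D (got shape {data.shape})")
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    return VideoStack(data, frame_rate=frame_rate, kind=kind)


def read_masks(path: str | Path, video: VideoStack | None = None) -> NeuronMasks:
    """Read neuron masks: (N, H, W) boolean HDF5 array or 2-D label image.

    The dataset named ``FinalMasks`` is preferred; any other single 3-D
    dataset is accepted with a warning.  In a label image, 0 is
    background and each positive label becomes one mask (ascending).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        with h5py.File(path, "r") as fh:
            if MASK_DATASET_NAME in fh:
                arr = fh[MASK_DATASET_NAME][:]
            else:
                ds = None
                for ndim in (3, 2):
                    try:
                        ds = _find_dataset(fh, ndim)
                        break
                    except ValueError:
                        continue
                if ds is None:
                    raise ValueError("no 2-D or 3-D mask dataset in file")
                warnings.warn(
                    f"mask dataset {ds.name!r} used in place of '{MASK_DATASET_NAME}'",
                    stacklevel=2,
                )
                arr = ds[:]
    arr = np.asarray(arr)
    if arr.ndim == 2:
        labels = np.unique(arr)
        labels = labels[labels != 0]
        if labels.size == 0:
            raise ValueError("label image contains no neurons")
        masks = np.stack([arr == lab for lab in labels])
        ids = labels.astype(int)
    elif arr.ndim == 3:
        masks = arr.astype(bool)
        ids = np.arange(masks.shape[0])
    else:
        raise ValueError(f"masks must be 2-D or 3-D (got shape {arr.shape})")
    out = NeuronMasks(masks, ids)
    if video is not None and out.shape_spatial != video.shape_spatial:
        raise ValueError(
            f"mask grid {out.shape_spatial} does not match video {video.shape_spatial}"
        )
    return out


def write_video_h5(video: VideoStack, path: str | Path, dataset: str = "video") -> None:
    """Write a video (e.g. an SNR video) as float32 HDF5."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset(dataset, data=video.data.astype(np.float32))
        ds.attrs["frame_rate"] = video.frame_rate
        ds.attrs["kind"] = video.kind


def write_traces(
    results: list[NeuronUnmix], path: str | Path, csv_path: str | Path | None = None
) -> None:
    """Write per-neuron unmixing results to HDF5 (one group per neuron:
    raw, background-subtracted and unmixed traces, mixing matrix, final
    α) with an optional long-format CSV export."""
    path = Path(path)
    rows = []
    with h5py.File(path, "w") as fh:
        for res in results:
            grp = fh.create_group(f"neuron_{res.neuron_id}")
            grp.attrs["neuron_id"] = res.neuron_id
            grp.attrs["ok"] = res.ok
            grp.attrs["row_labels"] = json.dumps(res.row_labels)
            grp.create_dataset("raw", data=res.raw_trace)
            grp.create_dataset("bg_sub", data=res.bg_sub_trace)
            if res.ok:
                grp.create_dataset("unmixed", data=res.unmixed_trace)
                grp.create_dataset("M", data=res.M)
                grp.attrs["alpha_final"] = res.alpha_final
            else:
                grp.attrs["error"] = res.error
            for kind_name, trace in (
                ("raw", res.raw_trace),
                ("bg_sub", res.bg_sub_trace),
                ("unmixed", res.unmixed_trace),
            ):
                if trace is None:
                    continue
                rows.append(
                    {"neuron_id": res.neuron_id, "kind": kind_name}
                    | {f"f{t}": v for t, v in enumerate(np.asarray(trace))}
                )
    if csv_path is not None:
        pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_traces(path: str | Path) -> list[NeuronUnmix]:
    """Inverse of :func:`write_traces` (HDF5 side)."""
    out = []
    with h5py.File(path, "r") as fh:
        keys = sorted(fh.keys(), key=lambda k: int(k.split("_")[1]))
        for key in keys:
            grp = fh[key]
            ok = bool(grp.attrs["ok"])
            out.append(
                NeuronUnmix(
                    neuron_id=int(grp.attrs["neuron_id"]),
                    row_labels=json.loads(grp.attrs["row_labels"]),
                    raw_trace=grp["raw"][:],
                    bg_sub_trace=grp["bg_sub"][:],
                    unmixed_trace=grp["unmixed"][:] if ok else None,
                    M=grp["M"][:] if ok else None,
                    alpha_final=float(grp.attrs["alpha_final"]) if ok else None,
                    error=None if ok else str(grp.attrs["error"]),
                )
            )
    return out


def write_transients_csv(
    transients: dict[int, list[Transient]], path: str | Path
) -> None:
    """CSV with one row per transient: neuron_id, start, peak, end."""
    rows = [
        {
            "neuron_id": nid,
            "start_frame": tr.start_frame,
            "peak_frame": tr.peak_frame,
            "end_frame": tr.end_frame,
        }
        for nid, trs in transients.items()
        for tr in trs
    ]
    pd.DataFrame(
        rows, columns=["neuron_id", "start_frame", "peak_frame", "end_frame"]
    ).to_csv(path, index=False)


def read_transients_csv(path: str | Path) -> dict[int, list[Transient]]:
    """Inverse of :func:`write_transients_csv`."""
    df = pd.read_csv(path)
    out: dict[int, list[Transient]] = {}
    for _, row in df.iterrows():
        out.setdefault(int(row["neuron_id"]), []).append(
            Transient(int(row["start_frame"]), int(row["end_frame"]), int(row["peak_frame"]))
        )
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON; unknown keys are rejected."""
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if payload is None:
        payload = {}
    valid = set(asdict(RunConfig()).keys())
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**payload)
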