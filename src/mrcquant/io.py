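"""File I/O: TIFF stacks, ground-truth sidecars and tabular outputs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack, Spot
from .simulate import GroundTruth


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a multi-channel stack as TIFF with pixel-size metadata."""
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        metadata={
            "axes": "CZYX" if stack.has_z else "CYX",
            "pixel_size_um": stack.pixel_size_xy,
            "channel_names": list(stack.channel_names),
        },
    )


def read_stack(path: str | Path, pixel_size_um: float = 0.08) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None, ...]
    return ImageStack(
        data=np.asarray(data, dtype=float),
        pixel_size_xy=float(meta.get("pixel_size_um", pixel_size_um)),
        channel_names=tuple(meta.get("channel_names", ())),
    )


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), mask.astype(np.int32))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    Path(path).write_text(
        json.dumps(_jsonify(dataclasses.asdict(truth)), indent=1, sort_keys=True)
    )


def spots_to_frame(spots: list[Spot]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "cell_id": s.cell_id,
            "channel": s.channel,
            "x_um": s.centroid_um[0],
            "y_um": s.centroid_um[1],
            "peak": s.peak_intensity,
            "area_um2": s.area_um2,
            "snr": s.snr,
        }
        for s in spots
    ])


def trajectories_to_frame(tracks) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, (x, y) in zip(tr.frames, tr.positions):
            rows.append({"track_id": tr.track_id, "frame": int(f),
                         "x_um": float(x), "y_um": float(y)})
    return pd.DataFrame(rows)


def write_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(_jsonify(report), indent=1, sort_keys=True))
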