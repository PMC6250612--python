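"""Readers and writers for the pipeline's on-disk formats.

Images travel as single-channel 16-bit TIFF (one file per channel), masks
as 8-bit 0/255 TIFF, point sets and detections as CSV, curves as CSV, and
process/render specifications as JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import CellDetection, ChannelImage, PointPattern, RegionMask, SpatialCurve

__all__ = [
    "write_channel", "read_channel", "write_mask", "read_mask",
    "write_points", "read_points", "write_detections", "read_detections",
    "write_curve", "read_curve", "write_spec_json",
]


def write_channel(img: ChannelImage, path: str | Path) -> Path:
    path = Path(path)
    data = np.clip(np.rint(img.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"channel": img.channel, "pixel_size_um": img.pixel_size})
    return path


def read_channel(path: str | Path, channel: str = "", pixel_size: float = 0.74) -> ChannelImage:
    data = tifffile.imread(path).astype(float)
    return ChannelImage(data, channel or Path(path).stem, pixel_size)


def write_mask(mask: RegionMask, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        (mask.mask.astype(np.uint8) * 255),
        metadata={"label": mask.label, "pixel_size_um": mask.pixel_size},
    )
    return path


def read_mask(path: str | Path, label: str = "", pixel_size: float = 0.74) -> RegionMask:
    data = tifffile.imread(path)
    return RegionMask(data > 0, pixel_size, label or Path(path).stem)


def write_points(pp: PointPattern, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "cell_type": pp.cell_type,
            "x_um": pp.points[:, 0],
            "y_um": pp.points[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_points(path: str | Path, window: RegionMask) -> PointPattern:
    df = pd.read_csv(path)
    pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
    ctype = str(df["cell_type"].iloc[0]) if len(df) else ""
    return PointPattern(pts, window, ctype)


def write_detections(dets: list[CellDetection], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "cell_type": [d.cell_type for d in dets],
            "x_um": [d.centroid[0] for d in dets],
            "y_um": [d.centroid[1] for d in dets],
            "area_um2": [d.area for d in dets],
            "marker_score": [d.marker_score for d in dets],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_detections(path: str | Path) -> list[CellDetection]:
    df = pd.read_csv(path)
    return [
        CellDetection(
            centroid=(row.x_um, row.y_um),
            area=row.area_um2,
            cell_type=row.cell_type,
            marker_score=row.marker_score,
        )
        for row in df.itertuples()
    ]


def write_curve(curve: SpatialCurve, path: str | Path) -> Path:
    path = Path(path)
    cols = {"r_um": curve.r}
    for name in ("k", "g", "lo", "med", "hi"):
        val = getattr(curve, name)
        if val is not None:
            cols[name] = val
    df = pd.DataFrame(cols)
    df["source"] = curve.source
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_curve(path: str | Path) -> SpatialCurve:
    df = pd.read_csv(path)
    kw = {"r": df["r_um"].to_numpy()}
    for name in ("k", "g", "lo", "med", "hi"):
        if name in df.columns:
            kw[name] = df[name].to_numpy()
    kw["source"] = str(df["source"].iloc[0]) if len(df) else "single"
    return SpatialCurve(**kw)


def write_spec_json(spec, path: str | Path) -> Path:
    """Serialize a dataclass spec (ProcessSpec, RenderSpec, ...) to JSON."""
    path = Path(path)
    payload = dataclasses.asdict(spec) if dataclasses.is_dataclass(spec) else dict(spec)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
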