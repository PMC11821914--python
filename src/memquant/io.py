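"""Readers and writers for the pipeline's standard formats.

TIFF / OME-TIFF stacks (pixel sizes from OME metadata, overridable), JSON
polyline annotations (the canonical format) plus a convenience reader for
ImageJ ``.roi``/``.zip`` polylines, CSV landmark tables, and machine-readable
result reports (JSON + CSV with deterministic field order).
"""

from __future__ import annotations

import dataclasses
import json
import struct
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError, UnitError, UnsupportedROIError
from .model import ImageStack, LandmarkSet, MembranePath

__all__ = [
    "read_stack",
    "write_stack",
    "read_polylines",
    "write_polylines",
    "read_landmarks",
    "write_landmarks",
    "write_report",
]

_LANDMARK_COLS = ["pre_z", "pre_y", "pre_x", "post_z", "post_y", "post_x"]


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def _pixel_size_from_ome(tf: tifffile.TiffFile):
    """(z, y, x) pixel size in nm from OME metadata, or None."""
    if not tf.ome_metadata:
        return None
    import xml.etree.ElementTree as ET

    root = ET.fromstring(tf.ome_metadata)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    px = root.find(".//ome:Pixels", ns)
    if px is None:
        return None
    scale = {"nm": 1.0, "µm": 1000.0, "um": 1000.0, "mm": 1e6}

    def get(axis, default=None):
        v = px.get(f"PhysicalSize{axis}")
        if v is None:
            return default
        unit = px.get(f"PhysicalSize{axis}Unit", "µm")
        return float(v) * scale.get(unit, 1000.0)

    x = get("X")
    if x is None:
        return None
    y = get("Y", x)
    z = get("Z", x)
    return (z, y, x)


def _channel_names_from_ome(tf: tifffile.TiffFile):
    if not tf.ome_metadata:
        return None
    import xml.etree.ElementTree as ET

    root = ET.fromstring(tf.ome_metadata)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    names = [c.get("Name") for c in root.findall(".//ome:Channel", ns)]
    return tuple(names) if names and all(names) else None


def read_stack(path, pixel_size_nm=None, expansion_factor=None,
               channel_names=None, axes: str = "czyx") -> ImageStack:
    """Read a TIFF/OME-TIFF into an ImageStack normalized to (C, Z, Y, X).

    Explicit overrides win over file metadata; a file without pixel-size
    metadata requires the ``pixel_size_nm`` override.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            src_axes = series.axes.upper()
            meta_px = _pixel_size_from_ome(tf)
            meta_names = _channel_names_from_ome(tf)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc

    # normalize axis order to C, (Z|T), Y, X
    order = "CT" if "T" in src_axes and "Z" not in src_axes else "CZ"
    want = order + "YX"
    for ax in src_axes:
        if ax not in want:
            raise ValueError(f"unsupported axis {ax!r} in {src_axes}")
    for ax in want:
        if ax not in src_axes:
            data = np.expand_dims(data, 0)
            src_axes = ax + src_axes
    data = np.transpose(data, [src_axes.index(ax) for ax in want])

    px = pixel_size_nm if pixel_size_nm is not None else meta_px
    if px is None:
        raise UnitError(f"{path} has no pixel-size metadata; pass pixel_size_nm")
    px = tuple(float(p) for p in np.broadcast_to(np.asarray(px, float), (3,)))
    if any(p <= 0 for p in px):
        raise UnitError(f"pixel sizes must be positive, got {px}")
    factor = float(expansion_factor) if expansion_factor is not None else 1.0
    names = channel_names or meta_names or ()
    if names and len(names) != data.shape[0]:
        names = ()
    return ImageStack(data, pixel_size_nm=px, expansion_factor=factor,
                      channel_names=names, axes="ctyx" if "T" in want else "czyx")


def write_stack(stack: ImageStack, path) -> Path:
    """Write an ImageStack as OME-TIFF with physical pixel sizes (µm)."""
    path = Path(path)
    z, y, x = stack.pixel_size_nm
    axes = "CTYX" if stack.is_timeseries else "CZYX"
    tifffile.imwrite(path, stack.data.astype(np.float32), ome=True,
                     metadata={"axes": axes,
                               "Channel": {"Name": list(stack.channel_names)},
                               "PhysicalSizeX": x / 1000.0, "PhysicalSizeXUnit": "µm",
                               "PhysicalSizeY": y / 1000.0, "PhysicalSizeYUnit": "µm",
                               "PhysicalSizeZ": z / 1000.0, "PhysicalSizeZUnit": "µm"})
    return path


# ---------------------------------------------------------------------------
# polylines
# ---------------------------------------------------------------------------

# ImageJ ROI type byte; only open polylines are traces
_ROI_POLYLINE_TYPES = {3: "line", 4: "freeline", 5: "polyline"}


def _parse_imagej_roi(buf: bytes, name: str) -> np.ndarray:
    """Decode one ImageJ .roi blob into (n, 2) (y, x) pixel coordinates."""
    if buf[:4] != b"Iout":
        raise SchemaError(f"{name}: not an ImageJ ROI file")
    roi_type = buf[6]
    if roi_type not in _ROI_POLYLINE_TYPES:
        raise UnsupportedROIError(
            f"{name}: ROI type {roi_type} is not a polyline")
    top, left, bottom, right, n = struct.unpack(">hhhhh", buf[8:18])
    if roi_type == 3:  # straight line: float endpoints at offset 18
        x1, y1, x2, y2 = struct.unpack(">ffff", buf[18:34])
        return np.array([[y1, x1], [y2, x2]])
    if n < 2:
        raise SchemaError(f"{name}: polyline with {n} point(s)")
    xs = np.frombuffer(buf, ">h", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(buf, ">h", count=n, offset=64 + 2 * n).astype(float) + top
    return np.column_stack([ys, xs])


def read_polylines(path, bio_pixel_size_nm) -> list:
    """Read membrane traces from JSON (canonical) or ImageJ .roi/.zip files.

    JSON schema: ``{"polylines": [{"points": [[z, y, x], ...],
    "source": "..."}, ...]}`` with 2-element points read as (y, x), z = 0.
    Arclength is computed in biological nm from ``bio_pixel_size_nm``.
    """
    path = Path(path)
    paths = []
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        entries = doc["polylines"] if isinstance(doc, dict) else doc
        for i, entry in enumerate(entries):
            pts = np.asarray(entry["points"], dtype=float)
            if pts.ndim != 2 or len(pts) < 2:
                raise SchemaError(f"polyline {i}: need >= 2 points")
            paths.append(MembranePath.from_pixel_points(
                pts, bio_pixel_size_nm, source=entry.get("source", str(path))))
    elif path.suffix.lower() == ".roi":
        pts = _parse_imagej_roi(path.read_bytes(), path.name)
        paths.append(MembranePath.from_pixel_points(pts, bio_pixel_size_nm,
                                                    source=str(path)))
    elif path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if not name.lower().endswith(".roi"):
                    continue
                pts = _parse_imagej_roi(zf.read(name), name)
                paths.append(MembranePath.from_pixel_points(
                    pts, bio_pixel_size_nm, source=f"{path}:{name}"))
    else:
        raise SchemaError(f"unsupported annotation format: {path.suffix}")
    return paths


def write_polylines(paths, out_path) -> Path:
    out_path = Path(out_path)
    doc = {"polylines": [{"points": p.points.tolist(), "source": p.source}
                         for p in paths]}
    out_path.write_text(json.dumps(doc, indent=1))
    return out_path


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    """Read a delimited landmark table with pre_{z,y,x} / post_{z,y,x} columns."""
    df = pd.read_csv(path)
    missing = [c for c in _LANDMARK_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing landmark columns {missing}")
    if len(df) < 2:
        raise SchemaError(f"{path}: need >= 2 landmark pairs, got {len(df)}")
    if df[_LANDMARK_COLS].isna().any().any():
        raise SchemaError(f"{path}: NaN landmark coordinates")
    return LandmarkSet(pre=df[["pre_z", "pre_y", "pre_x"]].to_numpy(),
                       post=df[["post_z", "post_y", "post_x"]].to_numpy())


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(np.hstack([landmarks.pre, landmarks.post]),
                      columns=_LANDMARK_COLS)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_report(result, out_dir, stem: str | None = None) -> list:
    """Write any result dataclass as JSON (scalars) + CSV (equal-length arrays).

    Field order follows the dataclass definition, so output is deterministic.
    Returns the list of files written.
    """
    if not dataclasses.is_dataclass(result):
        raise TypeError(f"expected a result dataclass, got {type(result)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or type(result).__name__.lower()

    scalars, columns = {}, {}
    for f in dataclasses.fields(result):
        v = getattr(result, f.name)
        if isinstance(v, np.ndarray) and v.ndim == 1:
            columns[f.name] = v
        elif isinstance(v, np.ndarray):
            scalars[f.name] = v.tolist()
        elif dataclasses.is_dataclass(v):
            continue  # nested results are written by their own call
        else:
            scalars[f.name] = _jsonable(v)

    written = []
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(scalars, indent=1))
    written.append(json_path)
    lengths = {len(c) for c in columns.values()}
    if columns and len(lengths) == 1:
        csv_path = out_dir / f"{stem}.csv"
        pd.DataFrame(columns).to_csv(csv_path, index=False)
        written.append(csv_path)
    elif columns:  # ragged arrays: one CSV per field
        for name, col in columns.items():
            csv_path = out_dir / f"{stem}_{name}.csv"
            pd.DataFrame({name: col}).to_csv(csv_path, index=False)
            written.append(csv_path)
    return written
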