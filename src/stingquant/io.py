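"""Shared readers/writers: multi-channel TIFF, ROI polygons (JSON and the
ImageJ .roi/.zip dialect), YAML run configuration with provenance echoing.

The ImageJ codec implements only the polygon subtype of the classic binary
.roi format (magic ``Iout``, big-endian headers, vertex coordinates relative
to the bounding box) — enough to exchange manual cell outlines with ImageJ.
"""

from __future__ import annotations

import hashlib
import json
import struct
import warnings
import zipfile
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .image import CellROI, ImageField

__all__ = [
    "read_image",
    "write_image",
    "read_rois",
    "write_rois_json",
    "write_imagej_roi",
    "write_imagej_roi_zip",
    "load_config",
    "config_hash",
    "provenance_lines",
    "write_csv_with_header",
]


def read_image(path, channel_names: list[str] | None = None) -> ImageField:
    """Read a single- or multi-channel TIFF into an ImageField.

    A 3-D array is interpreted as (channels, y, x). Channels are named from
    ``channel_names`` when given, otherwise positionally ``ch0, ch1, ...``.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(str(path))
    except Exception as err:  # tifffile raises several types for bad files
        raise IOError(f"cannot read TIFF {path}: {err}") from err
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise IOError(f"{path}: expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    # heuristics: channel axis is the smallest one and comes first
    if arr.shape[0] > min(arr.shape[1:]) and arr.shape[-1] <= 8:
        arr = np.moveaxis(arr, -1, 0)
    names = channel_names or [f"ch{i}" for i in range(arr.shape[0])]
    if len(names) != arr.shape[0]:
        raise ValueError(
            f"{path}: {arr.shape[0]} channels but {len(names)} names given"
        )
    bit_depth = arr.dtype.itemsize * 8 if arr.dtype.kind in "ui" else None
    return ImageField(
        channels={n: arr[i].astype(float) for i, n in enumerate(names)},
        bit_depth=bit_depth,
    )


def write_image(image: ImageField, path, dtype=np.float32) -> None:
    """Write an ImageField as a multi-channel TIFF (channel axis first)."""
    stack = np.stack([image.channels[n] for n in image.channel_names])
    tifffile.imwrite(
        str(path), stack.astype(dtype),
        photometric="minisblack", planarconfig="separate",
    )


# --------------------------------------------------------------------------
# ROI polygons
# --------------------------------------------------------------------------

def _rois_from_json(path: Path) -> list[CellROI]:
    data = json.loads(path.read_text())
    if isinstance(data, dict):
        data = data.get("rois", [])
    rois = []
    for i, entry in enumerate(data):
        if isinstance(entry, dict):
            cid = str(entry.get("cell_id", f"roi{i:03d}"))
            poly = entry["polygon"]
        else:
            cid, poly = f"roi{i:03d}", entry
        try:
            rois.append(CellROI(cell_id=cid, polygon=np.asarray(poly, float)))
            # validate early so a bad polygon names its cell
            from .image import polygon_to_mask

            polygon_to_mask(rois[-1].polygon, (4, 4))
        except ValueError as err:
            raise ValueError(f"ROI {cid!r}: {err}") from err
    return rois


_IJ_MAGIC = b"Iout"
_IJ_POLYGON = 0


def _decode_imagej_roi(buf: bytes, name: str) -> CellROI:
    if buf[:4] != _IJ_MAGIC:
        raise ValueError(f"{name}: not an ImageJ ROI file")
    roi_type = buf[6]
    if roi_type != _IJ_POLYGON:
        raise ValueError(f"{name}: unsupported ImageJ ROI type {roi_type}")
    top, left, _bottom, _right, n = struct.unpack(">hhhhh", buf[8:18])
    xs = struct.unpack(f">{n}h", buf[64 : 64 + 2 * n])
    ys = struct.unpack(f">{n}h", buf[64 + 2 * n : 64 + 4 * n])
    poly = np.column_stack(
        [np.asarray(xs, float) + left, np.asarray(ys, float) + top]
    )
    return CellROI(cell_id=name, polygon=poly)


def _encode_imagej_roi(roi: CellROI) -> bytes:
    if roi.polygon is None:
        raise ValueError(f"ROI {roi.cell_id} has no polygon")
    poly = np.round(roi.polygon).astype(int)
    left, top = int(poly[:, 0].min()), int(poly[:, 1].min())
    right, bottom = int(poly[:, 0].max()), int(poly[:, 1].max())
    n = len(poly)
    header = bytearray(64)
    header[:4] = _IJ_MAGIC
    struct.pack_into(">h", header, 4, 227)  # version
    header[6] = _IJ_POLYGON
    body = struct.pack(f">{n}h", *(poly[:, 0] - left)) + struct.pack(
        f">{n}h", *(poly[:, 1] - top)
    )
    struct.pack_into(">hhhhh", header, 8, top, left, bottom, right, n)
    return bytes(header) + body


def write_imagej_roi(roi: CellROI, path) -> None:
    """Write a polygon CellROI as a classic ImageJ .roi file."""
    Path(path).write_bytes(_encode_imagej_roi(roi))


def write_imagej_roi_zip(rois: list[CellROI], path) -> None:
    with zipfile.ZipFile(path, "w") as zf:
        for roi in rois:
            zf.writestr(f"{roi.cell_id}.roi", _encode_imagej_roi(roi))


def read_rois(path) -> list[CellROI]:
    """Read cell outlines from polygon JSON, an ImageJ .roi, or a .zip archive."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        return _rois_from_json(path)
    if suffix == ".roi":
        return [_decode_imagej_roi(path.read_bytes(), path.stem)]
    if suffix == ".zip":
        rois = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if name.lower().endswith(".roi"):
                    rois.append(
                        _decode_imagej_roi(zf.read(name), Path(name).stem)
                    )
        if not rois:
            warnings.warn(f"{path}: empty ROI archive")
        return rois
    raise ValueError(f"unrecognized ROI file type: {path}")


def write_rois_json(rois: list[CellROI], path) -> None:
    data = [
        {"cell_id": r.cell_id, "polygon": np.asarray(r.polygon).tolist()}
        for r in rois
    ]
    Path(path).write_text(json.dumps({"rois": data}, indent=1))


# --------------------------------------------------------------------------
# configuration and provenance
# --------------------------------------------------------------------------

KNOWN_SECTIONS = {
    "coloc", "puncta", "celldeath", "pore", "flux", "simulate",
    "seed", "output_dir", "strict",
}


def load_config(path, *, strict: bool = False) -> dict:
    """Load a YAML run configuration; unknown top-level keys are rejected in
    strict mode and warned about otherwise."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - KNOWN_SECTIONS
    if unknown:
        msg = f"{path}: unknown config keys {sorted(unknown)}"
        if strict or cfg.get("strict"):
            raise ValueError(msg)
        warnings.warn(msg)
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(cfg: dict, extra: dict | None = None) -> list[str]:
    """Header comment lines echoing the configuration into an output file."""
    lines = [f"config_hash: {config_hash(cfg)}"]
    flat: dict = {}

    def _flatten(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for k, v in obj.items():
                _flatten(f"{prefix}{k}.", v)
        else:
            flat[prefix[:-1]] = obj

    _flatten("", cfg)
    if extra:
        flat.update(extra)
    lines += [f"{k}: {v}" for k, v in sorted(flat.items())]
    return lines


def write_csv_with_header(df, path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
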