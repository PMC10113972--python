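"""Minimal DICOM series reader (little-endian, uncompressed CT slices).

Supports explicit- and implicit-VR little endian transfer syntaxes with
monochrome 8/16-bit pixel data — the common ground of CT exports.  Compressed
transfer syntaxes and sequences nested inside pixel data are rejected.

Only the tags the pipeline needs are interpreted; everything else is skipped
structurally.
"""

from __future__ import annotations

import os
import struct

import numpy as np

from .errors import FormatError, GeometryError

# (group, element) tags
TAG_MODALITY = (0x0008, 0x0060)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_IMAGE_ORIENTATION = (0x0020, 0x0037)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)
TAG_TRANSFER_SYNTAX = (0x0002, 0x0010)

_EXPLICIT_LE = "1.2.840.10008.1.2.1"
_IMPLICIT_LE = "1.2.840.10008.1.2"

# VRs with a 4-byte length preceded by 2 reserved bytes in explicit VR
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}


def _parse_elements(buf: bytes, offset: int, explicit: bool):
    """Yield ((group, element), VR, value_bytes) until the buffer ends."""
    n = len(buf)
    pos = offset
    while pos + 8 <= n:
        group, element = struct.unpack_from("<HH", buf, pos)
        pos += 4
        if explicit:
            vr = buf[pos : pos + 2]
            if vr in _LONG_VRS:
                length = struct.unpack_from("<I", buf, pos + 4)[0]
                pos += 8
            else:
                length = struct.unpack_from("<H", buf, pos + 2)[0]
                pos += 4
        else:
            vr = b"UN"
            length = struct.unpack_from("<I", buf, pos)[0]
            pos += 4
        if length == 0xFFFFFFFF:
            raise FormatError("undefined-length elements are not supported")
        value = buf[pos : pos + length]
        if len(value) < length:
            raise FormatError("truncated DICOM element")
        pos += length
        yield (group, element), vr, value


def _decode_str(value: bytes) -> str:
    return value.decode("ascii", errors="replace").strip("\x00 ").strip()


def _decode_multi_float(value: bytes) -> list[float]:
    text = _decode_str(value)
    return [float(p) for p in text.split("\\") if p != ""]


def read_dicom_file(path):
    """Parse one DICOM file into a dict of the tags we care about."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise FormatError(f"{path}: missing DICM magic (not a part-10 DICOM file)")

    # File-meta group (0002,xxxx) is always explicit VR little endian.
    transfer_syntax = _EXPLICIT_LE
    pos = 132
    dataset_start = None
    for tag, _vr, value in _parse_elements(buf, 132, explicit=True):
        if tag[0] != 0x0002:
            break
        if tag == TAG_TRANSFER_SYNTAX:
            transfer_syntax = _decode_str(value)
        # recompute where the meta group ends as we walk it
        pos = _element_end(buf, pos, explicit=True)
    dataset_start = pos

    if transfer_syntax == _EXPLICIT_LE:
        explicit = True
    elif transfer_syntax == _IMPLICIT_LE:
        explicit = False
    else:
        raise FormatError(
            f"{path}: unsupported transfer syntax {transfer_syntax!r} "
            "(only uncompressed little endian is supported)"
        )

    out: dict = {}
    for tag, _vr, value in _parse_elements(buf, dataset_start, explicit):
        if tag == TAG_MODALITY:
            out["modality"] = _decode_str(value)
        elif tag == TAG_ROWS:
            out["rows"] = struct.unpack("<H", value[:2])[0]
        elif tag == TAG_COLS:
            out["cols"] = struct.unpack("<H", value[:2])[0]
        elif tag == TAG_BITS_ALLOCATED:
            out["bits"] = struct.unpack("<H", value[:2])[0]
        elif tag == TAG_PIXEL_REPRESENTATION:
            out["signed"] = struct.unpack("<H", value[:2])[0] == 1
        elif tag == TAG_PIXEL_SPACING:
            out["pixel_spacing"] = _decode_multi_float(value)  # (row, col) mm
        elif tag == TAG_IMAGE_POSITION:
            out["position"] = _decode_multi_float(value)
        elif tag == TAG_IMAGE_ORIENTATION:
            out["orientation"] = _decode_multi_float(value)
        elif tag == TAG_RESCALE_INTERCEPT:
            out["intercept"] = float(_decode_str(value))
        elif tag == TAG_RESCALE_SLOPE:
            out["slope"] = float(_decode_str(value))
        elif tag == TAG_PIXEL_DATA:
            out["pixel_data"] = value
    return out


def _element_end(buf: bytes, pos: int, explicit: bool) -> int:
    """Return the offset just past the element starting at ``pos``."""
    pos += 4
    if explicit:
        vr = buf[pos : pos + 2]
        if vr in _LONG_VRS:
            length = struct.unpack_from("<I", buf, pos + 4)[0]
            pos += 8
        else:
            length = struct.unpack_from("<H", buf, pos + 2)[0]
            pos += 4
    else:
        length = struct.unpack_from("<I", buf, pos)[0]
        pos += 4
    return pos + length


def _slice_pixels(meta: dict, path) -> np.ndarray:
    rows, cols = meta["rows"], meta["cols"]
    bits = meta.get("bits", 16)
    if bits == 16:
        dtype = np.int16 if meta.get("signed", True) else np.uint16
    elif bits == 8:
        dtype = np.int8 if meta.get("signed", False) else np.uint8
    else:
        raise FormatError(f"{path}: unsupported BitsAllocated={bits}")
    raw = np.frombuffer(meta["pixel_data"], dtype=np.dtype(dtype).newbyteorder("<"))
    if raw.size < rows * cols:
        raise FormatError(f"{path}: pixel data shorter than Rows x Columns")
    stored = raw[: rows * cols].reshape(rows, cols).astype(np.float64)
    slope = meta.get("slope", 1.0)
    intercept = meta.get("intercept", 0.0)
    return slope * stored + intercept


def read_dicom_series(directory):
    """Read a directory of CT DICOM slices into ``(voxels, spacing)``.

    Slices are sorted by the projection of ImagePositionPatient onto the
    slice normal; slice spacing must be uniform to within 1%.
    """
    if not os.path.isdir(directory):
        raise FileNotFoundError(directory)
    paths = sorted(
        os.path.join(directory, name)
        for name in os.listdir(directory)
        if not name.startswith(".")
    )
    slices = []
    for p in paths:
        if os.path.isdir(p):
            continue
        meta = read_dicom_file(p)
        if "pixel_data" not in meta:
            continue
        slices.append((p, meta))
    if not slices:
        raise FormatError(f"{directory}: no readable DICOM slices found")

    ref = slices[0][1]
    if ref.get("modality", "CT") != "CT":
        raise FormatError(
            f"{directory}: modality {ref.get('modality')!r} is not CT"
        )
    if "slope" not in ref or "intercept" not in ref:
        raise FormatError(f"{directory}: rescale slope/intercept missing")
    orient = ref.get("orientation", [1, 0, 0, 0, 1, 0])
    spacing_rc = ref.get("pixel_spacing")
    if spacing_rc is None:
        raise FormatError(f"{directory}: PixelSpacing missing")
    for p, meta in slices[1:]:
        if meta.get("orientation", orient) != orient:
            raise GeometryError(f"{p}: slice orientation differs within series")
        if not np.allclose(meta.get("pixel_spacing", spacing_rc), spacing_rc):
            raise GeometryError(f"{p}: in-plane spacing differs within series")

    row_dir = np.asarray(orient[:3], dtype=float)
    col_dir = np.asarray(orient[3:6], dtype=float)
    normal = np.cross(row_dir, col_dir)

    def slice_z(item):
        pos = item[1].get("position", [0.0, 0.0, 0.0])
        return float(np.dot(normal, pos))

    slices.sort(key=slice_z)
    zs = np.array([slice_z(s) for s in slices])
    if len(slices) > 1:
        dzs = np.diff(zs)
        if np.any(dzs <= 0):
            raise GeometryError(f"{directory}: duplicate or unordered slice positions")
        if (dzs.max() - dzs.min()) > 0.01 * dzs.mean():
            raise GeometryError(
                f"{directory}: slice spacing varies by more than 1% "
                f"(min {dzs.min():.4g}, max {dzs.max():.4g} mm)"
            )
        dz = float(dzs.mean())
    else:
        dz = 1.0

    planes = [_slice_pixels(meta, p) for p, meta in slices]
    voxels = np.stack(planes, axis=0).astype(np.float32)
    dy, dx = float(spacing_rc[0]), float(spacing_rc[1])
    return voxels, (dz, dy, dx)
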