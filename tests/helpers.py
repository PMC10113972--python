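"""Test-only helpers: a minimal explicit-VR little-endian DICOM slice writer."""

import struct

import numpy as np

_LONG_VRS = (b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN")


def _elem(group: int, element: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"UI", b"OB") else b" "
    head = struct.pack("<HH", group, element) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _ds(values) -> bytes:
    return "\\".join(f"{float(v):g}" for v in values).encode()


def write_dicom_slice(
    path,
    pixels,
    *,
    position=(0.0, 0.0, 0.0),
    pixel_spacing=(1.0, 1.0),  # (row, col) mm
    slope=1.0,
    intercept=-1024.0,
    modality="CT",
    orientation=(1, 0, 0, 0, 1, 0),
):
    """Write one uncompressed CT slice (16-bit signed) as a part-10 DICOM file."""
    pixels = np.asarray(pixels)
    rows, cols = pixels.shape
    body = b"".join(
        [
            _elem(0x0008, 0x0060, b"CS", modality.encode()),
            _elem(0x0020, 0x0032, b"DS", _ds(position)),
            _elem(0x0020, 0x0037, b"DS", _ds(orientation)),
            _elem(0x0028, 0x0010, b"US", struct.pack("<H", rows)),
            _elem(0x0028, 0x0011, b"US", struct.pack("<H", cols)),
            _elem(0x0028, 0x0030, b"DS", _ds(pixel_spacing)),
            _elem(0x0028, 0x0100, b"US", struct.pack("<H", 16)),
            _elem(0x0028, 0x0103, b"US", struct.pack("<H", 1)),
            _elem(0x0028, 0x1052, b"DS", _ds([intercept])),
            _elem(0x0028, 0x1053, b"DS", _ds([slope])),
            _elem(0x7FE0, 0x0010, b"OW", pixels.astype("<i2").tobytes()),
        ]
    )
    meta = _elem(0x0002, 0x0010, b"UI", b"1.2.840.10008.1.2.1")
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)


def write_dicom_series(directory, stored, *, dz=2.5, pixel_spacing=(1.0, 1.0),
                       slope=1.0, intercept=-1024.0, modality="CT", z_positions=None):
    """Write a stack of stored-value slices; returns the file paths."""
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(stored.shape[0]):
        z = z_positions[k] if z_positions is not None else k * dz
        p = directory / f"slice_{k:03d}.dcm"
        write_dicom_slice(
            p,
            stored[k],
            position=(0.0, 0.0, z),
            pixel_spacing=pixel_spacing,
            slope=slope,
            intercept=intercept,
            modality=modality,
        )
        paths.append(p)
    return paths
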