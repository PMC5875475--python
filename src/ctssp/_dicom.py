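"""Minimal single-frame CT DICOM codec.

Writes Explicit VR Little Endian files with a standard 128-byte preamble and
file-meta group; reads Explicit and Implicit VR Little Endian (uncompressed
transfer syntaxes only).  Only the small tag subset needed for slice-profile
analysis is interpreted; unknown elements are skipped on read.
"""

from __future__ import annotations

import struct
import uuid
from pathlib import Path

import numpy as np

from .errors import InputError

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"
CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
_UID_ROOT = "1.2.826.0.1.3680043.10.1546"

# (group, element) tags used by this package
TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_MODALITY = (0x0008, 0x0060)
TAG_SERIES_DESCRIPTION = (0x0008, 0x103E)
TAG_SLICE_THICKNESS = (0x0018, 0x0050)
TAG_SERIES_UID = (0x0020, 0x000E)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_IMAGE_ORIENTATION = (0x0020, 0x0037)
TAG_SLICE_LOCATION = (0x0020, 0x1041)
TAG_SAMPLES_PER_PIXEL = (0x0028, 0x0002)
TAG_PHOTOMETRIC = (0x0028, 0x0004)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLUMNS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_BITS_STORED = (0x0028, 0x0101)
TAG_HIGH_BIT = (0x0028, 0x0102)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)

# VRs whose explicit encoding uses a 2-byte reserved field + 4-byte length
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

# VR lookup for implicit-VR decoding of the tags we interpret
_IMPLICIT_VR = {
    TAG_SOP_CLASS: b"UI",
    TAG_SOP_INSTANCE: b"UI",
    TAG_MODALITY: b"CS",
    TAG_SERIES_DESCRIPTION: b"LO",
    TAG_SLICE_THICKNESS: b"DS",
    TAG_SERIES_UID: b"UI",
    TAG_INSTANCE_NUMBER: b"IS",
    TAG_IMAGE_POSITION: b"DS",
    TAG_IMAGE_ORIENTATION: b"DS",
    TAG_SLICE_LOCATION: b"DS",
    TAG_SAMPLES_PER_PIXEL: b"US",
    TAG_PHOTOMETRIC: b"CS",
    TAG_ROWS: b"US",
    TAG_COLUMNS: b"US",
    TAG_PIXEL_SPACING: b"DS",
    TAG_BITS_ALLOCATED: b"US",
    TAG_BITS_STORED: b"US",
    TAG_HIGH_BIT: b"US",
    TAG_PIXEL_REPRESENTATION: b"US",
    TAG_RESCALE_INTERCEPT: b"DS",
    TAG_RESCALE_SLOPE: b"DS",
    TAG_PIXEL_DATA: b"OW",
}


def new_uid() -> str:
    return f"{_UID_ROOT}.{uuid.uuid4().int % 10**30}"


def _fmt_ds(x: float) -> str:
    """Format a float as a DICOM DS string.

    Uses the shortest round-tripping decimal representation so written axial
    positions are recovered bit-exactly.  This may exceed the standard's
    16-byte DS limit for floats that need 17 significant digits; position
    fidelity is prioritized over strict conformance here.
    """
    x = float(x)
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


class Dataset:
    """Flat tag -> (vr, raw bytes) mapping with typed accessors."""

    def __init__(self) -> None:
        self._elements: dict[tuple[int, int], tuple[bytes, bytes]] = {}

    def __contains__(self, tag: tuple[int, int]) -> bool:
        return tag in self._elements

    def raw(self, tag: tuple[int, int]) -> bytes:
        return self._elements[tag][1]

    def get_str(self, tag, default=None):
        if tag not in self._elements:
            return default
        return self._elements[tag][1].decode("ascii").rstrip(" \x00")

    def get_floats(self, tag, default=None):
        s = self.get_str(tag)
        if s is None or s == "":
            return default
        return [float(part) for part in s.split("\\")]

    def get_float(self, tag, default=None):
        vals = self.get_floats(tag)
        return default if vals is None else vals[0]

    def get_int(self, tag, default=None):
        if tag not in self._elements:
            return default
        vr, raw = self._elements[tag]
        if vr == b"US":
            return struct.unpack("<H", raw[:2])[0]
        if vr == b"UL":
            return struct.unpack("<I", raw[:4])[0]
        return int(self.get_str(tag))

    def pixel_array(self) -> np.ndarray:
        rows = self.get_int(TAG_ROWS)
        cols = self.get_int(TAG_COLUMNS)
        bits = self.get_int(TAG_BITS_ALLOCATED, 16)
        signed = self.get_int(TAG_PIXEL_REPRESENTATION, 0) == 1
        if rows is None or cols is None or TAG_PIXEL_DATA not in self:
            raise InputError("missing image geometry or pixel data")
        if bits != 16:
            raise InputError(f"unsupported bits allocated: {bits}")
        dtype = np.dtype("<i2") if signed else np.dtype("<u2")
        raw = self.raw(TAG_PIXEL_DATA)
        expected = rows * cols * 2
        if len(raw) < expected:
            raise InputError("pixel data shorter than Rows x Columns")
        return np.frombuffer(raw[:expected], dtype=dtype).reshape(rows, cols)


def _parse_elements(data: bytes, offset: int, explicit: bool, stop_at_group=None):
    """Yield (tag, vr, value) from *data* starting at *offset*."""
    n = len(data)
    while offset + 8 <= n:
        group, elem = struct.unpack_from("<HH", data, offset)
        if stop_at_group is not None and group > stop_at_group:
            return
        tag = (group, elem)
        if explicit:
            vr = data[offset + 4 : offset + 6]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", data, offset + 8)
                value_off = offset + 12
            else:
                (length,) = struct.unpack_from("<H", data, offset + 6)
                value_off = offset + 8
        else:
            vr = _IMPLICIT_VR.get(tag, b"UN")
            (length,) = struct.unpack_from("<I", data, offset + 4)
            value_off = offset + 8
        if length == 0xFFFFFFFF:
            raise InputError("undefined-length elements (sequences) not supported")
        if value_off + length > n:
            raise InputError("truncated DICOM element")
        yield tag, vr, data[value_off : value_off + length]
        offset = value_off + length


def read_file(path) -> Dataset:
    """Parse a single DICOM file into a flat :class:`Dataset`."""
    data = Path(path).read_bytes()
    if len(data) < 132 or data[128:132] != b"DICM":
        raise InputError(f"not a DICOM file (missing DICM magic): {path}")
    # file meta group is always explicit VR little endian
    transfer_syntax = EXPLICIT_VR_LE
    meta_end = 132
    for tag, vr, value in _parse_elements(data, 132, explicit=True, stop_at_group=0x0002):
        meta_end += (12 if vr in _LONG_VRS else 8) + len(value)
        if tag == (0x0002, 0x0010):
            transfer_syntax = value.decode("ascii").rstrip(" \x00")
    if transfer_syntax == EXPLICIT_VR_LE:
        explicit = True
    elif transfer_syntax == IMPLICIT_VR_LE:
        explicit = False
    else:
        raise InputError(f"unsupported transfer syntax: {transfer_syntax}")
    ds = Dataset()
    for tag, vr, value in _parse_elements(data, meta_end, explicit=explicit):
        if tag[0] == 0x0002:
            continue
        ds._elements[tag] = (vr, value)
    return ds


def _encode_element(tag: tuple[int, int], vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"UI", b"OB") else b" "
    head = struct.pack("<HH", *tag)
    if vr in _LONG_VRS:
        return head + vr + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + vr + struct.pack("<H", len(value)) + value


def _txt(s: str) -> bytes:
    return s.encode("ascii")


def write_ct_slice(
    path,
    stored: np.ndarray,
    *,
    z: float,
    thickness: float,
    pixel_spacing: tuple[float, float],
    slope: float = 1.0,
    intercept: float = -1024.0,
    series_uid: str,
    sop_uid: str,
    instance_number: int,
    series_description: str = "",
) -> None:
    """Write one int16 CT slice as an Explicit VR LE DICOM file."""
    stored = np.ascontiguousarray(stored, dtype="<i2")
    rows, cols = stored.shape
    elements = [
        (TAG_SOP_CLASS, b"UI", _txt(CT_IMAGE_STORAGE)),
        (TAG_SOP_INSTANCE, b"UI", _txt(sop_uid)),
        (TAG_MODALITY, b"CS", b"CT"),
        (TAG_SERIES_DESCRIPTION, b"LO", _txt(series_description)),
        (TAG_SLICE_THICKNESS, b"DS", _txt(_fmt_ds(thickness))),
        (TAG_SERIES_UID, b"UI", _txt(series_uid)),
        (TAG_INSTANCE_NUMBER, b"IS", _txt(str(instance_number))),
        (TAG_IMAGE_POSITION, b"DS", _txt(f"0\\0\\{_fmt_ds(z)}")),
        (TAG_IMAGE_ORIENTATION, b"DS", b"1\\0\\0\\0\\1\\0"),
        (TAG_SLICE_LOCATION, b"DS", _txt(_fmt_ds(z))),
        (TAG_SAMPLES_PER_PIXEL, b"US", struct.pack("<H", 1)),
        (TAG_PHOTOMETRIC, b"CS", b"MONOCHROME2"),
        (TAG_ROWS, b"US", struct.pack("<H", rows)),
        (TAG_COLUMNS, b"US", struct.pack("<H", cols)),
        (TAG_PIXEL_SPACING, b"DS", _txt(f"{_fmt_ds(pixel_spacing[0])}\\{_fmt_ds(pixel_spacing[1])}")),
        (TAG_BITS_ALLOCATED, b"US", struct.pack("<H", 16)),
        (TAG_BITS_STORED, b"US", struct.pack("<H", 16)),
        (TAG_HIGH_BIT, b"US", struct.pack("<H", 15)),
        (TAG_PIXEL_REPRESENTATION, b"US", struct.pack("<H", 1)),
        (TAG_RESCALE_INTERCEPT, b"DS", _txt(_fmt_ds(intercept))),
        (TAG_RESCALE_SLOPE, b"DS", _txt(_fmt_ds(slope))),
        (TAG_PIXEL_DATA, b"OW", stored.tobytes()),
    ]
    body = b"".join(_encode_element(t, vr, v) for t, vr, v in sorted(elements))

    meta_elements = [
        ((0x0002, 0x0001), b"OB", b"\x00\x01"),
        ((0x0002, 0x0002), b"UI", _txt(CT_IMAGE_STORAGE)),
        ((0x0002, 0x0003), b"UI", _txt(sop_uid)),
        ((0x0002, 0x0010), b"UI", _txt(EXPLICIT_VR_LE)),
        ((0x0002, 0x0012), b"UI", _txt(_UID_ROOT + ".1")),
    ]
    meta_body = b"".join(_encode_element(t, vr, v) for t, vr, v in meta_elements)
    group_length = _encode_element((0x0002, 0x0000), b"UL", struct.pack("<I", len(meta_body)))

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + group_length + meta_body + body)
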