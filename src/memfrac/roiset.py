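"""Minimal reader/writer for ImageJ line ROIs (.roi files and .zip RoiSets).

Only straight-line ROIs are handled, which is all the line-scan workflow
needs; other ROI types encountered in a RoiSet are skipped with a warning.
The binary layout follows ImageJ's RoiDecoder: a 64-byte big-endian header
starting with the magic ``Iout``, with line endpoints stored as float32 at
offsets 18-33 and the stroke (line) width as an int16 at offset 34.
"""

from __future__ import annotations

import io
import struct
import warnings
import zipfile
from dataclasses import dataclass
from pathlib import Path

_MAGIC = b"Iout"
_VERSION = 227
_TYPE_LINE = 5


@dataclass(frozen=True)
class LineRoi:
    """A straight line ROI in pixel coordinates with an averaging width.

    ``(x1, y1)`` and ``(x2, y2)`` are the endpoints; ``width`` is the number
    of 1-px-spaced parallel samples averaged perpendicular to the line.
    """

    x1: float
    y1: float
    x2: float
    y2: float
    width: int = 10
    name: str | None = None

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("line width must be >= 1 px")
        if (self.x1, self.y1) == (self.x2, self.y2):
            raise ValueError("line endpoints must be distinct")

    @property
    def length_px(self) -> float:
        return float(((self.x2 - self.x1) ** 2 + (self.y2 - self.y1) ** 2) ** 0.5)

    def length_um(self, pixel_size: float) -> float:
        return self.length_px * pixel_size


def encode_roi(roi: LineRoi) -> bytes:
    """Serialize a line ROI to ImageJ's binary .roi format."""
    buf = bytearray(64)
    buf[0:4] = _MAGIC
    struct.pack_into(">h", buf, 4, _VERSION)
    buf[6] = _TYPE_LINE
    top = int(min(roi.y1, roi.y2))
    left = int(min(roi.x1, roi.x2))
    bottom = int(max(roi.y1, roi.y2)) + 1
    right = int(max(roi.x1, roi.x2)) + 1
    struct.pack_into(">hhhh", buf, 8, top, left, bottom, right)
    struct.pack_into(">ffff", buf, 18, roi.x1, roi.y1, roi.x2, roi.y2)
    struct.pack_into(">h", buf, 34, int(roi.width))
    return bytes(buf)


def decode_roi(data: bytes, name: str | None = None) -> LineRoi | None:
    """Parse one .roi blob; returns None (with a warning) for non-line ROIs."""
    if len(data) < 64 or data[0:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI (bad magic)")
    roi_type = data[6]
    if roi_type != _TYPE_LINE:
        warnings.warn(
            f"skipping non-line ROI {name or '<unnamed>'} (type {roi_type})",
            stacklevel=2,
        )
        return None
    x1, y1, x2, y2 = struct.unpack_from(">ffff", data, 18)
    (stroke_width,) = struct.unpack_from(">h", data, 34)
    return LineRoi(x1, y1, x2, y2, width=max(int(stroke_width), 1), name=name)


def read_roiset(path: str | Path) -> list[LineRoi]:
    """Read line ROIs from a single .roi file or a .zip RoiSet."""
    path = Path(path)
    rois: list[LineRoi] = []
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for entry in zf.namelist():
                if not entry.lower().endswith(".roi"):
                    continue
                roi = decode_roi(zf.read(entry), name=Path(entry).stem)
                if roi is not None:
                    rois.append(roi)
    else:
        data = path.read_bytes()
        roi = decode_roi(data, name=path.stem)
        if roi is not None:
            rois.append(roi)
    return rois


def write_roiset(rois: list[LineRoi], path: str | Path) -> None:
    """Write ROIs as a .zip RoiSet (or a bare .roi if the suffix is .roi)."""
    path = Path(path)
    if path.suffix.lower() == ".roi":
        if len(rois) != 1:
            raise ValueError("a .roi file holds exactly one ROI; use .zip")
        path.write_bytes(encode_roi(rois[0]))
        return
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, roi in enumerate(rois):
            name = roi.name or f"line-{i:04d}"
            zf.writestr(f"{name}.roi", encode_roi(roi))
    path.write_bytes(buf.getvalue())
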