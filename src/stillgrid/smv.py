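"""SMV still-image reader/writer.

The dialect is the classic ADSC layout: a 512-byte ASCII header delimited
by ``{`` ... ``}`` followed by a little-endian unsigned 16-bit raster in
slow-major order.  Beam centre is stored in mm in the header
(``BEAM_CENTER_X`` = fast axis, ``BEAM_CENTER_Y`` = slow axis) and in
pixels in memory.  A companion ``<name>.mask`` file, same layout with 0/1
payload, carries the exclusion mask when present.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .frame import ImageFrame
from .geometry import DetectorGeometry

__all__ = ["read_frame", "write_frame"]

HEADER_BYTES = 512

_REQUIRED_KEYS = ("SIZE1", "SIZE2", "PIXEL_SIZE", "DISTANCE", "WAVELENGTH",
                  "BEAM_CENTER_X", "BEAM_CENTER_Y")


def _format_header(frame: ImageFrame) -> bytes:
    g = frame.geometry
    items = [
        ("HEADER_BYTES", f"{HEADER_BYTES:4d}"),
        ("DIM", "2"),
        ("TYPE", "unsigned_short"),
        ("BYTE_ORDER", "little_endian"),
        ("SIZE1", str(g.n_slow)),
        ("SIZE2", str(g.n_fast)),
        ("PIXEL_SIZE", f"{g.pixel_size:.6f}"),
        ("DISTANCE", f"{g.distance:.6f}"),
        ("WAVELENGTH", f"{frame.wavelength:.6f}"),
        ("BEAM_CENTER_X", f"{g.beam_center[1] * g.pixel_size:.6f}"),
        ("BEAM_CENTER_Y", f"{g.beam_center[0] * g.pixel_size:.6f}"),
    ]
    text = "{\n" + "".join(f"{k}={v};\n" for k, v in items) + "}\n"
    header = text.encode("ascii")
    if len(header) > HEADER_BYTES:
        raise ValueError("header exceeds fixed 512-byte budget")
    return header + b" " * (HEADER_BYTES - len(header))


def write_frame(frame: ImageFrame, path) -> Path:
    """Write frame (and ``.mask`` sidecar if masked) to ``path``."""
    path = Path(path)
    raster = np.clip(np.rint(frame.raster), 0, 65535).astype("<u2")
    with open(path, "wb") as fh:
        fh.write(_format_header(frame))
        fh.write(raster.tobytes())
    if frame.mask is not None and frame.mask.any():
        mask_frame = ImageFrame(frame.mask.astype("<u2"), frame.geometry,
                                frame.wavelength, source_id=frame.source_id)
        write_frame(mask_frame, path.with_suffix(path.suffix + ".mask"))
    return path


def _parse_header(raw: bytes, path) -> dict[str, str]:
    try:
        text = raw.decode("ascii", errors="replace")
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"{path}: undecodable header") from exc
    start, end = text.find("{"), text.find("}")
    if start < 0 or end < 0:
        raise ValueError(f"{path}: missing {{...}} header block")
    fields = {}
    for line in text[start + 1:end].splitlines():
        line = line.strip().rstrip(";")
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    return fields


def read_frame(path) -> ImageFrame:
    """Read an SMV frame; raises ``ValueError`` with the missing header key
    or the expected-vs-found byte counts on a truncated payload."""
    path = Path(path)
    with open(path, "rb") as fh:
        fields = _parse_header(fh.read(HEADER_BYTES), path)
        for key in _REQUIRED_KEYS:
            if key not in fields:
                raise ValueError(f"{path}: missing header key {key}")
        if fields.get("DIM", "2") != "2":
            raise ValueError(f"{path}: unsupported DIM={fields.get('DIM')}")
        if fields.get("TYPE", "unsigned_short") != "unsigned_short":
            raise ValueError(f"{path}: unsupported TYPE={fields.get('TYPE')}")
        n_slow, n_fast = int(fields["SIZE1"]), int(fields["SIZE2"])
        pixel_size = float(fields["PIXEL_SIZE"])
        payload = fh.read()
    expected = 2 * n_slow * n_fast
    if len(payload) < expected:
        raise ValueError(
            f"{path}: truncated payload, expected {expected} bytes, "
            f"found {len(payload)}")
    raster = np.frombuffer(payload[:expected], dtype="<u2")
    raster = raster.reshape(n_slow, n_fast).astype(np.int64)
    geom = DetectorGeometry(
        n_slow=n_slow, n_fast=n_fast, pixel_size=pixel_size,
        distance=float(fields["DISTANCE"]),
        beam_center=(float(fields["BEAM_CENTER_Y"]) / pixel_size,
                     float(fields["BEAM_CENTER_X"]) / pixel_size))
    mask = None
    mask_path = path.with_suffix(path.suffix + ".mask")
    if os.path.exists(mask_path):
        mask = read_frame(mask_path).raster.astype(bool)
    return ImageFrame(raster, geom, float(fields["WAVELENGTH"]), mask=mask,
                      source_id=path.name)
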