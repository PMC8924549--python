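"""Skeleton serialization: plain-text SWC and a compact binary variant.

Text SWC is the standard 7-column format: ``id type x y z radius parent``,
one node per line, '#' comments ignored, parent -1 for roots.  Coordinates
and radii are stored in nanometres (the dataset-native unit).

The binary variant trades readability for load speed.  Layout (little
endian): ``uint32 node_count`` followed by ``node_count`` records of
``{int32 id, int32 type, float32 x, float32 y, float32 z, float32 radius,
int32 parent}`` (28 bytes each; parent -1 marks a root).  The round trip is
lossless at float32 precision.  This layout is this package's own versioned
dialect; no compatibility with other binary SWC flavours is claimed.
"""

from __future__ import annotations

import io
import struct

import numpy as np

from .errors import FormatError
from .skeleton import Skeleton

__all__ = ["read_swc", "write_swc", "read_swc_binary", "write_swc_binary",
           "load_swc", "save_swc"]

_RECORD = struct.Struct("<iiffffi")


def read_swc(text: str) -> Skeleton:
    """Parse SWC text into a Skeleton.

    Raises :class:`FormatError` (with the line number) for malformed lines
    and for parent references that never resolve.
    """
    ids, structs, xyz, radii, parents = [], [], [], [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise FormatError(f"line {lineno}: expected 7 fields, got {len(fields)}")
        try:
            ids.append(int(fields[0]))
            structs.append(int(fields[1]))
            xyz.append([float(f) for f in fields[2:5]])
            radii.append(float(fields[5]))
            parents.append(int(fields[6]))
        except ValueError as e:
            raise FormatError(f"line {lineno}: non-numeric field ({e})") from None
    try:
        return Skeleton(np.asarray(ids), np.asarray(structs),
                        np.asarray(xyz).reshape(-1, 3), np.asarray(radii),
                        np.asarray(parents))
    except ValueError as e:
        raise FormatError(str(e)) from None


def write_swc(skel: Skeleton, header: str | None = None) -> str:
    """Serialize a Skeleton to SWC text (nm units)."""
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    for i, s, x, y, z, r, p in skel.to_records():
        lines.append(f"{i} {s} {x:.6f} {y:.6f} {z:.6f} {r:.6f} {p}")
    return "\n".join(lines) + "\n"


def write_swc_binary(skel: Skeleton) -> bytes:
    buf = io.BytesIO()
    buf.write(struct.pack("<I", skel.n_nodes))
    for i, s, x, y, z, r, p in skel.to_records():
        buf.write(_RECORD.pack(i, s, x, y, z, r, p))
    return buf.getvalue()


def read_swc_binary(payload: bytes) -> Skeleton:
    if len(payload) < 4:
        raise FormatError("truncated payload: missing node count")
    (count,) = struct.unpack_from("<I", payload, 0)
    expected = 4 + count * _RECORD.size
    if len(payload) != expected:
        raise FormatError(f"truncated payload: expected {expected} bytes, got {len(payload)}")
    ids, structs, xyz, radii, parents = [], [], [], [], []
    for k in range(count):
        i, s, x, y, z, r, p = _RECORD.unpack_from(payload, 4 + k * _RECORD.size)
        ids.append(i)
        structs.append(s)
        xyz.append([x, y, z])
        radii.append(r)
        parents.append(p)
    try:
        return Skeleton(np.asarray(ids), np.asarray(structs),
                        np.asarray(xyz).reshape(-1, 3), np.asarray(radii),
                        np.asarray(parents))
    except ValueError as e:
        raise FormatError(str(e)) from None


def load_swc(path) -> Skeleton:
    """Load a skeleton from a file path; ``.swc.bin`` selects the binary codec."""
    path = str(path)
    if path.endswith(".bin"):
        with open(path, "rb") as f:
            return read_swc_binary(f.read())
    with open(path) as f:
        return read_swc(f.read())


def save_swc(skel: Skeleton, path, header: str | None = None):
    path = str(path)
    if path.endswith(".bin"):
        with open(path, "wb") as f:
            f.write(write_swc_binary(skel))
    else:
        with open(path, "w") as f:
            f.write(write_swc(skel, header=header))
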