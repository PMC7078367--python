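"""Reading and writing marker and joint trajectory files.

Supported formats:

* **C3D** — the binary biomechanics interchange standard.  A minimal
  reader/writer for the Intel floating-point variant is implemented here:
  point labels from ``POINT:LABELS``, rate from ``POINT:RATE`` (falling
  back to the header), units from ``POINT:UNITS`` (mm converted to m).
* **TRC** — the tab-separated marker format with a five-line header
  carrying DataRate / NumMarkers / Units.
* **CSV** — a documented dialect with header
  ``frame,time,<label>_x,<label>_y,<label>_z`` and coordinates in meters.
* **JSON** — the package's own versioned joint-clip interchange
  (schema ``pldstim.jointclip/1``); lossless round-trip.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .clips import JOINT_NAMES, ClipError, JointClip, MarkerClip


class ParseError(ValueError):
    """A file failed to parse under its declared format."""


# --------------------------------------------------------------------------
# C3D (minimal Intel-float subset)
# --------------------------------------------------------------------------

_C3D_BLOCK = 512


def _c3d_param_blocks(labels: list[str], rate: float, n_frames: int) -> bytes:
    """Build the C3D parameter section with POINT group essentials."""

    def group(gid: int, name: bytes, desc: bytes = b"") -> bytes:
        head = struct.pack("<bb", len(name), -gid) + name
        offset = 3 + len(desc)  # next-entry offset counted from its own field
        return head + struct.pack("<h", offset) + struct.pack("<B", len(desc)) + desc

    def param(gid: int, name: bytes, dtype: int, dims: list[int], data: bytes) -> bytes:
        head = struct.pack("<bb", len(name), gid) + name
        body = struct.pack("<b", dtype) + struct.pack("<b", len(dims))
        for d in dims:
            body += struct.pack("<B", d)
        body += data + struct.pack("<B", 0)  # empty description
        offset = 2 + len(body)
        return head + struct.pack("<h", offset) + body

    label_w = max(4, max((len(s) for s in labels), default=4))
    label_data = b"".join(s.ljust(label_w).encode("ascii") for s in labels)

    params = b""
    params += group(1, b"POINT")
    params += param(1, b"USED", 2, [], struct.pack("<h", len(labels)))
    params += param(1, b"FRAMES", 2, [], struct.pack("<h", min(n_frames, 32767)))
    params += param(1, b"RATE", 4, [], struct.pack("<f", rate))
    params += param(1, b"SCALE", 4, [], struct.pack("<f", -1.0))
    params += param(1, b"UNITS", -1, [1], b"m")
    params += param(1, b"DATA_START", 2, [], b"\x00\x00")  # patched by caller
    params += param(1, b"LABELS", -1, [label_w, len(labels)], label_data)
    params += struct.pack("<bb", 0, 0)  # terminator

    n_blocks = -(-(4 + len(params)) // _C3D_BLOCK)
    header = struct.pack("<BBBB", 0x01, 0x50, n_blocks, 84)  # 84 = Intel
    section = header + params
    return section + b"\x00" * (n_blocks * _C3D_BLOCK - len(section))


def write_marker_clip_c3d(clip: MarkerClip, path: str | Path) -> None:
    """Write a MarkerClip as a floating-point Intel C3D file (meters)."""
    path = Path(path)
    n_frames, n_pts = clip.positions.shape[:2]
    param_section = _c3d_param_blocks(clip.labels, clip.rate, n_frames)
    n_param_blocks = len(param_section) // _C3D_BLOCK
    data_start_block = 2 + n_param_blocks  # 1-based: header(1) + params

    header = bytearray(_C3D_BLOCK)
    struct.pack_into("<BB", header, 0, 2, 0x50)  # parameter section at block 2
    struct.pack_into("<H", header, 2, n_pts)
    struct.pack_into("<H", header, 4, 0)  # no analog channels
    struct.pack_into("<H", header, 6, 1)  # first frame
    struct.pack_into("<H", header, 8, min(n_frames, 65535))  # last frame
    struct.pack_into("<H", header, 10, 0)  # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)  # negative scale => float data
    struct.pack_into("<H", header, 16, data_start_block)
    struct.pack_into("<H", header, 18, 0)  # analog samples per frame
    struct.pack_into("<f", header, 20, clip.rate)

    # patch DATA_START inside the parameter section
    param = bytearray(param_section)
    marker = b"\nDATA_START" if False else b"DATA_START"
    idx = param.find(marker)
    # value sits after: offset(2) + dtype(1) + ndims(1)
    struct.pack_into("<h", param, idx + len(marker) + 4, data_start_block)

    frames = np.zeros((n_frames, n_pts, 4), dtype="<f4")
    frames[:, :, :3] = clip.positions
    frames[:, :, 3] = 0.0  # residual/camera word

    with path.open("wb") as fh:
        fh.write(header)
        fh.write(param)
        raw = frames.tobytes()
        fh.write(raw)
        pad = (-len(raw)) % _C3D_BLOCK
        fh.write(b"\x00" * pad)


def _read_c3d(path: Path) -> MarkerClip:
    blob = path.read_bytes()
    if len(blob) < _C3D_BLOCK or blob[1] != 0x50:
        raise ParseError(f"{path}: not a C3D file (bad magic byte)")
    param_block = blob[0]
    n_pts = struct.unpack_from("<H", blob, 2)[0]
    first_frame = struct.unpack_from("<H", blob, 6)[0]
    last_frame = struct.unpack_from("<H", blob, 8)[0]
    scale = struct.unpack_from("<f", blob, 12)[0]
    data_start = struct.unpack_from("<H", blob, 16)[0]
    rate = struct.unpack_from("<f", blob, 20)[0]
    n_frames = last_frame - first_frame + 1

    # ---- parameter section ------------------------------------------------
    p = (param_block - 1) * _C3D_BLOCK
    proc = blob[p + 3]
    if proc != 84:
        raise ParseError(f"{path}: only Intel-format C3D is supported (processor {proc})")
    pos = p + 4
    params: dict[tuple[str, str], tuple[int, list[int], bytes]] = {}
    groups: dict[int, str] = {}
    pending: list[tuple[int, str, int, list[int], bytes]] = []
    while pos < len(blob):
        nchar, gid = struct.unpack_from("<bb", blob, pos)
        if nchar == 0 or gid == 0:
            break
        name = blob[pos + 2 : pos + 2 + abs(nchar)].decode("ascii", "replace")
        pos2 = pos + 2 + abs(nchar)
        offset = struct.unpack_from("<h", blob, pos2)[0]
        body = pos2 + 2
        if gid < 0:  # group record
            groups[-gid] = name
        else:  # parameter record
            dtype = struct.unpack_from("<b", blob, body)[0]
            ndims = struct.unpack_from("<b", blob, body + 1)[0]
            dims = [blob[body + 2 + i] for i in range(ndims)]
            count = int(np.prod(dims)) if dims else 1
            width = abs(dtype)
            data = blob[body + 2 + ndims : body + 2 + ndims + count * width]
            pending.append((gid, name, dtype, dims, data))
        if offset <= 0:
            break
        pos = pos2 + offset
    for gid, name, dtype, dims, data in pending:
        params[(groups.get(gid, str(gid)), name)] = (dtype, dims, data)

    def get(group: str, name: str):
        return params.get((group, name))

    if (e := get("POINT", "RATE")) is not None:
        rate = struct.unpack("<f", e[2][:4])[0]
    unit = "m"
    if (e := get("POINT", "UNITS")) is not None:
        unit = e[2].decode("ascii", "replace").strip().lower() or "m"
    labels: list[str] = []
    if (e := get("POINT", "LABELS")) is not None:
        dtype, dims, data = e
        width = dims[0] if dims else len(data)
        count = dims[1] if len(dims) > 1 else 1
        labels = [
            data[i * width : (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(count)
        ]
    if (e := get("POINT", "DATA_START")) is not None:
        data_start = struct.unpack("<h", e[2][:2])[0]
    if (e := get("POINT", "FRAMES")) is not None:
        n_frames = max(n_frames, struct.unpack("<h", e[2][:2])[0])

    if len(labels) != n_pts:
        raise ParseError(
            f"{path}: POINT:LABELS lists {len(labels)} names but header declares {n_pts} points"
        )

    # ---- data section -----------------------------------------------------
    d = (data_start - 1) * _C3D_BLOCK
    if scale >= 0:
        raise ParseError(f"{path}: integer-scaled C3D data not supported (scale {scale})")
    need = n_frames * n_pts * 4 * 4
    raw = np.frombuffer(blob, dtype="<f4", count=need // 4, offset=d)
    frames = raw.reshape(n_frames, n_pts, 4)[:, :, :3].astype(float)
    if unit.startswith("mm"):
        frames = frames / 1000.0
    return MarkerClip(labels=labels, positions=frames, rate=float(rate))


# --------------------------------------------------------------------------
# TRC
# --------------------------------------------------------------------------


def _read_trc(path: Path) -> MarkerClip:
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: truncated TRC header")
    hdr_keys = lines[1].split("\t")
    hdr_vals = lines[2].split("\t")
    hdr = dict(zip(hdr_keys, hdr_vals))
    try:
        rate = float(hdr["DataRate"])
        n_markers = int(hdr["NumMarkers"])
        units = hdr.get("Units", "mm").strip().lower()
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: malformed TRC header line: {exc}") from exc
    names_row = lines[3].split("\t")
    labels = [s.strip() for s in names_row[2:] if s.strip()]
    if len(labels) != n_markers:
        raise ParseError(
            f"{path}: header declares {n_markers} markers but {len(labels)} names listed"
        )
    rows = []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        rows.append([float(x) if x.strip() else np.nan for x in parts[2 : 2 + 3 * n_markers]])
    data = np.asarray(rows, dtype=float).reshape(len(rows), n_markers, 3)
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ParseError(f"{path}: non-finite coordinate at frame {bad[0]}, marker {labels[bad[1]]}")
    if units.startswith("mm"):
        data = data / 1000.0
    return MarkerClip(labels=labels, positions=data, rate=rate)


def write_marker_clip_trc(clip: MarkerClip, path: str | Path, units: str = "mm") -> None:
    path = Path(path)
    scale = 1000.0 if units == "mm" else 1.0
    n_frames, n_markers = clip.positions.shape[:2]
    out = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{clip.rate:g}\t{clip.rate:g}\t{n_frames}\t{n_markers}\t{units}\t{clip.rate:g}\t1\t{n_frames}",
        "Frame#\tTime\t" + "\t\t\t".join(clip.labels) + "\t\t",
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(n_markers)),
    ]
    for f in range(n_frames):
        vals = (clip.positions[f] * scale).reshape(-1)
        out.append(f"{f+1}\t{f/clip.rate:.6f}\t" + "\t".join(f"{v:.6f}" for v in vals))
    path.write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# CSV dialect: frame,time,<label>_x,<label>_y,<label>_z  (meters)
# --------------------------------------------------------------------------


def _read_csv(path: Path) -> MarkerClip:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:2] != ["frame", "time"]:
        raise ParseError(f"{path}: CSV must start with 'frame,time' columns, got {cols[:2]}")
    labels: list[str] = []
    for c in cols[2:]:
        if c.endswith("_x"):
            labels.append(c[:-2])
    expected = ["frame", "time"] + [f"{l}_{ax}" for l in labels for ax in "xyz"]
    if cols != expected:
        raise ParseError(f"{path}: CSV columns not in <label>_x,_y,_z triplet order")
    data = df[expected[2:]].to_numpy(dtype=float).reshape(len(df), len(labels), 3)
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ParseError(f"{path}: non-finite coordinate at frame {bad[0]}, marker {labels[bad[1]]}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6:
            raise ParseError(f"{path}: time column is not uniformly increasing")
        rate = 1.0 / dt.mean()
    else:
        rate = 1.0
    return MarkerClip(labels=labels, positions=data, rate=float(round(rate, 6)))


def write_marker_clip_csv(clip: MarkerClip, path: str | Path) -> None:
    path = Path(path)
    n_frames, n_markers = clip.positions.shape[:2]
    cols = {"frame": np.arange(n_frames), "time": np.arange(n_frames) / clip.rate}
    flat = clip.positions.reshape(n_frames, -1)
    for i, label in enumerate(clip.labels):
        for k, ax in enumerate("xyz"):
            cols[f"{label}_{ax}"] = flat[:, 3 * i + k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9f")


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

_READERS = {"c3d": _read_c3d, "trc": _read_trc, "csv": _read_csv}
_WRITERS = {
    "c3d": write_marker_clip_c3d,
    "trc": write_marker_clip_trc,
    "csv": write_marker_clip_csv,
}


def read_marker_clip(path: str | Path, format: str | None = None) -> MarkerClip:
    """Read a marker trajectory file; format inferred from suffix if omitted."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _READERS:
        raise ParseError(f"unknown marker file format {fmt!r} (supported: c3d, trc, csv)")
    if not path.exists():
        raise FileNotFoundError(path)
    return _READERS[fmt](path)


def write_marker_clip(clip: MarkerClip, path: str | Path, format: str | None = None, **kw) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _WRITERS:
        raise ParseError(f"unknown marker file format {fmt!r} (supported: c3d, trc, csv)")
    _WRITERS[fmt](clip, path, **kw)


# --------------------------------------------------------------------------
# JSON joint-clip interchange
# --------------------------------------------------------------------------

JOINTCLIP_SCHEMA = "pldstim.jointclip/1"


def write_joint_clip(clip: JointClip, path: str | Path) -> None:
    doc = {
        "schema": JOINTCLIP_SCHEMA,
        "rate": clip.rate,
        "joints": list(clip.joints),
        "positions": clip.positions.tolist(),
        "events": clip.events,
        "meta": clip.meta,
    }
    Path(path).write_text(json.dumps(doc))


def read_joint_clip(path: str | Path) -> JointClip:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != JOINTCLIP_SCHEMA:
        raise ParseError(f"{path}: missing or unsupported schema tag (want {JOINTCLIP_SCHEMA})")
    for key in ("rate", "joints", "positions"):
        if key not in doc:
            raise ParseError(f"{path}: schema error, missing required field {key!r}")
    if list(doc["joints"]) != list(JOINT_NAMES):
        raise ParseError(f"{path}: joints are not the canonical 13-joint list")
    try:
        return JointClip(
            positions=np.asarray(doc["positions"], dtype=float),
            rate=float(doc["rate"]),
            events={k: float(v) for k, v in doc.get("events", {}).items()},
            meta=doc.get("meta", {}),
        )
    except (ClipError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: schema error: {exc}") from exc
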