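"""Minimal FCS 3.0/3.1 reader and FCS 3.1 writer for mass-cytometry data.

Supports list-mode (``$MODE L``) files with float (``F``, ``D``) or unsigned
integer (``I``) data, which covers CyTOF output and the files this package
writes. No compensation/spillover handling: CyTOF data need none.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FCSFile", "read_fcs", "write_fcs"]

_DELIM = b"/"


@dataclass
class FCSFile:
    """Parsed content of one FCS file."""

    data: np.ndarray  # events x channels, float64
    channel_names: list[str]  # $PnN (short names)
    channel_labels: list[str]  # $PnS where present, else $PnN
    text: dict[str, str] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return self.data.shape[0]


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ValueError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Doubled delimiters escape a literal delimiter inside a value.
    sentinel = b"\x00\x01\x02"
    parts = body.replace(delim + delim, sentinel).split(delim)
    parts = [p.replace(sentinel, delim) for p in parts]
    if len(parts) % 2:
        parts = parts[:-1]
    out: dict[str, str] = {}
    for key, val in zip(parts[::2], parts[1::2]):
        out[key.decode("utf-8", "replace").strip().upper()] = val.decode(
            "utf-8", "replace"
        ).strip()
    return out


def read_fcs(path: str | Path) -> FCSFile:
    """Read an FCS 3.0 or 3.1 list-mode file into an events x channels array."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise ValueError(f"{path}: too short to be an FCS file")
    version = blob[0:6].decode("ascii", "replace")
    if not version.startswith("FCS"):
        raise ValueError(f"{path}: not an FCS file (header {version!r})")

    def _off(lo: int, hi: int) -> int:
        s = blob[lo:hi].decode("ascii", "replace").strip()
        return int(s) if s else 0

    text_start, text_end = _off(10, 18), _off(18, 26)
    data_start, data_end = _off(26, 34), _off(34, 42)
    text = _parse_text_segment(blob[text_start : text_end + 1])

    if data_start == 0 or data_end == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    if data_start == 0 or data_end == 0 or data_end < data_start:
        raise ValueError(f"{path}: cannot locate DATA segment")

    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise ValueError(f"{path}: unsupported $MODE {mode!r} (only list mode)")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    raw = blob[data_start : data_end + 1]

    if datatype in ("F", "D"):
        width = 32 if datatype == "F" else 64
        if any(b != width for b in bits):
            raise ValueError(f"{path}: $PnB inconsistent with $DATATYPE {datatype}")
        dt = np.dtype(f"{order}f{width // 8}")
        need = n_tot * n_par * dt.itemsize
        arr = np.frombuffer(raw[:need], dtype=dt).reshape(n_tot, n_par)
        data = arr.astype(np.float64)
    elif datatype == "I":
        if len(set(bits)) == 1 and bits[0] in (8, 16, 32, 64):
            dt = np.dtype(f"{order}u{bits[0] // 8}")
            need = n_tot * n_par * dt.itemsize
            data = np.frombuffer(raw[:need], dtype=dt).reshape(n_tot, n_par).astype(
                np.float64
            )
        else:  # mixed widths: unpack event by event
            fmt = order + "".join(
                {8: "B", 16: "H", 32: "I", 64: "Q"}[b] for b in bits
            )
            size = struct.calcsize(fmt)
            rows = [
                struct.unpack_from(fmt, raw, i * size) for i in range(n_tot)
            ]
            data = np.asarray(rows, dtype=np.float64)
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {datatype!r}")

    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    labels = [text.get(f"$P{i}S", names[i - 1]) for i in range(1, n_par + 1)]
    return FCSFile(data=data, channel_names=names, channel_labels=labels, text=text)


def write_fcs(
    path: str | Path,
    data: np.ndarray,
    channel_names: list[str],
    channel_labels: list[str] | None = None,
    extra_text: dict[str, str] | None = None,
) -> None:
    """Write an events x channels array as FCS 3.1, float32 little-endian."""
    data = np.ascontiguousarray(np.asarray(data, dtype=np.float32))
    if data.ndim != 2:
        raise ValueError("data must be 2-D (events x channels)")
    n_tot, n_par = data.shape
    if len(channel_names) != n_par:
        raise ValueError("channel_names length must match data columns")
    labels = list(channel_labels) if channel_labels is not None else list(channel_names)

    pairs: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    col_max = np.nanmax(np.abs(data), axis=0) if n_tot else np.ones(n_par)
    for i in range(n_par):
        rng = max(float(col_max[i]), 1.0)
        pairs += [
            (f"$P{i + 1}N", channel_names[i].replace("/", "-")),
            (f"$P{i + 1}S", labels[i].replace("/", "-")),
            (f"$P{i + 1}B", "32"),
            (f"$P{i + 1}E", "0,0"),
            (f"$P{i + 1}R", str(int(np.ceil(rng)) + 1)),
        ]
    if extra_text:
        pairs += [(k, v.replace("/", "-")) for k, v in extra_text.items()]

    # DATA offsets appear inside TEXT, so reserve fixed-width fields first.
    ph = "0" * 10
    begin_data_key, end_data_key = "$BEGINDATA", "$ENDDATA"

    def _render(bd: str, ed: str) -> bytes:
        items = pairs + [(begin_data_key, bd), (end_data_key, ed)]
        out = _DELIM
        for k, v in items:
            out += k.encode() + _DELIM + (v or " ").encode() + _DELIM
        return out

    header_len = 58
    text_bytes = _render(ph, ph)
    text_start = header_len
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1
    text_bytes = _render(str(data_start).zfill(10), str(data_end).zfill(10))

    def _hfield(x: int) -> bytes:
        s = str(x)
        return (s if len(s) <= 8 else "0").rjust(8).encode()

    header = b"FCS3.1    "
    header += _hfield(text_start) + _hfield(text_end)
    header += _hfield(data_start if data_end <= 99999999 else 0)
    header += _hfield(data_end if data_end <= 99999999 else 0)
    header += _hfield(0) + _hfield(0)
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(data.tobytes())
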