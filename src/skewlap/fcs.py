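"""Minimal FCS 3.0/3.1 list-mode reader and single-channel writer.

Covers the subset of the Flow Cytometry Standard that event-level analysis
needs: one TEXT segment, list-mode DATA in float32/float64 or unsigned
integers of uniform bit width, either byte order.  The writer emits valid
single-parameter FCS 3.0 files (float32, little-endian) so that generated
fixtures can exercise the reading path offline.  Compensation, analysis
segments, multi-dataset files and bit-packed integer data are out of scope.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from numpy.typing import NDArray

__all__ = ["read_fcs", "write_fcs"]

_HEADER_LEN = 58


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[0:1].decode("latin-1")
    parts = raw.decode("latin-1").strip(delim).split(delim)
    # keyword/value pairs; keywords are case-insensitive per the standard
    kv = {}
    for key, val in zip(parts[::2], parts[1::2]):
        kv[key.strip().upper()] = val
    return kv


def read_fcs(path: Union[str, Path]) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an FCS file into an events DataFrame (one column per channel).

    Returns ``(events, keywords)`` where column names come from $PnN.
    """
    blob = Path(path).read_bytes()
    if not blob[:6] == b"FCS3.0" and not blob[:6] == b"FCS3.1":
        raise ValueError(f"{path}: not an FCS 3.0/3.1 file")
    offsets = [int(blob[10 + 8 * i: 18 + 8 * i].decode("ascii").strip() or 0) for i in range(4)]
    text_beg, text_end, data_beg, data_end = offsets
    kw = _parse_text(blob[text_beg: text_end + 1])
    if data_beg == 0:
        data_beg, data_end = int(kw["$BEGINDATA"]), int(kw["$ENDDATA"])
    if kw.get("$MODE", "L").upper() != "L":
        raise ValueError("only list-mode ($MODE L) FCS data is supported")
    n_par = int(kw["$PAR"])
    tot = int(kw["$TOT"])
    order = "<" if kw.get("$BYTEORD", "1,2,3,4").startswith("1") else ">"
    dtype_code = kw.get("$DATATYPE", "F").upper()
    if dtype_code == "F":
        dt = np.dtype(order + "f4")
    elif dtype_code == "D":
        dt = np.dtype(order + "f8")
    elif dtype_code == "I":
        bits = {int(kw[f"$P{i+1}B"]) for i in range(n_par)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise ValueError("integer FCS data requires a uniform $PnB of 16 or 32")
        dt = np.dtype(order + ("u2" if int(kw["$P1B"]) == 16 else "u4"))
    else:
        raise ValueError(f"unsupported $DATATYPE {dtype_code!r}")
    raw = blob[data_beg: data_end + 1]
    events = np.frombuffer(raw, dtype=dt, count=tot * n_par).reshape(tot, n_par)
    names = [kw.get(f"$P{i+1}N", f"P{i+1}") for i in range(n_par)]
    return pd.DataFrame(np.asarray(events, dtype=float), columns=names), kw


def write_fcs(values: NDArray[np.float64], path: Union[str, Path],
              channel: str = "FS") -> None:
    """Write one channel of events as a minimal single-parameter FCS 3.0 file."""
    x = np.asarray(values, dtype="<f4").ravel()
    n = x.size
    rng_max = int(np.ceil(float(np.max(x)))) + 1 if n else 1024
    data = x.tobytes()
    d = "/"
    # fixed-width data offsets so the TEXT length is known up front
    kw_pairs = [
        ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "{:>10d}"), ("$ENDDATA", "{:>10d}"),
        ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"),
        ("$MODE", "L"), ("$NEXTDATA", "0"),
        ("$PAR", "1"), ("$TOT", str(n)),
        ("$P1N", channel), ("$P1B", "32"), ("$P1E", "0,0"),
        ("$P1R", str(rng_max)),
    ]
    template = d + d.join(f"{k}{d}{v}" for k, v in kw_pairs) + d
    text_beg = _HEADER_LEN
    text_end = text_beg + len(template.format(0, 0)) - 1
    data_beg = text_end + 1
    data_end = data_beg + len(data) - 1
    text = template.format(data_beg, data_end).encode("ascii")
    header = (
        b"FCS3.0    "
        + f"{text_beg:>8d}".encode() + f"{text_end:>8d}".encode()
        + f"{data_beg:>8d}".encode() + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode() + f"{0:>8d}".encode()
    )
    assert len(header) == _HEADER_LEN
    Path(path).write_bytes(header + text + data)
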