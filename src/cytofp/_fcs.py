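"""Minimal FCS 3.0/3.1 list-mode reader.

Supports the subset of the standard produced by common bench cytometers:
list-mode ($MODE L) data with $DATATYPE F, D or I, uniform-width integer
parameters, and little- or big-endian byte order. Channels are matched by
their $PnN short names. No dedicated FCS library is assumed at runtime.
"""

from __future__ import annotations

import numpy as np


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ValueError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    fields = [p.decode("utf-8", errors="replace") for p in parts]
    if len(fields) % 2 != 0:
        fields = fields[: len(fields) - 1]
    return {
        fields[j].strip().upper(): fields[j + 1]
        for j in range(0, len(fields), 2)
    }


def read_fcs(path: str) -> tuple[list[str], np.ndarray]:
    """Return (channel short names, N x D float64 event matrix)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    version = raw[0:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = _parse_text_segment(raw[text_start : text_end + 1])

    mode = text.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise ValueError(f"only list-mode FCS supported, got $MODE={mode}")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text["$DATATYPE"].strip().upper()
    byteord = text["$BYTEORD"].strip()
    little = byteord.startswith("1")
    order = "<" if little else ">"

    names = []
    widths = []
    for p in range(1, n_par + 1):
        names.append(text.get(f"$P{p}N", f"P{p}").strip())
        widths.append(int(text[f"$P{p}B"]))
    if len(set(widths)) != 1:
        raise ValueError("mixed parameter bit widths are not supported")
    width = widths[0] // 8

    data_start = int(text.get("$BEGINDATA", 0)) or int(raw[26:34])
    data_end = int(text.get("$ENDDATA", 0)) or int(raw[34:42])
    blob = raw[data_start : data_end + 1]

    if datatype == "F":
        dtype = np.dtype(f"{order}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{order}f8")
    elif datatype == "I":
        dtype = np.dtype(f"{order}u{width}")
    else:
        raise ValueError(f"unsupported $DATATYPE={datatype}")

    n_values = n_tot * n_par
    arr = np.frombuffer(blob, dtype=dtype, count=n_values)
    return names, arr.reshape(n_tot, n_par).astype(float)
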