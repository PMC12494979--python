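"""Minimal FCS 3.1 list-mode reader/writer.

Writes single-dataset FCS 3.1 files with 32-bit float list-mode data
(``$DATATYPE/F``, ``$MODE/L``, little-endian ``$BYTEORD/1,2,3,4``) and reads
them (plus FCS 3.0 files of the same layout) back. Channel names are taken
from ``$PnS`` when present, falling back to ``$PnN``. This covers the event
data produced and consumed by this package; it is not a general-purpose FCS
implementation (no analysis segments, no integer or multi-dataset files).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import ParameterError

_DELIM = b"/"


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [b""]
    for key, value in keywords.items():
        kb = key.encode("ascii")
        vb = str(value).encode("ascii")
        if _DELIM in kb or _DELIM in vb:
            raise ParameterError("FCS keyword/value may not contain '/'")
        parts.append(kb)
        parts.append(vb)
    parts.append(b"")
    return _DELIM.join(parts)


def write_fcs(path, data: np.ndarray, channel_names: list[str]) -> None:
    """Write a cells x channels float matrix as an FCS 3.1 file."""
    data = np.ascontiguousarray(np.asarray(data, dtype="<f4"))
    if data.ndim != 2:
        raise ParameterError("FCS data must be 2-D (events x parameters)")
    n_events, n_par = data.shape
    if n_par != len(channel_names):
        raise ParameterError("channel_names length must match data columns")
    if n_events == 0:
        raise ParameterError("refusing to write an FCS file with zero events")

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(channel_names, start=1):
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}S"] = str(name)
        rng = float(np.nanmax(data[:, i - 1])) if n_events else 0.0
        keywords[f"$P{i}R"] = str(int(np.ceil(max(rng, 1.0))) + 1)

    data_bytes = data.tobytes()
    header_len = 58  # 6-byte version + 4-byte pad + 6 eight-byte offsets
    # Offsets depend on the text length, which depends on the offsets; the
    # digit counts stabilize after a couple of passes.
    begin_data = end_data = 0
    text = b""
    for _ in range(4):
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(end_data)
        text = _text_segment(kw)
        text_start = header_len
        text_end = text_start + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + len(data_bytes) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text_start = header_len
    text_end = text_start + len(text) - 1

    def _off(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for the header slot; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    "
    header += _off(text_start) + _off(text_end)
    header += _off(begin_data if end_data <= 99_999_999 else 0)
    header += _off(end_data if end_data <= 99_999_999 else 0)
    header += _off(0) + _off(0)
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1]
    fields = raw[1:].split(delim)
    if fields and fields[-1] == b"":
        fields = fields[:-1]
    if len(fields) % 2:
        raise ParameterError("malformed FCS TEXT segment")
    out: dict[str, str] = {}
    for i in range(0, len(fields), 2):
        out[fields[i].decode("ascii", "replace").strip().upper()] = (
            fields[i + 1].decode("ascii", "replace").strip()
        )
    return out


def read_fcs(path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS file; returns (data, channel_names, text keywords)."""
    blob = Path(path).read_bytes()
    if not blob[:3] == b"FCS":
        raise ParameterError(f"{path} is not an FCS file")
    text_start = int(blob[10:18])
    text_end = int(blob[18:26])
    keywords = _parse_text(blob[text_start : text_end + 1])

    begin = int(keywords.get("$BEGINDATA") or blob[26:34] or 0)
    end = int(keywords.get("$ENDDATA") or blob[34:42] or 0)
    if begin == 0 or end == 0:
        begin = int(blob[26:34])
        end = int(blob[34:42])

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    if keywords.get("$DATATYPE", "F").upper() != "F":
        raise ParameterError("only $DATATYPE/F (float) FCS data is supported")
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    raw = blob[begin : end + 1]
    expected = n_par * n_tot * 4
    if len(raw) < expected:
        raise ParameterError("FCS data segment shorter than $PAR * $TOT events")
    data = np.frombuffer(raw[:expected], dtype=f"{endian}f4").reshape(n_tot, n_par)

    names = []
    for i in range(1, n_par + 1):
        names.append(keywords.get(f"$P{i}S") or keywords.get(f"$P{i}N") or f"P{i}")
    return data.astype(float), names, keywords
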