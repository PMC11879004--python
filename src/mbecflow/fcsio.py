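"""Minimal FCS 3.1 reader/writer for list-mode, linear, float32 event data.

Covers exactly the dialect this package produces: one dataset per file,
``$DATATYPE/F``, ``$MODE/L``, little-endian ``$BYTEORD/1,2,3,4``, linear
channels (``$PnE/0,0``), no analysis segment and no spillover matrix.  A CSV
"tabular fallback" with one column per channel is supported alongside, and the
two round-trip to identical event tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_fcs", "read_fcs", "read_events_table", "write_events_table"]

_DELIM = "/"
_HEADER_LEN = 58  # "FCS3.1" + 4 spaces + 6 eight-char offsets


class FCSFormatError(ValueError):
    """Raised when a file is not parseable as the supported FCS dialect."""


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [""]
    for k, v in keywords.items():
        if _DELIM in k or _DELIM in str(v):
            raise ValueError(f"delimiter {_DELIM!r} may not appear in keyword {k!r}")
        parts.append(k)
        parts.append(str(v))
    parts.append("")
    return _DELIM.join(parts).encode("ascii")


def write_fcs(path: str | Path, table: pd.DataFrame, metadata: dict[str, str] | None = None) -> None:
    """Write an event table (rows = events, columns = channels) as FCS 3.1."""
    path = Path(path)
    data = np.ascontiguousarray(table.to_numpy(dtype=np.float32))
    n_events, n_par = data.shape
    if n_par == 0:
        raise ValueError("event table must have at least one channel")

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        # placeholders padded to fixed width so the TEXT length is stable
        "$BEGINDATA": "0" * 10,
        "$ENDDATA": "0" * 10,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(table.columns, start=1):
        col_max = float(data[:, i - 1].max()) if n_events else 0.0
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(max(col_max, 1.0)) + 1)
    for k, v in (metadata or {}).items():
        key = k if k.startswith("$") else k.upper()
        keywords.setdefault(key, str(v).replace(_DELIM, "|"))

    text = _text_segment(keywords)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + data.nbytes - 1
    keywords["$BEGINDATA"] = f"{data_begin:010d}"
    keywords["$ENDDATA"] = f"{data_end:010d}"
    text = _text_segment(keywords)
    assert text_begin + len(text) - 1 == text_end  # fixed-width values keep length stable

    def off(x: int) -> bytes:
        s = str(x)
        return s.rjust(8).encode("ascii") if len(s) <= 8 else b"       0"

    header = b"FCS3.1    " + b"".join(
        off(x) for x in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def _parse_text(raw: bytes) -> dict[str, str]:
    txt = raw.decode("ascii", errors="replace")
    delim = txt[0]
    fields = txt[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        raise FCSFormatError("TEXT segment has an odd number of fields")
    return {fields[i]: fields[i + 1] for i in range(0, len(fields), 2)}


def read_fcs(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read one FCS 3.1 dataset; returns (event table, TEXT keywords)."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER_LEN or not blob.startswith(b"FCS3"):
        raise FCSFormatError(f"{path.name}: not an FCS 3.x file")
    try:
        text_begin = int(blob[10:18])
        text_end = int(blob[18:26])
    except ValueError as exc:
        raise FCSFormatError(f"{path.name}: unreadable header offsets") from exc
    if text_end >= len(blob) or text_begin >= text_end:
        raise FCSFormatError(f"{path.name}: truncated TEXT segment")
    kw = _parse_text(blob[text_begin : text_end + 1])

    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise FCSFormatError(f"{path.name}: only list-mode float data is supported")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    dtype = np.dtype("<f4") if byteord == "1,2,3,4" else np.dtype(">f4")
    n_par = int(kw["$PAR"])
    n_events = int(kw["$TOT"])
    data_begin = int(kw.get("$BEGINDATA") or blob[26:34])
    data_end = int(kw.get("$ENDDATA") or blob[34:42])
    expected = n_par * n_events * 4
    if data_end - data_begin + 1 != expected or data_end >= len(blob):
        raise FCSFormatError(
            f"{path.name}: DATA segment size mismatch (truncated or corrupt file)"
        )
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    data = np.frombuffer(blob[data_begin : data_end + 1], dtype=dtype).reshape(
        n_events, n_par
    )
    return pd.DataFrame(np.asarray(data, dtype=np.float64), columns=names), kw


def write_events_table(path: str | Path, table: pd.DataFrame) -> None:
    """Tabular fallback: one CSV column per channel."""
    table.to_csv(path, index=False)


def read_events_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        return read_fcs(path)[0]
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)
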