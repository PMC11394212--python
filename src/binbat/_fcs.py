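"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Supports the subset of the standard this package needs: list mode
(``$MODE L``), float/double/integer data types, little- or big-endian
byte order, one data set per file.  Other versions or layouts are
rejected with a :class:`~binbat.errors.ParseError`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ParseError

_SUPPORTED_VERSIONS = ("FCS3.0", "FCS3.1")


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise ParseError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Escaped delimiters (doubled) are not produced by our writer and are
    # rare in the wild; split-and-rejoin handles the plain case.
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise ParseError("TEXT segment has an odd number of delimited fields")
    kw: dict[str, str] = {}
    for k, v in zip(parts[::2], parts[1::2]):
        kw[k.decode("utf-8", "replace").strip().upper()] = v.decode("utf-8", "replace").strip()
    return kw


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Return (values, channel_names, text_keywords)."""
    data = Path(path).read_bytes()
    if len(data) < 58:
        raise ParseError(f"{path}: too short to be an FCS file")
    version = data[0:6].decode("ascii", "replace")
    if version not in _SUPPORTED_VERSIONS:
        raise ParseError(
            f"{path}: unsupported FCS version {version!r} (supported: {_SUPPORTED_VERSIONS})"
        )

    def _offset(lo: int, hi: int) -> int:
        try:
            return int(data[lo:hi].decode("ascii").strip() or "0")
        except ValueError as exc:
            raise ParseError(f"{path}: bad header offset field") from exc

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    kw = _parse_text(data[text_start : text_end + 1])
    if data_start == 0:
        data_start = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if kw.get("$MODE", "L").upper() != "L":
        raise ParseError(f"{path}: only list mode ($MODE L) is supported")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}N", f"P{i}"))
    bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]

    if datatype == "F":
        if any(b != 32 for b in bits):
            raise ParseError(f"{path}: $DATATYPE F requires 32-bit parameters")
        dt = np.dtype("<f4" if little else ">f4")
    elif datatype == "D":
        if any(b != 64 for b in bits):
            raise ParseError(f"{path}: $DATATYPE D requires 64-bit parameters")
        dt = np.dtype("<f8" if little else ">f8")
    elif datatype == "I":
        widths = set(bits)
        if len(widths) != 1 or widths.pop() not in (16, 32):
            raise ParseError(f"{path}: $DATATYPE I supported only with uniform 16/32-bit widths")
        w = bits[0] // 8
        dt = np.dtype(("<" if little else ">") + f"u{w}")
    else:
        raise ParseError(f"{path}: unsupported $DATATYPE {datatype!r}")

    n_bytes = n_tot * n_par * dt.itemsize
    raw = data[data_start : data_start + n_bytes]
    if len(raw) < n_bytes:
        raise ParseError(f"{path}: DATA segment truncated ({len(raw)} < {n_bytes} bytes)")
    values = np.frombuffer(raw, dtype=dt).reshape(n_tot, n_par).astype(np.float64)
    return values, names, kw


def write_fcs(path: str | Path, values: np.ndarray, channel_names: list[str]) -> None:
    """Write an FCS 3.1 file, list mode, 32-bit little-endian float data."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2 or values.shape[1] != len(channel_names):
        raise ValueError("values must be events x channels matching channel_names")
    n_tot, n_par = values.shape
    delim = "/"
    kw: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for i, name in enumerate(channel_names, start=1):
        if delim in name:
            raise ValueError(f"channel name {name!r} contains the TEXT delimiter")
        kw += [(f"$P{i}B", "32"), (f"$P{i}E", "0,0"),
               (f"$P{i}N", name), (f"$P{i}R", "262144")]

    data_bytes = values.astype("<f4").tobytes(order="C")

    # TEXT length depends on the BEGINDATA/ENDDATA digits; fix with padding.
    def render(begin: int, end: int) -> bytes:
        fields = kw + [("$BEGINDATA", str(begin)), ("$ENDDATA", str(end))]
        out = delim + delim.join(f"{k}{delim}{v}" for k, v in fields) + delim
        return out.encode("ascii")

    header_len = 58
    text_start = header_len
    # iterate to a fixed point on offsets (digit counts stabilise quickly)
    begin, end = 0, 0
    for _ in range(5):
        text = render(begin, end)
        new_begin = text_start + len(text)
        new_end = new_begin + len(data_bytes) - 1
        if (new_begin, new_end) == (begin, end):
            break
        begin, end = new_begin, new_end
    text = render(begin, end)
    text_end = text_start + len(text) - 1

    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{begin:>8d}".encode() if begin <= 99_999_999 else b"       0")
        + (f"{end:>8d}".encode() if end <= 99_999_999 else b"       0")
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text + data_bytes)
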