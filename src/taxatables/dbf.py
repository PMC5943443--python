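"""Minimal dBASE-III (.dbf) reader and writer.

Turboveg stores its species lists and attribute tables as flat DBF files.
Only what those tables need is implemented: character (``C``), numeric
(``N``) and logical (``L``) fields, fixed-width records, configurable text
encoding (DBF headers carry no reliable encoding information, so latin-1 is
the default).  Deleted records (``*`` flag) are skipped on read.
"""

from __future__ import annotations

import datetime as _dt
import struct
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

_HEADER = struct.Struct("<BBBBLHH20x")  # version, Y, M, D, n_records, header_len, record_len
_FIELD = struct.Struct("<11sc4xBB14x")


class DbfError(Exception):
    """Structurally broken or unsupported DBF content."""


@dataclass(frozen=True)
class DbfField:
    """One column of a DBF table."""

    name: str
    type: str  # 'C', 'N' or 'L'
    length: int
    decimals: int = 0

    def __post_init__(self) -> None:
        if self.type not in ("C", "N", "L"):
            raise DbfError(f"unsupported field type '{self.type}' for {self.name}")
        if not 1 <= self.length <= 254:
            raise DbfError(f"field {self.name}: length {self.length} outside 1..254")
        if len(self.name) > 10:
            raise DbfError(f"field name '{self.name}' longer than 10 characters")


def read_dbf(path: str | Path, encoding: str = "latin-1") -> pd.DataFrame:
    """Read a DBF table into a DataFrame.

    ``N`` fields become nullable Int64 (or float64 when declared with
    decimals), ``L`` fields nullable boolean, ``C`` fields stripped strings.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER.size:
        raise DbfError(f"{path}: truncated header")
    version, _, _, _, n_records, header_len, record_len = _HEADER.unpack_from(raw, 0)
    if version & 0x07 != 0x03:
        raise DbfError(f"{path}: unsupported DBF version byte 0x{version:02x}")

    fields: list[DbfField] = []
    offset = _HEADER.size
    while offset < header_len - 1:
        if raw[offset] == 0x0D:
            break
        name_raw, ftype, length, decimals = _FIELD.unpack_from(raw, offset)
        fields.append(
            DbfField(
                name=name_raw.split(b"\x00", 1)[0].decode("ascii", "replace"),
                type=ftype.decode("ascii"),
                length=length,
                decimals=decimals,
            )
        )
        offset += _FIELD.size
    if not fields:
        raise DbfError(f"{path}: no field descriptors")
    expected_len = 1 + sum(f.length for f in fields)
    if expected_len != record_len:
        raise DbfError(f"{path}: record length {record_len} != field sum {expected_len}")

    columns: dict[str, list] = {f.name: [] for f in fields}
    pos = header_len
    for _ in range(n_records):
        if pos + record_len > len(raw):
            raise DbfError(f"{path}: truncated records")
        record = raw[pos : pos + record_len]
        pos += record_len
        if record[0:1] == b"*":  # deleted row
            continue
        cell_pos = 1
        for f in fields:
            cell = record[cell_pos : cell_pos + f.length]
            cell_pos += f.length
            text = cell.decode(encoding).strip()
            if f.type == "C":
                columns[f.name].append(text)
            elif f.type == "N":
                if not text:
                    columns[f.name].append(None)
                elif f.decimals:
                    columns[f.name].append(float(text))
                else:
                    columns[f.name].append(int(float(text)))
            else:  # L
                columns[f.name].append(True if text in "TtYy" else False if text in "FfNn" else None)

    df = pd.DataFrame(columns)
    for f in fields:
        if f.type == "N":
            df[f.name] = df[f.name].astype("float64" if f.decimals else "Int64")
        elif f.type == "L":
            df[f.name] = df[f.name].astype("boolean")
    return df


def write_dbf(
    path: str | Path,
    df: pd.DataFrame,
    fields: list[DbfField],
    encoding: str = "latin-1",
) -> Path:
    """Write a DataFrame as a DBF table with the given field layout.

    Values too long for their field are truncated (characters) or rejected
    (numbers, to avoid silent data corruption).
    """
    for f in fields:
        if f.name not in df.columns:
            raise DbfError(f"column '{f.name}' missing from frame")
    record_len = 1 + sum(f.length for f in fields)
    header_len = _HEADER.size + len(fields) * _FIELD.size + 1
    today = _dt.date.today()
    out = bytearray()
    out += _HEADER.pack(0x03, today.year % 100, today.month, today.day, len(df), header_len, record_len)
    for f in fields:
        out += _FIELD.pack(f.name.encode("ascii").ljust(11, b"\x00"), f.type.encode("ascii"), f.length, f.decimals)
    out += b"\x0d"

    for _, row in df.iterrows():
        out += b" "
        for f in fields:
            value = row[f.name]
            missing = value is None or (pd.api.types.is_scalar(value) and pd.isna(value))
            if f.type == "C":
                text = "" if missing else str(value)
                cell = text.encode(encoding, "replace")[: f.length].ljust(f.length)
            elif f.type == "N":
                if missing:
                    cell = b" " * f.length
                else:
                    text = f"{float(value):.{f.decimals}f}" if f.decimals else str(int(value))
                    if len(text) > f.length:
                        raise DbfError(f"value {text} overflows field {f.name}({f.length})")
                    cell = text.encode("ascii").rjust(f.length)
            else:  # L
                cell = b"?" if missing else (b"T" if value else b"F")
            out += cell
    out += b"\x1a"
    target = Path(path)
    target.write_bytes(bytes(out))
    return target


__all__ = ["DbfField", "DbfError", "read_dbf", "write_dbf"]
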