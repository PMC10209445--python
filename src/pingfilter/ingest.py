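"""Compilation of raw receiver export files into one canonical detection table.

Acoustic receivers are downloaded file by file, often with vendor preamble
rows, split or combined date/time columns, and exact duplicate rows when
download periods overlap. This module discovers all export files in a folder,
parses each one according to a declarative :class:`ColumnMapping` (no
interactive dialogue, so a compile is reproducible), concatenates them in a
deterministic order, and partitions exact duplicates — detections of the same
transmitter on the same receiver at the same instant — into their own bin.

The canonical detection table has columns ``timestamp`` (tz-aware UTC),
``transmitter``, ``receiver``, ``source_file`` plus every retained extra
source column, and is sorted by (timestamp, transmitter, receiver).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError, NoDetectionFilesError, PingFilterError
from .report import PartitionReport
from .timeparse import parse_timestamps

#: Canonical columns every detection table carries, in order.
CORE_COLUMNS = ["timestamp", "transmitter", "receiver", "source_file"]

#: The duplicate key: same tag heard on the same receiver at the same instant.
DUPLICATE_KEY = ["transmitter", "receiver", "timestamp"]


@dataclass(frozen=True)
class ColumnMapping:
    """Declarative description of one raw detection file dialect.

    Parameters
    ----------
    transmitter_column, receiver_column
        Source column labels holding the tag and receiver IDs.
    datetime_mode
        ``"combined"`` (one timestamp column) or ``"split"`` (separate date
        and time columns, concatenated before parsing).
    datetime_columns
        One label (combined) or two labels ``[date, time]`` (split).
    datetime_formats
        Ordered candidate formats; see :mod:`pingfilter.timeparse`.
    header_row
        1-based row index of the column-name row, or ``None`` for headerless
        files (then ``column_names`` must be given).
    skip_rows
        Leading preamble rows to drop before the header.
    drop_columns
        Source columns to discard; everything else is retained as extras.
    delimiter
        Single field-separator character.
    utc_offset_hours
        Receiver clock offset ahead of UTC; timestamps are normalized to UTC.
    """

    transmitter_column: str
    receiver_column: str
    datetime_columns: tuple[str, ...]
    datetime_formats: tuple[str, ...]
    datetime_mode: str = "combined"
    header_row: int | None = 1
    skip_rows: int = 0
    drop_columns: tuple[str, ...] = ()
    delimiter: str = ","
    utc_offset_hours: float = 0.0
    column_names: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "datetime_columns", tuple(self.datetime_columns))
        object.__setattr__(self, "datetime_formats", tuple(self.datetime_formats))
        object.__setattr__(self, "drop_columns", tuple(self.drop_columns))
        if self.column_names is not None:
            object.__setattr__(self, "column_names", tuple(self.column_names))
        if self.datetime_mode not in ("combined", "split"):
            raise ConfigError(f"datetime_mode must be combined|split, got {self.datetime_mode!r}")
        want = 1 if self.datetime_mode == "combined" else 2
        if len(self.datetime_columns) != want:
            raise ConfigError(
                f"datetime_mode={self.datetime_mode!r} needs {want} datetime column(s), "
                f"got {list(self.datetime_columns)}"
            )
        if not self.datetime_formats:
            raise ConfigError("datetime_formats must not be empty")
        if self.transmitter_column == self.receiver_column:
            raise ConfigError("transmitter_column and receiver_column must differ")
        if len(self.delimiter) != 1:
            raise ConfigError("delimiter must be a single character")
        if self.header_row is not None and self.header_row < 1:
            raise ConfigError("header_row is 1-based; use None for headerless files")
        if self.header_row is None and self.column_names is None:
            raise ConfigError("headerless files need explicit column_names")
        if self.skip_rows < 0:
            raise ConfigError("skip_rows must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnMapping":
        d = dict(d)
        hr = d.get("header_row", 1)
        if isinstance(hr, str) and hr.lower() == "none":
            d["header_row"] = None
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMapping":
        doc = yaml.safe_load(Path(path).read_text())
        if isinstance(doc, dict) and "mapping" in doc:
            doc = doc["mapping"]
        return cls.from_dict(doc)

    def with_offset(self, hours: float) -> "ColumnMapping":
        return replace(self, utc_offset_hours=hours)


def scan_files(folder: str | Path, extension: str = ".csv") -> list[Path]:
    """List detection files under ``folder`` whose names end in ``extension``.

    Matching is case-insensitive (vendors export both ``.csv`` and ``.CSV``)
    and the result is sorted lexicographically so the compile order — and
    hence which duplicate copy survives — is deterministic.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise NoDetectionFilesError(f"detection folder does not exist: {folder}")
    ext = extension.lower()
    hits = sorted(
        (p for p in folder.iterdir() if p.is_file() and p.name.lower().endswith(ext)),
        key=lambda p: p.name,
    )
    if not hits:
        raise NoDetectionFilesError(
            f"no detection files with extension {extension!r} found in {folder}"
        )
    return hits


def parse_detection_file(path: str | Path, mapping: ColumnMapping) -> pd.DataFrame:
    """Parse one raw export into canonical detection rows, in source order."""
    path = Path(path)
    raw = path.read_text()
    lines = raw.splitlines()
    body = "\n".join(lines[mapping.skip_rows:])
    header = None if mapping.header_row is None else mapping.header_row - 1
    df = pd.read_csv(
        io.StringIO(body),
        sep=mapping.delimiter,
        header=header,
        names=list(mapping.column_names) if mapping.column_names else None,
        dtype=str,
        keep_default_na=False,
        skip_blank_lines=True,
    )
    missing = [
        c
        for c in (mapping.transmitter_column, mapping.receiver_column, *mapping.datetime_columns)
        if c not in df.columns
    ]
    if missing:
        raise PingFilterError(f"{path.name}: mapped column(s) not found: {missing}")
    df = df.drop(columns=[c for c in mapping.drop_columns if c in df.columns])

    if mapping.datetime_mode == "combined":
        stamp_raw = df[mapping.datetime_columns[0]]
    else:
        date_col, time_col = mapping.datetime_columns
        stamp_raw = df[date_col].str.strip() + " " + df[time_col].str.strip()
    timestamp = parse_timestamps(
        stamp_raw,
        list(mapping.datetime_formats),
        utc_offset_hours=mapping.utc_offset_hours,
        source=path.name,
    )

    transmitter = df[mapping.transmitter_column].str.strip()
    receiver = df[mapping.receiver_column].str.strip()
    if (transmitter == "").any() or (receiver == "").any():
        bad = int(((transmitter == "") | (receiver == "")).sum())
        raise PingFilterError(f"{path.name}: {bad} row(s) with empty transmitter/receiver ID")

    consumed = {mapping.transmitter_column, mapping.receiver_column, *mapping.datetime_columns}
    extras = [c for c in df.columns if c not in consumed]
    out = pd.DataFrame(
        {
            "timestamp": timestamp,
            "transmitter": transmitter,
            "receiver": receiver,
            "source_file": path.name,
        }
    )
    for c in extras:
        out[c] = df[c]
    return out


def partition_duplicates(detections: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split exact duplicates off the detection table.

    For each (transmitter, receiver, timestamp) group of size *k*, the first
    row in compile order is kept and the other *k − 1* go to the duplicates
    bin. Fractional seconds, when present, participate in the key.
    """
    dup = detections.duplicated(subset=DUPLICATE_KEY, keep="first")
    return (
        detections.loc[~dup].reset_index(drop=True),
        detections.loc[dup].reset_index(drop=True),
    )


def sort_canonical(detections: pd.DataFrame) -> pd.DataFrame:
    return detections.sort_values(
        ["timestamp", "transmitter", "receiver"], kind="mergesort"
    ).reset_index(drop=True)


def compile_detections(
    folder: str | Path,
    mapping: ColumnMapping,
    *,
    extension: str = ".csv",
    batch_size: int | None = None,
    dedupe: bool = True,
    report: PartitionReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PartitionReport]:
    """Compile every raw file in ``folder`` into one canonical table.

    ``batch_size`` limits how many files are concatenated at a time; it is a
    memory tactic only and the result is identical for any value. Returns
    ``(detections, duplicates, report)``.
    """
    if batch_size is not None and batch_size < 1:
        raise ConfigError("batch_size must be >= 1")
    files = scan_files(folder, extension)
    step = batch_size or len(files)
    batches = []
    for i in range(0, len(files), step):
        parsed = [parse_detection_file(p, mapping) for p in files[i : i + step]]
        batches.append(pd.concat(parsed, ignore_index=True))
    detections = pd.concat(batches, ignore_index=True)
    n_input = len(detections)

    if dedupe:
        detections, duplicates = partition_duplicates(detections)
    else:
        duplicates = detections.iloc[0:0].copy()
    detections = sort_canonical(detections)

    report = report or PartitionReport()
    report.record("compile", n_input, len(detections), {"duplicates": len(duplicates)})
    return detections, duplicates, report
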