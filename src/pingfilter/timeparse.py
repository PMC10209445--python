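"""Timestamp parsing shared by every reader in the pipeline.

Receiver exports disagree wildly on datetime layout, so a mapping declares an
ordered list of candidate formats and each value is parsed by the first format
that fits. Two format styles are accepted:

* strptime patterns (anything containing ``%``), e.g. ``"%d.%m.%Y %H:%M"``;
* order strings in the ``ymd HMS`` style, where only the order of the
  year/month/day/hour/minute/second fields matters and any non-alphanumeric
  separators are tolerated (``"2021-06-01 12:00:00"`` and ``"2021/6/1
  12:00"`` both parse as ``ymd HMS`` / ``ymd HM``).

All parsed instants are normalized to UTC; a constant clock offset (hours
ahead of UTC) may be declared per input and is subtracted on ingest. A value
that fails every candidate format is an error, never a silent drop.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .errors import ConfigError, TimestampParseError

_ORDER_TOKENS = set("ymdHMS")
_FIELD_SPLIT = re.compile(r"[^0-9.]+")


def _order_tokens(fmt: str) -> list[str]:
    tokens = [c for c in fmt if not c.isspace()]
    if not tokens or any(c not in _ORDER_TOKENS for c in tokens):
        raise ConfigError(
            f"invalid datetime order string {fmt!r}: use characters ymdHMS"
        )
    if len(set(tokens)) != len(tokens):
        raise ConfigError(f"repeated field in datetime order string {fmt!r}")
    return tokens


def _expand_year(v: int) -> int:
    if v >= 100:
        return v
    return 1900 + v if v >= 69 else 2000 + v


def _parse_order_value(value: str, tokens: list[str]) -> pd.Timestamp:
    fields = [f for f in _FIELD_SPLIT.split(value.strip()) if f]
    if len(fields) != len(tokens):
        return pd.NaT
    parts = {"H": 0, "M": 0, "S": 0.0}
    try:
        for tok, fld in zip(tokens, fields):
            parts[tok] = float(fld) if tok == "S" else int(fld)
        sec = parts["S"]
        return pd.Timestamp(
            year=_expand_year(int(parts["y"])),
            month=int(parts["m"]),
            day=int(parts["d"]),
            hour=int(parts["H"]),
            minute=int(parts["M"]),
            second=int(sec),
            microsecond=int(round((sec - int(sec)) * 1e6)),
        )
    except (ValueError, KeyError):
        return pd.NaT


def _apply_format(values: pd.Series, fmt: str) -> pd.Series:
    if "%" in fmt:
        return pd.to_datetime(values, format=fmt, errors="coerce")
    tokens = _order_tokens(fmt)
    return values.map(lambda v: _parse_order_value(v, tokens))


def parse_timestamps(
    values: pd.Series,
    formats: list[str],
    *,
    utc_offset_hours: float = 0.0,
    source: str = "<memory>",
) -> pd.Series:
    """Parse a string series into tz-aware UTC timestamps.

    Each value is tried against ``formats`` in order; the first success wins.
    Raises :class:`TimestampParseError` listing every unparseable value.
    """
    if not formats:
        raise ConfigError("datetime_formats must list at least one format")
    values = values.astype(str)
    out = pd.Series(pd.NaT, index=values.index, dtype="datetime64[ns]")
    todo = pd.Series(True, index=values.index)
    for fmt in formats:
        if not todo.any():
            break
        parsed = _apply_format(values[todo], fmt)
        good = parsed.notna()
        out.loc[good[good].index] = parsed[good]
        todo.loc[good[good].index] = False
    if todo.any():
        bad = values[todo]
        raise TimestampParseError(
            source,
            rows=(np.flatnonzero(todo.to_numpy()) + 1).tolist(),
            values=bad.tolist(),
            formats=formats,
        )
    out = out.dt.tz_localize("UTC")
    if utc_offset_hours:
        out = out - pd.Timedelta(hours=utc_offset_hours)
    return out


def format_timestamps(values: pd.Series) -> pd.Series:
    """Serialize UTC timestamps as ``YYYY-mm-dd HH:MM:SS[.ffffff]``.

    Fractional seconds are emitted only when present, so re-parsing the
    output reproduces the same instants (round-trip invariant).
    """
    base = values.dt.strftime("%Y-%m-%d %H:%M:%S")
    frac = values.dt.microsecond
    if (frac != 0).any():
        with_frac = values.dt.strftime("%Y-%m-%d %H:%M:%S.%f").str.rstrip("0")
        return base.where(frac == 0, with_frac)
    return base


#: Formats that always round-trip the serializer above.
CANONICAL_FORMATS = ["%Y-%m-%d %H:%M:%S.%f", "%Y-%m-%d %H:%M:%S"]
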