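"""Solitary-detection filter.

When an animal is inside a receiver's range it typically stays long enough
to log several detections, so a detection with no same-animal neighbour
within a chosen delay on either side is very likely spurious (a tag-code
collision or noise). The rule is fully configurable: the neighbourhood can
be evaluated per receiver (an animal must be heard twice on the *same*
receiver, cf. the 1 h rule of Kessel et al. 2014) or across the whole array
(cf. the 24 h array-wide rule of Meyer et al.).

Semantics pinned down here:

* a gap of exactly ``delay`` does NOT rescue — "delay hours after the
  previous one" reads as reaching the delay; a neighbour strictly closer
  than ``delay`` rescues;
* detections sharing a timestamp in one group have gap 0 and rescue each
  other;
* flags are computed on the full input in one pass and all flagged rows are
  removed together. The filter is deliberately not iterated: removing a
  detection can isolate its former neighbour, but re-running would erode
  genuine data, so a second application may flag new rows (documented
  non-idempotence).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError
from .report import PartitionReport


@dataclass(frozen=True)
class SolitaryConfig:
    """``delay_hours`` defines the isolation window; ``per_receiver`` picks
    the grouping scope (per receiver vs whole array), always per animal."""

    delay_hours: float = 1.0
    per_receiver: bool = True

    def __post_init__(self):
        if not self.delay_hours > 0:
            raise ConfigError(f"delay must be > 0 hours, got {self.delay_hours}")


def solitary_flags(
    detections: pd.DataFrame,
    config: SolitaryConfig,
    *,
    animal_col: str = "animal",
    receiver_col: str = "receiver",
    time_col: str = "timestamp",
) -> pd.Series:
    """Boolean flag per input row: True where the detection is solitary."""
    key = [animal_col] + ([receiver_col] if config.per_receiver else [])
    d = detections.sort_values(key + [time_col], kind="mergesort")
    grouped = d.groupby(key, sort=False)[time_col]
    gap_prev = d[time_col] - grouped.shift(1)
    gap_next = grouped.shift(-1) - d[time_col]
    delay = pd.Timedelta(hours=config.delay_hours)
    solo = (gap_prev.isna() | (gap_prev >= delay)) & (
        gap_next.isna() | (gap_next >= delay)
    )
    return solo.reindex(detections.index)


def find_solitary(
    detections: pd.DataFrame,
    config: SolitaryConfig,
    *,
    animal_col: str = "animal",
    receiver_col: str = "receiver",
    time_col: str = "timestamp",
    report: PartitionReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PartitionReport]:
    """Partition detections into (kept, solitary) under ``config``."""
    solo = solitary_flags(
        detections,
        config,
        animal_col=animal_col,
        receiver_col=receiver_col,
        time_col=time_col,
    )
    kept = detections.loc[~solo].reset_index(drop=True)
    solitary = detections.loc[solo].reset_index(drop=True)
    report = report or PartitionReport()
    report.record("solitary", len(detections), len(kept), {"solitary": len(solitary)})
    return kept, solitary, report
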