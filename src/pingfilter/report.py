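"""Exhaustive accounting of where every input row ended up.

Every pipeline stage partitions its input into a kept table and one or more
discard bins. The report records, per stage, the input count, the kept count
and each bin count, and enforces the conservation invariant
``input == kept + sum(bins)`` at record time, so a row can never be lost or
double-counted silently.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import PingFilterError


@dataclass
class StageRecord:
    stage: str
    n_input: int
    n_kept: int
    bins: dict[str, int]
    recorded_at: str


@dataclass
class PartitionReport:
    stages: list[StageRecord] = field(default_factory=list)

    def record(self, stage: str, n_input: int, n_kept: int, bins: dict[str, int]) -> None:
        discarded = sum(bins.values())
        if n_input != n_kept + discarded:
            raise PingFilterError(
                f"partition broken at stage {stage!r}: "
                f"input={n_input} != kept={n_kept} + discarded={discarded}"
            )
        self.stages.append(
            StageRecord(
                stage=stage,
                n_input=n_input,
                n_kept=n_kept,
                bins=dict(bins),
                recorded_at=_dt.datetime.now(_dt.timezone.utc).isoformat(),
            )
        )

    @property
    def counts(self) -> dict[str, int]:
        """Aggregate view: initial input, final kept, and each discard bin."""
        out: dict[str, int] = {}
        if self.stages:
            out["input"] = self.stages[0].n_input
            out["kept"] = self.stages[-1].n_kept
        for s in self.stages:
            for name, n in s.bins.items():
                out[name] = out.get(name, 0) + n
        return out

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "stages": [
                {
                    "stage": s.stage,
                    "input": s.n_input,
                    "kept": s.n_kept,
                    "bins": s.bins,
                    "recorded_at": s.recorded_at,
                }
                for s in self.stages
            ],
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
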