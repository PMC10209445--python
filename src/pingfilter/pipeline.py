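"""End-to-end orchestration of the five cleaning stages.

compile → attribute (stations, animals) → solitary filter → speed filter,
with every discard bin retained and a single :class:`PartitionReport`
accounting for all input rows. The actel export is a separate, optional
last step (:func:`pingfilter.export.export_actel`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .attribution import attribute
from .ingest import ColumnMapping, compile_detections
from .report import PartitionReport
from .solitary import SolitaryConfig, find_solitary
from .speed import DistanceMatrix, RangeSpec, SpeedModel, filter_by_speed
from .timeparse import format_timestamps


@dataclass
class PipelineResult:
    kept: pd.DataFrame
    bins: dict[str, pd.DataFrame]
    report: PartitionReport
    speed_iterations: int

    @property
    def n_input(self) -> int:
        return self.report.stages[0].n_input if self.report.stages else 0


@dataclass
class PipelineConfig:
    """Every tunable of the five stages in one place."""

    mapping: ColumnMapping
    solitary: SolitaryConfig = field(default_factory=SolitaryConfig)
    speed_model: SpeedModel | None = None
    ranges: RangeSpec | None = None
    matrix: DistanceMatrix | None = None  # default: haversine from spatial
    max_distance: float | None = None
    discard_first: float = 0.0
    dedupe: bool = True
    batch_size: int | None = None
    extension: str = ".csv"


def run_pipeline(
    detection_folder: str | Path,
    spatial: pd.DataFrame,
    deployments: pd.DataFrame,
    animals: pd.DataFrame,
    config: PipelineConfig,
) -> PipelineResult:
    """Run all stages on a folder of raw files; nothing is written to disk."""
    report = PartitionReport()
    detections, duplicates, _ = compile_detections(
        detection_folder,
        config.mapping,
        extension=config.extension,
        batch_size=config.batch_size,
        dedupe=config.dedupe,
        report=report,
    )
    attributed, out_window, unknown, _ = attribute(
        detections,
        spatial,
        deployments,
        animals,
        discard_first=config.discard_first,
        report=report,
    )
    kept, solitary, _ = find_solitary(attributed, config.solitary, report=report)

    iterations = 1
    removed = kept.iloc[0:0].copy()
    if config.speed_model is not None:
        matrix = config.matrix or DistanceMatrix.from_spatial(spatial)
        ranges = config.ranges or RangeSpec(scalar_range=0.0)
        kept, removed, iterations, _ = filter_by_speed(
            kept,
            matrix,
            config.speed_model,
            ranges,
            max_distance=config.max_distance,
            report=report,
        )

    return PipelineResult(
        kept=kept,
        bins={
            "duplicates": duplicates,
            "out_of_deployment": out_window,
            "unknown_tag": unknown,
            "solitary": solitary,
            "speed_removed": removed,
        },
        report=report,
        speed_iterations=iterations,
    )


def write_result(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Persist kept table, every bin, and the JSON report.

    The kept table is written both as CSV and as a parquet mirror (the
    columnar copy preserves dtypes for large studies).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def dump(df: pd.DataFrame, name: str) -> None:
        d = df.copy()
        if "timestamp" in d.columns and len(d):
            d["timestamp"] = format_timestamps(d["timestamp"])
        p = out / f"{name}.csv"
        d.to_csv(p, index=False)
        paths[name] = p

    dump(result.kept, "detections_kept")
    for name, df in result.bins.items():
        dump(df, name)
    result.kept.to_parquet(out / "detections_kept.parquet", index=False)
    paths["parquet"] = out / "detections_kept.parquet"
    result.report.write(out / "report.json")
    paths["report"] = out / "report.json"
    return paths
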