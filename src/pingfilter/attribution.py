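"""Metadata attribution: join station, deployment and animal data onto
detections and partition out records that cannot belong to the study.

Three metadata tables drive this stage, with canonical column names:

* spatial — one row per station: ``station``, ``latitude``, ``longitude``
  and optionally ``range_category`` (used later by the speed filter);
* deployments — one row per deployment event of one receiver at one station:
  ``receiver``, ``station``, ``start``, ``end``. Windows are closed at both
  ends: a detection logged exactly at deployment or retrieval time counts as
  in-deployment (retrieval stamps are typically written after the unit stops
  listening);
* animals — one row per tag implantation: ``transmitter``, ``animal``,
  ``tagged_at`` plus any biometric columns. A transmitter may be reused in
  several animals consecutively; a detection resolves to the animal with the
  latest tagging time not after the detection.

Detections logged outside any deployment window of their receiver (receiver
on land, in transit, ...) go to the ``out_of_deployment`` bin; detections of
transmitters absent from the animal table, logged before first tagging, or
within the first ``discard_first`` hours after tagging go to the
``unknown_tag`` bin. Unknowns are data, not errors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .report import PartitionReport
from .timeparse import CANONICAL_FORMATS, format_timestamps, parse_timestamps

SPATIAL_COLUMNS = ["station", "latitude", "longitude"]
DEPLOYMENT_COLUMNS = ["receiver", "station", "start", "end"]
ANIMAL_COLUMNS = ["transmitter", "animal", "tagged_at"]


# ---------------------------------------------------------------- readers

def _read_mapped(
    path: str | Path,
    column_map: dict[str, str] | None,
    delimiter: str,
    datetime_formats: list[str] | None,
    time_cols: list[str],
) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in time_cols:
        if col in df.columns:
            df[col] = parse_timestamps(
                df[col],
                datetime_formats or CANONICAL_FORMATS,
                source=f"{Path(path).name}:{col}",
            )
    return df


def read_spatial(path, *, column_map=None, delimiter=",") -> pd.DataFrame:
    df = _read_mapped(path, column_map, delimiter, None, [])
    df["latitude"] = df["latitude"].astype(float)
    df["longitude"] = df["longitude"].astype(float)
    return validate_spatial(df)


def read_deployments(path, *, column_map=None, delimiter=",", datetime_formats=None):
    return _read_mapped(path, column_map, delimiter, datetime_formats, ["start", "end"])


def read_animals(path, *, column_map=None, delimiter=",", datetime_formats=None):
    return _read_mapped(path, column_map, delimiter, datetime_formats, ["tagged_at"])


# ------------------------------------------------------------- validators

def validate_spatial(spatial: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SPATIAL_COLUMNS if c not in spatial.columns]
    if missing:
        raise ValidationError(f"spatial table missing column(s): {missing}")
    dup = spatial["station"][spatial["station"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate station name(s): {sorted(set(dup))}")
    if (spatial["latitude"].abs() > 90).any() or (spatial["longitude"].abs() > 180).any():
        raise ValidationError("station coordinates outside [-90, 90] x [-180, 180]")
    return spatial


def validate_deployments(deployments: pd.DataFrame, spatial: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in deployments.columns]
    if missing:
        raise ValidationError(f"deployment table missing column(s): {missing}")
    if (deployments["start"] >= deployments["end"]).any():
        bad = deployments.loc[deployments["start"] >= deployments["end"], "receiver"]
        raise ValidationError(f"deployment start >= end for receiver(s): {sorted(set(bad))}")
    unknown = set(deployments["station"]) - set(spatial["station"])
    if unknown:
        raise ValidationError(f"deployment references unknown station(s): {sorted(unknown)}")
    # windows are closed, so even a shared endpoint between two deployments
    # of one receiver would make attribution ambiguous
    for receiver, grp in deployments.sort_values("start").groupby("receiver"):
        overlap = grp["start"].iloc[1:].to_numpy() <= grp["end"].iloc[:-1].to_numpy()
        if overlap.any():
            raise ValidationError(f"overlapping deployment windows for receiver {receiver!r}")
    return deployments


def validate_animals(animals: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANIMAL_COLUMNS if c not in animals.columns]
    if missing:
        raise ValidationError(f"animal table missing column(s): {missing}")
    if animals.duplicated(subset=["transmitter", "tagged_at"]).any():
        raise ValidationError("duplicate (transmitter, tagged_at) pair in animal table")
    return animals


def write_standard_tables(
    spatial: pd.DataFrame,
    deployments: pd.DataFrame,
    animals: pd.DataFrame,
    folder: str | Path,
) -> dict[str, Path]:
    """Persist validated metadata in the canonical layout so later runs can
    skip column re-mapping."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    paths = {}
    dep = deployments.copy()
    dep["start"] = format_timestamps(dep["start"])
    dep["end"] = format_timestamps(dep["end"])
    ani = animals.copy()
    ani["tagged_at"] = format_timestamps(ani["tagged_at"])
    for name, df in [("spatial", spatial), ("deployments", dep), ("animals", ani)]:
        p = folder / f"{name}_standard.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


# ------------------------------------------------------------ attribution

def attribute_stations(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    spatial: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach station/coordinate metadata via the deployment windows.

    A detection on receiver *r* at time *t* is attributed to the unique
    deployment of *r* with ``start <= t <= end`` and inherits that station's
    coordinates and range category; everything else goes to the
    out-of-deployment bin.
    """
    validate_spatial(spatial)
    validate_deployments(deployments, spatial)

    det = detections.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    dep = deployments[DEPLOYMENT_COLUMNS].sort_values("start", kind="mergesort")
    joined = pd.merge_asof(
        det,
        dep,
        left_on="timestamp",
        right_on="start",
        by="receiver",
        direction="backward",
    )
    inside = joined["start"].notna() & (joined["timestamp"] <= joined["end"])

    spatial_cols = SPATIAL_COLUMNS + (
        ["range_category"] if "range_category" in spatial.columns else []
    )
    attributed = (
        joined.loc[inside]
        .drop(columns=["start", "end"])
        .merge(spatial[spatial_cols], on="station", how="left")
        .reset_index(drop=True)
    )
    out_of_deployment = (
        joined.loc[~inside].drop(columns=["station", "start", "end"]).reset_index(drop=True)
    )
    return attributed, out_of_deployment


def attribute_animals(
    detections: pd.DataFrame,
    animals: pd.DataFrame,
    *,
    discard_first: float = 0.0,
    biometric_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach animal identity via tagging times; partition unknown tags.

    ``discard_first`` discards each tagging event's first hours (post-surgery
    behaviour is not representative); discarded rows join the unknown bin, as
    do transmitters absent from the animal table and detections logged before
    their transmitter's first tagging.
    """
    validate_animals(animals)
    if biometric_columns is None:
        biometric_columns = [c for c in animals.columns if c not in ANIMAL_COLUMNS]
    missing = [c for c in biometric_columns if c not in animals.columns]
    if missing:
        raise ValidationError(f"animal table missing biometric column(s): {missing}")

    det = detections.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    ani = animals[ANIMAL_COLUMNS + biometric_columns].sort_values(
        "tagged_at", kind="mergesort"
    )
    joined = pd.merge_asof(
        det,
        ani,
        left_on="timestamp",
        right_on="tagged_at",
        by="transmitter",
        direction="backward",
    )
    known = joined["tagged_at"].notna()
    if discard_first:
        known &= joined["timestamp"] >= joined["tagged_at"] + pd.Timedelta(
            hours=discard_first
        )
    attributed = joined.loc[known].drop(columns=["tagged_at"]).reset_index(drop=True)
    unknown = (
        joined.loc[~known]
        .drop(columns=["animal", "tagged_at"] + biometric_columns)
        .reset_index(drop=True)
    )
    return attributed, unknown


def attribute(
    detections: pd.DataFrame,
    spatial: pd.DataFrame,
    deployments: pd.DataFrame,
    animals: pd.DataFrame,
    *,
    discard_first: float = 0.0,
    biometric_columns: list[str] | None = None,
    report: PartitionReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, PartitionReport]:
    """Full attribution stage: stations first, then animals.

    Returns ``(attributed, out_of_deployment, unknown, report)``.
    """
    attributed, out_window = attribute_stations(detections, deployments, spatial)
    attributed, unknown = attribute_animals(
        attributed,
        animals,
        discard_first=discard_first,
        biometric_columns=biometric_columns,
    )
    report = report or PartitionReport()
    report.record(
        "attribute",
        len(detections),
        len(attributed),
        {"out_of_deployment": len(out_window), "unknown_tag": len(unknown)},
    )
    return attributed, out_window, unknown, report
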