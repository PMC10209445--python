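"""Export the cleaned dataset in the input layout of the actel R package.

actel expects four files: a detections table plus three metadata CSVs named
``biometrics.csv``, ``deployments.csv`` and ``spatial.csv`` with its
documented column headers (Station.name / Receiver / Start / Stop /
Release.date / Signal / Group / ...). We write the detections as a portable
``detections.csv`` rather than a language-native serialized object.

Transmitter IDs of the ``CODESPACE-SIGNAL`` form (e.g. ``A69-1601-1234``)
are split on the last hyphen into the code space and the numeric signal
actel matches on; IDs without a hyphen are passed through as the signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .timeparse import format_timestamps

_TIME_FMT = "%Y-%m-%d %H:%M:%S"


@dataclass(frozen=True)
class ExportBundle:
    detections_file: Path
    biometrics_file: Path
    deployments_file: Path
    spatial_file: Path

    def paths(self) -> list[Path]:
        return [
            self.detections_file,
            self.biometrics_file,
            self.deployments_file,
            self.spatial_file,
        ]


def split_transmitter(transmitter: str) -> tuple[str, str]:
    """``A69-1601-1234`` → (``A69-1601``, ``1234``)."""
    code, sep, signal = transmitter.rpartition("-")
    return (code, signal) if sep else ("", transmitter)


def _write_atomic(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_name(path.name + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def export_actel(
    detections: pd.DataFrame,
    animals: pd.DataFrame,
    deployments: pd.DataFrame,
    spatial: pd.DataFrame,
    target_folder: str | Path,
    *,
    group_column: str | None = None,
) -> ExportBundle:
    """Write the four actel input files into ``target_folder``.

    ``group_column`` optionally names an animal-table column to use as the
    actel Group; otherwise all animals share one group.
    """
    for col in ("timestamp", "transmitter", "receiver", "station"):
        if col not in detections.columns:
            raise ValidationError(f"detections missing required column {col!r} for export")
    for col in ("transmitter", "animal", "tagged_at"):
        if col not in animals.columns:
            raise ValidationError(f"animal table missing required column {col!r} for export")

    target = Path(target_folder)
    target.mkdir(parents=True, exist_ok=True)

    codespace_signal = detections["transmitter"].map(split_transmitter)
    det_out = pd.DataFrame(
        {
            "Timestamp": detections["timestamp"].dt.strftime(_TIME_FMT),
            "Receiver": detections["receiver"],
            "CodeSpace": codespace_signal.str[0],
            "Signal": codespace_signal.str[1],
            "Transmitter": detections["transmitter"],
            "Station.name": detections["station"],
        }
    )

    bio = pd.DataFrame(
        {
            "Release.date": animals["tagged_at"].dt.strftime(_TIME_FMT),
            "Signal": animals["transmitter"].map(lambda t: split_transmitter(t)[1]),
            "Group": animals[group_column] if group_column else "animals",
            "Animal.ID": animals["animal"],
        }
    )
    for extra in animals.columns:
        if extra not in ("transmitter", "animal", "tagged_at", group_column):
            bio[extra] = animals[extra]

    dep_out = pd.DataFrame(
        {
            "Receiver": deployments["receiver"],
            "Station.name": deployments["station"],
            "Start": deployments["start"].dt.strftime(_TIME_FMT),
            "Stop": deployments["end"].dt.strftime(_TIME_FMT),
        }
    )

    spa_out = pd.DataFrame(
        {
            "Station.name": spatial["station"],
            "Latitude": spatial["latitude"],
            "Longitude": spatial["longitude"],
            "Array": "A0",
            "Type": "Hydrophone",
        }
    )

    missing = set(dep_out["Station.name"]) - set(spa_out["Station.name"])
    if missing:
        raise ValidationError(f"deployments reference station(s) absent from spatial: {sorted(missing)}")

    bundle = ExportBundle(
        detections_file=target / "detections.csv",
        biometrics_file=target / "biometrics.csv",
        deployments_file=target / "deployments.csv",
        spatial_file=target / "spatial.csv",
    )
    for df, path in zip((det_out, bio, dep_out, spa_out), bundle.paths()):
        _write_atomic(df, path)
    return bundle
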