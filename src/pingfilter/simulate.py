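"""Seeded, ground-truth-labelled synthetic telemetry datasets.

The generator emits exactly the raw material the pipeline consumes — a
folder of receiver export files plus spatial, deployment and animal tables
and a distance matrix — together with a ``truth`` table naming the bin every
row should end up in. It emulates a small coastal array study: four tagged
fish moving among three receiver stations over two weeks, with a mid-study
service break when all receivers are lifted for a day.

Genuine detections are produced in residency bouts (clusters of >= 3 pings
within the solitary delay at one station) and animals move at most one
station between consecutive bouts, hours apart, so genuine data survives
both filters. Five contamination classes are planted, each violating exactly
one rule so bin attribution is unambiguous:

* ``duplicate`` — byte-exact copies of genuine rows (overlapping downloads);
* ``out_of_window`` — known tags logged during the service break;
* ``unknown_tag`` — transmitters from a disjoint ID namespace;
* ``solitary`` — lone same-animal pings placed >= 2x the solitary delay from
  every other detection of that animal;
* ``speed`` — "teleport" ghosts at a distant station seconds after a bout,
  planted in same-receiver clusters of two or three so the solitary rule
  cannot claim them, but requiring speeds far above the animal's maximum.

Movement kinematics are a simple Markov walk over adjacent stations —
plausible enough to exercise the filters, with no pretence of ecological
realism, acoustic propagation or collision physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ingest import ColumnMapping
from .solitary import SolitaryConfig
from .speed import DistanceMatrix, RangeSpec, SpeedModel

_PREAMBLE = [
    "# synthetic receiver export (pingfilter.simulate)",
    "# dialect: combined timestamp, comma separated",
]
_TIME_FMT = "%Y-%m-%d %H:%M:%S"

#: Truth labels, in pipeline order.
LABELS = ["genuine", "duplicate", "out_of_window", "unknown_tag", "solitary", "speed"]


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    The defaults mirror a small test study — four animals on three stations
    for 14 days — with ten planted rows per contamination class, a 1 h
    solitary delay, 150 m receiver range, 1.5 km station spacing, and the
    critical-swimming-speed model 0.019 * TL^0.75 m/s on total length in mm.
    """

    n_animals: int = 4
    n_stations: int = 3
    study_days: int = 14
    detection_rate: float = 1.5  # detections per animal-hour, on average
    n_duplicates: int = 10
    n_out_of_window: int = 10
    n_unknown_tag: int = 10
    n_solitary_ghosts: int = 10
    n_teleport_ghosts: int = 10
    seed: int = 0
    # study geometry / rule parameters the planted rows are calibrated to
    delay_hours: float = 1.0
    receiver_range_m: float = 150.0
    station_spacing_m: float = 1500.0
    speed_base: float = 0.019  # m/s, critical-speed scaling
    speed_exponent: float = 0.75
    bout_period_hours: float = 3.0
    start: str = "2021-05-01 00:00:00"

    def __post_init__(self):
        counts = {
            "n_animals": self.n_animals,
            "n_stations": self.n_stations,
            "study_days": self.study_days,
            "n_duplicates": self.n_duplicates,
            "n_out_of_window": self.n_out_of_window,
            "n_unknown_tag": self.n_unknown_tag,
            "n_solitary_ghosts": self.n_solitary_ghosts,
            "n_teleport_ghosts": self.n_teleport_ghosts,
        }
        for name, v in counts.items():
            low = 1 if name in ("n_animals", "n_stations", "study_days") else 0
            if v < low:
                raise ConfigError(f"{name} must be >= {low}, got {v}")
        if self.n_teleport_ghosts == 1:
            raise ConfigError(
                "n_teleport_ghosts=1 is infeasible: a lone ghost row would be "
                "claimed by the solitary rule; plant 0 or >= 2"
            )
        if self.n_teleport_ghosts > 0 and self.n_stations < 2:
            raise ConfigError("teleport ghosts need at least 2 stations")
        if self.detection_rate <= 0:
            raise ConfigError("detection_rate must be > 0")

    # --- derived pipeline conditions -------------------------------------
    def solitary_config(self) -> SolitaryConfig:
        return SolitaryConfig(delay_hours=self.delay_hours, per_receiver=True)

    def speed_model(self) -> SpeedModel:
        return SpeedModel(
            base=self.speed_base,
            factor_column="length_mm",
            exponent=self.speed_exponent,
            base_unit="m/s",
        )

    def range_spec(self) -> RangeSpec:
        return RangeSpec(scalar_range=self.receiver_range_m)

    def default_mapping(self) -> ColumnMapping:
        return ColumnMapping(
            transmitter_column="Transmitter",
            receiver_column="Receiver",
            datetime_columns=("Date and Time (UTC)",),
            datetime_formats=("%Y-%m-%d %H:%M:%S",),
            datetime_mode="combined",
            header_row=1,
            skip_rows=len(_PREAMBLE),
        )


@dataclass
class SyntheticDataset:
    """Everything :func:`generate` produced, on disk and in memory."""

    config: FixtureConfig
    detection_folder: Path
    spatial: pd.DataFrame
    deployments: pd.DataFrame
    animals: pd.DataFrame
    truth: pd.DataFrame
    matrix: DistanceMatrix
    paths: dict[str, Path] = field(default_factory=dict)


def _station_grid(cfg: FixtureConfig) -> pd.DataFrame:
    # stations on an east-west line; longitude step chosen so consecutive
    # stations are station_spacing_m apart at the study latitude
    lat0, lon0 = 54.0, 12.0
    deg_per_m = 1.0 / (111_194.926 * np.cos(np.radians(lat0)))
    return pd.DataFrame(
        {
            "station": [f"St{i + 1:02d}" for i in range(cfg.n_stations)],
            "latitude": lat0,
            "longitude": [
                lon0 + i * cfg.station_spacing_m * deg_per_m
                for i in range(cfg.n_stations)
            ],
            "range_category": "std",
        }
    )


def generate(config: FixtureConfig, out_dir: str | Path) -> SyntheticDataset:
    """Write a complete synthetic study under ``out_dir``.

    Layout: ``detections/`` with three raw export files, plus
    ``spatial.csv``, ``deployments.csv``, ``animals.csv``,
    ``distance_matrix.csv`` and ``truth.csv``. Fixed seed gives
    byte-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    det_dir = out / "detections"
    det_dir.mkdir(parents=True, exist_ok=True)

    start = pd.Timestamp(cfg.start, tz="UTC")
    end = start + pd.Timedelta(days=cfg.study_days)
    gap_start = start + pd.Timedelta(days=cfg.study_days // 2)
    gap_end = gap_start + pd.Timedelta(hours=24)
    windows = [(start, gap_start), (gap_end, end)]

    spatial = _station_grid(cfg)
    stations = spatial["station"].tolist()
    receivers = {s: f"VR2W-1200{i + 1:02d}" for i, s in enumerate(stations)}
    deployments = pd.DataFrame(
        [
            {"receiver": receivers[s], "station": s, "start": w0, "end": w1}
            for s in stations
            for (w0, w1) in windows
        ]
    )

    animals = pd.DataFrame(
        {
            "transmitter": [f"A69-1601-6{i + 1:04d}" for i in range(cfg.n_animals)],
            "animal": [f"Fish{i + 1:02d}" for i in range(cfg.n_animals)],
            "tagged_at": [
                start - pd.Timedelta(days=30) + pd.Timedelta(hours=i)
                for i in range(cfg.n_animals)
            ],
            "length_mm": np.round(rng.uniform(450, 750, cfg.n_animals), 0),
            "tag_status": "tagged",
        }
    )

    # bout slots: one candidate residency bout every bout_period, kept 1 h
    # clear of every deployment-window edge so planted rows stay unambiguous
    period = pd.Timedelta(hours=cfg.bout_period_hours)
    margin = pd.Timedelta(hours=1)
    slots = []
    t = start + margin
    while t < end:
        if any(t >= w0 + margin and t + margin <= w1 - margin for (w0, w1) in windows):
            slots.append(t)
        t += period
    n_slots = len(slots)

    per_animal_solo = _spread(cfg.n_solitary_ghosts, cfg.n_animals)
    clusters = _teleport_clusters(cfg.n_teleport_ghosts)
    per_animal_clusters = _spread_items(clusters, cfg.n_animals)
    for a in range(cfg.n_animals):
        need = per_animal_solo[a] + len(per_animal_clusters[a])
        if need + 1 > n_slots:
            raise ConfigError(
                f"study too short: animal {a} needs {need} contamination slot(s) "
                f"but only {n_slots} bout slot(s) exist"
            )

    rows: list[dict] = []  # raw detection rows + truth label

    def emit(ts, station, transmitter, label, animal=""):
        rows.append(
            {
                "timestamp": ts.floor("s"),
                "transmitter": transmitter,
                "receiver": receivers[station],
                "station": station,
                "animal": animal,
                "label": label,
                "sensor": int(rng.integers(0, 256)),
            }
        )

    for a in range(cfg.n_animals):
        tx = animals["transmitter"].iloc[a]
        aid = animals["animal"].iloc[a]
        solo_slots = set(
            rng.choice(n_slots, size=per_animal_solo[a], replace=False).tolist()
        )
        bout_slots = [k for k in range(n_slots) if k not in solo_slots]
        attach = rng.choice(
            len(bout_slots), size=len(per_animal_clusters[a]), replace=False
        )
        attach_map = {bout_slots[j]: sz for j, sz in zip(attach, per_animal_clusters[a])}

        station_i = int(rng.integers(0, cfg.n_stations))
        for k in range(n_slots):
            t0 = slots[k]
            if k in solo_slots:
                # lone ghost centred in the emptied slot: >= 2x delay from
                # every neighbouring bout by construction
                ghost_t = t0 + pd.Timedelta(hours=0.25) + pd.Timedelta(
                    seconds=float(rng.uniform(-850, 850))
                )
                emit(ghost_t, stations[station_i], tx, "solitary", aid)
                continue
            station_i = int(np.clip(station_i + rng.integers(-1, 2), 0, cfg.n_stations - 1))
            m = int(np.clip(rng.poisson(cfg.detection_rate * cfg.bout_period_hours), 3, 10))
            t = t0 + pd.Timedelta(seconds=float(rng.uniform(0, 300)))
            last = t
            for _ in range(m):
                emit(last, stations[station_i], tx, "genuine", aid)
                last = last + pd.Timedelta(seconds=float(rng.uniform(30, 150)))
            if k in attach_map:
                # teleport cluster: a far station seconds after the bout
                others = [s for s in range(cfg.n_stations) if s != station_i]
                ghost_station = stations[int(rng.choice(others))]
                for j in range(attach_map[k]):
                    emit(
                        last + pd.Timedelta(seconds=30 + 60 * j),
                        ghost_station,
                        tx,
                        "speed",
                        aid,
                    )

    # out-of-window rows: known tags logged during the service break
    gap_seconds = int((gap_end - gap_start).total_seconds()) - 7200
    if cfg.n_out_of_window:
        offs = rng.choice(gap_seconds, size=cfg.n_out_of_window, replace=False)
        for i, off in enumerate(sorted(offs.tolist())):
            a = i % cfg.n_animals
            emit(
                gap_start + pd.Timedelta(hours=1) + pd.Timedelta(seconds=int(off)),
                stations[int(rng.integers(0, cfg.n_stations))],
                animals["transmitter"].iloc[a],
                "out_of_window",
                animals["animal"].iloc[a],
            )

    # unknown tags: disjoint transmitter namespace, inside deployments
    if cfg.n_unknown_tag:
        w0, w1 = windows[0]
        span = int((w1 - w0).total_seconds()) - 7200
        offs = rng.choice(span, size=cfg.n_unknown_tag, replace=False)
        for i, off in enumerate(sorted(offs.tolist())):
            emit(
                w0 + pd.Timedelta(hours=1) + pd.Timedelta(seconds=int(off)),
                stations[int(rng.integers(0, cfg.n_stations))],
                f"A69-1601-9{i + 1:04d}",
                "unknown_tag",
            )

    raw = pd.DataFrame(rows)
    genuine_idx = raw.index[raw["label"] == "genuine"]
    if cfg.n_duplicates > len(genuine_idx):
        raise ConfigError(
            f"cannot plant {cfg.n_duplicates} duplicates: only "
            f"{len(genuine_idx)} genuine rows generated"
        )
    if cfg.n_duplicates:
        picks = rng.choice(genuine_idx.to_numpy(), size=cfg.n_duplicates, replace=False)
        dup = raw.loc[picks].copy()
        dup["label"] = "duplicate"
        raw = pd.concat([raw, dup], ignore_index=True)

    raw = raw.sort_values(["timestamp", "transmitter", "receiver"], kind="mergesort")
    raw = raw.reset_index(drop=True)

    # --- write everything -------------------------------------------------
    paths: dict[str, Path] = {}
    serial = raw["timestamp"].dt.strftime(_TIME_FMT)
    export = pd.DataFrame(
        {
            "Date and Time (UTC)": serial,
            "Receiver": raw["receiver"],
            "Transmitter": raw["transmitter"],
            "Sensor.Value": raw["sensor"],
        }
    )
    n_files = 3
    bounds = np.linspace(0, len(export), n_files + 1).astype(int)
    for f in range(n_files):
        part = export.iloc[bounds[f] : bounds[f + 1]]
        p = det_dir / f"receiver_export_{f + 1:02d}.csv"
        p.write_text("\n".join(_PREAMBLE) + "\n" + part.to_csv(index=False))
        paths[f"detections_{f + 1}"] = p

    dep_out = deployments.copy()
    dep_out["start"] = dep_out["start"].dt.strftime(_TIME_FMT)
    dep_out["end"] = dep_out["end"].dt.strftime(_TIME_FMT)
    ani_out = animals.copy()
    ani_out["tagged_at"] = ani_out["tagged_at"].dt.strftime(_TIME_FMT)
    matrix = DistanceMatrix.from_spatial(spatial)
    truth = raw[["timestamp", "transmitter", "receiver", "station", "animal", "label"]].copy()
    truth["timestamp"] = serial

    for name, df in [
        ("spatial", spatial),
        ("deployments", dep_out),
        ("animals", ani_out),
        ("truth", truth),
    ]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    p = out / "distance_matrix.csv"
    matrix.to_frame().to_csv(p)
    paths["distance_matrix"] = p

    return SyntheticDataset(
        config=cfg,
        detection_folder=det_dir,
        spatial=spatial,
        deployments=deployments,
        animals=animals,
        truth=truth,
        matrix=matrix,
        paths=paths,
    )


def _spread(n: int, k: int) -> list[int]:
    """Distribute n items over k groups as evenly as possible."""
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _teleport_clusters(n: int) -> list[int]:
    """Split n ghost rows into same-receiver clusters of 2 (one of 3 if odd)."""
    if n == 0:
        return []
    sizes = [2] * (n // 2)
    if n % 2:
        sizes[-1] = 3
    return sizes


def _spread_items(items: list, k: int) -> list[list]:
    out: list[list] = [[] for _ in range(k)]
    for i, item in enumerate(items):
        out[i % k].append(item)
    return out
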