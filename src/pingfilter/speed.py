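"""Speed-feasibility filter: remove detections implying impossible movement.

A detection is infeasible if reaching it from the animal's previous position
would require swimming faster than the animal plausibly can. The required
speed for a consecutive pair of detections is

    required = max(0, d(station_i, station_j) - range_i - range_j) / dt

where ``d`` is the station-to-station distance (great-circle by default, or
an externally supplied in-water matrix), the receiver detection ranges are
subtracted because the animal only has to cross the water *between* the two
detection footprints, and ``dt`` is the elapsed time in hours.

The per-animal maximum speed comes from a power-law model, e.g. the critical
swimming speed scaling ``0.019 · TL^0.75`` m/s for a fish of total length
``TL`` mm (a 616 mm fish works out to 8457 m/h), or a flat speed shared by
all animals.

Filtering sweeps each animal's time-ordered detections, vetting every
detection against the last retained one; a failing detection is flagged and
skipped as an anchor, so one spurious "teleport" does not drag its genuine
successor down with it. The sweep repeats until a pass flags nothing, and by
construction the kept output contains no consecutive-pair violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .report import PartitionReport

EARTH_RADIUS_M = 6_371_000.0


def haversine_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in meters on a sphere of radius 6371 km.

    Accepts scalars or arrays (broadcast). Raises on out-of-range
    coordinates.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if (np.abs(lat1) > 90).any() or (np.abs(lat2) > 90).any():
        raise ValidationError("latitude outside [-90, 90]")
    if (np.abs(lon1) > 180).any() or (np.abs(lon2) > 180).any():
        raise ValidationError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.shape else float(d)


@dataclass
class DistanceMatrix:
    """Symmetric station-to-station distance matrix in meters."""

    stations: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.stations)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} station(s)"
            )
        if (self.values < 0).any():
            raise ValidationError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T, rtol=1e-6, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        self._index = {s: i for i, s in enumerate(self.stations)}

    @classmethod
    def from_spatial(cls, spatial: pd.DataFrame) -> "DistanceMatrix":
        """Haversine matrix from station coordinates. For study areas with
        landmasses, supply an in-water matrix via :meth:`from_file` instead."""
        stations = spatial["station"].tolist()
        if len(set(stations)) != len(stations):
            raise ValidationError("station names must be unique")
        lat = spatial["latitude"].to_numpy(dtype=float)
        lon = spatial["longitude"].to_numpy(dtype=float)
        d = haversine_distance(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        d[np.diag_indices_from(d)] = 0.0
        d = (d + d.T) / 2
        return cls(stations, d)

    @classmethod
    def from_file(
        cls, path: str | Path, spatial: pd.DataFrame | None = None, *, delimiter=","
    ) -> "DistanceMatrix":
        """Load an external matrix (first row and column are station names)
        and validate it against the spatial table if given."""
        df = pd.read_csv(path, sep=delimiter, index_col=0)
        rows, cols = list(df.index.astype(str)), list(df.columns.astype(str))
        if rows != cols:
            raise ValidationError(
                f"distance matrix row labels != column labels: {rows} vs {cols}"
            )
        if spatial is not None:
            expect = set(spatial["station"])
            got = set(rows)
            if expect != got:
                raise ValidationError(
                    f"distance matrix stations do not match spatial table; "
                    f"missing={sorted(expect - got)} extra={sorted(got - expect)}"
                )
        return cls(rows, df.to_numpy(dtype=float))

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as e:
            raise ValidationError(f"station {e.args[0]!r} not in distance matrix") from None

    def indices(self, stations: pd.Series) -> np.ndarray:
        unknown = sorted(set(stations) - set(self._index))
        if unknown:
            raise ValidationError(f"station(s) not in distance matrix: {unknown}")
        return stations.map(self._index).to_numpy(dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.stations, columns=self.stations)


@dataclass(frozen=True)
class SpeedModel:
    """Per-animal maximum sustained speed.

    With a biometric factor: ``speed = base * value ** exponent`` in
    ``base_unit`` (default m/s, converted to m/h). Without a factor, ``base``
    itself is the speed for every animal, by convention already in m/h.
    """

    base: float
    factor_column: str | None = None
    exponent: float | None = None
    base_unit: str | None = None

    def __post_init__(self):
        if not self.base > 0:
            raise ConfigError("speed model base must be > 0")
        if (self.factor_column is None) != (self.exponent is None):
            raise ConfigError("factor_column and exponent must be given together")
        unit = self.base_unit or ("m/s" if self.factor_column else "m/h")
        if unit not in ("m/s", "m/h"):
            raise ConfigError(f"base_unit must be 'm/s' or 'm/h', got {unit!r}")
        object.__setattr__(self, "base_unit", unit)

    def speed_m_per_h(self, biometric_value: float | None = None) -> float:
        """Maximum speed in m/h for one animal."""
        if self.factor_column is None:
            if biometric_value is not None:
                raise ConfigError("model takes no biometric value (factor_column unset)")
            speed = self.base
        else:
            if biometric_value is None:
                raise ConfigError(
                    f"model requires biometric {self.factor_column!r} but none given"
                )
            speed = self.base * float(biometric_value) ** self.exponent
        return speed * 3600.0 if self.base_unit == "m/s" else speed


def animal_speed(model: SpeedModel, biometric_value: float | None = None) -> float:
    """Functional alias for :meth:`SpeedModel.speed_m_per_h`."""
    return model.speed_m_per_h(biometric_value)


def animal_speed_table(detections: pd.DataFrame, model: SpeedModel) -> pd.DataFrame:
    """One row per animal with its computed maximum speed (m/h) — the
    sanity-check table echoed to the user before filtering."""
    rows = []
    for animal, grp in detections.groupby("animal", sort=True):
        if model.factor_column is None:
            value = None
        else:
            if model.factor_column not in grp.columns:
                raise ConfigError(
                    f"biometric column {model.factor_column!r} missing from detections"
                )
            raw = grp[model.factor_column].iloc[0]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise ConfigError(
                    f"animal {animal!r} has no usable biometric "
                    f"{model.factor_column!r} (got {raw!r})"
                ) from None
        rows.append({"animal": animal, "biometric": value, "speed_m_per_h": model.speed_m_per_h(value)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RangeSpec:
    """Receiver detection range: a single scalar in meters, or a table
    ``(range_category, start, end, range_m)`` for ranges that differ by
    station category and/or change over time."""

    scalar_range: float | None = None
    table: pd.DataFrame | None = None

    def __post_init__(self):
        if (self.scalar_range is None) == (self.table is None):
            raise ConfigError("give exactly one of scalar_range or table")
        if self.scalar_range is not None and self.scalar_range < 0:
            raise ConfigError("receiver range must be >= 0")
        if self.table is not None:
            need = {"range_category", "start", "end", "range_m"}
            if not need.issubset(self.table.columns):
                raise ConfigError(f"range table needs columns {sorted(need)}")
            if (self.table["range_m"].astype(float) < 0).any():
                raise ConfigError("range table has negative range_m")
            for cat, grp in self.table.sort_values("start").groupby("range_category"):
                if (grp["start"].iloc[1:].to_numpy() <= grp["end"].iloc[:-1].to_numpy()).any():
                    raise ConfigError(f"overlapping range intervals for category {cat!r}")

    @classmethod
    def from_file(cls, path, *, delimiter=",", datetime_formats=None) -> "RangeSpec":
        from .timeparse import CANONICAL_FORMATS, parse_timestamps

        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
        for col in ("start", "end"):
            df[col] = parse_timestamps(
                df[col], datetime_formats or CANONICAL_FORMATS, source=f"{path}:{col}"
            )
        df["range_m"] = df["range_m"].astype(float)
        return cls(table=df)

    def resolve(self, detections: pd.DataFrame) -> np.ndarray:
        """Per-detection receiver range in meters."""
        if self.scalar_range is not None:
            return np.full(len(detections), float(self.scalar_range))
        if "range_category" not in detections.columns:
            raise ConfigError(
                "time-varying ranges need a range_category column on detections "
                "(declare one in the spatial table)"
            )
        out = np.full(len(detections), np.nan)
        ts = detections["timestamp"].astype("int64").to_numpy()
        cats = detections["range_category"].to_numpy()
        for _, row in self.table.iterrows():
            m = (cats == row["range_category"]) & (ts >= row["start"].value) & (
                ts <= row["end"].value
            )
            out[m] = float(row["range_m"])
        if np.isnan(out).any():
            i = int(np.flatnonzero(np.isnan(out))[0])
            raise ConfigError(
                f"no range interval covers category "
                f"{cats[i]!r} at {detections['timestamp'].iloc[i]}"
            )
        return out


def effective_distance(d, range_a, range_b, *, both_ends: bool = True):
    """Minimum water an animal must cross between two detection footprints:
    station distance minus the detection range(s), floored at zero.

    Subtracting both endpoint ranges is the physically conservative bound;
    ``both_ends=False`` subtracts only the destination's range.
    """
    d = np.asarray(d, dtype=float)
    ra = np.asarray(range_a, dtype=float)
    rb = np.asarray(range_b, dtype=float)
    eff = np.maximum(0.0, d - (ra if both_ends else 0.0) - rb)
    return eff if eff.shape else float(eff)


def filter_by_speed(
    detections: pd.DataFrame,
    matrix: DistanceMatrix,
    model: SpeedModel,
    ranges: RangeSpec,
    *,
    max_distance: float | None = None,
    both_ends: bool = True,
    animal_col: str = "animal",
    report: PartitionReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, int, PartitionReport]:
    """Iteratively remove detections implying impossible speeds.

    Per animal, detections are ordered by (timestamp, receiver). Each pass
    vets every retained detection against the last retained one before it:
    it is flagged when the required speed exceeds the animal's maximum, or
    when ``max_distance`` is set and the raw station distance exceeds it. A
    flagged detection never serves as a comparison anchor within the pass.
    All flagged rows are removed together and the pass repeats until one
    flags nothing, so the kept output has no consecutive-pair violation.

    Returns ``(kept, removed, iterations, report)`` where ``iterations``
    counts passes over the worst animal (>= 1; the final pass flags nothing).
    """
    det = detections.sort_values(
        [animal_col, "timestamp", "receiver"], kind="mergesort"
    ).reset_index(drop=True)
    if "station" not in det.columns:
        raise ValidationError("speed filter needs attributed detections (station column)")

    st_idx = matrix.indices(det["station"])
    rng = ranges.resolve(det)
    t_h = det["timestamp"].astype("int64").to_numpy() / 3.6e12  # hours
    D = matrix.values

    removed_mask = np.zeros(len(det), dtype=bool)
    iterations = 0
    for animal, grp in det.groupby(animal_col, sort=False):
        idx = grp.index.to_numpy()
        if model.factor_column is None:
            vmax = model.speed_m_per_h()
        else:
            if model.factor_column not in det.columns:
                raise ConfigError(
                    f"biometric column {model.factor_column!r} missing from detections"
                )
            raw = grp[model.factor_column].iloc[0]
            try:
                vmax = model.speed_m_per_h(float(raw))
            except (TypeError, ValueError):
                raise ConfigError(
                    f"animal {animal!r} has no usable biometric "
                    f"{model.factor_column!r} (got {raw!r})"
                ) from None

        retained = list(idx)
        passes = 0
        while True:
            passes += 1
            flagged = []
            anchor = None
            for i in retained:
                if anchor is None:
                    anchor = i
                    continue
                d = D[st_idx[anchor], st_idx[i]]
                bad = max_distance is not None and d > max_distance
                if not bad:
                    eff = effective_distance(
                        d, rng[anchor], rng[i], both_ends=both_ends
                    )
                    if eff > 0:
                        dt = t_h[i] - t_h[anchor]
                        bad = dt <= 0 or eff / dt > vmax
                if bad:
                    flagged.append(i)
                else:
                    anchor = i
            if not flagged:
                break
            removed_mask[flagged] = True
            retained = [i for i in retained if not removed_mask[i]]
        iterations = max(iterations, passes)

    kept = det.loc[~removed_mask].reset_index(drop=True)
    removed = det.loc[removed_mask].reset_index(drop=True)
    report = report or PartitionReport()
    report.record("speed", len(det), len(kept), {"speed_removed": len(removed)})
    return kept, removed, iterations, report


def audit_speed(
    detections: pd.DataFrame,
    matrix: DistanceMatrix,
    model: SpeedModel,
    ranges: RangeSpec,
    *,
    max_distance: float | None = None,
    both_ends: bool = True,
    animal_col: str = "animal",
) -> int:
    """Independent post-condition scan: count consecutive-pair violations in
    a (supposedly clean) detection table. Zero means the speed filter's
    contract holds."""
    det = detections.sort_values(
        [animal_col, "timestamp", "receiver"], kind="mergesort"
    ).reset_index(drop=True)
    rng = ranges.resolve(det)
    violations = 0
    for animal, grp in det.groupby(animal_col, sort=False):
        if model.factor_column is None:
            vmax = model.speed_m_per_h()
        else:
            vmax = model.speed_m_per_h(float(grp[model.factor_column].iloc[0]))
        idx = grp.index.to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            d = matrix.lookup(det["station"].iloc[a], det["station"].iloc[b])
            if max_distance is not None and d > max_distance:
                violations += 1
                continue
            eff = effective_distance(d, rng[a], rng[b], both_ends=both_ends)
            if eff > 0:
                dt = (
                    det["timestamp"].iloc[b] - det["timestamp"].iloc[a]
                ).total_seconds() / 3600.0
                if dt <= 0 or eff / dt > vmax:
                    violations += 1
    return violations
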