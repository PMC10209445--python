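import numpy as np
import pandas as pd
import pytest

from pingfilter import (
    ConfigError,
    DistanceMatrix,
    RangeSpec,
    SpeedModel,
    ValidationError,
    animal_speed,
    audit_speed,
    effective_distance,
    filter_by_speed,
    haversine_distance,
)

DEG_M = 6_371_000 * np.pi / 180  # meters per degree of great-circle arc


# -------------------------------------------------------------- haversine

def test_haversine_zero_at_identical_points():
    assert haversine_distance(54.0, 12.0, 54.0, 12.0) == 0.0


def test_haversine_equatorial_degree_closed_form():
    assert haversine_distance(0.0, 0.0, 0.0, 1.0) == pytest.approx(DEG_M, abs=0.1)


def test_haversine_symmetry_on_random_pairs():
    rng = np.random.default_rng(0)
    lat1, lat2 = rng.uniform(-90, 90, (2, 1000))
    lon1, lon2 = rng.uniform(-180, 180, (2, 1000))
    np.testing.assert_allclose(
        haversine_distance(lat1, lon1, lat2, lon2),
        haversine_distance(lat2, lon2, lat1, lon1),
        rtol=1e-12,
    )


def test_haversine_rejects_out_of_range_coordinates():
    with pytest.raises(ValidationError):
        haversine_distance(91.0, 0.0, 0.0, 0.0)


# -------------------------------------------------------- distance matrix

def small_spatial(n=3, spacing_m=1500.0, lat=54.0):
    step = spacing_m / (111_194.926 * np.cos(np.radians(lat)))
    return pd.DataFrame(
        {
            "station": [f"S{i + 1}" for i in range(n)],
            "latitude": lat,
            "longitude": [12.0 + i * step for i in range(n)],
            "range_category": "std",
        }
    )


def test_matrix_from_spatial_shape_and_invariants():
    m = DistanceMatrix.from_spatial(small_spatial(3))
    assert m.values.shape == (3, 3)
    assert np.allclose(np.diag(m.values), 0)
    assert np.allclose(m.values, m.values.T)
    assert m.lookup("S1", "S2") == pytest.approx(1500, rel=1e-3)
    assert m.lookup("S1", "S3") == pytest.approx(3000, rel=1e-3)


def test_external_matrix_label_mismatch_rejected(tmp_path):
    p = tmp_path / "m.csv"
    p.write_text(",S1,S2\nS1,0,100\nS2,100,0\n")
    with pytest.raises(ValidationError, match="S3"):
        DistanceMatrix.from_file(p, small_spatial(3))


def test_external_asymmetric_matrix_rejected(tmp_path):
    p = tmp_path / "m.csv"
    p.write_text(",S1,S2\nS1,0,100\nS2,999,0\n")
    with pytest.raises(ValidationError, match="symmetric"):
        DistanceMatrix.from_file(p)


# ------------------------------------------------------------ speed model

def test_critical_speed_worked_example():
    """A 616 mm fish under speed = 0.019 * TL^0.75 m/s swims 8457 m/h."""
    model = SpeedModel(base=0.019, factor_column="TL", exponent=0.75)
    assert round(animal_speed(model, 616)) == 8457


def test_flat_speed_is_already_m_per_h():
    assert animal_speed(SpeedModel(base=3600)) == 3600


def test_exponent_zero_reduces_to_base():
    model = SpeedModel(base=2.0, factor_column="TL", exponent=0.0)
    assert animal_speed(model, 123.0) == pytest.approx(2.0 * 3600)


def test_explicit_unit_overrides_default():
    model = SpeedModel(base=0.019, factor_column="TL", exponent=0.75, base_unit="m/h")
    assert animal_speed(model, 616) == pytest.approx(0.019 * 616**0.75)


def test_missing_biometric_is_an_error():
    model = SpeedModel(base=0.019, factor_column="TL", exponent=0.75)
    with pytest.raises(ConfigError):
        animal_speed(model)
    with pytest.raises(ConfigError):
        SpeedModel(base=1.0, factor_column="TL")  # exponent missing


# ------------------------------------------------------ effective distance

@pytest.mark.parametrize(
    "d, ra, rb, expected",
    [(1000, 200, 300, 500), (400, 200, 300, 0), (0, 200, 300, 0)],
)
def test_effective_distance(d, ra, rb, expected):
    assert effective_distance(d, ra, rb) == expected


def test_single_ended_range_subtraction():
    assert effective_distance(1000, 200, 300, both_ends=False) == 700


# ---------------------------------------------------------- speed filter

def detections_at(stations, hours, animal="A1", length=616.0):
    t0 = pd.Timestamp("2021-06-01", tz="UTC")
    return pd.DataFrame(
        {
            "timestamp": [t0 + pd.Timedelta(hours=h) for h in hours],
            "animal": animal,
            "transmitter": "T1",
            "receiver": [s.replace("S", "R") for s in stations],
            "station": stations,
            "range_category": "std",
            "length_mm": length,
        }
    )


MODEL = SpeedModel(base=0.019, factor_column="length_mm", exponent=0.75)
RANGES = RangeSpec(scalar_range=150.0)


def far_matrix(d=10_300.0):
    """Two stations d meters apart (effective 10,000 m at 150 m ranges)."""
    return DistanceMatrix(["S1", "S2"], np.array([[0.0, d], [d, 0.0]]))


def test_planted_infeasible_pair_removes_later_detection():
    # 10,000 m effective in 0.5 h needs 20,000 m/h; the fish can do 8457
    det = detections_at(["S1", "S2"], [0.0, 0.5])
    kept, removed, iters, _ = filter_by_speed(det, far_matrix(), MODEL, RANGES)
    assert removed["station"].tolist() == ["S2"]
    assert kept["station"].tolist() == ["S1"]


def test_single_station_is_a_no_op_with_one_pass():
    det = detections_at(["S1"] * 5, [0, 0.1, 0.2, 5.0, 9.0])
    kept, removed, iters, _ = filter_by_speed(det, far_matrix(), MODEL, RANGES)
    assert len(removed) == 0 and len(kept) == 5
    assert iters == 1


def test_ghost_spike_removed_neighbours_survive():
    """A -> ghost -> B where both ghost legs are infeasible but A -> B is
    fine: the ghost goes in pass 1 and pass 2 confirms convergence."""
    det = detections_at(["S1", "S2", "S1"], [0.0, 0.25, 0.5])
    kept, removed, iters, _ = filter_by_speed(det, far_matrix(), MODEL, RANGES)
    assert removed["station"].tolist() == ["S2"]
    assert kept["station"].tolist() == ["S1", "S1"]
    assert iters == 2


def test_simultaneous_detections_at_distant_stations():
    """dt = 0 across a positive effective distance implies infinite speed;
    the later-sorted detection is removed."""
    det = detections_at(["S1", "S2"], [0.0, 0.0])
    kept, removed, _, _ = filter_by_speed(det, far_matrix(), MODEL, RANGES)
    assert kept["station"].tolist() == ["S1"]
    assert removed["station"].tolist() == ["S2"]


def test_overlapping_ranges_make_any_speed_feasible():
    # stations 250 m apart with 150 m ranges: footprints overlap, eff = 0
    det = detections_at(["S1", "S2"], [0.0, 0.0])
    kept, removed, _, _ = filter_by_speed(det, far_matrix(250.0), MODEL, RANGES)
    assert len(removed) == 0


def test_infinite_speed_keeps_everything():
    rng = np.random.default_rng(5)
    det = detections_at(
        list(rng.choice(["S1", "S2"], 40)), sorted(rng.uniform(0, 48, 40))
    )
    model = SpeedModel(base=1e12)  # m/h
    kept, removed, _, _ = filter_by_speed(det, far_matrix(), model, RANGES)
    assert len(removed) == 0 and len(kept) == 40


def test_max_distance_rule_uses_raw_station_distance():
    det = detections_at(["S1", "S2"], [0.0, 1000.0])  # speed is trivially fine
    kept, removed, _, _ = filter_by_speed(
        det, far_matrix(), MODEL, RANGES, max_distance=5000.0
    )
    assert removed["station"].tolist() == ["S2"]


def test_unknown_station_errors():
    det = detections_at(["S9"], [0.0])
    with pytest.raises(ValidationError, match="S9"):
        filter_by_speed(det, far_matrix(), MODEL, RANGES)


def test_removed_set_shrinks_as_speed_threshold_rises():
    rng = np.random.default_rng(9)
    n = 120
    det = detections_at(
        list(rng.choice(["S1", "S2"], n)), sorted(rng.uniform(0, 24, n).tolist())
    )
    removed_counts = []
    for base_mh in (500.0, 2000.0, 8000.0, 50_000.0):
        model = SpeedModel(base=base_mh)  # flat speed in m/h
        _, removed, _, _ = filter_by_speed(det, far_matrix(3000.0), model, RANGES)
        removed_counts.append(len(removed))
    assert removed_counts == sorted(removed_counts, reverse=True)


def test_post_condition_audit_and_termination_on_random_fixtures():
    rng = np.random.default_rng(17)
    for _ in range(10):
        n = int(rng.integers(10, 150))
        det = detections_at(
            list(rng.choice(["S1", "S2"], n)),
            sorted(rng.uniform(0, 12, n).tolist()),
        )
        kept, removed, iters, _ = filter_by_speed(det, far_matrix(3000.0), MODEL, RANGES)
        assert len(kept) + len(removed) == n
        assert 1 <= iters <= n
        assert audit_speed(kept, far_matrix(3000.0), MODEL, RANGES) == 0


# ---------------------------------------------------------------- ranges

def test_time_varying_range_changes_the_verdict():
    """A mid-study range increase makes the same spatial jump feasible
    after the change but not before."""
    t0 = pd.Timestamp("2021-06-01", tz="UTC")
    table = pd.DataFrame(
        {
            "range_category": ["std", "std"],
            "start": [t0, t0 + pd.Timedelta(days=10)],
            "end": [t0 + pd.Timedelta(days=10) - pd.Timedelta(seconds=1), t0 + pd.Timedelta(days=20)],
            "range_m": [150.0, 5100.0],
        }
    )
    ranges = RangeSpec(table=table)
    before = detections_at(["S1", "S2"], [0.0, 0.5])
    after = detections_at(["S1", "S2"], [260.0, 260.5])
    _, removed_before, _, _ = filter_by_speed(before, far_matrix(), MODEL, ranges)
    _, removed_after, _, _ = filter_by_speed(after, far_matrix(), MODEL, ranges)
    assert len(removed_before) == 1  # 10,000 m effective at 150 m ranges
    assert len(removed_after) == 0  # footprints overlap at 5,100 m ranges


def test_uncovered_range_interval_is_an_error():
    t0 = pd.Timestamp("2021-06-01", tz="UTC")
    table = pd.DataFrame(
        {
            "range_category": ["std"],
            "start": [t0],
            "end": [t0 + pd.Timedelta(days=1)],
            "range_m": [150.0],
        }
    )
    det = detections_at(["S1"], [100.0])  # outside the covered day
    with pytest.raises(ConfigError, match="range"):
        filter_by_speed(det, far_matrix(), MODEL, RangeSpec(table=table))


def test_range_spec_scalar_xor_table_enforced():
    with pytest.raises(ConfigError):
        RangeSpec()
    with pytest.raises(ConfigError):
        RangeSpec(scalar_range=100.0, table=pd.DataFrame())
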