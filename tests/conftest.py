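import numpy as np
import pandas as pd
import pytest

from pingfilter import FixtureConfig, PipelineConfig, generate, run_pipeline


def make_detections(rows):
    """Canonical detection table from (timestamp, transmitter, receiver, ...)
    tuples; extra keys become extra columns."""
    df = pd.DataFrame(rows)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    if "source_file" not in df.columns:
        df["source_file"] = "test.csv"
    return df


def write_raw_file(path, rows, *, preamble=(), header="Date and Time (UTC),Receiver,Transmitter,Sensor.Value"):
    """Write a raw receiver export: rows are (timestamp_str, receiver, transmitter, sensor)."""
    lines = list(preamble) + [header]
    for r in rows:
        lines.append(",".join(str(x) for x in r))
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture(scope="session")
def fixture_config():
    return FixtureConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(fixture_config, tmp_path_factory):
    return generate(fixture_config, tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def pipeline_config(fixture_config):
    return PipelineConfig(
        mapping=fixture_config.default_mapping(),
        solitary=fixture_config.solitary_config(),
        speed_model=fixture_config.speed_model(),
        ranges=fixture_config.range_spec(),
    )


@pytest.fixture(scope="session")
def result(dataset, pipeline_config):
    return run_pipeline(
        dataset.detection_folder,
        dataset.spatial,
        dataset.deployments,
        dataset.animals,
        pipeline_config,
    )


def detection_keys(df):
    """Sorted (timestamp, transmitter, receiver) key multiset of a table."""
    ts = df["timestamp"]
    if len(df) and ts.dtype != object:
        ts = ts.dt.strftime("%Y-%m-%d %H:%M:%S")
    return sorted(zip(ts, df["transmitter"], df["receiver"]))


def truth_keys(truth, labels):
    if isinstance(labels, str):
        labels = [labels]
    t = truth[truth["label"].isin(labels)]
    return sorted(zip(t["timestamp"], t["transmitter"], t["receiver"]))


def random_detections(rng, n, *, n_animals=3, n_receivers=3, span_hours=48.0):
    """Unstructured random detection table for oracle comparisons."""
    t0 = pd.Timestamp("2021-05-01", tz="UTC")
    seconds = rng.uniform(0, span_hours * 3600, n)
    return pd.DataFrame(
        {
            "timestamp": [t0 + pd.Timedelta(seconds=float(s)) for s in seconds],
            "animal": rng.choice([f"A{i}" for i in range(n_animals)], n),
            "receiver": rng.choice([f"R{i}" for i in range(n_receivers)], n),
            "transmitter": "T0",
        }
    )
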