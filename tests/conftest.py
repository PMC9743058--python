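import numpy as np
import pandas as pd
import pytest

from broodtrack import io_tracks, simulate
from broodtrack.io_tracks import Trajectory


def make_traj(
    xy: np.ndarray,
    interval_s: float = 60.0,
    start: str = "2019-05-01",
    tag_id: str = "T1",
    times_s: np.ndarray | None = None,
) -> Trajectory:
    """Trajectory straight from planar coordinates (lon/lat set to zero)."""
    xy = np.asarray(xy, dtype=float)
    if times_s is None:
        times_s = np.arange(len(xy)) * interval_s
    ts = pd.Timestamp(start) + pd.to_timedelta(times_s, unit="s")
    df = pd.DataFrame(
        {"timestamp": ts, "lon": 0.0, "lat": 0.0, "n_satellites": 9,
         "x": xy[:, 0], "y": xy[:, 1]}
    )
    return Trajectory(tag_id, df, sampling_interval=pd.Timedelta(seconds=interval_s))


@pytest.fixture(scope="session")
def sim_bird():
    """One default simulated bird (pre / incubation / chick guarding / post)."""
    out = simulate.simulate_bird(simulate.SimConfig(seed=42))
    traj = io_tracks.prepare(out.trajectory)
    return out, traj


@pytest.fixture
def track_csv(tmp_path):
    """Factory writing a small raw track CSV and returning its path."""

    def _write(rows: list[dict], name: str = "tracks.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write
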