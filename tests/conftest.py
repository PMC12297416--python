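import numpy as np
import pytest

from spt.trajectory_io import CellGeometry, Dataset, Localization, Trajectory

DT = 0.005
PULSE = 0.003


def make_traj(traj_id, frames, xy, cell_id="c0", exp_id="e0", dt=DT, pulse=PULSE,
              loc_sd=None):
    pts = [
        Localization(frame=int(f), x=float(x), y=float(y), loc_sd=loc_sd)
        for f, (x, y) in zip(frames, xy)
    ]
    return Trajectory(traj_id=traj_id, cell_id=cell_id, experiment_id=exp_id,
                      points=pts, frame_interval=dt, pulse_duration=pulse)


def make_cell(cell_id="c0", exp_id="e0", center=(10.0, 10.0), orientation=0.0,
              length=3.0, width=0.8):
    return CellGeometry(cell_id=cell_id, experiment_id=exp_id, center=center,
                        orientation=orientation, length=length, width=width)


def random_dataset(rng, n_traj=5, n_pts=10, dt=DT, pulse=PULSE):
    """Small random-walk dataset in one cell, no gaps."""
    trajs = []
    for i in range(n_traj):
        xy = np.cumsum(rng.normal(0, 0.1, size=(n_pts, 2)), axis=0) + 10.0
        trajs.append(make_traj(f"t{i}", np.arange(n_pts), xy, dt=dt, pulse=pulse))
    return Dataset(trajectories=trajs, cells=[make_cell()], condition="test")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)
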