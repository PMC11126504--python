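import numpy as np
import pytest
from hypothesis import settings

from antwalks.trajectory import Trajectory

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_traj(thorax, head=None, frame_rate=25.0, label="unknown"):
    """Trajectory from a thorax point list; head defaults to 0.4 cm North of it."""
    thorax = np.asarray(thorax, dtype=float)
    if head is None:
        head = thorax + np.array([0.0, 0.4])
    return Trajectory(
        frame_index=np.arange(len(thorax)),
        head=np.asarray(head, dtype=float),
        thorax=thorax,
        frame_rate=frame_rate,
        label=label,
    )


@pytest.fixture
def straight_walk():
    """Constant-speed straight path: 1 cm East per frame for 2 s."""
    n = 51
    pts = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return make_traj(pts)


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """A 5-ant synthetic study input tree (written once per session)."""
    from antwalks.synthetic import ExperimentConfig, gen_experiment

    out = tmp_path_factory.mktemp("study")
    gen_experiment(ExperimentConfig(n_ants=5, seed=11), out)
    return out
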