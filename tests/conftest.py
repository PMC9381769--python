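import numpy as np
import pytest

from hippoquant.core import ArenaConfig, Trajectory


@pytest.fixture
def arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture
def small_arena() -> ArenaConfig:
    """Coarse grid for hand-checkable maps."""
    return ArenaConfig(side_length=10.0, n_bins_per_side=5, dt=0.1)


def make_path_trajectory(
    points: list[tuple[float, float]],
    dt: float = 0.1,
    arena: ArenaConfig | None = None,
) -> Trajectory:
    """Trajectory visiting the given (x, y) points at fixed dt."""
    pts = np.asarray(points, float)
    t = np.arange(pts.shape[0]) * dt
    return Trajectory(t=t, x=pts[:, 0], y=pts[:, 1], arena=arena)
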