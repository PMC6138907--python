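import numpy as np
import pytest

from mzlspatial import (
    SimulationConfig,
    ThomasParams,
    Window,
    simulate_csr,
    simulate_thomas,
)

UNIT_WINDOW = Window(0.0, 0.0, 1000.0, 1000.0)


@pytest.fixture
def window():
    return UNIT_WINDOW


@pytest.fixture
def csr_pattern(window):
    return simulate_csr(SimulationConfig(window=window, seed=42, intensity=1e-3))


@pytest.fixture
def thomas_pattern(window):
    cfg = SimulationConfig(
        window=window,
        seed=42,
        process_kind="thomas",
        thomas=ThomasParams(parent_intensity=5e-5, mean_offspring=20.0, cluster_sd=20.0),
    )
    return simulate_thomas(cfg)


def brute_force_k(x, y, area, n, radii):
    """O(n²) pair-count oracle for the uncorrected K estimator."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    np.fill_diagonal(d, np.inf)
    return np.array([area / (n * (n - 1)) * (d <= r).sum() for r in radii])


def brute_force_nn(qx, qy, tx, ty):
    """O(n·m) oracle for cross-type nearest-neighbour distances."""
    qx = np.asarray(qx, float)[:, None]
    qy = np.asarray(qy, float)[:, None]
    tx = np.asarray(tx, float)[None, :]
    ty = np.asarray(ty, float)[None, :]
    return np.sqrt((qx - tx) ** 2 + (qy - ty) ** 2).min(axis=1)
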