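import numpy as np
import pytest

from sawdesign.acoustics import FieldSolver, SimConfig


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def default_solver(default_config):
    return FieldSolver(default_config)


@pytest.fixture(scope="session")
def toy_config():
    """Small grid for brute-force oracles and fast dataset tests."""
    return SimConfig(grid_shape=(32, 32), design_region_size=15)


def pytest_addoption(parser):
    parser.addoption(
        "--quick-model",
        action="store_true",
        default=False,
        help="Train the shared session model at reduced scale (development only).",
    )


@pytest.fixture(scope="session")
def trained_pipeline(request):
    """Shared scaled-down corpus + trained inverse model.

    Generated once per session; used by the recovery, self-consistency and
    design tests.  Sizes are chosen so the whole build stays within a normal
    desktop test run (see docs/methods.md).
    """
    from sawdesign.dataset import generate_dataset
    from sawdesign.inverse_net import NetworkSpec, TrainingRun, build_network, train

    config = SimConfig()
    if request.config.getoption("--quick-model"):
        n_samples, epochs, hidden = 600, 8, (64, 32, 16, 8)
    else:
        n_samples, epochs, hidden = 12_500, 45, (256, 128, 64, 32)
    data = generate_dataset(n_samples=n_samples, rng_seed=20260919, config=config)
    spec = NetworkSpec(hidden_widths=hidden)
    net = build_network(spec, seed=12345)
    run = TrainingRun(epochs=epochs, batch_size=256, seed=12345)
    train(net, data, run, config=config)
    solver = FieldSolver(config)
    return {"config": config, "data": data, "net": net, "run": run, "solver": solver}


def measure_nodal_spacing(theta: float, config: SimConfig, solver: FieldSolver) -> float:
    """Median spacing (in pixels) of pressure-minima lines next to a flat wall
    whose normal makes angle ``theta`` with the SAW propagation direction.

    Builds a half-plane fluid domain bounded by the wall 90 px upstream of
    the grid center, samples amplitude profiles along the wall normal
    (averaged over positions along the wall), and takes the median distance
    between successive local minima.
    """
    from scipy.ndimage import map_coordinates
    from scipy.signal import find_peaks

    from sawdesign.acoustics import compute_pressure

    rows, cols = config.grid_shape
    n = np.array([np.cos(theta), np.sin(theta)])  # wall normal (x, y), into fluid
    u = np.array([-np.sin(theta), np.cos(theta)])  # along the wall
    p0 = -90.0 * n  # wall offset upstream of the grid center
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = cc - (cols - 1) / 2.0
    y = (rows - 1) / 2.0 - rr
    mask = (x - p0[0]) * n[0] + (y - p0[1]) * n[1] >= 0
    amp = compute_pressure(mask, config, solver).amplitude
    dists = np.arange(6, 230, 0.25)
    profiles = []
    for off in np.linspace(-80, 80, 81):
        pt = p0[:, None] + off * u[:, None] + dists[None, :] * n[:, None]
        px = pt[0] + (cols - 1) / 2.0
        py = (rows - 1) / 2.0 - pt[1]
        if px.min() < 1 or px.max() > cols - 2 or py.min() < 1 or py.max() > rows - 2:
            continue
        profiles.append(map_coordinates(amp, [py, px], order=1))
    profile = np.mean(profiles, axis=0)
    minima, _ = find_peaks(-profile, prominence=0.02 * profile.max())
    return float(np.median(np.diff(dists[minima])))
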