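import numpy as np
import pytest

from msbind import AssayConfig, SimulationConfig, generate_library, simulate_screen


@pytest.fixture(scope="session")
def config():
    return AssayConfig()


@pytest.fixture(scope="session")
def single_hit_screen(config):
    """One 16-compound sublibrary with a planted Ki 100 nM inhibitor, CV 5%."""
    lib, _ = generate_library(16, 16, [(4, 100.0)], seed=42)
    meas, truth = simulate_screen(lib, config, SimulationConfig(seed=42, noise_cv=0.05))
    return lib, meas, truth


def grid_solve_tfree(target_total, ligands, passes=4, points=2001):
    """Independent equilibrium oracle: iterative grid refinement of the
    target-conservation function on [0, target_total]."""

    def f(t):
        return t * (1.0 + sum(L.total_conc / (L.kd + t) for L in ligands)) - target_total

    lo, hi = 0.0, target_total
    for _ in range(passes):
        grid = np.linspace(lo, hi, points)
        vals = np.array([f(t) for t in grid])
        i = int(np.argmin(np.abs(vals)))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, points - 1)]
    return 0.5 * (lo + hi)
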