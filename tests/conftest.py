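import numpy as np
import pytest

from respmech.chestwall import build_grid, canonical_layout
from respmech.pipeline import default_grid_spec
from respmech.synthetic import SyntheticConfig, generate_trial


@pytest.fixture(scope="session")
def default_grid():
    return build_grid(
        [f"CW_{r}_{c}" for r in range(4) for c in range(8)], default_grid_spec()
    )


@pytest.fixture(scope="session")
def quiet_trial():
    """One noiseless synthetic trial shared by deterministic checks."""
    cfg = SyntheticConfig(seed=0, marker_noise_mm=0.0, cop_noise_m=0.0)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    """One synthetic trial at the default (realistic) noise levels."""
    return generate_trial(SyntheticConfig(seed=1))


def cylinder_markers(radius: float, height: float, rows: int, cols: int) -> np.ndarray:
    """Marker grid sampled on a right circular cylinder, row-major order."""
    theta = 2 * np.pi * np.arange(cols) / cols
    z = np.linspace(height, 0.0, rows)
    pts = np.empty((rows * cols, 3))
    for r in range(rows):
        pts[r * cols : (r + 1) * cols, 0] = radius * np.cos(theta)
        pts[r * cols : (r + 1) * cols, 1] = radius * np.sin(theta)
        pts[r * cols : (r + 1) * cols, 2] = z[r]
    return pts


def cylinder_grid(rows: int, cols: int):
    layout = canonical_layout(rows=rows, cols=cols)
    if rows < 4:
        layout["compartment_rows"] = None
    labels = list(layout["cells"])
    return labels, build_grid(labels, layout)
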