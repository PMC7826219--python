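import numpy as np
import pytest

import choroidseg as cs
from choroidseg.patching import grid_labels, make_grid


@pytest.fixture(scope="session")
def flat_phantom():
    """Noise-free phantom with flat RPE at row 40 and flat CSI at row 95."""
    spec = cs.PhantomSpec(seed=0, speckle_sigma=0, n_shadows=0,
                          rpe_poly=(40.0,), csi_poly=(95.0,))
    img, truth = cs.generate_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def curved_phantom():
    """Noise-free phantom with gently curved layers (generator defaults)."""
    spec = cs.PhantomSpec(seed=0, speckle_sigma=0, n_shadows=0)
    img, truth = cs.generate_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Speckled phantom with vessel shadows at the default noise level."""
    spec = cs.PhantomSpec(seed=1)
    img, truth = cs.generate_phantom(spec)
    return spec, img, truth


class OraclePredictor:
    """Patch-probability oracle: p=1 exactly when the recognition-area rule
    would label the patch positive.  Relies on the heat-map builder visiting
    patches in grid order (which it does)."""

    def __init__(self, truth_csi, H=150, W=600, stride=3):
        grid = make_grid(H, W, stride=stride)
        self.labels = grid_labels(grid, truth_csi).astype(float)
        self.i = 0

    def __call__(self, patches):
        n = len(patches)
        out = self.labels[self.i : self.i + n]
        self.i += n
        return out


@pytest.fixture
def oracle_predictor():
    return OraclePredictor
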