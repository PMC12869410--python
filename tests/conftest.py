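import numpy as np
import pytest

from ptgmm.gmm_core import GaussianMixtureModel, Structure
from ptgmm.workflows import (CompExperimentConfig, MotionExperimentConfig,
                             run_compositional_experiment,
                             run_motion_experiment)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_gmm():
    rng = np.random.default_rng(7)
    n = 20
    return GaussianMixtureModel(
        rng.uniform(-0.3, 0.3, (n, 3)),
        rng.uniform(0.5, 1.5, n),
        rng.uniform(0.02, 0.05, n),
    )


@pytest.fixture
def two_blob_structure():
    rng = np.random.default_rng(3)
    a = rng.normal([-20, 0, 0], 3.0, (40, 3))
    b = rng.normal([20, 5, -5], 3.0, (40, 3))
    coords = np.concatenate([a, b])
    labels = np.repeat([0, 1], 40)
    return Structure(coords, labels, np.ones(80), box_size_A=100.0)


# ---------------------------------------------------------------------------
# trained-model fixtures, shared across evaluation/interpretability tests
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def trained_easy_comp():
    """Small, high-SNR 3-segment compositional run (trains in ~1 min)."""
    cfg = CompExperimentConfig(n_segments=3, pts_per_segment=50,
                               n_particles=400, n_gaussians=96, snr=2.0)
    return run_compositional_experiment(seed=3, cfg=cfg, epochs=10,
                                        batch_size=32)


@pytest.fixture(scope="session")
def trained_single_motion():
    """Single moving region, high SNR, large tilt (trains in ~4 min)."""
    cfg = MotionExperimentConfig(n_segments=3, pts_per_segment=60,
                                 n_particles=600, n_gaussians=224,
                                 moving_segments=(1,), angle_range_deg=120.0,
                                 snr=8.0, atom_sigma_A=3.0)
    return run_motion_experiment(seed=5, cfg=cfg, epochs=32, batch_size=32)
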