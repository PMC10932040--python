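import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kinoscreen as ks

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_sim():
    """A small learnable dataset: 600 compounds, 5 tasks, one pattern each."""
    cfg = ks.SimConfig(
        n_compounds=600, n_tasks=5, k_latent=5, task_sharing=0.0,
        active_fraction=(0.02, 0.1), seed=7,
    )
    fps, matrix, truth = ks.generate(cfg)
    return fps, matrix, truth


@pytest.fixture(scope="session")
def kapi_view(tiny_sim):
    fps, matrix, _ = tiny_sim
    return ks.build_view(matrix, "kapi", features=fps)


@pytest.fixture(scope="session")
def smiles_library():
    """A grammar-built toy SMILES library with core-defined activity."""
    return ks.generate_smiles_mode(n_compounds=240, n_tasks=4, seed=3)


def random_scored_task(rng, n_total, n_active, ties=False):
    """A random ranked task instance for metric oracle checks."""
    labels = np.zeros(n_total, dtype=int)
    labels[rng.choice(n_total, size=n_active, replace=False)] = 1
    if ties:
        scores = rng.integers(0, max(2, n_total // 3), size=n_total).astype(float)
    else:
        scores = rng.random(n_total)
    return scores, labels
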