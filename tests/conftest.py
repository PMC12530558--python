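import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spnmorph as sp

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mouse_recon():
    recon, _ = sp.sample_morphology(sp.MOUSE, seed=2)
    return recon


@pytest.fixture(scope="session")
def human_recon():
    recon, _ = sp.sample_morphology(sp.HUMAN, seed=2)
    return recon


@pytest.fixture(scope="session")
def mouse_cohort():
    return sp.generate_cohort(sp.MOUSE, 6, seed=7)


@pytest.fixture()
def straight():
    return sp.straight_dendrite(300.0, 1.0)


def simple_tree() -> sp.Reconstruction:
    """Soma + one primary that bifurcates into two terminals (hand-built)."""
    ids = np.arange(1, 8)
    types = np.array([1, 3, 3, 3, 3, 3, 3])
    xyz = np.array([
        [0, 0, 0],
        [5, 0, 0],
        [15, 0, 0],        # bifurcation point
        [15, 10, 0],
        [15, 20, 0],       # terminal A
        [25, 0, 0],
        [35, 0, 0],        # terminal B
    ], dtype=float)
    radius = np.array([5.0, 1.0, 0.8, 0.5, 0.5, 0.5, 0.5])
    parents = np.array([-1, 1, 2, 3, 4, 3, 6])
    return sp.Reconstruction(ids, types, xyz, radius, parents,
                             provenance={"standardized": True})


@pytest.fixture()
def tiny_tree():
    return simple_tree()
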