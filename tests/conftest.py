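import numpy as np
import pytest
from hypothesis import settings

import octmosaic as om

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """A tiny random OCT volume with consistent metadata."""
    arr = rng.uniform(0, 1000, size=(6, 20, 9))
    meta = om.ScanMetadata(nominal_fov_mm=(1.2, 1.2), n_ascans=9, n_bscans=6)
    return om.OCTVolume(intensity=arr, meta=meta)


@pytest.fixture(scope="session")
def noiseless_spec():
    return om.PhantomSpec(
        noise_sd=0, speckle_factor=0, breathing_amplitude_px=0, n_vessels=0
    )


@pytest.fixture(scope="session")
def default_phantom():
    """Default-noise phantom volume + truth, shared across tests (seed 7)."""
    spec = om.PhantomSpec()
    vol, truth = om.generate_volume(spec, seed=7)
    return spec, vol, truth


def greedy_f1(detected, truth, tol_px=1.5):
    """One-to-one greedy matching F1 between detected and true centres."""
    from scipy.spatial import cKDTree

    if len(detected) == 0 or len(truth) == 0:
        return 0.0
    d, i = cKDTree(detected).query(truth)
    used, tp = set(), 0
    for di, ii in sorted(zip(d, i)):
        if di <= tol_px and ii not in used:
            used.add(ii)
            tp += 1
    return 2 * tp / (len(detected) + len(truth))
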