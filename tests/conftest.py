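import numpy as np
import pytest

import visfeedback as vf


@pytest.fixture(scope="session")
def stim():
    return vf.make_stimulus_set(seed=0)


@pytest.fixture(scope="session")
def occlusion(stim):
    return vf.make_occlusion_schedule(stim, seed=0)


@pytest.fixture(scope="session")
def sensory(stim):
    return vf.make_sensory_schedule(stim, seed=0)


@pytest.fixture(scope="session")
def small_occlusion(stim):
    """2 runs × 2 repetitions: enough structure for CV/crossnobis, fast."""
    return vf.make_occlusion_schedule(stim, n_runs=2, reps=2, seed=0)


@pytest.fixture
def noise_truth():
    return vf.GroundTruthParams(n_voxels=16, w_ctx=0.0, w_mne_epi=0.0, w_mne_sem=0.0,
                                w_ff=0.0, noise_sd=1.0, orthogonalize=False)


@pytest.fixture
def mixed_truth():
    return vf.GroundTruthParams(n_voxels=30, w_ctx=1.0, w_mne_epi=0.5, w_mne_sem=0.1,
                                w_ff=1.0, noise_sd=1.0)


@pytest.fixture(scope="session")
def warm_svm():
    """Trigger numba compilation once so timings in tests are stable."""
    from visfeedback._svm import svm_train_decision

    rng = np.random.default_rng(0)
    x = rng.standard_normal((8, 4))
    svm_train_decision(x @ x.T, np.tile([0, 1], 4), x[:2] @ x.T)
    return svm_train_decision
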