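import numpy as np
import pytest

import efpcouple as ec


@pytest.fixture(scope="session")
def slow_latent():
    """300-s unit-variance latent drive at 4 Hz, 0.1-Hz cutoff."""
    return ec.make_latent(300.0, 0.25, rng_seed=3)


@pytest.fixture(scope="session")
def tracked_eeg(slow_latent):
    """Preprocessed EEG whose 4-8 Hz band power tracks the latent."""
    rec = ec.simulate_eeg(slow_latent, rng_seed=5, noise_sd=1.0)
    return ec.preprocess_eeg(rec)


@pytest.fixture(scope="session")
def demo_efp(tracked_eeg):
    """EFP time-course of the tracked recording under the demo model."""
    return ec.compute_efp_timecourse(tracked_eeg, ec.demo_model())


@pytest.fixture(scope="session")
def short_cohort_cfg():
    """Fast study-shaped run: 300 s (200 volumes), two scenes."""
    run = ec.build_run_timeline(
        [("fixation", 5.0), ("farewell", 150.0), ("fixation", 10.0),
         ("snakes", 120.0), ("fixation", 15.0)]
    )
    return ec.CohortConfig(run=run, n_brain_voxels=60, n_target_voxels=40)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
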