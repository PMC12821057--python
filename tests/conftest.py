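import numpy as np
import pytest

import elvmass as em


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 patients, default effect model, fixed seed."""
    return em.synthesize_cohort(20, seed=3)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    return em.dataset_from_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free records: no white noise, no drift, no voltage variability."""
    effect = em.EffectModel(amp_variation_sd=0.0)
    return em.synthesize_cohort(
        8, effect_model=effect, seed=5, noise_sd=0.0, baseline_drift_amp=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
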