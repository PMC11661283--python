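import numpy as np
import pytest

from mmsurv.synthetic_cohort import (BagConfig, ModalityConfig,
                                     SimulationConfig, simulate_cohort)


def random_survival(rng, n, censor_frac=0.4, tie_prob=0.0):
    """Small random censored dataset for oracle comparisons."""
    time = rng.exponential(10.0, n)
    if tie_prob > 0:
        time = np.ceil(time)  # force tied times
    event = (rng.random(n) > censor_frac).astype(float)
    if event.sum() == 0:
        event[rng.integers(n)] = 1.0
    risks = rng.standard_normal(n)
    return risks, time, event


@pytest.fixture(scope="session")
def small_multimodal_bundle():
    """150-patient cohort with two tabular modalities and embedding bags."""
    cfg = SimulationConfig(
        n_patients=150, seed=11, censoring_target=0.35,
        modalities={
            "clinical": ModalityConfig(n_features=10, n_informative=2,
                                       effect_sizes=(1.0, -0.8)),
            "omics": ModalityConfig(n_features=25, n_informative=2,
                                    effect_sizes=(0.9, 0.7)),
        },
        bags=BagConfig(dim=12, patches_min=15, patches_max=40, risk_weight=1.0))
    return simulate_cohort(cfg)
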