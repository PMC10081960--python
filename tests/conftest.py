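import numpy as np
import pytest

from spiralmrf import pipeline, undersample
from spiralmrf.presets import get_preset


@pytest.fixture(scope="session")
def tiny_cfg():
    return get_preset("tiny")


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    """Small synthetic acquisition shared across tests.

    Returns the noisy fully sampled k-space, its noiseless twin, and the
    objects that generated them.
    """
    ksn, phantom, coils, acq = pipeline.simulate_from_config(tiny_cfg, seed=0, noiseless=True)
    ks, _, _, _ = pipeline.simulate_from_config(tiny_cfg, seed=0)
    return {
        "cfg": tiny_cfg,
        "ks": ks,
        "ksn": ksn,
        "phantom": phantom,
        "coils": coils,
        "acq": acq,
    }


@pytest.fixture(scope="session")
def tiny_undersampled(tiny_sim):
    return undersample(tiny_sim["ks"])


def nmse(est, ref):
    return float(np.sum(np.abs(est - ref) ** 2) / np.sum(np.abs(ref) ** 2))
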