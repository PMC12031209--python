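"""Shared fixtures.

Expensive artifacts (the default synthetic campaign, its feature dataset,
and the cross-validation runs used by the acceptance checks) are
session-scoped so they are computed once per test run.
"""

import numpy as np
import pytest

import enosemix as em
from enosemix.training import TrainConfig, ablation_configs, cross_validate

CAMPAIGN_SEED = 1
CV_SEED = 0


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f at x (float64)."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g


@pytest.fixture(scope="session")
def sensor_bank():
    return em.default_sensor_bank()


@pytest.fixture(scope="session")
def campaign_recordings():
    return em.generate_campaign(em.CampaignConfig(), seed=CAMPAIGN_SEED)


@pytest.fixture(scope="session")
def campaign_dataset(campaign_recordings):
    return em.preprocess_campaign(campaign_recordings)


@pytest.fixture(scope="session")
def mrca_cv(campaign_dataset):
    """Grouped 5-fold CV of the full model on the default campaign."""
    return cross_validate(campaign_dataset, config=TrainConfig(), k=5, seed=CV_SEED)


@pytest.fixture(scope="session")
def ablation_cvs(campaign_dataset):
    """NO-Cross and direct-sum ablations on the same folds and seeds."""
    out = {}
    for name in ("no_cross", "mrca_3"):
        mcfg, tcfg = ablation_configs(name)
        out[name] = cross_validate(campaign_dataset, mcfg, tcfg, k=5, seed=CV_SEED)
    return out
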