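"""Shared cohorts and trained pipelines.

Training a pipeline takes tens of seconds, so the trained fixtures are
session-scoped and shared across test modules.  Each fixture's cohort is a
designed experiment: the mixed cohort carries one categorical field that
is fully determined by severity class (to measure reconstruction), and
the noiseless cohort makes sick leave an exact function of the static
covariates (to measure endpoint recovery).
"""

from __future__ import annotations

import numpy as np
import pytest

import caselatent as cl
from caselatent.cohort import DEFAULT_CATEGORY_VOCAB, LogNormalParams


def class_determined_vocab() -> dict:
    """Default vocabulary, but nature_of_loss is deterministic given class."""
    vocab = {k: {kk: list(vv) for kk, vv in v.items()} for k, v in DEFAULT_CATEGORY_VOCAB.items()}
    vocab["nature_of_loss"] = {
        "levels": ["Sprain", "Fracture", "Laceration", "Contusion", "Amputation"],
        "BLM": [1, 0, 0, 0, 0],
        "HLM": [0, 1, 0, 0, 0],
    }
    return vocab


@pytest.fixture(scope="session")
def mixed_cohort():
    cfg = cl.CohortConfig(n_cases=2000, seed=21, category_vocab=class_determined_vocab())
    return cl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def trained(mixed_cohort):
    model = cl.WorkInjuryModel.from_cohort(mixed_cohort, vae_config=cl.VaeConfig(epochs=40))
    return model.fit(seed=1)


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = cl.CohortConfig(
        n_cases=1200,
        seed=5,
        hlm_fraction=0.0,
        sl_blm_params=LogNormalParams(mu=np.log(20.0), sigma=0.0),
        sl_hlm_params=LogNormalParams(mu=np.log(150.0), sigma=0.0),
        pd_noise_sd={"BLM": 0.0, "HLM": 0.0},
    )
    return cl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_trained(noiseless_cohort):
    model = cl.WorkInjuryModel.from_cohort(noiseless_cohort, vae_config=cl.VaeConfig(epochs=50))
    return model.fit(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    return cl.generate_cohort(cl.CohortConfig(n_cases=400, seed=3))


@pytest.fixture(scope="session")
def tiny_trained(small_cohort):
    model = cl.WorkInjuryModel.from_cohort(small_cohort, vae_config=cl.VaeConfig(epochs=8))
    return model.fit(seed=0)
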