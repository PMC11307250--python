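import dataclasses

import pytest
from hypothesis import settings

import sfc_qsrr as sq

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from sfc_qsrr.workflow import CONVERGED_ANN

SMALL = sq.SyntheticConfig(
    n_compounds=40,
    n_descriptors=30,
    n_informative=5,
    n_distinctive=10,
    n_null_groups=5,
    conditions=(("silica", "MeOH"), ("diol", "MeOH")),
    elution_prob=1.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_study():
    """A small drift-free two-condition study with every compound eluting."""
    return sq.generate_study(SMALL)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def converged_ann():
    return CONVERGED_ANN


def converged(seed: int, **kw) -> sq.AnnConfig:
    return dataclasses.replace(CONVERGED_ANN, seed=seed, **kw)
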