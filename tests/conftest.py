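import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rmdose import (
    DualDesignConfig,
    POModelSpec,
    ToxProbArray,
    WeightMatrix,
    gen_tox_prob,
)
from rmdose.fixtures import flat_efficacy, patdata, po_spec_dual, po_spec_tox

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def wm() -> WeightMatrix:
    return WeightMatrix.default()


@pytest.fixture(scope="session")
def patdata_df() -> pd.DataFrame:
    return patdata()


@pytest.fixture(scope="session")
def tox_spec() -> POModelSpec:
    return po_spec_tox()


@pytest.fixture(scope="session")
def dual_spec() -> POModelSpec:
    return po_spec_dual()


@pytest.fixture(scope="session")
def tox_array(tox_spec) -> ToxProbArray:
    return gen_tox_prob(tox_spec, 6, 5)


@pytest.fixture(scope="session")
def dual_array(dual_spec) -> ToxProbArray:
    return gen_tox_prob(dual_spec, 6, 6)


@pytest.fixture(scope="session")
def degenerate_array() -> ToxProbArray:
    probs = np.zeros((6, 6, 3, 5))
    probs[..., 0] = 1.0
    return ToxProbArray(probs)


@pytest.fixture(scope="session")
def dual_cfg() -> DualDesignConfig:
    """Flat-efficacy worked-example settings: target/bounds 0.23, cutoffs 0.1."""
    return DualDesignConfig(
        tox_target=0.23, c1=0.23, c2=0.23, p1=0.1, p2=0.1, ps1=0.1,
        trial_size=36, cohort_size=3, max_cycle=6,
    )


@pytest.fixture(scope="session")
def flat_eff():
    return flat_efficacy()
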