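import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import twinmetab as tm
from twinmetab.twin import PairedData

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with every nuisance layer switched on."""
    spec = tm.SimulationSpec(
        n_mz_pairs=60,
        n_dz_pairs=40,
        n_mz_singletons=2,
        n_dz_singletons=1,
        n_metabolites={"amine": 4, "organic_acid": 2, "steroid": 2},
        lod_quantile=0.02,
        missing_rate=0.02,
        seed=11,
    )
    return spec, tm.simulate_cohort(spec)


@pytest.fixture(scope="session")
def fixture_roster():
    return tm.make_paper_fixture_roster()


def balanced_paired(n_mz, n_dz, v, cov_mz, cov_dz, seed=0) -> PairedData:
    """Complete pairs whose ML moments are exactly the requested values."""
    rng = np.random.default_rng(seed)
    mz = tm.simulate.exact_moment_pairs(n_mz, v, cov_mz, rng)
    dz = tm.simulate.exact_moment_pairs(n_dz, v, cov_dz, rng)
    return PairedData(
        mz,
        np.zeros((n_mz, 2)),
        np.zeros(n_mz),
        dz,
        np.zeros((n_dz, 2)),
        np.zeros(n_dz),
        np.empty(0),
        np.empty(0),
        np.empty(0),
        np.empty(0, dtype=bool),
    )
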