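import numpy as np
import pytest

from bacscan.phantom import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small rendered phantom cohort shared across tests."""
    return generate_cohort(PhantomSpec(n_patients=12, seed=7))


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One desk-profile end-to-end pipeline run shared across the suite.

    300 patients, reduced backbone, 10 epochs — the scaled-down study
    conditions under which detection and quantification are assessed.
    """
    from bacscan.pipeline import RunConfig, run

    cfg = RunConfig(profile="desk", seed=1)
    return run(cfg, str(tmp_path_factory.mktemp("desk_run")))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
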