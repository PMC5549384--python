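import numpy as np
import pytest

from ccvarscan.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A written 6-gene cohort shared by the pipeline-level tests."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = SimulationConfig(n_genes=6)
    bundle = simulate_cohort(cfg, seed=11, out_dir=str(out), n_changes=120)
    return {"dir": out, "bundle": bundle, "config": cfg}
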