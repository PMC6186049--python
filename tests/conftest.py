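import numpy as np
import pytest

from lncflow.simulate import (
    SimConfig,
    simulate_conservation,
    simulate_ct,
    simulate_expression_modules,
    simulate_identification,
)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def ident_bundle(sim_config):
    return simulate_identification(sim_config, np.random.default_rng(11))


@pytest.fixture(scope="session")
def expr_bundle(sim_config):
    return simulate_expression_modules(sim_config, np.random.default_rng(11))


@pytest.fixture(scope="session")
def cons_bundle(sim_config):
    return simulate_conservation(sim_config, np.random.default_rng(11))


@pytest.fixture(scope="session")
def ct_bundle(sim_config):
    return simulate_ct(sim_config, np.random.default_rng(11))


@pytest.fixture(scope="session")
def file_bundle(tmp_path_factory):
    """Full on-disk bundle + manifest, generated once per session."""
    from lncflow.simulate import generate

    outdir = tmp_path_factory.mktemp("bundle")
    manifest = generate(SimConfig(seed=11), outdir)
    return outdir, manifest
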