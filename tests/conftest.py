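import pytest

from fernspike import assemblage as asm
from fernspike import carboncycle as cc
from fernspike import experiments as xp
from fernspike import synthetic as syn


@pytest.fixture(scope="session")
def groups():
    return asm.default_group_map()


@pytest.fixture(scope="session")
def noisefree_record():
    """Deterministic record with counting noise and δ13C noise disabled."""
    spec = syn.SyntheticSiteSpec(seed=0, count_noise=False, d13c_noise_sd=0.0)
    return syn.generate_site(spec)


@pytest.fixture(scope="session")
def noisy_record():
    return syn.generate_site(syn.SyntheticSiteSpec(seed=7))


@pytest.fixture(scope="session")
def fig4_result():
    """Calibrated control + 30/50/70 % GPP-reduction suite (shared across
    acceptance tests; the model is deterministic)."""
    return xp.fig4_suite()


@pytest.fixture(scope="session")
def model_params():
    return cc.ModelParams()
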