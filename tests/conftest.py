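import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from overturnlab import stats_report, synthetic

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_config():
    return synthetic.noiseless(synthetic.default_config())


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_config):
    return synthetic.generate_experiment(noiseless_config, seed=123)


@pytest.fixture(scope="session")
def bundle_dir(noiseless_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    synthetic.write_bundle(noiseless_bundle, d)
    return d


@pytest.fixture(scope="session")
def report_dir(bundle_dir, tmp_path_factory):
    d = tmp_path_factory.mktemp("report")
    stats_report.run_pipeline(bundle_dir, d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
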