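import numpy as np
import pytest

from enose.calibration import load_sensor_models
from enose.dataset import build_instances
from enose.synthetic import SyntheticConfig, simulate_cohort

#: desk-scale cohort used by dataset and end-to-end tests: 4 patients per
#: class, 2 containers, 2 acquisitions -> 32 files, 1024 instances
DESK_CONFIG = SyntheticConfig(
    n_patients_per_class=4,
    containers_per_patient=2,
    acquisitions_per_container=2,
    seed=11,
)


@pytest.fixture(scope="session")
def desk_config():
    return DESK_CONFIG


@pytest.fixture(scope="session")
def sensor_models():
    return load_sensor_models()


@pytest.fixture(scope="session")
def desk_cohort(tmp_path_factory):
    """Synthetic desk-scale cohort on disk: (manifest, directory)."""
    root = tmp_path_factory.mktemp("cohort")
    manifest = simulate_cohort(DESK_CONFIG, root)
    return manifest, root


@pytest.fixture(scope="session")
def desk_instances(desk_cohort, sensor_models):
    manifest, _ = desk_cohort
    return build_instances(manifest, models=sensor_models)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
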