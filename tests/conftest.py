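import numpy as np
import pytest

from accelxfer import (
    DeviceModel,
    RunConfig,
    StudyConfig,
    build_study,
    extract_table,
    make_windows,
)


@pytest.fixture(scope="session")
def identity_device() -> DeviceModel:
    """Noise-free unit-gain device: output equals the true signal."""
    return DeviceModel(device_id="ideal")


@pytest.fixture(scope="session")
def default_study():
    """The default paired-device wear study at master seed 0."""
    return build_study(StudyConfig(master_seed=0))


@pytest.fixture(scope="session")
def study_windows(default_study):
    """20-s windows from the last minute of every bout, per device."""
    return {
        dev: [w for rec in recs for w in make_windows(rec)]
        for dev, recs in default_study.items()
    }


@pytest.fixture(scope="session")
def default_tables(study_windows):
    """TD and FD feature tables per device for the seed-0 study."""
    return {
        (dev, fset): extract_table(wins, fset)
        for dev, wins in study_windows.items()
        for fset in ("TD", "FD")
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
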