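import warnings

import pytest

from glcga.candidate_db import build_channels
from glcga.identify import PipelineConfig
from glcga.synth_data import builtin_registry, predicted_ri_table, reference_calibration


@pytest.fixture(scope="session")
def registry():
    return {r.name: r for r in builtin_registry()}


@pytest.fixture(scope="session")
def channels(registry):
    return build_channels(list(registry.values()))


@pytest.fixture(scope="session")
def calibration():
    return reference_calibration()


@pytest.fixture()
def pipeline_config(registry, calibration):
    return PipelineConfig(
        registry=registry,
        calibration=calibration,
        predictions=predicted_ri_table(),
    )


@pytest.fixture(autouse=True)
def _quiet_retention_warnings():
    # missing-prediction / extrapolation warnings are expected in pipeline tests
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
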