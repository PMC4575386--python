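import numpy as np
import pytest

from toxprint import synth
from toxprint.io import CONTROL, Condition
from toxprint.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def default_model():
    return synth.make_default_truth(seed=1)


@pytest.fixture(scope="session")
def marker_run(tmp_path_factory):
    """One full pipeline run on the marker design, shared across tests."""
    outdir = tmp_path_factory.mktemp("marker_run")
    config = RunConfig(seed=1, design="marker", outdir=str(outdir))
    return run_pipeline(config)


@pytest.fixture()
def quiet_model(default_model):
    """Noise-free, drift-free, replicate-exact copy of the default truth."""
    import dataclasses

    return dataclasses.replace(
        default_model,
        noise_sd=0.0,
        abundance_cv=0.0,
        drift_slope_sd=0.0,
        drift_offset_sd=0.0,
    )


@pytest.fixture()
def control_condition():
    return CONTROL


@pytest.fixture()
def copper_high():
    return Condition("copper_sulfate", 9.0, "mg/L")
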