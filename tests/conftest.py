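import numpy as np
import pytest

import yeastcycle as yc
from yeastcycle.cycle_analysis import measure_cycles
from yeastcycle.experiments import EXPERIMENT_SETTINGS
from yeastcycle.phase_annotation import detect_transitions


@pytest.fixture(scope="session")
def model():
    return yc.build_reference_model()


@pytest.fixture(scope="session")
def reference_trajectory(model):
    """Long unperturbed run at the fast analysis tolerances."""
    return yc.integrate(model, t_end=1800.0, output_step=0.5,
                        settings=EXPERIMENT_SETTINGS)


@pytest.fixture(scope="session")
def reference_annotation(reference_trajectory):
    return detect_transitions(reference_trajectory)


@pytest.fixture(scope="session")
def reference_metrics(reference_annotation):
    return measure_cycles(reference_annotation)


@pytest.fixture(scope="session")
def tight_trajectory(model):
    """Ten-plus cycles at the tight default tolerances (conservation tests)."""
    return yc.integrate(model, t_end=1250.0, output_step=0.5,
                        settings=yc.IntegratorSettings(rtol=1e-8, atol=1e-10))


@pytest.fixture(scope="session")
def random_states(model):
    rng = np.random.default_rng(12345)
    return rng.uniform(0.0, 2000.0, size=(100, model.n_species))
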