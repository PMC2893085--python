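import numpy as np
import pytest

from aralogic import (
    DiauxicScenario,
    GradientDesign,
    IntegrationCoefficients,
    LossModel,
    NoiseModel,
    ReporterCalibration,
    simulate_diauxic_experiment,
)


@pytest.fixture
def cal() -> ReporterCalibration:
    """A reporter with span 100 and basal 10: easy numbers to invert by hand."""
    return ReporterCalibration(alpha_rep=100.0, basal_T=10.0)


@pytest.fixture
def plate_cal() -> ReporterCalibration:
    """A plate-realistic calibration (CPS/OD scale)."""
    return ReporterCalibration(alpha_rep=1000.0, basal_T=20.0)


@pytest.fixture
def design() -> GradientDesign:
    return GradientDesign()


@pytest.fixture
def arabad_truth() -> IntegrationCoefficients:
    return IntegrationCoefficients(alpha=2.535, gamma=4.347)


@pytest.fixture
def noise_free() -> NoiseModel:
    return NoiseModel(lum_lognormal_sigma=0.0, od_gaussian_sd=0.0, seed=0)


@pytest.fixture
def diauxic_dataset(arabad_truth, plate_cal, noise_free):
    """Seven noise-free shift replicates with jittered exhaustion times."""
    return simulate_diauxic_experiment(
        DiauxicScenario(),
        arabad_truth,
        LossModel(tau_min=30.0),
        plate_cal,
        plate_cal,
        noise=noise_free,
    )
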