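import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circaluc.synthetic import OscillatorParams, TreatmentResponse, packaged_response

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_params():
    """Noiseless, undamped oscillator on a constant-free decaying baseline."""
    return OscillatorParams(
        period_h=24.0,
        amplitude=100.0,
        damping_rate=0.0,
        initial_peak_time_h=6.0,
        baseline_level=300.0,
        baseline_decay_rate=0.01,
        noise_sd=0.0,
        duration_h=168.0,
    )


@pytest.fixture(scope="session")
def oxm():
    return packaged_response("OXM")


@pytest.fixture(scope="session")
def gcg():
    return packaged_response("GCG")


@pytest.fixture(scope="session")
def null_response():
    return TreatmentResponse(peptide_name="GLP-1")


def constant_prc(shift_h: float, name: str = "CONST") -> TreatmentResponse:
    """Response whose PRC is flat at ``shift_h`` for any treatment phase."""
    return TreatmentResponse(
        peptide_name=name,
        prc_coefficients=(shift_h, 0.0, 0.0, 0.0, 0.0),
        ec50_nM=1.0,
        hill_n=1.0,
    )


@pytest.fixture(scope="session")
def saturating_dose():
    return 1e9


def rng(seed=0):
    return np.random.default_rng(seed)
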