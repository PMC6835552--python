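import pytest

from rollgaze import NoiseConfig, SubjectEyeParams, simulate_session


@pytest.fixture(scope="session")
def average_eye() -> SubjectEyeParams:
    """Average adult kappa offsets: alpha = 3 deg, beta = 1.5 deg."""
    return SubjectEyeParams(alpha_deg=3.0, beta_deg=1.5)


@pytest.fixture(scope="session")
def clean_session(average_eye):
    """Noise-free multi-roll session: forward model is exactly invertible."""
    return simulate_session(
        average_eye,
        noise=NoiseConfig(feature_sigma_mm=0.0, tracker_sigma_deg=0.0, seed=0),
        frames_per_target=5,
    )


@pytest.fixture(scope="session")
def noisy_calibration_session(average_eye):
    """Single-roll calibration session at the default (~1 deg baseline) noise."""
    return simulate_session(average_eye, rolls_deg=[0.0], noise=NoiseConfig(seed=11))
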