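import warnings

import numpy as np
import pytest

import gaitpain as gp

warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def symmetric_trial():
    """A clean, perfectly symmetric walking trial with ground-truth events."""
    spec = gp.SignalSpec(cadence=110, duration=20, step_time_cv=0.0,
                         left_right_amplitude_ratio=1.0, noise_sd=0.0, seed=0)
    return gp.generate_signal(spec)


@pytest.fixture(scope="session")
def asymmetric_trial():
    """Amplitude-asymmetric gait (left impulses 1.5x right), light noise."""
    spec = gp.SignalSpec(cadence=110, duration=30, left_right_amplitude_ratio=1.5,
                         step_time_cv=0.0, noise_sd=0.02, seed=3)
    return gp.generate_signal(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-person cohort with a known step-regularity effect."""
    spec = gp.CohortSpec(
        n_participants=400,
        coefficients={"step_regularity": float(np.log(0.5))},
        intercept=-1.2,
        bilateral_rate=0.05,
        seed=42,
    )
    return gp.generate_cohort(spec)
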