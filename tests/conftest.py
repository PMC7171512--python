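import numpy as np
import pytest

from ramanqf.preprocess import RollingBallConfig
from ramanqf.simulate import (
    DetectorModel,
    make_dark_reference,
    make_response_curve,
    make_tissue_profile,
)
from ramanqf.spectra import AcquisitionParams, RawSpectrum, default_axis


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def params():
    return AcquisitionParams(n_repeats=5, exposure_time_ms=75.0, laser_power_mw=60.0)


@pytest.fixture(scope="session")
def detector():
    return DetectorModel()


@pytest.fixture(scope="session")
def profile(axis):
    """Deterministic tissue profile (no amplitude jitter)."""
    return make_tissue_profile(
        "normal", seed=3, axis=axis, peak_jitter_sd=0.0, background_jitter_sd=0.0
    )


@pytest.fixture(scope="session")
def cancer_profile(axis):
    return make_tissue_profile(
        "cancer", seed=3, axis=axis, peak_jitter_sd=0.0, background_jitter_sd=0.0
    )


@pytest.fixture(scope="session")
def response(axis):
    return make_response_curve(axis)


@pytest.fixture(scope="session")
def dark(axis, detector):
    return make_dark_reference(axis, detector, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def rb_config():
    return RollingBallConfig()


@pytest.fixture(scope="session")
def noise_free_spectrum(axis, profile, params):
    """Noise-free expected counts (no gain, no dark) for the fixture profile."""
    dose = params.dose
    counts = dose * (profile.raman_rate + profile.background_rate)
    return RawSpectrum(axis, counts, params, {"noise_free": True})
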