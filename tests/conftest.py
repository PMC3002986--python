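import numpy as np
import pytest

from adaptif import ChannelKinetics, PIFConfig


def make_kinetics(n_channels=100, tau_a=100.0, pulse=1.0, p0=0.0):
    return ChannelKinetics(n_channels=n_channels, tau_a=tau_a,
                           pulse_duration=pulse, subthreshold_activation=p0)


def reference_config(n_channels=100, D=0.0, tau_a=100.0, alpha=0.5,
                     rate=0.1):
    """Reference parameter set: rate 0.1/ms, pulse 1 ms, adaptation degree
    alpha; Delta and mu chosen so the stationary rate is ``rate``."""
    delta_strength = (1.0 / alpha - 1.0)  # pulse = 1 ms, theta = 1
    mu = rate * (1.0 + delta_strength)
    return PIFConfig(
        base_drive=mu, adaptation_strength=delta_strength,
        kinetics=make_kinetics(n_channels, tau_a=tau_a),
        white_noise_intensity=D)


@pytest.fixture(scope="session")
def ref_config():
    return reference_config()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def blocked_mean_se(x, n_blocks=50):
    """SE of the mean that is robust to serial correlation (block means)."""
    blocks = np.array_split(np.asarray(x), n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)
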