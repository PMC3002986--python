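"""Adaptive perfect integrate-and-fire simulators and model reductions.

Four model variants share one configuration (:class:`PIFConfig`):

* ``simulate_pif_channel``   -- explicit two-state adaptation channels
  (event-driven and exact for D = 0, Euler-Maruyama voltage otherwise),
* ``simulate_pif_diffusion`` -- deterministic adaptation filter plus an
  Ornstein-Uhlenbeck fluctuation (diffusion approximation),
* ``simulate_pif_white``     -- deterministic adaptation, white noise only,
* ``simulate_pif_colored``   -- the reduced colored-noise model without
  adaptation feedback, driven by :class:`EffectiveColoredParams`.

Also provides the non-dimensionalization, the effective-parameter mapping of
the colored-noise reduction, and the step-response experiment.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from . import _kernels
from .channels import ChannelTrajectory, channel_noise_intensity
from .config import (ChannelKinetics, EffectiveColoredParams, NondimConfig,
                     NonFiringError, ParameterError, PIFConfig)

__all__ = [
    "SpikeTrain", "nondimensionalize", "effective_colored_params",
    "simulate_pif_channel", "simulate_pif_diffusion", "simulate_pif_white",
    "simulate_pif_colored", "simulate_step_response", "stationary_intervals",
    "StepResponse",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times within an observation window."""

    times: np.ndarray
    window: Tuple[float, float]
    units: str = "ms"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if len(t) and (t[0] < self.window[0] or t[-1] > self.window[1]):
            raise ParameterError("spike times outside the window")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("spike times must be strictly increasing")

    def __len__(self):
        return len(self.times)

    def intervals(self) -> np.ndarray:
        return np.diff(self.times)

    def rate(self) -> float:
        span = self.window[1] - self.window[0]
        return len(self.times) / span if span > 0 else np.nan

    def save(self, path, header_extra: str = ""):
        header = (f"spike times ({self.units}); window "
                  f"[{self.window[0]}, {self.window[1]}]")
        if header_extra:
            header += "\n" + header_extra
        np.savetxt(path, self.times, header=header)

    @classmethod
    def load(cls, path, window=None, units="ms"):
        times = np.atleast_1d(np.loadtxt(path))
        if window is None:
            window = (min(0.0, times[0] if len(times) else 0.0),
                      times[-1] if len(times) else 0.0)
        return cls(times=times, window=tuple(window), units=units)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------
def nondimensionalize(config: PIFConfig) -> NondimConfig:
    """Measure voltage in threshold units and time in units of tau_a."""
    k = config.kinetics
    theta, tau = config.threshold, k.tau_a
    if k.is_infinite:
        d_channel = 0.0
    else:
        a_mean = config.mean_activation()
        d_channel = ((config.adaptation_strength * tau / theta) ** 2
                     * a_mean * (1.0 - a_mean) / k.n_channels)
    return NondimConfig(
        mu_hat=config.base_drive * tau / theta,
        delta_hat=config.adaptation_strength * tau / theta,
        pulse_hat=k.pulse_duration / tau,
        d_hat=config.white_noise_intensity * tau / theta**2,
        d_channel_hat=d_channel,
        subthreshold_activation=k.subthreshold_activation,
    )


def effective_colored_params(config: PIFConfig) -> EffectiveColoredParams:
    """Map an adaptive PIF configuration onto the reduced colored-noise model.

    The adaptation filter tracks (and cancels) drive fluctuations slower
    than alpha*tau_a; the residual fluctuation seen by the voltage is
    exactly an OU process whose drive, correlation time and variance are all
    scaled by the common factor ``alpha = theta/(theta+Delta*pulse*(1-p0))``
    (the degree of adaptation):

        mu_eff = alpha*(mu - Delta*p0),  tau_eff = alpha*tau_a,
        sigma2_eff = alpha * Delta^2 * Var(a).
    """
    k = config.kinetics
    p0 = k.subthreshold_activation
    rate = config.stationary_rate()
    if rate <= 0:
        raise NonFiringError("stationary rate must be positive")
    alpha = config.threshold / (
        config.threshold
        + config.adaptation_strength * k.pulse_duration * (1.0 - p0))
    mu_eff = alpha * (config.base_drive - config.adaptation_strength * p0)
    if k.is_infinite:
        var_a = 0.0
    else:
        var_a, _, _ = channel_noise_intensity(k, rate, warn=False)
    sigma2_eff = alpha * config.adaptation_strength**2 * var_a
    epsilon = sigma2_eff / mu_eff**2
    if epsilon >= 1.0:
        warnings.warn(
            f"epsilon = {epsilon:.2f} >= 1: the weak-noise expansion is "
            "unreliable for this configuration", stacklevel=2)
    return EffectiveColoredParams(
        alpha=alpha, mu_eff=mu_eff, sigma2_eff=sigma2_eff,
        tau_eff=alpha * k.tau_a, epsilon=epsilon, rho=k.tau_a * rate,
        threshold=config.threshold)


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------
def _check_t_end(t_end):
    if t_end <= 0:
        raise ParameterError("t_end must be > 0")


def _max_spikes(config: PIFConfig, t_end: float, delta_mu: float = 0.0):
    bound = (config.base_drive + max(delta_mu, 0.0)) / config.threshold
    return int(t_end * bound * 1.2) + 1000


def _warn_overlap(n_overlap, n_spikes):
    if n_spikes > 0 and n_overlap / n_spikes > 0.01:
        warnings.warn(
            f"{n_overlap}/{n_spikes} ISIs shorter than the spike pulse; "
            "pulse restarts were applied", stacklevel=3)


def simulate_pif_channel(config: PIFConfig, t_end: float, seed: int,
                         return_channels: bool = False,
                         step: Tuple[float, float] = (np.inf, 0.0)):
    """Adaptive PIF coupled to an explicit channel population.

    With D = 0 the integration is event-driven and exact; with D > 0 the
    voltage uses Euler-Maruyama steps while the channel process stays exact.
    """
    _check_t_end(t_end)
    k = config.kinetics
    if k.is_infinite:
        if return_channels:
            raise ParameterError("no channel trajectory for infinite N")
        return simulate_pif_white(config, t_end, seed, step=step)
    t_on, delta_mu = step
    n0 = int(round(k.n_channels * config.mean_activation()))
    max_spk = _max_spikes(config, t_end, delta_mu)
    if config.white_noise_intensity == 0.0:
        rec_cap = 0
        if return_channels:
            rec_cap = min(int(4 * k.n_channels * t_end / k.tau_a
                              + 10 * k.n_channels + 1000), 50_000_000)
        rec_t = np.empty(rec_cap)
        rec_n = np.empty(rec_cap, dtype=np.int64)
        spikes, nrec, n_overlap = _kernels.pif_channel_event(
            config.base_drive, delta_mu, t_on, config.adaptation_strength,
            config.threshold, k.n_channels, k.tau_a, k.pulse_duration,
            k.subthreshold_activation, n0, t_end, seed, max_spk,
            rec_t, rec_n, rec_cap)
        _warn_overlap(n_overlap, len(spikes))
        train = SpikeTrain(times=spikes, window=(0.0, t_end))
        if return_channels:
            traj = ChannelTrajectory(
                times=np.concatenate([[0.0], rec_t[:nrec]]),
                n_open=np.concatenate([[n0], rec_n[:nrec]]).astype(np.int64),
                window=(0.0, t_end), n_channels=k.n_channels)
            return train, traj
        return train
    if return_channels:
        raise ParameterError("channel trajectory recording requires D = 0")
    spikes, n_overlap = _kernels.pif_channel_em(
        config.base_drive, delta_mu, t_on, config.adaptation_strength,
        config.threshold, k.n_channels, k.tau_a, k.pulse_duration,
        k.subthreshold_activation, config.white_noise_intensity, n0,
        config.default_dt(), t_end, seed, max_spk)
    _warn_overlap(n_overlap, len(spikes))
    return SpikeTrain(times=spikes[spikes <= t_end], window=(0.0, t_end))


def _filter_sim(config: PIFConfig, t_end, seed, sig_eta2, step):
    _check_t_end(t_end)
    k = config.kinetics
    t_on, delta_mu = step
    spikes, n_overlap = _kernels.pif_filter_em(
        config.base_drive, delta_mu, t_on, config.adaptation_strength,
        config.threshold, k.tau_a, k.pulse_duration,
        k.subthreshold_activation, config.white_noise_intensity, sig_eta2,
        config.mean_activation(), config.default_dt(), t_end, seed,
        _max_spikes(config, t_end, delta_mu))
    _warn_overlap(n_overlap, len(spikes))
    return SpikeTrain(times=spikes[spikes <= t_end], window=(0.0, t_end))


def simulate_pif_diffusion(config: PIFConfig, t_end: float, seed: int,
                           step: Tuple[float, float] = (np.inf, 0.0)
                           ) -> SpikeTrain:
    """Diffusion approximation: deterministic adaptation filter plus an OU
    fluctuation with matched variance and correlation time tau_a."""
    k = config.kinetics
    if k.is_infinite:
        sig_eta2 = 0.0
    else:
        sig_eta2, _, _ = channel_noise_intensity(
            k, config.stationary_rate(), warn=False)
    return _filter_sim(config, t_end, seed, sig_eta2, step)


def simulate_pif_white(config: PIFConfig, t_end: float, seed: int,
                       step: Tuple[float, float] = (np.inf, 0.0)
                       ) -> SpikeTrain:
    """Deterministic adaptation plus white current noise (infinite-N limit)."""
    return _filter_sim(config, t_end, seed, 0.0, step)


def simulate_pif_colored(params: EffectiveColoredParams, t_end: float,
                         seed: int, dt: Optional[float] = None) -> SpikeTrain:
    """PIF driven by constant mu_eff plus OU noise; no adaptation feedback."""
    _check_t_end(t_end)
    mean_isi = params.threshold / params.mu_eff
    if dt is None:
        dt = min(params.tau_eff, mean_isi) / 1000.0
    max_spk = int(t_end / mean_isi * (1.0 + 5.0 * np.sqrt(params.epsilon))
                  ) + 1000
    spikes = _kernels.pif_colored_em(
        params.mu_eff, params.sigma2_eff, params.tau_eff, params.threshold,
        dt, t_end, seed, max_spk)
    return SpikeTrain(times=spikes[spikes <= t_end], window=(0.0, t_end))


def stationary_intervals(train: SpikeTrain, tau_a: float) -> np.ndarray:
    """ISIs after transient removal: drop spikes before 10*tau_a or the
    first 20 ISIs, whichever discards more."""
    t = train.times
    if len(t) < 25:
        return np.diff(t)
    i_time = int(np.searchsorted(t, 10.0 * tau_a))
    i0 = max(i_time, 20)
    return np.diff(t[i0:])


# ---------------------------------------------------------------------------
# step-response experiment
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class StepResponse:
    """Trial-averaged firing rate around a step stimulus."""

    bin_centers: np.ndarray
    rate: np.ndarray
    rate_se: np.ndarray
    t_on: float
    decay_time: float
    plateau: float
    onset_rate: float
    pre_rate: float

    @property
    def degree_of_adaptation(self) -> float:
        return (self.plateau - self.pre_rate) / (self.onset_rate
                                                 - self.pre_rate)


def simulate_step_response(config: PIFConfig, step: Tuple[float, float],
                           n_trials: int, seed: int,
                           variant: str = "channel",
                           t_end: Optional[float] = None,
                           binwidth: Optional[float] = None) -> StepResponse:
    """PSTH of the response to a base-current step mu -> mu + delta_mu.

    The post-step rate is fitted with r(t) = r_inf + (r_on - r_inf)
    exp(-(t - t_on)/tau_fit).  The pre-step window must be long enough to
    reach stationarity.
    """
    t_on, delta_mu = step
    if n_trials < 100:
        raise ParameterError("n_trials must be >= 100")
    tau_a = config.kinetics.tau_a
    if t_end is None:
        t_end = t_on + 8.0 * tau_a
    if t_on <= 0 or t_on >= t_end:
        raise ParameterError("step onset must lie inside the window")
    if delta_mu < 0:
        raise ParameterError("only positive steps are supported")
    if binwidth is None:
        binwidth = tau_a / 20.0
    sim = {"channel": simulate_pif_channel,
           "white": simulate_pif_white,
           "diffusion": simulate_pif_diffusion}[variant]
    edges = np.arange(0.0, t_end + binwidth, binwidth)
    counts = np.zeros(len(edges) - 1)
    counts2 = np.zeros(len(edges) - 1)
    for i in range(n_trials):
        train = sim(config, t_end, seed + 7919 * i, step=(t_on, delta_mu))
        c, _ = np.histogram(train.times, bins=edges)
        counts += c
        counts2 += c.astype(float)**2
    rate = counts / (n_trials * binwidth)
    var_c = counts2 / n_trials - (counts / n_trials) ** 2
    rate_se = np.sqrt(np.maximum(var_c, 0.0) / n_trials) / binwidth
    centers = 0.5 * (edges[1:] + edges[:-1])

    pre_mask = (centers > min(10.0 * tau_a, 0.8 * t_on)) & (centers < t_on)
    if not np.any(pre_mask):
        pre_mask = centers < t_on
    pre_rate = float(np.mean(rate[pre_mask]))
    post = centers >= t_on
    tpost = centers[post] - t_on
    rpost = rate[post]

    if delta_mu == 0.0:
        return StepResponse(centers, rate, rate_se, t_on, np.nan,
                            pre_rate, pre_rate, pre_rate)

    def model(t, r_inf, r_on, tau):
        return r_inf + (r_on - r_inf) * np.exp(-t / tau)

    p0 = (float(np.mean(rpost[tpost > 3 * tau_a])) if np.any(
        tpost > 3 * tau_a) else rpost[-1],
        rpost[0], 0.5 * tau_a)
    popt, _ = curve_fit(model, tpost, rpost, p0=p0, maxfev=20000)
    r_inf, r_on, tau_fit = popt
    return StepResponse(centers, rate, rate_se, t_on, float(tau_fit),
                        float(r_inf), float(r_on), pre_rate)
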