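"""Finite populations of two-state adaptation channels.

Exact Gillespie sample paths with piecewise-constant activation schedules,
the Ornstein-Uhlenbeck fluctuation of the diffusion approximation, and the
channel-noise intensity entering the reduced colored-noise model.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from . import _kernels
from .config import ChannelKinetics, ParameterError


@dataclass(frozen=True)
class ChannelTrajectory:
    """Piecewise-constant open-channel count: ``n_open[i]`` holds from
    ``times[i]`` until ``times[i+1]``."""

    times: np.ndarray
    n_open: np.ndarray
    window: Tuple[float, float]
    n_channels: int

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("event times must be strictly increasing")
        if np.any(self.n_open < 0) or np.any(self.n_open > self.n_channels):
            raise ParameterError("open count outside [0, N]")

    def open_fraction_at(self, t: np.ndarray) -> np.ndarray:
        """Open fraction sampled at times t (piecewise-constant)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.empty(len(t))
        valid = idx >= 0
        out[~valid] = self.n_open[0] / self.n_channels
        out[valid] = self.n_open[idx[valid]] / self.n_channels
        return out

    def to_csv(self, path):
        np.savetxt(path, np.column_stack([self.times, self.n_open]),
                   delimiter=",", header="time,n_open", comments="")


@dataclass(frozen=True)
class OUPath:
    """Discretized stationary Ornstein-Uhlenbeck path."""

    times: np.ndarray
    values: np.ndarray
    sigma2: float
    tau: float


def rates_from_activation(p_inf: float, tau_a: float):
    """Per-channel opening/closing rates for steady-state activation p_inf.

    opening = p_inf / tau_a (per closed channel), closing = (1 - p_inf) /
    tau_a (per open channel); their sum is the inverse channel time constant.
    """
    if tau_a <= 0:
        raise ParameterError(f"tau_a must be > 0, got {tau_a}")
    if not 0.0 <= p_inf <= 1.0:
        raise ParameterError(f"p_inf must be in [0, 1], got {p_inf}")
    return p_inf / tau_a, (1.0 - p_inf) / tau_a


def simulate_two_state_gillespie(kinetics: ChannelKinetics,
                                 rate_schedule: Sequence[Tuple[float, float]],
                                 n_open_init: int, t_end: float,
                                 seed: int) -> ChannelTrajectory:
    """Statistically exact sample path of the N-channel birth-death process.

    rate_schedule: sequence of (t_start, p_inf) segments, sorted by t_start;
    waiting times are capped at segment breakpoints and redrawn so that the
    piecewise-constant rates are treated exactly.
    """
    if kinetics.is_infinite:
        raise ParameterError("Gillespie simulation needs a finite n_channels")
    n_ch = kinetics.n_channels
    if not 0 <= n_open_init <= n_ch:
        raise ParameterError("n_open_init outside [0, N]")
    seg = np.asarray([[t, p] for t, p in rate_schedule], dtype=float)
    if seg.ndim != 2 or seg.shape[1] != 2 or len(seg) == 0:
        raise ParameterError("rate_schedule must be a list of (t, p) pairs")
    if np.any(np.diff(seg[:, 0]) <= 0):
        raise ParameterError("rate_schedule breakpoints must be sorted")
    if np.any((seg[:, 1] < 0) | (seg[:, 1] > 1)):
        raise ParameterError("p_inf values must be in [0, 1]")
    # generous bound on the expected number of transitions
    max_events = int(4 * n_ch * t_end / kinetics.tau_a + 10 * n_ch + 1000)
    times, n_open, nrec = _kernels.gillespie_two_state(
        n_ch, kinetics.tau_a, seg[:, 0].copy(), seg[:, 1].copy(),
        n_open_init, t_end, seed, max_events)
    times = np.concatenate([[0.0], times])
    n_open = np.concatenate([[n_open_init], n_open])
    return ChannelTrajectory(times=times, n_open=n_open.astype(np.int64),
                             window=(0.0, t_end), n_channels=n_ch)


def simulate_ou_fluctuation(sigma2: float, tau_a: float, dt: float,
                            t_end: float, seed: int) -> OUPath:
    """Stationary OU process, exact conditional-Gaussian update."""
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if sigma2 < 0:
        raise ParameterError("sigma2 must be >= 0")
    if tau_a <= 0:
        raise ParameterError("tau_a must be > 0")
    if dt > tau_a / 10:
        warnings.warn("dt > tau_a/10: OU path will be under-resolved",
                      stacklevel=2)
    n = int(np.ceil(t_end / dt))
    if sigma2 == 0.0:
        vals = np.zeros(n + 1)
    else:
        vals = _kernels.ou_path(sigma2, tau_a, dt, n, seed)
    return OUPath(times=np.arange(n + 1) * dt, values=vals,
                  sigma2=sigma2, tau=tau_a)


def channel_noise_intensity(kinetics: ChannelKinetics, firing_rate: float,
                            warn: bool = True):
    """Stationary adaptation-fluctuation variance and channel-noise intensity.

    Returns (noise_variance, noise_intensity, additive_validity_ratio):

    * noise_variance  -- Var(a) = <a>(1-<a>)/N of the open fraction,
    * noise_intensity -- dimensionless OU intensity delta_hat-free form
      Var(a) * tau_a (variance times correlation time),
    * additive_validity_ratio -- relative fluctuation of the multiplicative
      noise strength, |1-2<a>| / (2 sqrt(N <a>(1-<a>))); the additive-noise
      approximation requires this to be small.
    """
    if firing_rate <= 0:
        raise ParameterError("firing_rate must be > 0")
    p0 = kinetics.subthreshold_activation
    a_mean = p0 + firing_rate * kinetics.pulse_duration * (1.0 - p0)
    if a_mean >= 1.0:
        raise ParameterError("mean activation >= 1: rate * pulse too large")
    if kinetics.is_infinite:
        return 0.0, 0.0, 0.0
    n_ch = kinetics.n_channels
    var_a = a_mean * (1.0 - a_mean) / n_ch
    intensity = var_a * kinetics.tau_a
    ratio = abs(1.0 - 2.0 * a_mean) / (
        2.0 * np.sqrt(n_ch * a_mean * (1.0 - a_mean)))
    if warn and ratio > 0.5:
        warnings.warn(
            f"additive-noise approximation questionable: relative "
            f"fluctuation of the noise strength is {ratio:.2f}", stacklevel=2)
    return var_a, intensity, ratio


def schedule_to_json(schedule: Sequence[Tuple[float, float]]) -> str:
    return json.dumps([[float(t), float(p)] for t, p in schedule])


def schedule_from_json(text: str):
    return [(float(t), float(p)) for t, p in json.loads(text)]
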