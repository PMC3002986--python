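"""Conductance-based Traub-Miles neuron with an M-type adaptation current.

Two variants: deterministic M-current with additive white current noise, and
a stochastic M-current carried by N two-state channels simulated with a
hybrid Gillespie scheme (voltage-dependent rates frozen over at most
``gillespie_cap`` per update).

The voltage-dependent M time constant is ``tau_scale / (3.3 exp((V+35)/20) +
exp(-(V+35)/20))``; ``calibrate_tau_scale`` tunes ``tau_scale`` so that the
exponential buildup of the M activation during periodic firing at the
reference rate matches a requested adaptation time constant.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq, curve_fit

from . import _kernels
from .config import ParameterError
from .pif import SpikeTrain


@dataclass(frozen=True)
class TraubMilesConfig:
    """All parameters of the Traub-Miles model (mV, ms, uA/cm2, mS/cm2)."""

    c_m: float = 1.0
    g_na: float = 100.0
    e_na: float = 50.0
    g_k: float = 80.0
    e_k: float = -100.0
    g_l: float = 0.1
    e_l: float = -67.0
    g_m: float = 1.0
    tau_scale: float = 100.0
    i_app: float = 10.0
    noise_intensity: float = 0.0   # D, (uA/cm2)^2 * ms
    n_channels: int = 1000
    dt: float = 0.01
    gillespie_cap: float = 0.05
    spike_threshold: float = 0.0   # mV, upward crossing
    refractory: float = 2.0        # ms

    def __post_init__(self):
        for name in ("c_m", "dt", "gillespie_cap", "tau_scale"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("g_na", "g_k", "g_l", "g_m", "noise_intensity"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_channels < 1:
            raise ParameterError("n_channels must be >= 1")

    def replace(self, **kw) -> "TraubMilesConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TraubMilesConfig":
        return cls(**d)


@dataclass(frozen=True)
class HHState:
    """Dynamical state of the conductance-based model."""

    v: float
    m: float
    h: float
    n: float
    w: float            # continuous M activation (deterministic variant)
    n_open: int = 0     # open M channels (stochastic variant)

    def __post_init__(self):
        for g in ("m", "h", "n", "w"):
            val = getattr(self, g)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"gating variable {g} outside [0, 1]")


def tm_gating(v: float):
    """Steady states and time constants of m, h, n and w at voltage v.

    Returns a dict with keys 'm', 'h', 'n', 'w' mapping to (x_inf, tau_x)
    using tau_scale = 100 for w (rescale tau_w by tau_scale/100 for other
    configurations).
    """
    if not np.isfinite(v):
        raise ParameterError("voltage must be finite")
    am, bm, ah, bh, an, bn = _kernels.tm_rates(float(v))
    winf, tw = _kernels.tm_w_gate(float(v), 100.0)
    return {
        "m": (am / (am + bm), 1.0 / (am + bm)),
        "h": (ah / (ah + bh), 1.0 / (ah + bh)),
        "n": (an / (an + bn), 1.0 / (an + bn)),
        "w": (winf, tw),
    }


def _run(config: TraubMilesConfig, t_end, seed, stochastic, record,
         v_stride=1, max_spikes=None):
    if t_end <= 0:
        raise ParameterError("t_end must be > 0")
    if stochastic and config.dt > config.gillespie_cap:
        raise ParameterError("dt must not exceed gillespie_cap for the "
                             "stochastic M-current variant")
    if max_spikes is None:
        max_spikes = int(t_end) + 1000  # < 1 kHz firing
    cap = int(np.ceil(t_end / config.dt / v_stride)) + 1 if record else 0
    v_out = np.empty(cap)
    w_out = np.empty(cap)
    spikes, nspk, nrec, status = _kernels.tm_run(
        config.c_m, config.g_na, config.e_na, config.g_k, config.e_k,
        config.g_l, config.e_l, config.g_m, config.tau_scale, config.i_app,
        config.noise_intensity, config.n_channels, 1 if stochastic else 0,
        config.dt, t_end, seed, config.spike_threshold, config.refractory,
        max_spikes, v_stride, v_out, w_out)
    if status != 0:
        raise RuntimeError(
            f"integration blew up (NaN voltage) at dt = {config.dt}; "
            "reduce the step size")
    train = SpikeTrain(times=spikes, window=(0.0, t_end))
    if record:
        t_grid = np.arange(nrec) * config.dt * v_stride
        return train, t_grid, v_out[:nrec], w_out[:nrec]
    return train


def simulate_tm_deterministic(config: TraubMilesConfig, t_end: float,
                              seed: int, record: bool = False,
                              v_stride: int = 1):
    """Deterministic M-current plus additive white current noise."""
    return _run(config, t_end, seed, stochastic=False, record=record,
                v_stride=v_stride)


def simulate_tm_stochastic_m(config: TraubMilesConfig, t_end: float,
                             seed: int, record: bool = False,
                             v_stride: int = 1):
    """Stochastic M-current: N two-state channels, hybrid Gillespie gating
    (rates refreshed at least every ``gillespie_cap``); white noise optional
    (mixed case)."""
    return _run(config, t_end, seed, stochastic=True, record=record,
                v_stride=v_stride)


def detect_spikes(times: np.ndarray, voltage: np.ndarray,
                  threshold: float = 0.0,
                  refractory: float = 2.0) -> SpikeTrain:
    """Upward threshold crossings of a uniformly sampled voltage trace;
    crossings within the refractory window are merged."""
    v = np.asarray(voltage, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(v) == 0:
        raise ParameterError("empty voltage trace")
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    out = []
    last = -np.inf
    for i in up:
        ts = t[i + 1]
        if ts - last >= refractory:
            out.append(ts)
            last = ts
    return SpikeTrain(times=np.asarray(out), window=(t[0], t[-1]))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------
def calibrate_rate(config: TraubMilesConfig, target_rate_hz: float,
                   seed: int = 0, t_sim: float = 3000.0,
                   i_lo: float = 0.5, i_hi: float = 40.0,
                   stochastic: Optional[bool] = None) -> float:
    """Find the applied current giving the target mean firing rate."""
    if stochastic is None:
        stochastic = False

    def rate_of(i_app):
        cfg = config.replace(i_app=i_app)
        run = (simulate_tm_stochastic_m if stochastic
               else simulate_tm_deterministic)
        tr = run(cfg, t_sim, seed)
        t = tr.times[tr.times > 500.0]
        return len(t) / (t_sim - 500.0) * 1000.0  # Hz

    f_lo = rate_of(i_lo) - target_rate_hz
    f_hi = rate_of(i_hi) - target_rate_hz
    if f_lo * f_hi > 0:
        raise ParameterError("target rate not bracketed by [i_lo, i_hi]")
    return brentq(lambda i: rate_of(i) - target_rate_hz, i_lo, i_hi,
                  xtol=0.02)


def m_buildup_time(config: TraubMilesConfig, seed: int = 0,
                   t_sim: float = 1500.0) -> float:
    """Exponential buildup time constant of the M activation w during
    repetitive firing, with the M feedback switched off (g_m = 0)."""
    cfg = config.replace(g_m=0.0)
    _, t, _, w = simulate_tm_deterministic(cfg, t_sim, seed, record=True,
                                           v_stride=10)
    # cycle-average with a running window of ~10 ms to remove spike phases
    win = max(1, int(10.0 / (cfg.dt * 10)))
    kern = np.ones(win) / win
    w_s = np.convolve(w, kern, mode="valid")
    t_s = t[win - 1:]

    def model(tt, w_inf, tau):
        return w_inf * (1.0 - np.exp(-tt / tau))

    p0 = (max(w_s[-1], 1e-3), config.tau_scale)
    popt, _ = curve_fit(model, t_s, w_s, p0=p0, maxfev=20000)
    return float(popt[1])


def calibrate_tau_scale(config: TraubMilesConfig, tau_a_target: float,
                        seed: int = 0, n_iter: int = 3) -> float:
    """Adjust tau_scale so the M-activation buildup time constant during
    repetitive firing matches tau_a_target (buildup scales linearly with
    tau_scale to a good approximation)."""
    scale = config.tau_scale
    for _ in range(n_iter):
        tau_meas = m_buildup_time(config.replace(tau_scale=scale), seed=seed)
        scale *= tau_a_target / tau_meas
    return scale
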