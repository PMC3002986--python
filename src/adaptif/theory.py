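"""Closed-form theory for the adaptive PIF model.

Contents
--------
* inverse-Gaussian ISI density and moments (white noise, mean-adaptation
  approximation),
* self-consistent stationary rate and mean adaptation,
* weak-noise ISI density, cumulants, rescaled skewness/kurtosis and serial
  correlations of the reduced colored-noise model,
* noise-free limit cycle of the deterministic-adaptation model and the
  resulting geometric serial-correlation sequence,
* the exponential step response of the trial-averaged firing rate.

The weak-noise cumulants were obtained by a systematic expansion of the
first-passage problem (flux approximation with flux-biased initial noise
distribution) in powers of eps = sigma_eff^2/mu_eff^2, with s = 1/rho the
mean ISI in units of the noise correlation time and x = exp(-s):

    kappa1 = s                       (exact at all computed orders)
    kappa2 = 2(s-1+x) eps + 2(2x^2+s x-3x+1) eps^2
             + x(s^2+16 s x-10 s+27 x^2-48 x+21) eps^3
    kappa3 = 12(1-x)(s-1+x) eps^2
             - 12(s^2 x+8 s x^2-8 s x+9 x^3-20 x^2+13 x-2) eps^3
             + 6x(-s^3-48 s^2 x+18 s^2-243 s x^2+336 s x-93 s
                  -256 x^3+648 x^2-528 x+136) eps^4
    kappa4 = 24(s-1+x)(2 s x+7 x^2-12 x+5) eps^3
             + 12(4 s^3 x+102 s^2 x^2-64 s^2 x+358 s x^3-640 s x^2
                  +282 s x+289 x^4-858 x^3+878 x^2-338 x+29) eps^4

In the quasi-static limit (rho -> inf) these reduce to the exactly solvable
frozen-noise model; in the opposite limit (rho -> 0) the shape measures
approach the inverse-Gaussian values.  The leading-order rescaled skewness
and kurtosis are

    S0(rho) = s(1-x)/(s-1+x),
    K0(rho) = s^2 (2 s x+7 x^2-12 x+5) / (5 (s-1+x)^2),

which saturate at 2 and 24/5 for rho -> inf and tend to 1 for rho -> 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import integrate
from scipy.optimize import brentq

from .config import (EffectiveColoredParams, NonFiringError, ParameterError,
                     PIFConfig)

__all__ = [
    "IGParams", "ig_density", "ig_moments", "ig_from_drift_diffusion",
    "stationary_rate_adapted", "mean_adaptation",
    "colored_isi_density", "small_t_limit", "colored_isi_cumulants",
    "weak_noise_shape", "WeakNoiseShape", "scc_colored",
    "LimitCycle", "limit_cycle", "scc_deterministic", "rate_step_response",
    "SKEWNESS_SATURATION", "KURTOSIS_SATURATION",
]

#: large-rho saturation values of the leading-order rescaled skewness and
#: kurtosis of the colored-noise model
SKEWNESS_SATURATION = 2.0
KURTOSIS_SATURATION = 24.0 / 5.0


# ---------------------------------------------------------------------------
# inverse Gaussian
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class IGParams:
    """Inverse-Gaussian ISI density parametrized by mean and CV."""

    mean: float
    cv: float

    def __post_init__(self):
        if self.mean <= 0 or self.cv <= 0:
            raise ParameterError("mean and cv must be > 0")

    @property
    def shape(self) -> float:
        """Shape parameter lambda = mean / CV^2."""
        return self.mean / self.cv**2


def ig_from_drift_diffusion(mu: float, D: float,
                            theta: float = 1.0) -> IGParams:
    """IG parameters of the first-passage time of drift mu, diffusion D
    (increment variance 2 D dt) from 0 to theta."""
    if mu <= 0 or D <= 0:
        raise ParameterError("mu and D must be > 0")
    return IGParams(mean=theta / mu, cv=math.sqrt(2.0 * D / (theta * mu)))


def ig_density(t, params: IGParams):
    """Inverse-Gaussian probability density; 0 for t <= 0 by convention."""
    t = np.asarray(t, dtype=float)
    lam = params.shape
    m = params.mean
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.sqrt(lam / (2.0 * np.pi * tp**3)) * np.exp(
        -lam * (tp - m) ** 2 / (2.0 * m**2 * tp))
    return out if out.ndim else float(out)


def ig_moments(params: IGParams) -> Tuple[float, float, float, float]:
    """(mean, cv, skewness, excess kurtosis) of the IG density."""
    cv = params.cv
    return params.mean, cv, 3.0 * cv, 15.0 * cv**2


# ---------------------------------------------------------------------------
# stationary rate / mean adaptation
# ---------------------------------------------------------------------------
def stationary_rate_adapted(config: PIFConfig) -> float:
    """Self-consistent stationary firing rate of the adapted PIF."""
    r = config.stationary_rate()
    if r <= 0:
        raise NonFiringError("configuration does not fire")
    return r


def mean_adaptation(config: PIFConfig) -> float:
    """Stationary mean open fraction <a> = p0 + r* delta (1 - p0)."""
    return config.mean_activation()


# ---------------------------------------------------------------------------
# colored-noise ISI density (weak-noise approximation)
# ---------------------------------------------------------------------------
def _colored_raw_density(t, mu, sigma2, tau, theta, epsilon):
    """Gaussian first-passage (flux) approximation, un-normalized."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    u = tp / tau
    eu = np.exp(-u)
    var = sigma2 * tau**2 * (2.0 * u - 3.0 + 4.0 * eu - eu**2)
    var = var + sigma2 * tau**2 * (1.0 - eu) ** 2  # initial-value spread
    # flux-biased mean of the initial noise value: <eta0> = sigma^2/mu
    mshift = (sigma2 / mu) * tau * (1.0 - eu)
    dm = (sigma2 / mu) * eu
    dvar = 2.0 * sigma2 * tau * (1.0 - eu)
    gap = theta - mu * tp - mshift
    sd = np.sqrt(np.maximum(var, 1e-300))
    z = gap / sd
    out[pos] = (np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)
                * (mu + dm + gap * dvar / (2.0 * var)) / sd)
    return np.maximum(out, 0.0)


def _colored_support(params: EffectiveColoredParams):
    mean = params.mean_isi
    r = params.rho_eff
    sd = mean * math.sqrt(max(
        2.0 * params.epsilon * r**2
        * (1.0 / r - 1.0 + math.exp(-1.0 / r)), 1e-12))
    return max(mean - 12.0 * sd, mean * 1e-6), mean + 12.0 * sd


def colored_isi_density(t, params: EffectiveColoredParams,
                        renormalize: bool = True):
    """Weak-noise ISI density of the colored-noise-driven PIF.

    The truncated asymptotic density is not exactly normalized; by default it
    is renormalized numerically over [mean - 12 sd, mean + 12 sd].
    """
    if params.epsilon >= 1.0:
        import warnings
        warnings.warn("epsilon >= 1: weak-noise density unreliable",
                      stacklevel=2)
    args = (params.mu_eff, params.sigma2_eff, params.tau_eff,
            params.threshold, params.epsilon)
    val = _colored_raw_density(t, *args)
    if renormalize:
        lo, hi = _colored_support(params)
        norm, _ = integrate.quad(
            lambda tt: float(_colored_raw_density(np.array([tt]), *args)[0]),
            lo, hi, limit=400, epsabs=1e-12, epsrel=1e-10)
        val = val / norm
    return val


def small_t_limit(t, params: EffectiveColoredParams):
    """Quasi-static limit of the ISI density, valid for t << tau_eff.

    This is the frozen-noise density with the O(eps) drive bias retained, so
    that it is the exact t << tau limit of :func:`colored_isi_density`.
    """
    t = np.asarray(t, dtype=float)
    mu = params.mu_eff * (1.0 + params.epsilon)
    sig = math.sqrt(params.sigma2_eff)
    theta = params.threshold
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = (theta / (sig * tp**2 * np.sqrt(2.0 * np.pi))
                * np.exp(-(theta - mu * tp) ** 2
                         / (2.0 * sig**2 * tp**2)))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# weak-noise cumulants and shape measures
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class WeakNoiseShape:
    """Weak-noise ISI cumulants (in units of tau_eff) and shape measures."""

    epsilon: float
    rho: float
    kappa1: float
    kappa2: float
    kappa3: float
    kappa4: float
    cv2: float
    rescaled_skewness: float
    rescaled_kurtosis: float
    rescaled_skewness_leading: float
    rescaled_kurtosis_leading: float


def _wn_kappas(eps, s):
    x = math.exp(-s)
    g = s - 1.0 + x
    k1 = s
    k2 = (2.0 * g * eps
          + 2.0 * (2 * x * x + s * x - 3 * x + 1) * eps**2
          + x * (s * s + 16 * s * x - 10 * s + 27 * x * x - 48 * x + 21)
          * eps**3)
    k3 = (12.0 * (1 - x) * g * eps**2
          - 12.0 * (s * s * x + 8 * s * x * x - 8 * s * x + 9 * x**3
                    - 20 * x * x + 13 * x - 2) * eps**3
          + 6.0 * x * (-s**3 - 48 * s * s * x + 18 * s * s
                       - 243 * s * x * x + 336 * s * x - 93 * s
                       - 256 * x**3 + 648 * x * x - 528 * x + 136) * eps**4)
    k4 = (24.0 * g * (2 * s * x + 7 * x * x - 12 * x + 5) * eps**3
          + 12.0 * (4 * s**3 * x + 102 * s * s * x * x - 64 * s * s * x
                    + 358 * s * x**3 - 640 * s * x * x + 282 * s * x
                    + 289 * x**4 - 858 * x**3 + 878 * x * x - 338 * x
                    + 29) * eps**4)
    return k1, k2, k3, k4


def weak_noise_shape(epsilon: float, rho: float) -> WeakNoiseShape:
    """Closed-form weak-noise shape quantities at (epsilon, rho)."""
    if epsilon < 0:
        raise ParameterError("epsilon must be >= 0")
    if rho <= 0:
        raise ParameterError("rho must be > 0")
    s = 1.0 / rho
    x = math.exp(-s)
    g = s - 1.0 + x
    k1, k2, k3, k4 = _wn_kappas(epsilon, s)
    # second-order CV^2
    cv2 = (2.0 * g * epsilon
           + 2.0 * (2 * x * x + s * x - 3 * x + 1) * epsilon**2) / s**2
    s0 = s * (1.0 - x) / g
    k0 = s * s * (2 * s * x + 7 * x * x - 12 * x + 5) / (5.0 * g * g)
    if epsilon > 0:
        sr = k3 * k1 / (3.0 * k2**2)
        kr = k4 * k1**2 / (15.0 * k2**3)
    else:
        sr, kr = s0, k0
    return WeakNoiseShape(
        epsilon=epsilon, rho=rho, kappa1=k1, kappa2=k2, kappa3=k3, kappa4=k4,
        cv2=cv2, rescaled_skewness=sr, rescaled_kurtosis=kr,
        rescaled_skewness_leading=s0, rescaled_kurtosis_leading=k0)


def colored_isi_cumulants(params: EffectiveColoredParams):
    """Weak-noise ISI cumulants in the time units of the parameters."""
    s = 1.0 / params.rho_eff
    k1, k2, k3, k4 = _wn_kappas(params.epsilon, s)
    tau = params.tau_eff
    return k1 * tau, k2 * tau**2, k3 * tau**3, k4 * tau**4


def weak_noise_shape_for(params: EffectiveColoredParams) -> WeakNoiseShape:
    """Weak-noise shape quantities of a reduced colored-noise model."""
    return weak_noise_shape(params.epsilon, params.rho_eff)


def scc_colored(lag: int, params: EffectiveColoredParams) -> float:
    """Weak-noise serial correlation coefficient of the colored-noise model.

    rho_k = exp(-(k-1) s) (1-exp(-s))^2 / (2 (s-1+exp(-s))),  s = 1/rho_eff:
    positive with geometric decay exp(-s) per lag; independent of epsilon at
    leading order.
    """
    if lag < 1:
        raise ParameterError("lag must be >= 1")
    s = 1.0 / params.rho_eff
    x = math.exp(-s)
    return float(math.exp(-(lag - 1) * s) * (1.0 - x) ** 2
                 / (2.0 * (s - 1.0 + x)))


# ---------------------------------------------------------------------------
# deterministic-adaptation limit cycle and serial correlations
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class LimitCycle:
    """Noise-free limit cycle of the adaptive PIF with pulse activation."""

    period: float
    a_spike: float      # open fraction at the spike (pre-pulse)
    a_reset: float      # open fraction just after the pulse
    x0: float           # adaptation drive Delta * a_reset
    jump: float         # Delta * (a_reset - a_spike)

    def residual(self, config: PIFConfig) -> float:
        """Residual of the threshold condition at the solution."""
        return _lc_threshold_residual(config, self.period)


def _lc_geometry(config: PIFConfig, T: float):
    k = config.kinetics
    tau, delta, p0 = k.tau_a, k.pulse_duration, k.subthreshold_activation
    q = math.exp(-delta / tau)
    E = math.exp(-T / tau)
    if delta == 0.0:
        # degenerate: no pulse, adaptation stays at p0
        return p0, p0
    a0 = (p0 * (1 - E / q) * q + E * (1.0 - q)) / (q * (1.0 - E))
    a_delta = 1.0 - (1.0 - a0) * q
    return a0, a_delta


def _lc_threshold_residual(config: PIFConfig, T: float):
    k = config.kinetics
    tau, delta, p0 = k.tau_a, k.pulse_duration, k.subthreshold_activation
    q = math.exp(-delta / tau)
    E = math.exp(-T / tau)
    a0, a_delta = _lc_geometry(config, T)
    int_pulse = delta - (1.0 - a0) * tau * (1.0 - q)
    int_decay = p0 * (T - delta) + (a_delta - p0) * tau * (1.0 - E / q)
    return (config.base_drive * T
            - config.adaptation_strength * (int_pulse + int_decay)
            - config.threshold)


def limit_cycle(config: PIFConfig) -> LimitCycle:
    """Solve the periodic orbit of the noise-free dynamics."""
    rate = config.stationary_rate()
    if rate <= 0:
        raise NonFiringError("no limit cycle: configuration does not fire")
    k = config.kinetics
    delta = k.pulse_duration
    if config.adaptation_strength == 0.0 or delta == 0.0:
        p0 = k.subthreshold_activation
        T = (config.threshold / (config.base_drive
                                 - config.adaptation_strength * p0))
        return LimitCycle(period=T, a_spike=p0, a_reset=p0,
                          x0=config.adaptation_strength * p0, jump=0.0)
    lo = delta * (1.0 + 1e-12)
    hi = max(2.0 * delta, 2.0 / rate)
    while _lc_threshold_residual(config, hi) < 0:
        hi *= 2.0
        if hi > 1e12 / rate:
            raise NonFiringError("limit cycle search failed")
    if _lc_threshold_residual(config, lo) > 0:
        raise ParameterError("limit cycle period <= pulse duration")
    T = brentq(lambda tt: _lc_threshold_residual(config, tt), lo, hi,
               xtol=1e-14, rtol=1e-14)
    a0, a_delta = _lc_geometry(config, T)
    return LimitCycle(period=float(T), a_spike=float(a0),
                      a_reset=float(a_delta),
                      x0=config.adaptation_strength * a_delta,
                      jump=config.adaptation_strength * (a_delta - a0))


def _scc_det_coeffs(config: PIFConfig):
    lc = limit_cycle(config)
    k = config.kinetics
    E = math.exp(-lc.period / k.tau_a)
    p0 = k.subthreshold_activation
    w0 = config.adaptation_strength * lc.a_spike
    v_t = config.base_drive - w0  # drift at threshold
    if v_t <= 0:
        raise ParameterError("non-positive drift at threshold")
    u = (config.adaptation_strength * (lc.a_spike - p0)
         * (1.0 - E) / v_t)
    a = E - u
    return a, u


def scc_deterministic(lag: int, config: PIFConfig) -> float:
    """Serial correlation coefficient of the white-noise model with
    deterministic adaptation (weak-noise limit; independent of D).

    rho_k = A * a^(k-1) with A = u (u a - (1 - a^2)) / (u^2 + 1 - a^2) < 0,
    where a is the linearized Poincare-map multiplier and u the coupling of
    the adaptation state into the ISI.  Odd lags are always negative; even
    lags follow the sign of a.
    """
    if lag < 1:
        raise ParameterError("lag must be >= 1")
    if config.adaptation_strength == 0.0:
        return 0.0
    a, u = _scc_det_coeffs(config)
    if u == 0.0:
        return 0.0
    amp = u * (u * a - (1.0 - a * a)) / (u * u + 1.0 - a * a)
    return float(amp * a ** (lag - 1))


# ---------------------------------------------------------------------------
# step response
# ---------------------------------------------------------------------------
def rate_step_response(t, config: PIFConfig, step) -> np.ndarray:
    """Trial-averaged firing rate for a base-current step mu -> mu+delta_mu.

    The rate jumps instantaneously by delta_mu/theta at onset and relaxes
    exponentially to the adapted rate with the effective time constant
    alpha * tau_a (alpha = degree of adaptation).
    """
    t_on, delta_mu = step
    t = np.asarray(t, dtype=float)
    r_pre = stationary_rate_adapted(config)
    post_cfg = config.replace(base_drive=config.base_drive + delta_mu)
    r_inf = stationary_rate_adapted(post_cfg)
    r_on = r_pre + delta_mu / config.threshold
    alpha = effective_alpha(config)
    tau_eff = alpha * config.kinetics.tau_a
    out = np.full_like(t, r_pre, dtype=float)
    post = t >= t_on
    out[post] = r_inf + (r_on - r_inf) * np.exp(-(t[post] - t_on) / tau_eff)
    return out


def effective_alpha(config: PIFConfig) -> float:
    """Degree of adaptation alpha = theta/(theta + Delta*pulse*(1-p0))."""
    k = config.kinetics
    return config.threshold / (
        config.threshold + config.adaptation_strength * k.pulse_duration
        * (1.0 - k.subthreshold_activation))


def curve_to_csv(path, x, y, header="x,y"):
    np.savetxt(path, np.column_stack([x, y]), delimiter=",", header=header,
               comments="")
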