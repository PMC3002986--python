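"""Domain types: channel kinetics, PIF configuration, reduced-model parameters.

Units are left to the user (the canonical choice in the documentation is ms
for time and threshold units for voltage); all statistics are reported in the
same units as the inputs.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional


class ParameterError(ValueError):
    """Invalid model parameter."""


class NonFiringError(ParameterError):
    """The stationary firing rate of the requested configuration is <= 0."""


@dataclass(frozen=True)
class ChannelKinetics:
    """A finite population of two-state adaptation channels.

    n_channels=None flags the infinite-population (deterministic) limit.
    ``pulse_duration`` is the width of the spike-triggered activation pulse
    during which the single-channel steady-state activation is one;
    ``subthreshold_activation`` is its value between spikes.
    """

    n_channels: Optional[int]
    tau_a: float
    pulse_duration: float
    subthreshold_activation: float = 0.0

    def __post_init__(self):
        if self.tau_a <= 0:
            raise ParameterError(f"tau_a must be > 0, got {self.tau_a}")
        if self.pulse_duration < 0:
            raise ParameterError("pulse_duration must be >= 0")
        if not 0.0 <= self.subthreshold_activation <= 1.0:
            raise ParameterError("subthreshold_activation must be in [0, 1]")
        if self.n_channels is not None and self.n_channels < 1:
            raise ParameterError("n_channels must be >= 1 (or None)")

    @property
    def is_infinite(self) -> bool:
        return self.n_channels is None


@dataclass(frozen=True)
class PIFConfig:
    """Perfect integrate-and-fire neuron with an adaptation current.

    base_drive (mu) and adaptation_strength (Delta) are in threshold units
    per time; white_noise_intensity (D) in threshold^2 per time.  The voltage
    is reset to 0 and spikes at ``threshold``.
    """

    base_drive: float
    adaptation_strength: float
    kinetics: ChannelKinetics
    white_noise_intensity: float = 0.0
    threshold: float = 1.0
    dt: Optional[float] = None  # None: min(tau_a, mean ISI)/1000

    def __post_init__(self):
        if self.white_noise_intensity < 0:
            raise ParameterError("white_noise_intensity must be >= 0")
        if self.threshold <= 0:
            raise ParameterError("threshold must be > 0")
        if self.adaptation_strength < 0:
            raise ParameterError("adaptation_strength must be >= 0")
        if self.dt is not None and self.dt <= 0:
            raise ParameterError("dt must be > 0")
        # firing must persist: stationary rate > 0
        if self.stationary_rate() <= 0:
            raise NonFiringError(
                "stationary firing rate is <= 0 for this configuration "
                f"(base_drive={self.base_drive})")

    # -- self-consistent stationary quantities (mean-adaptation balance) ----
    def stationary_rate(self) -> float:
        """Self-consistent stationary firing rate r*."""
        k = self.kinetics
        p0 = k.subthreshold_activation
        num = self.base_drive - self.adaptation_strength * p0
        den = (self.threshold
               + self.adaptation_strength * k.pulse_duration * (1.0 - p0))
        return num / den

    def mean_activation(self) -> float:
        """Stationary mean fraction of open channels <a>."""
        k = self.kinetics
        p0 = k.subthreshold_activation
        return p0 + self.stationary_rate() * k.pulse_duration * (1.0 - p0)

    def default_dt(self) -> float:
        if self.dt is not None:
            return self.dt
        mean_isi = 1.0 / self.stationary_rate()
        return min(self.kinetics.tau_a, mean_isi) / 1000.0

    def replace(self, **kw) -> "PIFConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PIFConfig":
        d = dict(d)
        kin = d.pop("kinetics")
        required = ("n_channels", "tau_a", "pulse_duration")
        for key in required:
            if key not in kin:
                raise ParameterError(f"missing kinetics field: {key!r}")
        if "base_drive" not in d:
            raise ParameterError("missing field: 'base_drive'")
        return cls(kinetics=ChannelKinetics(**kin), **d)


@dataclass(frozen=True)
class NondimConfig:
    """Dimensionless PIF parameters (voltage in threshold units, time in
    units of tau_a), plus the channel-noise intensity."""

    mu_hat: float          # mu * tau_a / theta
    delta_hat: float       # Delta * tau_a / theta
    pulse_hat: float       # pulse_duration / tau_a
    d_hat: float           # D * tau_a / theta^2
    d_channel_hat: float   # delta_hat^2 * <a>(1-<a>)/N, 0 for N = inf
    subthreshold_activation: float = 0.0

    def to_dimensional(self, theta: float, tau_a: float,
                       n_channels: Optional[int] = None) -> PIFConfig:
        kin = ChannelKinetics(
            n_channels=n_channels,
            tau_a=tau_a,
            pulse_duration=self.pulse_hat * tau_a,
            subthreshold_activation=self.subthreshold_activation,
        )
        return PIFConfig(
            base_drive=self.mu_hat * theta / tau_a,
            adaptation_strength=self.delta_hat * theta / tau_a,
            kinetics=kin,
            white_noise_intensity=self.d_hat * theta**2 / tau_a,
            threshold=theta,
        )


@dataclass(frozen=True)
class EffectiveColoredParams:
    """Parameters of the reduced colored-noise PIF model.

    The slow adaptation feedback cancels the low-frequency part of the
    channel fluctuation; solving the linearized filter dynamics exactly, the
    surviving drive fluctuation is an Ornstein-Uhlenbeck process whose
    parameters are all scaled by the common factor ``alpha`` (the degree of
    adaptation): ``mu_eff = alpha*mu``, ``tau_eff = alpha*tau_a`` and
    ``sigma2_eff = alpha*Delta^2*Var(a)``.

    ``epsilon = sigma2_eff/mu_eff**2`` is the weak-noise small parameter;
    ``rho = tau_a * r*`` is the bare time-scale separation, while
    ``rho_eff = tau_eff * r*`` is the separation of the reduced model that
    enters the weak-noise formulas.
    """

    alpha: float
    mu_eff: float
    sigma2_eff: float
    tau_eff: float
    epsilon: float
    rho: float
    threshold: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0 + 1e-12:
            raise ParameterError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.epsilon < 0 or self.rho <= 0:
            raise ParameterError("epsilon must be >= 0 and rho > 0")

    @property
    def mean_isi(self) -> float:
        return self.threshold / self.mu_eff

    @property
    def rho_eff(self) -> float:
        """Time-scale separation of the reduced model, tau_eff / mean ISI."""
        return self.tau_eff * self.mu_eff / self.threshold

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def config_to_json(config: PIFConfig, **extra) -> str:
    d = config.to_dict()
    d.update(extra)
    return json.dumps(d, indent=2, sort_keys=True)


def config_from_json(text: str) -> PIFConfig:
    return PIFConfig.from_dict(json.loads(text))
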