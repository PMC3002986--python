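"""Estimators for interspike-interval statistics.

Cumulants use unbiased k-statistics; shape measures are normalized so that an
inverse-Gaussian ISI density gives exactly one; serial correlations use a
single pooled mean and variance along the sequence.  Standard errors come
from a circular block bootstrap, so correlated sequences are handled.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .config import ParameterError


@dataclass(frozen=True)
class ISIStats:
    """Summary statistics of an ISI sequence."""

    n: int
    mean: float
    cv: float
    skewness: float
    kurtosis_excess: float
    rescaled_skewness: float
    rescaled_kurtosis: float
    scc: np.ndarray
    mean_se: float
    cv_se: float
    rescaled_skewness_se: float
    rescaled_kurtosis_se: float
    scc_se: np.ndarray

    def to_json(self, **provenance) -> str:
        d = {
            "n": self.n, "mean": self.mean, "cv": self.cv,
            "skewness": self.skewness,
            "kurtosis_excess": self.kurtosis_excess,
            "rescaled_skewness": self.rescaled_skewness,
            "rescaled_kurtosis": self.rescaled_kurtosis,
            "scc": list(self.scc), "scc_se": list(self.scc_se),
            "mean_se": self.mean_se, "cv_se": self.cv_se,
            "rescaled_skewness_se": self.rescaled_skewness_se,
            "rescaled_kurtosis_se": self.rescaled_kurtosis_se,
        }
        d.update(provenance)
        return json.dumps(d, indent=2, sort_keys=True)


def _as_intervals(sample) -> np.ndarray:
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ParameterError("interval sample must be one-dimensional")
    if len(x) and np.any(x <= 0):
        raise ParameterError("all intervals must be > 0")
    return x


def isi_cumulants(sample) -> Tuple[float, float, float, float]:
    """Unbiased k-statistics estimates of the first four cumulants."""
    x = _as_intervals(sample)
    n = len(x)
    if n < 8:
        raise ParameterError(
            f"need at least 8 intervals for the fourth cumulant, got {n}")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    m3 = np.mean(xc**3)
    m4 = np.mean(xc**4)
    k1 = float(np.mean(x))
    k2 = n / (n - 1.0) * m2
    k3 = n**2 / ((n - 1.0) * (n - 2.0)) * m3
    k4 = (n**2 * ((n + 1.0) * m4 - 3.0 * (n - 1.0) * m2**2)
          / ((n - 1.0) * (n - 2.0) * (n - 3.0)))
    return k1, float(k2), float(k3), float(k4)


def _shape_from_cumulants(k1, k2, k3, k4):
    cv = np.sqrt(k2) / k1
    skew = k3 / k2**1.5
    kurt = k4 / k2**2
    # normalized by the inverse-Gaussian values at the same CV:
    # skewness_IG = 3 CV, excess kurtosis_IG = 15 CV^2
    return cv, skew / (3.0 * cv), kurt / (15.0 * cv**2), skew, kurt


def isi_shape(sample) -> Tuple[float, float, float]:
    """(CV, rescaled skewness, rescaled kurtosis).

    Skewness and excess kurtosis are divided by their inverse-Gaussian
    values at the same CV (3*CV and 15*CV^2), so both equal one for
    inverse-Gaussian data.
    """
    k1, k2, k3, k4 = isi_cumulants(sample)
    if k2 <= 0:
        raise ParameterError("degenerate sample: zero interval variance")
    cv, s_r, k_r, _, _ = _shape_from_cumulants(k1, k2, k3, k4)
    return float(cv), float(s_r), float(k_r)


def serial_correlation(sample, k_max: int, n_boot: int = 200,
                       seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Serial correlation coefficients at lags 1..k_max with bootstrap SEs.

    A single pooled mean and variance along the sequence is used
    (stationarity assumed); SEs come from a circular block bootstrap with
    block length max(10, 2 * decorrelation lag).
    """
    x = _as_intervals(sample)
    n = len(x)
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    if k_max >= n / 10:
        raise ParameterError(
            f"k_max = {k_max} too large for n = {n} (need k_max < n/10)")
    rho = _scc_pooled(x, k_max)
    # decorrelation lag for block length
    dec = k_max
    for k in range(k_max):
        if abs(rho[k]) < 2.0 / np.sqrt(n):
            dec = k + 1
            break
    block = int(max(10, 2 * dec))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, k_max))
    n_blocks = int(np.ceil(n / block))
    for b in range(n_boot):
        starts = rng.integers(0, n, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel() % n
        boots[b] = _scc_pooled(x[idx[:n]], k_max)
    return rho, boots.std(axis=0, ddof=1)


def _scc_pooled(x, k_max):
    xc = x - x.mean()
    var = np.mean(xc**2)
    out = np.empty(k_max)
    if var == 0:
        out[:] = 0.0
        return out
    n = len(x)
    for k in range(1, k_max + 1):
        out[k - 1] = np.mean(xc[:-k] * xc[k:]) / var
    return out


def isi_histogram(sample, bins="fd") -> Tuple[np.ndarray, np.ndarray]:
    """Normalized ISI histogram.

    Returns (edges, density); the density integrates to one over the bins.
    ``bins`` follows numpy.histogram (Freedman-Diaconis by default).
    """
    x = _as_intervals(sample)
    if len(x) == 0:
        raise ParameterError("empty sample")
    if isinstance(bins, str) and len(x) < 100:
        raise ParameterError("need at least 100 intervals for automatic "
                             "binning")
    density, edges = np.histogram(x, bins=bins, density=True)
    return edges, density


def histogram_to_csv(path, edges, density):
    np.savetxt(path, np.column_stack([edges[:-1], edges[1:], density]),
               delimiter=",", header="bin_left,bin_right,density",
               comments="")


def time_dependent_rate(trials: Sequence, binwidth: float
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing rate (PSTH).

    ``trials`` is a sequence of SpikeTrain objects with a common window.
    Returns (bin_centers, rate); sum(rate)*binwidth equals the mean spike
    count per trial exactly.
    """
    if len(trials) < 2:
        raise ParameterError("need at least two trials")
    w0 = trials[0].window
    for tr in trials[1:]:
        if not (np.isclose(tr.window[0], w0[0])
                and np.isclose(tr.window[1], w0[1])):
            raise ParameterError("trials have mismatched windows")
    edges = np.arange(w0[0], w0[1] + binwidth, binwidth)
    counts = np.zeros(len(edges) - 1)
    for tr in trials:
        c, _ = np.histogram(tr.times, bins=edges)
        counts += c
    rate = counts / (len(trials) * binwidth)
    return 0.5 * (edges[1:] + edges[:-1]), rate


def _block_bootstrap_stats(x, n_boot, seed, k_max):
    rng = np.random.default_rng(seed)
    n = len(x)
    block = max(10, int(2 * _decorrelation_lag(x)))
    n_blocks = int(np.ceil(n / block))
    rows = []
    for _ in range(n_boot):
        starts = rng.integers(0, n, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel() % n
        xb = x[idx[:n]]
        k1, k2, k3, k4 = isi_cumulants(xb)
        cv, s_r, k_r, _, _ = _shape_from_cumulants(k1, k2, k3, k4)
        rows.append((k1, cv, s_r, k_r))
    return np.array(rows).std(axis=0, ddof=1)


def _decorrelation_lag(x):
    n = len(x)
    k_max = min(100, n // 10)
    if k_max < 1:
        return 1
    rho = _scc_pooled(x, k_max)
    thr = 2.0 / np.sqrt(n)
    for k in range(k_max):
        if abs(rho[k]) < thr:
            return k + 1
    return k_max


def compute_isi_stats(sample, k_max: int = 10, n_boot: int = 200,
                      seed: int = 0) -> ISIStats:
    """All summary statistics of an ISI sequence, with bootstrap errors."""
    x = _as_intervals(sample)
    k1, k2, k3, k4 = isi_cumulants(x)
    if k2 <= 0:
        raise ParameterError("degenerate sample: zero interval variance")
    cv, s_r, k_r, skew, kurt = _shape_from_cumulants(k1, k2, k3, k4)
    k_max_eff = min(k_max, max(1, len(x) // 10 - 1))
    scc, scc_se = serial_correlation(x, k_max_eff, n_boot=n_boot, seed=seed)
    ses = _block_bootstrap_stats(x, n_boot, seed + 1, k_max_eff)
    return ISIStats(
        n=len(x), mean=float(k1), cv=float(cv), skewness=float(skew),
        kurtosis_excess=float(kurt), rescaled_skewness=float(s_r),
        rescaled_kurtosis=float(k_r), scc=scc,
        mean_se=float(ses[0]), cv_se=float(ses[1]),
        rescaled_skewness_se=float(ses[2]), rescaled_kurtosis_se=float(ses[3]),
        scc_se=scc_se)
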