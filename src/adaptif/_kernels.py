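"""Numba-compiled simulation kernels.

All kernels are seeded explicitly (np.random.seed inside the jitted function)
and return plain arrays; user-facing wrappers live in :mod:`adaptif.channels`,
:mod:`adaptif.pif` and :mod:`adaptif.traubmiles`.

Conventions
-----------
* Voltage threshold crossings are located by linear interpolation within an
  Euler-Maruyama step; the overshoot above threshold is carried over after
  reset (the perfect integrator is shift invariant, so this is exact for the
  deterministic part of the dynamics).
* Channel gating is a birth-death process with piecewise-constant rates;
  proposed waiting times are capped at the next rate breakpoint and redrawn,
  which is statistically exact for exponential waiting times.
"""
import numpy as np
from numba import njit

INF = np.inf


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck path (exact conditional-Gaussian update)
# ---------------------------------------------------------------------------
@njit(cache=True)
def ou_path(sigma2, tau, dt, n_steps, seed):
    np.random.seed(seed)
    out = np.empty(n_steps + 1)
    sig = np.sqrt(sigma2)
    a = np.exp(-dt / tau)
    b = sig * np.sqrt(1.0 - a * a)
    out[0] = sig * np.random.normal()
    for k in range(n_steps):
        out[k + 1] = out[k] * a + b * np.random.normal()
    return out


# ---------------------------------------------------------------------------
# Two-state channel population, piecewise-constant activation schedule
# ---------------------------------------------------------------------------
@njit(cache=True)
def gillespie_two_state(n_ch, tau_a, seg_t, seg_p, n_open0, t_end, seed,
                        max_events):
    """Exact Gillespie simulation of N two-state channels.

    seg_t/seg_p: sorted segment start times and activation values p_inf;
    the schedule is clamped (first segment extends to -inf, last to t_end).
    Returns (times, n_open, n_recorded).
    """
    np.random.seed(seed)
    times = np.empty(max_events)
    nopen = np.empty(max_events, dtype=np.int64)
    t = 0.0
    n = n_open0
    idx = 0
    nseg = len(seg_t)
    nrec = 0
    while t < t_end:
        while idx + 1 < nseg and seg_t[idx + 1] <= t:
            idx += 1
        p = seg_p[idx]
        t_bp = seg_t[idx + 1] if idx + 1 < nseg else t_end
        if t_bp > t_end:
            t_bp = t_end
        lam_o = (n_ch - n) * p / tau_a
        lam_c = n * (1.0 - p) / tau_a
        lam = lam_o + lam_c
        if lam <= 0.0:
            t = t_bp
            continue
        t_ev = t + np.random.exponential() / lam
        if t_ev >= t_bp:
            t = t_bp  # redraw after the breakpoint (memoryless)
            continue
        t = t_ev
        if np.random.random() * lam < lam_o:
            n += 1
        else:
            n -= 1
        if nrec < max_events:
            times[nrec] = t
            nopen[nrec] = n
            nrec += 1
    return times[:nrec], nopen[:nrec], nrec


# ---------------------------------------------------------------------------
# PIF with explicit channels, D = 0: exact event-driven integration
# ---------------------------------------------------------------------------
@njit(cache=True)
def pif_channel_event(mu, delta_mu, t_on, big_delta, theta, n_ch, tau_a,
                      pulse, p0, n_open0, t_end, seed, max_spikes,
                      rec_t, rec_n, rec_cap):
    """Event-driven adaptive PIF with channel noise only (D = 0).

    Drift is constant between channel events, so threshold crossings are
    solved analytically.  A step stimulus mu -> mu + delta_mu at t_on is
    supported (t_on = inf for none).  rec_t/rec_n record the channel
    trajectory when rec_cap > 0.
    """
    np.random.seed(seed)
    spikes = np.empty(max_spikes)
    t = 0.0
    v = 0.0
    n = n_open0
    pulse_end = -1.0
    nspk = 0
    nrec = 0
    n_overlap = 0
    while t < t_end and nspk < max_spikes:
        p = 1.0 if t < pulse_end else p0
        lam_o = (n_ch - n) * p / tau_a
        lam_c = n * (1.0 - p) / tau_a
        lam = lam_o + lam_c
        t_ev = t + np.random.exponential() / lam if lam > 0.0 else INF
        g = (mu + delta_mu if t >= t_on else mu) - big_delta * n / n_ch
        gap = theta - v
        if gap < 0.0:
            gap = 0.0
        t_cr = t + gap / g if g > 0.0 else INF
        t_next = t_ev
        kind = 0  # 0 channel, 1 crossing, 2 breakpoint, 3 end
        if t_cr < t_next:
            t_next = t_cr
            kind = 1
        if t < pulse_end and pulse_end < t_next:
            t_next = pulse_end
            kind = 2
        if t < t_on and t_on < t_next:
            t_next = t_on
            kind = 2
        if t_end < t_next:
            t_next = t_end
            kind = 3
        v += g * (t_next - t)
        t = t_next
        if kind == 1:
            if nspk > 0 and t - spikes[nspk - 1] < pulse:
                n_overlap += 1
            spikes[nspk] = t
            nspk += 1
            v = 0.0
            pulse_end = t + pulse
        elif kind == 0:
            if np.random.random() * lam < lam_o:
                n += 1
            else:
                n -= 1
            if nrec < rec_cap:
                rec_t[nrec] = t
                rec_n[nrec] = n
                nrec += 1
        # kind 2: rates/drift change at the breakpoint; nothing else to do
    return spikes[:nspk], nrec, n_overlap


# ---------------------------------------------------------------------------
# PIF with explicit channels and white noise: Euler-Maruyama voltage,
# exact channel sub-process within each step
# ---------------------------------------------------------------------------
@njit(cache=True)
def pif_channel_em(mu, delta_mu, t_on, big_delta, theta, n_ch, tau_a,
                   pulse, p0, D, n_open0, dt, t_end, seed, max_spikes):
    np.random.seed(seed)
    spikes = np.empty(max_spikes)
    sqD = np.sqrt(2.0 * D * dt)
    t = 0.0
    v = 0.0
    n = n_open0
    pulse_end = -1.0
    nspk = 0
    n_overlap = 0
    n_steps = int(np.ceil(t_end / dt))
    for _ in range(n_steps):
        # advance channels exactly over [t, t+dt)
        tc = t
        t_stop_step = t + dt
        a_int = 0.0
        while tc < t_stop_step:
            p = 1.0 if tc < pulse_end else p0
            lam_o = (n_ch - n) * p / tau_a
            lam_c = n * (1.0 - p) / tau_a
            lam = lam_o + lam_c
            t_bp = pulse_end if tc < pulse_end and pulse_end < t_stop_step \
                else t_stop_step
            if lam <= 0.0:
                a_int += n * (t_bp - tc)
                tc = t_bp
                continue
            t_ev = tc + np.random.exponential() / lam
            if t_ev >= t_bp:
                a_int += n * (t_bp - tc)
                tc = t_bp
                continue
            a_int += n * (t_ev - tc)
            tc = t_ev
            if np.random.random() * lam < lam_o:
                n += 1
            else:
                n -= 1
        a_bar = a_int / (n_ch * dt)
        mu_t = mu + delta_mu if t >= t_on else mu
        v_new = v + (mu_t - big_delta * a_bar) * dt + sqD * np.random.normal()
        t += dt
        if v_new >= theta:
            frac = (theta - v) / (v_new - v)
            ts = t - dt + frac * dt
            if nspk > 0 and ts - spikes[nspk - 1] < pulse:
                n_overlap += 1
            spikes[nspk] = ts
            nspk += 1
            pulse_end = ts + pulse
            v_new -= theta
            if nspk == max_spikes:
                break
        v = v_new
    return spikes[:nspk], n_overlap


# ---------------------------------------------------------------------------
# PIF with deterministic adaptation filter (+ optional OU fluctuation):
# the diffusion model (sig_eta2 > 0) and the white-noise model (sig_eta2 = 0)
# ---------------------------------------------------------------------------
@njit(cache=True)
def pif_filter_em(mu, delta_mu, t_on, big_delta, theta, tau_a, pulse, p0,
                  D, sig_eta2, a_init, dt, t_end, seed, max_spikes):
    np.random.seed(seed)
    spikes = np.empty(max_spikes)
    decay = np.exp(-dt / tau_a)
    sqD = np.sqrt(2.0 * D * dt)
    sig_eta = np.sqrt(sig_eta2)
    beta = sig_eta * np.sqrt(1.0 - decay * decay)
    v = 0.0
    a_bar = a_init
    eta = sig_eta * np.random.normal() if sig_eta2 > 0.0 else 0.0
    pulse_end = -1.0
    t = 0.0
    nspk = 0
    n_overlap = 0
    n_steps = int(np.ceil(t_end / dt))
    for _ in range(n_steps):
        p = 1.0 if t < pulse_end else p0
        mu_t = mu + delta_mu if t >= t_on else mu
        drift = mu_t - big_delta * (a_bar + eta)
        v_new = v + drift * dt
        if D > 0.0:
            v_new += sqD * np.random.normal()
        a_bar = p + (a_bar - p) * decay  # exact within the step
        if sig_eta2 > 0.0:
            eta = eta * decay + beta * np.random.normal()
        t += dt
        if v_new >= theta:
            frac = (theta - v) / (v_new - v)
            ts = t - dt + frac * dt
            if nspk > 0 and ts - spikes[nspk - 1] < pulse:
                n_overlap += 1
            spikes[nspk] = ts
            nspk += 1
            pulse_end = ts + pulse
            v_new -= theta
            if nspk == max_spikes:
                break
        v = v_new
    return spikes[:nspk], n_overlap


# ---------------------------------------------------------------------------
# Colored-noise-driven PIF (no adaptation feedback)
# ---------------------------------------------------------------------------
@njit(cache=True)
def pif_colored_em(mu_eff, sigma2, tau, theta, dt, t_end, seed, max_spikes):
    np.random.seed(seed)
    spikes = np.empty(max_spikes)
    decay = np.exp(-dt / tau)
    sig = np.sqrt(sigma2)
    beta = sig * np.sqrt(1.0 - decay * decay)
    v = 0.0
    eta = sig * np.random.normal()
    t = 0.0
    nspk = 0
    n_steps = int(np.ceil(t_end / dt))
    for _ in range(n_steps):
        v_new = v + (mu_eff + eta) * dt
        eta = eta * decay + beta * np.random.normal()
        t += dt
        if v_new >= theta:
            frac = (theta - v) / (v_new - v)
            spikes[nspk] = t - dt + frac * dt
            nspk += 1
            v_new -= theta
            if nspk == max_spikes:
                break
        v = v_new
    return spikes[:nspk]


# ---------------------------------------------------------------------------
# Traub-Miles conductance-based neuron with M-current adaptation
# ---------------------------------------------------------------------------
@njit(cache=True, inline="always")
def _sigexp(v, k):
    """v / (1 - exp(-v/k)) with the removable singularity at v = 0."""
    x = v / k
    if abs(x) < 1e-7:
        return k * (1.0 + x / 2.0)
    return v / (1.0 - np.exp(-x))


@njit(cache=True, inline="always")
def _posexp(v, k):
    """v / (exp(v/k) - 1) with the removable singularity at v = 0."""
    x = v / k
    if abs(x) < 1e-7:
        return k * (1.0 - x / 2.0)
    return v / (np.exp(x) - 1.0)


@njit(cache=True)
def tm_rates(V):
    am = 0.32 * _sigexp(V + 54.0, 4.0)
    bm = 0.28 * _posexp(V + 27.0, 5.0)
    ah = 0.128 * np.exp(-(V + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(V + 27.0) / 5.0))
    an = 0.032 * _sigexp(V + 52.0, 5.0)
    bn = 0.5 * np.exp(-(V + 57.0) / 40.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def tm_w_gate(V, tau_scale):
    winf = 1.0 / (1.0 + np.exp(-(V + 20.0) / 5.0))
    tw = tau_scale / (3.3 * np.exp((V + 35.0) / 20.0)
                      + np.exp(-(V + 35.0) / 20.0))
    return winf, tw


@njit(cache=True)
def tm_run(c_m, g_na, e_na, g_k, e_k, g_l, e_l, g_m, tau_scale, i_app, D,
           n_ch, stochastic_m, dt, t_end, seed,
           v_thresh, refractory, max_spikes, v_stride, v_out, w_out):
    """Traub-Miles model; deterministic w (stochastic_m=0) or Gillespie
    M-channel gating with rates frozen over each dt (stochastic_m=1).

    v_out/w_out: optional recording buffers (len 0 disables); every
    v_stride-th step is stored.  Returns (spikes, n_spk, n_recorded, status);
    status 1 flags a numerical blow-up (NaN/overflow).
    """
    np.random.seed(seed)
    spikes = np.empty(max_spikes)
    V = -65.0
    am, bm, ah, bh, an, bn = tm_rates(V)
    m = am / (am + bm)
    h = ah / (ah + bh)
    n = an / (an + bn)
    winf, tw = tm_w_gate(V, tau_scale)
    if stochastic_m == 1:
        n_open = np.random.binomial(n_ch, winf)
    else:
        n_open = 0
    w = winf
    sqD = np.sqrt(2.0 * D * dt) / c_m
    t = 0.0
    nspk = 0
    nrec = 0
    cap = len(v_out)
    t_last = -1e9
    n_steps = int(np.ceil(t_end / dt))
    for step in range(n_steps):
        if not np.isfinite(V) or V > 500.0 or V < -500.0:
            return spikes[:nspk], nspk, nrec, 1
        am, bm, ah, bh, an, bn = tm_rates(V)
        winf, tw = tm_w_gate(V, tau_scale)
        if stochastic_m == 1:
            # exact two-state gating over [t, t+dt) at frozen V
            tc = 0.0
            while True:
                lam_o = (n_ch - n_open) * winf / tw
                lam_c = n_open * (1.0 - winf) / tw
                lam = lam_o + lam_c
                if lam <= 0.0:
                    break
                tc += np.random.exponential() / lam
                if tc >= dt:
                    break
                if np.random.random() * lam < lam_o:
                    n_open += 1
                else:
                    n_open -= 1
            w_eff = n_open / n_ch
        else:
            # exponential Euler for w
            w = winf + (w - winf) * np.exp(-dt / tw)
            w_eff = w
        i_ion = (g_na * m * m * m * h * (V - e_na)
                 + g_k * n * n * n * n * (V - e_k)
                 + g_l * (V - e_l)
                 + g_m * w_eff * (V - e_k))
        V_new = V + dt * (i_app - i_ion) / c_m
        if D > 0.0:
            V_new += sqD * np.random.normal()
        # exponential Euler for fast gates
        m = am / (am + bm) + (m - am / (am + bm)) * np.exp(-dt * (am + bm))
        h = ah / (ah + bh) + (h - ah / (ah + bh)) * np.exp(-dt * (ah + bh))
        n = an / (an + bn) + (n - an / (an + bn)) * np.exp(-dt * (an + bn))
        t += dt
        if not np.isfinite(V_new):
            return spikes[:nspk], nspk, nrec, 1
        if V < v_thresh and V_new >= v_thresh and t - t_last >= refractory:
            t_last = t
            if nspk < max_spikes:
                spikes[nspk] = t
                nspk += 1
        V = V_new
        if cap > 0 and step % v_stride == 0 and nrec < cap:
            v_out[nrec] = V
            w_out[nrec] = w_eff
            nrec += 1
        if nspk == max_spikes:
            break
    return spikes[:nspk], nspk, nrec, 0
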