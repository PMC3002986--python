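import numpy as np
import pytest

from adaptif import (ChannelKinetics, NonFiringError, ParameterError,
                     PIFConfig, SpikeTrain, effective_colored_params,
                     nondimensionalize, simulate_pif_channel,
                     simulate_pif_colored, simulate_pif_diffusion,
                     simulate_pif_white, simulate_step_response,
                     stationary_intervals)
from adaptif import stats, theory
from adaptif.config import EffectiveColoredParams

from conftest import blocked_mean_se, make_kinetics, reference_config


class TestSpikeTrain:
    def test_roundtrip(self, tmp_path):
        tr = SpikeTrain(times=np.array([1.0, 2.5, 7.25]), window=(0.0, 10.0))
        path = tmp_path / "spikes.txt"
        tr.save(path)
        tr2 = SpikeTrain.load(path, window=(0.0, 10.0))
        assert np.allclose(tr.times, tr2.times)

    def test_monotonicity_enforced(self):
        with pytest.raises(ParameterError):
            SpikeTrain(times=np.array([2.0, 1.0]), window=(0.0, 10.0))

    def test_window_enforced(self):
        with pytest.raises(ParameterError):
            SpikeTrain(times=np.array([20.0]), window=(0.0, 10.0))


class TestNondimensionalize:
    def test_reference_values(self, ref_config):
        nd = nondimensionalize(ref_config)
        assert nd.mu_hat == pytest.approx(0.2 * 100.0)
        assert nd.delta_hat == pytest.approx(100.0)
        assert nd.pulse_hat == pytest.approx(0.01)
        # threshold maps to 1 by construction of the inverse
        back = nd.to_dimensional(theta=1.0, tau_a=100.0, n_channels=100)
        assert back.threshold == 1.0

    def test_roundtrip(self, ref_config):
        nd = nondimensionalize(ref_config)
        back = nd.to_dimensional(theta=ref_config.threshold, tau_a=100.0,
                                 n_channels=100)
        assert back.base_drive == pytest.approx(ref_config.base_drive)
        assert back.adaptation_strength == pytest.approx(
            ref_config.adaptation_strength)
        assert back.white_noise_intensity == pytest.approx(
            ref_config.white_noise_intensity)

    def test_time_rescaling_invariance(self):
        """The exact symmetry (mu, Delta, D, pulse, tau_a) ->
        (mu/c, Delta/c, D/c, c*pulse, c*tau_a) leaves every dimensionless
        parameter unchanged."""
        c = 3.0
        cfg = reference_config(D=0.01)
        kin = cfg.kinetics
        scaled = PIFConfig(
            base_drive=cfg.base_drive / c,
            adaptation_strength=cfg.adaptation_strength / c,
            kinetics=ChannelKinetics(
                n_channels=kin.n_channels, tau_a=kin.tau_a * c,
                pulse_duration=kin.pulse_duration * c),
            white_noise_intensity=cfg.white_noise_intensity / c)
        a, b = nondimensionalize(cfg), nondimensionalize(scaled)
        for field in ("mu_hat", "delta_hat", "pulse_hat", "d_hat",
                      "d_channel_hat"):
            assert getattr(a, field) == pytest.approx(getattr(b, field))


class TestEffectiveParams:
    def test_no_adaptation(self):
        cfg = PIFConfig(base_drive=0.5, adaptation_strength=0.0,
                        kinetics=make_kinetics())
        eff = effective_colored_params(cfg)
        assert eff.alpha == 1.0
        assert eff.mu_eff == pytest.approx(0.5)
        assert eff.tau_eff == pytest.approx(100.0)

    def test_alpha_value(self, ref_config):
        eff = effective_colored_params(ref_config)
        assert eff.alpha == pytest.approx(0.5)
        assert eff.mu_eff == pytest.approx(0.1)
        assert eff.rho == pytest.approx(10.0)
        assert eff.rho_eff == pytest.approx(5.0)

    def test_epsilon_decreases_with_n(self):
        eps = [effective_colored_params(reference_config(n_channels=n)
                                        ).epsilon
               for n in (30, 100, 300, 1000, 3000)]
        assert np.all(np.diff(eps) < 0)

    def test_alpha_matches_step_response(self):
        cfg = reference_config(n_channels=100, alpha=0.7)
        sr = simulate_step_response(cfg, step=(1300.0, 0.05), n_trials=400,
                                    seed=10, variant="channel")
        eff = effective_colored_params(cfg)
        assert abs(sr.degree_of_adaptation - eff.alpha) < 0.06

    def test_epsilon_warning(self):
        cfg = reference_config(n_channels=2, alpha=0.2)
        with pytest.warns(UserWarning, match="epsilon"):
            effective_colored_params(cfg)


class TestChannelSimulator:
    def test_infinite_n_periodic(self):
        cfg = reference_config(n_channels=None)
        tr = simulate_pif_channel(cfg, 30000.0, 1)
        isi = stationary_intervals(tr, 100.0)
        rate_th = theory.stationary_rate_adapted(cfg)
        assert np.std(isi) / np.mean(isi) < 1e-3
        assert 1.0 / np.mean(isi) == pytest.approx(rate_th, rel=1e-3)

    def test_rate_invariance_d_and_n(self):
        """Long-run firing rate is independent of noise source and size."""
        for cfg in (reference_config(n_channels=20),
                    reference_config(n_channels=500),
                    reference_config(n_channels=100, D=0.005)):
            tr = simulate_pif_channel(cfg, 150_000.0, 3)
            isi = stationary_intervals(tr, 100.0)
            se = blocked_mean_se(isi)
            assert abs(np.mean(isi) - 10.0) < max(4 * se, 0.03)

    def test_small_n_multimodal(self):
        # weak per-channel increments (Delta/N << mu) so that single open
        # counts map to distinct, finite ISIs
        cfg = reference_config(n_channels=10, alpha=0.8)
        tr = simulate_pif_channel(cfg, 200_000.0, 4)
        isi = stationary_intervals(tr, 100.0)
        counts, edges = np.histogram(isi, bins=200)
        floor = 0.02 * counts.max()
        peaks = 0
        for i in range(1, len(counts) - 1):
            if (counts[i] > counts[i - 1] and counts[i] >= counts[i + 1]
                    and counts[i] > floor):
                peaks += 1
        assert peaks >= 3

    def test_channel_trajectory_output(self):
        cfg = reference_config(n_channels=50)
        tr, traj = simulate_pif_channel(cfg, 2000.0, 5, return_channels=True)
        assert traj.n_channels == 50
        assert np.all(traj.n_open >= 0) and np.all(traj.n_open <= 50)

    def test_t_end_error(self, ref_config):
        with pytest.raises(ParameterError):
            simulate_pif_channel(ref_config, -5.0, 1)


class TestFilterSimulators:
    def test_white_mean_isi_matches_rate(self):
        cfg = reference_config(D=0.002)
        tr = simulate_pif_white(cfg, 100_000.0, 6)
        isi = stationary_intervals(tr, 100.0)
        se = np.std(isi) / np.sqrt(len(isi))
        assert abs(np.mean(isi) - 10.0) < max(3 * se, 0.03)

    def test_white_no_adaptation_ig_shape(self):
        kin = ChannelKinetics(n_channels=None, tau_a=1.0, pulse_duration=0.0)
        cfg = PIFConfig(base_drive=1.0, adaptation_strength=0.0,
                        kinetics=kin, white_noise_intensity=0.02, dt=5e-4)
        tr = simulate_pif_white(cfg, 30_000.0, 7)
        isi = stationary_intervals(tr, 1.0)
        st = stats.compute_isi_stats(isi, k_max=2, n_boot=150, seed=2)
        assert abs(st.rescaled_skewness - 1.0) < 3 * st.rescaled_skewness_se
        assert abs(st.rescaled_kurtosis - 1.0) < 3 * st.rescaled_kurtosis_se

    def test_white_negative_scc_at_rho_one(self):
        cfg = reference_config(tau_a=10.0, D=0.002)  # rho = 1
        tr = simulate_pif_white(cfg, 150_000.0, 8)
        isi = stationary_intervals(tr, 10.0)
        scc, se = stats.serial_correlation(isi, 1)
        assert scc[0] < -3 * se[0]

    def test_diffusion_positive_scc(self):
        cfg = reference_config(n_channels=100, alpha=0.8)
        tr = simulate_pif_diffusion(cfg, 200_000.0, 9)
        isi = stationary_intervals(tr, 100.0)
        scc, se = stats.serial_correlation(isi, 1)
        assert scc[0] > 3 * se[0]

    def test_diffusion_infinite_n_is_deterministic(self):
        cfg = reference_config(n_channels=None)
        tr = simulate_pif_diffusion(cfg, 20000.0, 10)
        isi = stationary_intervals(tr, 100.0)
        assert np.std(isi) / np.mean(isi) < 1e-3


class TestColoredSimulator:
    def test_zero_noise_periodic(self):
        eff = EffectiveColoredParams(alpha=0.5, mu_eff=0.1, sigma2_eff=0.0,
                                     tau_eff=50.0, epsilon=0.0, rho=10.0)
        tr = simulate_pif_colored(eff, 5000.0, 1)
        isi = np.diff(tr.times)
        assert np.allclose(isi, 10.0, rtol=1e-6)

    def test_scc_positive_geometric(self):
        eps, rho = 0.03, 5.0
        eff = EffectiveColoredParams(alpha=1.0, mu_eff=rho,
                                     sigma2_eff=eps * rho**2, tau_eff=1.0,
                                     epsilon=eps, rho=rho)
        tr = simulate_pif_colored(eff, 30000.0 / rho, 2)
        isi = np.diff(tr.times[tr.times > 20.0])
        scc, se = stats.serial_correlation(isi, 4)
        assert np.all(scc > 0)
        ratio = scc[1:] / scc[:-1]
        assert np.all(np.abs(ratio - np.exp(-1.0 / rho)) < 0.15)


class TestStepResponse:
    def test_zero_step_flat(self):
        cfg = reference_config(n_channels=100)
        sr = simulate_step_response(cfg, step=(1200.0, 0.0), n_trials=150,
                                    seed=3, variant="channel", t_end=2000.0)
        r0 = theory.stationary_rate_adapted(cfg)
        mask = sr.bin_centers > 1000.0
        assert np.all(np.abs(sr.rate[mask] - r0)
                      < 4 * np.maximum(sr.rate_se[mask], 0.01 * r0))

    def test_decay_constant(self):
        cfg = reference_config(n_channels=100, alpha=0.9)
        sr = simulate_step_response(cfg, step=(1300.0, 0.1), n_trials=500,
                                    seed=4, variant="channel")
        tau_eff = theory.effective_alpha(cfg) * 100.0
        assert abs(sr.decay_time - tau_eff) / tau_eff < 0.15

    def test_step_before_window_error(self, ref_config):
        with pytest.raises(ParameterError):
            simulate_step_response(ref_config, step=(-5.0, 0.1),
                                   n_trials=100, seed=1)

    def test_too_few_trials_error(self, ref_config):
        with pytest.raises(ParameterError):
            simulate_step_response(ref_config, step=(100.0, 0.1),
                                   n_trials=10, seed=1)


class TestProperties:
    def test_rate_invariance_all_variants(self, ref_config):
        """Every simulator variant reproduces the stationary rate."""
        eff = effective_colored_params(ref_config)
        trains = {
            "channel": simulate_pif_channel(ref_config, 100_000.0, 11),
            "diffusion": simulate_pif_diffusion(ref_config, 100_000.0, 12),
            "white": simulate_pif_white(
                ref_config.replace(white_noise_intensity=0.002), 100_000.0,
                13),
            "colored": simulate_pif_colored(eff, 100_000.0, 14),
        }
        for name, tr in trains.items():
            isi = (stationary_intervals(tr, 100.0) if name != "colored"
                   else np.diff(tr.times[tr.times > 1000.0]))
            mean = np.mean(isi)
            se = blocked_mean_se(isi)  # robust to serial correlation
            assert abs(mean - 10.0) < max(4 * se, 0.03), name

    def test_step_size_robustness(self):
        cfg = reference_config(n_channels=100, D=0.002)
        res = []
        for dt in (0.01, 0.005):
            tr = simulate_pif_channel(cfg.replace(dt=dt), 80_000.0, 15)
            isi = stationary_intervals(tr, 100.0)
            st = stats.compute_isi_stats(isi, k_max=1, n_boot=100, seed=5)
            res.append(st)
        assert abs(res[0].cv - res[1].cv) < 3 * np.hypot(res[0].cv_se,
                                                         res[1].cv_se)
        assert abs(res[0].scc[0] - res[1].scc[0]) < 3 * np.hypot(
            res[0].scc_se[0], res[1].scc_se[0])

    def test_sign_dichotomy(self):
        """White-noise variant: negative lag-1 SCC; stochastic adaptation:
        positive lag-1 SCC at the same reference parameters."""
        cfg_w = reference_config(n_channels=None, D=0.002, tau_a=10.0)
        cfg_c = reference_config(n_channels=100)
        tr_w = simulate_pif_white(cfg_w, 120_000.0, 16)
        tr_c = simulate_pif_channel(cfg_c, 120_000.0, 17)
        s_w, se_w = stats.serial_correlation(
            stationary_intervals(tr_w, 10.0), 1)
        s_c, se_c = stats.serial_correlation(
            stationary_intervals(tr_c, 100.0), 1)
        assert s_w[0] < -3 * se_w[0]
        assert s_c[0] > 3 * se_c[0]

    def test_nonfiring_guard(self):
        with pytest.raises(NonFiringError):
            PIFConfig(base_drive=0.01, adaptation_strength=1.0,
                      kinetics=make_kinetics(p0=0.5))
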