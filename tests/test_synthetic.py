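"""Synthetic speckle generators: ground-truth fidelity and invariants."""

import numpy as np
import pytest

import speckledyn as sd
from speckledyn.exceptions import ConfigError
from speckledyn.synthetic import embedding_eigenvalues


class TestSimConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"levy_index": 2.5}, {"levy_index": 0.0}, {"n_modes": 0},
        {"mean_counts": 0.0}, {"frame_interval": 0.0},
        {"q_targets": (0.1, -0.05)}, {"event_rate": -1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            sd.SimConfig(**kwargs)

    def test_velocity_calibration(self):
        # stable scale c gives field correlation exp[-(c q t)^mu], so
        # tau = 1/(c q) by construction
        cfg = sd.SimConfig(velocity_scale=sd.SimConfig.velocity_for_tau(50, 0.1))
        assert np.isclose(cfg.tau_at(0.1), 50.0)
        assert np.isclose(cfg.tau_at(0.05), 100.0)   # ballistic: 1/tau ~ q


class TestHeterogeneitySchedule:
    def test_invariants(self):
        with pytest.raises(ConfigError):
            sd.HeterogeneitySchedule(fast_tau=300, slow_tau=200)
        het = sd.HeterogeneitySchedule()
        temps = np.linspace(180, 290, 200)
        amps = np.array([het.amplitude(t) for t in temps])
        assert np.all((amps >= 0) & (amps <= 1))
        # unique maximum at t_star
        assert temps[np.argmax(amps)] == pytest.approx(het.t_star, abs=0.5)
        assert np.sum(amps == amps.max()) == 1

    def test_occupancy(self):
        het = sd.HeterogeneitySchedule(rate_to_fast=1 / 800,
                                       rate_to_slow=1 / 300)
        rng = np.random.default_rng(0)
        seq = sd.telegraph_sequence(rng, 200000, 1.0, het.rate_to_fast,
                                    het.rate_to_slow)
        assert abs(seq.mean() - het.p_fast) < 0.05


class TestTemperatureProtocol:
    def test_arrhenius_monotone_on_cooling(self):
        p = sd.TemperatureProtocol()
        taus = [p.tau_observed(t) for t in p.temperatures]
        assert all(np.diff(taus) > 0)          # grows as T drops 290 -> 180
        assert p.tau_observed(290) < p.tau_observed(180)

    def test_zero_coupling_gives_equilibrium_tau(self):
        p = sd.TemperatureProtocol(coupling_a=0.0)
        for t in (290.0, 230.0, 180.0):
            assert p.tau_observed(t) == pytest.approx(p.tau0(t), rel=1e-12)

    def test_non_monotone_temperatures_rejected(self):
        with pytest.raises(ConfigError):
            sd.TemperatureProtocol(temperatures=(290, 250, 260))


class TestBallisticGenerator:
    def test_static_speckle_flat_g2(self):
        cfg = sd.SimConfig(seed=4, velocity_scale=0.0, n_frames=40,
                           n_pixels=600, n_modes=2)
        series = sd.simulate_ballistic_series(cfg, 0.1, poisson=False)
        lag_s, g2, se, _ = sd.g2_from_series(series, [1, 5, 20])
        # frozen field: g2 identical at every lag, at the 1 + beta plateau
        assert np.allclose(g2, g2[0], rtol=1e-12)
        assert abs(g2[0] - 1.5) < 0.1

    def test_poisson_sampling_preserves_g2(self):
        # photon sampling at decent count rate changes g2 by less than the
        # statistical error of the curve (same underlying field)
        cfg = sd.SimConfig(seed=11, n_frames=4000, n_pixels=100,
                           mean_counts=50.0,
                           velocity_scale=sd.SimConfig.velocity_for_tau(40, 0.1))
        noiseless = sd.simulate_ballistic_series(cfg, 0.1, poisson=False)
        sampled = sd.simulate_ballistic_series(cfg, 0.1, poisson=True)
        lags = sd.LagScheme().lags(4000)
        _, g2a, se, _ = sd.g2_from_series(noiseless, lags)
        _, g2b, _, _ = sd.g2_from_series(sampled, lags)
        assert np.nanmax(np.abs(g2a - g2b) / se) < 1.0

    def test_gaussian_limit_mu_2(self):
        # mu = 2: stable law is Gaussian, characteristic function
        # exp[-(c q t)^2], so the fitted KWW exponent approaches 2
        cfg = sd.SimConfig(seed=9, levy_index=2.0, n_frames=8000,
                           n_pixels=150,
                           velocity_scale=sd.SimConfig.velocity_for_tau(60, 0.1))
        series = sd.simulate_ballistic_series(cfg, 0.1)
        lags = sd.LagScheme().lags(8000)
        lag_s, g2, se, groups = sd.g2_from_series(series, lags)
        curve = sd.G2Curve(q=0.1, lags=lag_s, g2=g2, se=se, n_pixels=150,
                           n_frames=8000, meta={"frame_interval": 1.0},
                           group_g2=groups)
        fit = sd.fit_kww(curve)
        assert abs(fit.alpha - 2.0) < 0.1
        assert abs(fit.tau - 60.0) / 60.0 < 0.1

    def test_frequent_events_give_exponential_decay(self):
        # with Poisson velocity redraws at rate lambda >> 1/tau the phase
        # accumulates over many independent sojourns, so the field
        # correlation becomes exponential in the lag (alpha -> 1) with
        # rate (c q)^mu * lambda^(1-mu) * Gamma(1+mu)  [sojourn Delta-t are
        # Exp(lambda); E[Delta^mu] = Gamma(1+mu)/lambda^mu]
        from scipy.special import gamma as gamma_fn
        mu, lam = 1.5, 1.0
        cq = (1.0 / 80.0) ** (1.0 / mu)
        tau_expected = 80.0 / gamma_fn(1.0 + mu)     # = 60.2 frames
        cfg = sd.SimConfig(seed=6, n_frames=6000, n_pixels=120,
                           event_rate=lam, velocity_scale=cq / 0.1)
        series = sd.simulate_ballistic_series(cfg, 0.1)
        lags = sd.LagScheme().lags(6000)
        lag_s, g2, se, groups = sd.g2_from_series(series, lags)
        curve = sd.G2Curve(q=0.1, lags=lag_s, g2=g2, se=se, n_pixels=120,
                           n_frames=6000, meta={"frame_interval": 1.0},
                           group_g2=groups)
        fit = sd.fit_kww(curve)
        assert abs(fit.alpha - 1.0) < 0.15
        assert abs(fit.tau - tau_expected) / tau_expected < 0.15


class TestKWWOracle:
    @pytest.mark.parametrize("alpha", [0.8, 1.0, 1.5, 2.0])
    def test_embedding_positive_definite(self, alpha):
        lam = embedding_eigenvalues(50.0, alpha, 2000)
        assert lam.min() >= -1e-10 * lam.max()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            sd.generate_kww_oracle_series(50, 2.5, 1.0, 100)
        with pytest.raises(ConfigError):
            sd.generate_kww_oracle_series(-1, 1.0, 1.0, 100)
        with pytest.raises(ConfigError):
            sd.generate_kww_oracle_series(50, 1.0, 0.37, 100)  # not 1/M

    def test_g2_matches_analytic_target(self):
        # brute-force check of the e^-2 point on a long realization
        tau, n = 50.0, 100000
        series = sd.generate_kww_oracle_series(tau, 1.0, 1.0, n, seed=2,
                                               n_pixels=20)
        lags = np.array([1, 25, 50, 100])
        lag_s, g2, se, _ = sd.g2_from_series(series, lags)
        model = sd.kww_g2_expected(lag_s, tau, 1.0, 1.0)
        assert np.all(np.abs(g2 - model) < 3.5 * se)
        assert abs(g2[2] - 1 - np.exp(-2)) < 3.5 * se[2]

    def test_frozen_limit_flat_at_one_plus_beta(self):
        series = sd.generate_kww_oracle_series(np.inf, 1.5, 0.5, 200,
                                               seed=3, n_pixels=800)
        lags = np.array([1, 10, 50])
        _, g2, _, _ = sd.g2_from_series(series, lags)
        assert np.allclose(g2, g2[0], rtol=1e-10)
        assert abs(g2[0] - 1.5) < 0.1


class TestGeneratorEquivalence:
    def test_ballistic_matches_gaussian_oracle(self):
        # the two independent generative routes, configured to the same
        # (tau, alpha, beta), must produce statistically identical g2
        tau, mu, beta = 50.0, 1.5, 0.5
        n_frames, n_pix = 8000, 120
        cfg = sd.SimConfig(seed=31, n_frames=n_frames, n_pixels=n_pix,
                           levy_index=mu,
                           velocity_scale=sd.SimConfig.velocity_for_tau(tau, 0.1))
        ball = sd.simulate_ballistic_series(cfg, 0.1, poisson=False)
        orac = sd.generate_kww_oracle_series(tau, mu, beta, n_frames,
                                             seed=32, n_pixels=n_pix)
        lags = sd.LagScheme().lags(n_frames)
        _, g2_b, se_b, _ = sd.g2_from_series(ball, lags)
        _, g2_o, se_o, _ = sd.g2_from_series(orac, lags)
        pooled = np.sqrt(se_b ** 2 + se_o ** 2)
        assert np.all(np.abs(g2_b - g2_o) < 3.0 * pooled)

    @pytest.mark.parametrize("mu", [0.8, 1.0])
    def test_levy_index_recovered_as_kww_exponent(self, mu):
        # stretched-side indices: full-pipeline alpha within +-0.1 of mu
        tau = 300.0
        cfg = sd.SimConfig(seed=13, n_frames=20000, n_pixels=200,
                           levy_index=mu,
                           velocity_scale=sd.SimConfig.velocity_for_tau(tau, 0.08))
        series = sd.simulate_ballistic_series(cfg, 0.08)
        lags = sd.LagScheme().lags(20000)
        lag_s, g2, se, groups = sd.g2_from_series(series, lags)
        curve = sd.G2Curve(q=0.08, lags=lag_s, g2=g2, se=se, n_pixels=200,
                           n_frames=20000, meta={"frame_interval": 1.0},
                           group_g2=groups)
        fit = sd.fit_kww(curve)
        assert abs(fit.alpha - mu) < 0.1


class TestRenderFrameStack:
    def test_determinism_bit_identical(self):
        cfg = sd.SimConfig(seed=77, n_frames=200, n_pixels=60,
                           q_targets=(0.08, 0.1))
        s1 = sd.render_frame_stack(cfg)
        s2 = sd.render_frame_stack(cfg)
        assert np.array_equal(s1.images, s2.images)
        assert s1.meta["truth"] == s2.meta["truth"]

    def test_q_target_out_of_range(self):
        cfg = sd.SimConfig(q_targets=(5.0,), n_frames=10)
        with pytest.raises(ConfigError, match="valid q interval"):
            sd.render_frame_stack(cfg)

    def test_ring_pixels_carry_signal(self, ring_stack, ring_qmap):
        sel = ring_qmap.pixels_in_bin(0, ring_stack.mask)
        assert sel.sum() >= 50
        series = ring_stack.pixel_series(sel)
        assert series.mean() > 0
        # outside the rings the detector is dark
        assert ring_stack.images[:, ~ring_stack.mask].sum() == 0

    def test_truth_metadata_embedded(self, ring_stack):
        truth = ring_stack.meta["truth"]
        assert truth["levy_index"] == 1.5
        assert truth["beta"] == 0.5
        assert np.isclose(truth["tau_per_q_s"]["0.1"], 50.0)


class TestTemperatureScanGeneration:
    def test_scan_ground_truths(self):
        protocol = sd.TemperatureProtocol(
            temperatures=(290.0, 250.0, 230.0, 210.0, 180.0))
        base = sd.SimConfig(seed=5, n_frames=60, n_pixels=60,
                            q_targets=(0.1,))
        stacks = sd.generate_temperature_scan(protocol, None, base)
        assert len(stacks) == 5
        for stack, temp in zip(stacks, protocol.temperatures):
            truth = stack.meta["truth"]
            assert truth["temperature_k"] == temp
            assert np.isclose(truth["tau0_s"], protocol.tau0(temp))
            assert np.isclose(truth["tau_observed_s"],
                              protocol.tau_observed(temp))
        taus = [s.meta["truth"]["tau_observed_s"] for s in stacks]
        assert all(np.diff(taus) > 0)       # slower on cooling

    def test_heterogeneity_amplitude_recorded(self):
        protocol = sd.TemperatureProtocol(
            temperatures=(290.0, 250.0, 227.0, 210.0, 180.0))
        het = sd.HeterogeneitySchedule()
        base = sd.SimConfig(seed=5, n_frames=60, n_pixels=60,
                            q_targets=(0.1,))
        stacks = sd.generate_temperature_scan(protocol, het, base)
        amps = {s.temperature_k: s.meta["truth"]["het_amplitude"]
                for s in stacks}
        assert amps[227.0] == pytest.approx(1.0)
        assert amps[290.0] < 0.01
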