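"""Generative-model checks: Hill kinetics, calcium ODE, pool dynamics,
current rendering, sucrose and imaging forward models."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from presyn import (
    NumericalError,
    SimParams,
    StimulusProtocol,
    ValidationError,
    egta_capture_length,
    hill_activation,
    pure_depletion_params,
    render_current,
    render_imaging,
    resting_calcium,
    simulate_calcium,
    simulate_experiment,
    simulate_pool,
    simulate_sucrose,
    standard_train_protocol,
    tko_params,
    trpc5_params,
)
from presyn.simulate import GCaMPParams, _quantal_kernel


class TestHillActivation:
    def test_half_activation_at_ec50(self):
        for n in (1.0, 2.0, 3.7):
            assert hill_activation(635.0, 635.0, n) == pytest.approx(0.5)

    def test_zero_at_zero(self):
        assert hill_activation(0.0, 635.0, 2.0) == 0.0

    @pytest.mark.parametrize("n", [1.0, 2.0, 4.0])
    def test_ninety_percent_point(self, n):
        # Hill equation solved for f = 0.9: c = ec50 * 9^(1/n)
        c = 635.0 * 9.0 ** (1.0 / n)
        assert hill_activation(c, 635.0, n) == pytest.approx(0.9, rel=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        c1=st.floats(min_value=0.0, max_value=1e5),
        c2=st.floats(min_value=0.0, max_value=1e5),
        n=st.floats(min_value=1.0, max_value=6.0),
    )
    def test_monotone_and_bounded(self, c1, c2, n):
        f1, f2 = hill_activation(c1, 635.0, n), hill_activation(c2, 635.0, n)
        assert 0.0 <= f1 <= 1.0
        if c1 < c2:
            assert f1 <= f2

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            hill_activation(-1.0, 635.0, 2.0)


class TestEgtaCaptureLength:
    def test_default_exceeds_350_nm(self):
        # sqrt(6 * 2.2e-6 cm^2/s * 100 us) = 3.633e-5 cm = 363.3 nm
        r = egta_capture_length(2.2e-6, 100e-6)
        assert r == pytest.approx(363.318, abs=0.01)
        assert r > 350.0

    def test_vanishes_with_tau(self):
        assert egta_capture_length(2.2e-6, 1e-12) < 0.1

    def test_square_root_scaling(self):
        assert egta_capture_length(2.2e-6, 4e-4) == pytest.approx(
            2.0 * egta_capture_length(2.2e-6, 1e-4)
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            egta_capture_length(0.0, 1e-4)
        with pytest.raises(ValidationError):
            egta_capture_length(2.2e-6, -1.0)


class TestCalcium:
    def test_single_ap_monoexponential_decay_without_trpc(self):
        params = SimParams(j_trpc=0.0, deterministic=True)
        proto = StimulusProtocol(ap_times=[0.05], train_count=1)
        ca = simulate_calcium(params, proto, duration=0.8)
        t0 = int(0.06 / ca.dt)
        supra = ca.concentration[t0:] - params.c_rest
        # log-linear decay with slope -1/tau_clear
        sel = supra > 1e-3
        slope = np.polyfit(ca.times[t0:][sel], np.log(supra[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(params.tau_clear, rel=1e-3)

    def test_trpc_entry_raises_peak_and_slows_decay(self, protocol):
        ca0 = simulate_calcium(SimParams(j_trpc=0.0, deterministic=True), protocol)
        ca1 = simulate_calcium(SimParams(j_trpc=7000.0, deterministic=True), protocol)
        assert ca1.concentration.max() > ca0.concentration.max()
        i_post = int(2.4 / ca0.dt)  # 0.35 s after the last AP
        c_rest = 50.0
        rel0 = (ca0.concentration[i_post] - c_rest) / (ca0.concentration.max() - c_rest)
        rel1 = (ca1.concentration[i_post] - c_rest) / (ca1.concentration.max() - c_rest)
        assert rel1 > rel0

    def test_egta_buffering_scales_supra_resting_calcium(self, protocol):
        p = trpc5_params(deterministic=True)
        ca = simulate_calcium(p, protocol)
        ca_egta = simulate_calcium(replace(p, egta_mode=True), protocol)
        supra = ca.concentration.max() - p.c_rest
        supra_egta = ca_egta.concentration.max() - p.c_rest
        # buffering removes at least kappa/(1+kappa) of the free increment
        assert supra_egta <= supra / (1.0 + p.egta_kappa) * 1.01

    def test_rest_stability_over_60_s(self):
        # a single terminal AP forces the integrator through the full grid
        p = trpc5_params(deterministic=True)
        proto = StimulusProtocol(ap_times=[59.9], train_count=1)
        ca = simulate_calcium(p, proto, duration=60.0)
        seg = ca.concentration[: int(59.8 / ca.dt)]
        assert np.abs(seg - seg[0]).max() / seg[0] < 0.01

    def test_oversized_step_rejected(self, protocol):
        with pytest.raises(ValidationError):
            SimParams(dt=1e-3)

    def test_divergence_reported_as_numerical_error(self, protocol):
        p = SimParams(j_trpc=1e10, deterministic=True)
        with pytest.raises(NumericalError):
            simulate_calcium(p, protocol)


class TestPool:
    def test_geometric_depletion_closed_form(self, protocol):
        params = pure_depletion_params(deterministic=True)
        ca = simulate_calcium(params, protocol)
        truth = simulate_pool(params, ca, protocol)
        k = np.arange(40)
        expected = params.n_max * params.p_r * (1 - params.p_r) ** k
        assert np.allclose(truth.sync_quanta, expected, rtol=1e-12)

    def test_full_release_on_first_ap_when_pr_is_one(self, protocol):
        params = pure_depletion_params(p_r=1.0, deterministic=True)
        ca = simulate_calcium(params, protocol)
        truth = simulate_pool(params, ca, protocol)
        assert truth.sync_quanta[0] == pytest.approx(params.n_max)
        assert np.all(truth.sync_quanta[1:] == 0)

    def test_binomial_first_release_expectation(self, protocol):
        params = pure_depletion_params()
        ca = simulate_calcium(replace(params, deterministic=True), protocol)
        first = [
            simulate_pool(replace(params, seed=s), ca, protocol).sync_quanta[0]
            for s in range(1, 201)
        ]
        first = np.asarray(first)
        sem = first.std(ddof=1) / math.sqrt(first.size)
        assert abs(first.mean() - 30.0) < 3 * sem + 1e-9

    def test_vesicle_conservation_deterministic(self, protocol):
        params = trpc5_params(deterministic=True)
        ca = simulate_calcium(params, protocol)
        truth = simulate_pool(params, ca, protocol)
        released = truth.sync_quanta.sum() + np.sum(truth.async_rate) * ca.dt
        supplied = params.n_max + np.sum(truth.repl_flux) * ca.dt
        assert released <= supplied + 1.0

    def test_seed_required_in_stochastic_mode(self, protocol):
        from presyn import ConfigurationError

        params = pure_depletion_params()  # no seed
        ca = simulate_calcium(replace(params, deterministic=True), protocol)
        with pytest.raises(ConfigurationError):
            simulate_pool(params, ca, protocol)

    def test_stochastic_mean_matches_deterministic(self, protocol):
        det = SimParams(deterministic=True)
        ca = simulate_calcium(det, protocol)
        truth_det = simulate_pool(det, ca, protocol)
        quanta = np.array([
            simulate_pool(SimParams(seed=s), ca, protocol).sync_quanta
            for s in range(1, 201)
        ])
        mean = quanta.mean(axis=0)
        sem = quanta.std(axis=0, ddof=1) / math.sqrt(quanta.shape[0])
        dev = np.abs(mean - truth_det.sync_quanta) / np.maximum(sem, 1e-12)
        assert dev[0] < 3.0          # first-AP expectation
        assert np.mean(dev < 3.0) >= 0.95  # family-wise, 40 comparisons


class TestRenderCurrent:
    def test_single_quantum_peak_equals_amplitude(self):
        params = SimParams(deterministic=True)
        proto = StimulusProtocol(ap_times=[0.05], train_count=1)
        ca = simulate_calcium(pure_depletion_params(p_r=1.0, n_max=1,
                                                    deterministic=True), proto,
                              duration=0.3)
        truth = simulate_pool(pure_depletion_params(p_r=1.0, n_max=1,
                                                    deterministic=True), ca, proto)
        trace = render_current(truth, pure_depletion_params(
            p_r=1.0, n_max=1, deterministic=True), 0.3)
        peak = -trace.samples.min()
        assert peak == pytest.approx(25.0, rel=1e-3)

    def test_quantal_charge_closed_form_matches_integral(self):
        params = SimParams(deterministic=True)
        kernel = _quantal_kernel(params, params.dt)
        numeric = np.trapezoid(params.q_mean * kernel, dx=params.dt)
        closed = params.quantal_charge_mean
        assert numeric == pytest.approx(closed, rel=1e-3)

    def test_noise_sd_reproduced(self):
        params = SimParams(noise_sd=2.0, mini_rate0=0.0, seed=3)
        proto = StimulusProtocol(ap_times=[], train_count=0)
        trace, _, _ = simulate_experiment(params, proto, duration=10.0)
        assert np.std(trace.samples) == pytest.approx(2.0, rel=0.05)

    def test_rise_slower_than_decay_rejected(self):
        with pytest.raises(ValidationError):
            SimParams(tau_rise=0.005, tau_decay=0.004)

    def test_bit_identical_for_equal_seeds(self, protocol):
        t1, _, _ = simulate_experiment(SimParams(seed=7), protocol)
        t2, _, _ = simulate_experiment(SimParams(seed=7), protocol)
        assert np.array_equal(t1.samples, t2.samples)


class TestSucrose:
    def test_no_replenishment_gives_pure_rrp_transient(self):
        from presyn import analyze_sucrose

        params = SimParams(k0=0.0, deterministic=True)
        res = analyze_sucrose(simulate_sucrose(params))
        assert res.transient_charge == pytest.approx(params.true_rrp_charge, rel=0.02)
        assert res.steady_state_current < 0.05 * params.true_rrp_charge

    def test_transient_scales_with_pool_size(self):
        from presyn import analyze_sucrose

        r1 = analyze_sucrose(simulate_sucrose(SimParams(k0=0.0, n_max=100,
                                                        deterministic=True)))
        r2 = analyze_sucrose(simulate_sucrose(SimParams(k0=0.0, n_max=200,
                                                        deterministic=True)))
        assert r2.transient_charge == pytest.approx(2 * r1.transient_charge, rel=0.02)

    def test_replenishment_sustains_plateau(self):
        from presyn import analyze_sucrose

        res = analyze_sucrose(simulate_sucrose(SimParams(k0=0.5, deterministic=True)))
        assert res.steady_state_current > 1.0  # pA


class TestRenderImaging:
    def _constant_ca(self, c=50.0, duration=5.0, dt=1e-4):
        from presyn import CaTrace

        n = int(duration / dt)
        return CaTrace(times=np.arange(n) * dt,
                       concentration=np.full(n, c), dt=dt)

    def test_resting_calcium_gives_flat_dff(self, config):
        from presyn import compute_dff
        from presyn.imaging import background_noise_sd

        stack, rois = render_imaging(self._constant_ca(),
                                     gcamp=GCaMPParams(photon_noise=False),
                                     seed=1)
        rt = compute_dff(stack, rois[0], config, background_sd=1e-6)
        assert np.allclose(rt.dff, 0.0, atol=1e-9)

    def test_monotone_calcium_gives_monotone_dff(self, config):
        from presyn import CaTrace, compute_dff

        dt = 1e-4
        n = int(5.0 / dt)
        conc = np.concatenate([
            np.full(int(0.6 / dt), 50.0),
            np.linspace(50.0, 800.0, n - int(0.6 / dt)),
        ])
        ca = CaTrace(times=np.arange(n) * dt, concentration=conc, dt=dt)
        stack, rois = render_imaging(ca, gcamp=GCaMPParams(photon_noise=False),
                                     seed=1)
        rt = compute_dff(stack, rois[0], config, background_sd=1e-6)
        assert np.all(np.diff(rt.dff[2:]) >= -1e-12)

    def test_train_raises_dff_across_train_frames(self, config):
        from presyn import compute_dff

        proto = standard_train_protocol(t0=0.7)
        ca = simulate_calcium(SimParams(deterministic=True), proto, duration=4.6)
        stack, rois = render_imaging(ca, gcamp=GCaMPParams(photon_noise=False),
                                     seed=1)
        rt = compute_dff(stack, rois[0], config, background_sd=1e-6)
        # 20-Hz, 2-s train imaged at 5 Hz: rise spread over ~10 frames
        during = rt.dff[3:13]
        assert np.all(np.diff(during) > 0)
        assert rt.dff[12] > 10 * max(rt.dff[2], 1e-12)

    def test_too_many_synapses_rejected(self):
        with pytest.raises(ValidationError):
            render_imaging(self._constant_ca(), n_synapses=1000, seed=1)
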