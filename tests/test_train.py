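"""Train-analysis checks: charge decomposition, RRP back-extrapolation,
release probability, replenishment slope, plasticity indices, recovery fits
and sucrose measurements."""

import math
from dataclasses import replace

import numpy as np
import pytest

from presyn import (
    AnalysisConfig,
    ConfigurationError,
    CurrentTrace,
    SimParams,
    ValidationError,
    analyze_recovery,
    analyze_sucrose,
    analyze_train,
    estimate_rrp_train,
    fit_recovery,
    measure_train,
    plasticity_indices,
    release_probability,
    replenishment_rate,
    simulate_experiment,
    standard_train_protocol,
)
from presyn.simulate import pure_depletion_params
from presyn.train import TrainMetrics


def brute_force_ols(x, y):
    """Independent textbook OLS oracle: normal equations via explicit sums."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def metrics_from_charges(sync, total=None, amps=None, freq=20.0):
    sync = np.asarray(sync, dtype=float)
    total = sync.copy() if total is None else np.asarray(total, dtype=float)
    amps = sync / 1000.0 if amps is None else np.asarray(amps, dtype=float)
    return TrainMetrics(
        amplitudes=amps,
        total_charge=total,
        async_charge=total - sync,
        sync_charge=sync,
        cumulative_sync=np.cumsum(sync),
        cumulative_total=np.cumsum(total),
        train_frequency=freq,
    )


class TestMeasureTrain:
    def _trace_with_quanta(self, protocol, amp_pA=500.0, tau=0.003, fs=10000.0):
        """Identical noiseless quanta decaying fully within each interval."""
        n = int((protocol.train_end + 0.1) * fs)
        t = np.arange(n) / fs
        y = np.zeros(n)
        for t_ap in protocol.ap_times:
            m = t >= t_ap + 0.001
            y[m] += amp_pA * np.exp(-(t[m] - (t_ap + 0.001)) / tau)
            y[t < t_ap + 0.001] += 0.0
        # quanta placed independently per AP so they fully decay: rebuild
        y = np.zeros(n)
        for t_ap in protocol.ap_times:
            i0 = int((t_ap + 0.001) * fs)
            tt = np.arange(n - i0) / fs
            y[i0:] += amp_pA * np.exp(-tt / tau)
        return CurrentTrace(-y, sampling_rate=fs)

    def test_fully_decaying_quanta_have_no_async_component(self, protocol, config):
        trace = self._trace_with_quanta(protocol)
        m = measure_train(trace, protocol, config)
        assert np.all(np.abs(m.async_charge) < 0.02 * np.abs(m.total_charge).max())
        assert np.allclose(m.sync_charge, m.total_charge, atol=0.02 * m.total_charge.max())

    def test_constant_offset_is_pure_async_charge(self, protocol, config):
        fs = 10000.0
        n = int((protocol.train_end + 0.1) * fs)
        t = np.arange(n) / fs
        i0_pA = 200.0
        y = np.where(t >= protocol.ap_times[0], i0_pA, 0.0)
        m = measure_train(CurrentTrace(-y, sampling_rate=fs), protocol, config)
        isi = protocol.interstimulus_interval
        assert np.allclose(m.async_charge, i0_pA * isi, rtol=1e-6)
        # zero up to one sample of charge (index-rounding at interval edges)
        assert np.all(np.abs(m.sync_charge) <= 1.5 * i0_pA / fs)

    def test_charge_conservation_identity(self, protocol, config):
        trace, _, _ = simulate_experiment(SimParams(seed=11), protocol)
        m = measure_train(trace, protocol, config)
        assert np.allclose(m.sync_charge + m.async_charge, m.total_charge,
                           atol=1e-9)

    def test_sync_charge_tracks_released_quanta(self, protocol, config):
        trace, _, truth = simulate_experiment(SimParams(deterministic=True), protocol)
        m = measure_train(trace, protocol, config)
        expected = truth.sync_quanta[:40] * truth.quantal_charge_mean
        assert np.allclose(m.sync_charge, expected, rtol=0.05)

    def test_short_trace_rejected(self, protocol, config):
        trace = CurrentTrace(np.zeros(1000), sampling_rate=10000.0)
        with pytest.raises(ValidationError):
            measure_train(trace, protocol, config)


class TestRrpBackExtrapolation:
    def test_constant_charge_extrapolates_to_zero_pool(self, config):
        m = metrics_from_charges(np.full(40, 2.0))
        rrp, steady = estimate_rrp_train(m, config)
        assert rrp == pytest.approx(0.0, abs=1e-9)
        assert steady

    def test_geometric_depletion_recovers_initial_pool(self, config):
        # cumulative Q(1 - (1-p)^k) is flat for p = 0.5 at k >= 36
        Q, p = 17.3, 0.5
        k = np.arange(1, 41)
        sync = Q * p * (1 - p) ** (k - 1)
        m = metrics_from_charges(sync)
        rrp, _ = estimate_rrp_train(m, config)
        assert rrp == pytest.approx(Q, rel=1e-6)

    def test_matches_brute_force_regression_oracle(self, protocol, config):
        trace, _, _ = simulate_experiment(SimParams(deterministic=True), protocol)
        m = analyze_train(trace, protocol, config)
        pts = config.regression_points_sync
        x = list(range(40 - pts + 1, 41))
        y = list(m.cumulative_sync[-pts:])
        slope, intercept = brute_force_ols(x, y)
        assert m.diagnostics["rrp_intercept"] == pytest.approx(intercept, rel=1e-9)
        assert m.diagnostics["rrp_slope"] == pytest.approx(slope, rel=1e-9)

    def test_negative_intercept_reported_undefined_not_clamped(self, config):
        # convex cumulative growth back-extrapolates below zero
        sync = np.linspace(0.1, 8.0, 40) ** 2
        m = metrics_from_charges(sync)
        rrp, _ = estimate_rrp_train(m, config)
        assert math.isnan(rrp)
        assert not m.rrp_defined
        assert m.diagnostics["rrp_intercept"] < 0

    def test_too_few_points_is_configuration_error(self, config):
        m = metrics_from_charges(np.full(3, 1.0))
        with pytest.raises(ConfigurationError):
            estimate_rrp_train(m, config)


class TestReleaseProbability:
    def test_unity_when_first_charge_equals_pool(self, config):
        m = metrics_from_charges(np.full(40, 2.0))
        assert release_probability(m, rrp_charge=2.0) == pytest.approx(1.0)

    def test_pure_depletion_recovers_generative_pr(self, protocol, config):
        params = pure_depletion_params(deterministic=True)
        trace, _, _ = simulate_experiment(params, protocol)
        m = analyze_train(trace, protocol, config)
        assert abs(m.pr - params.p_r) < 0.02

    def test_undefined_rrp_propagates(self, config):
        m = metrics_from_charges(np.full(40, 2.0))
        assert math.isnan(release_probability(m, rrp_charge=float("nan")))
        assert math.isnan(release_probability(m, rrp_charge=-1.0))


class TestReplenishmentRate:
    def test_constant_charge_slope_times_frequency(self, config):
        q = 1.7
        m = metrics_from_charges(np.full(40, q), freq=20.0)
        assert replenishment_rate(m, config) == pytest.approx(20.0 * q, rel=1e-9)
        assert m.replenishment_per_stimulus == pytest.approx(q, rel=1e-9)

    def test_zero_late_charges_give_zero_rate(self, config):
        sync = np.concatenate([np.linspace(5, 0.1, 30), np.zeros(10)])
        m = metrics_from_charges(sync)
        assert replenishment_rate(m, config) == pytest.approx(0.0, abs=1e-9)

    def test_matches_ground_truth_flux_at_steady_state(self, protocol, config):
        trace, _, truth = simulate_experiment(SimParams(deterministic=True), protocol)
        m = analyze_train(trace, protocol, config)
        assert m.replenishment_rate_per_s == pytest.approx(
            truth.true_replenishment_flux, rel=0.10
        )

    def test_matches_brute_force_regression_oracle(self, protocol, config):
        trace, _, _ = simulate_experiment(SimParams(deterministic=True), protocol)
        m = analyze_train(trace, protocol, config)
        pts = config.regression_points_total
        x = list(range(40 - pts + 1, 41))
        slope, _ = brute_force_ols(x, list(m.cumulative_total[-pts:]))
        assert m.replenishment_per_stimulus == pytest.approx(slope, rel=1e-9)


class TestPlasticityIndices:
    def test_flat_amplitudes_classify_as_depression_on_tie(self):
        m = metrics_from_charges(np.ones(40), amps=np.ones(40))
        ppr, ste, cls = plasticity_indices(m)
        assert ppr == 1.0 and ste == 1.0
        assert cls == "STD"  # STE is strictly > 1

    def test_halving_amplitudes(self):
        amps = 2.0 ** -np.arange(40, dtype=float)
        m = metrics_from_charges(np.ones(40), amps=amps)
        _, ste, cls = plasticity_indices(m)
        assert ste == pytest.approx(2.0 ** -9)
        assert cls == "STD"

    def test_high_trpc_simulation_shows_enhancement(self, protocol, config):
        from presyn import trpc5_params

        trace, _, _ = simulate_experiment(trpc5_params(deterministic=True), protocol)
        m = analyze_train(trace, protocol, config)
        assert m.ste_ratio > 1.0
        assert m.plasticity_class == "STE"

    def test_silent_first_response_flags_undefined(self):
        m = metrics_from_charges(np.ones(40), amps=np.zeros(40))
        ppr, ste, cls = plasticity_indices(m)
        assert math.isnan(ppr) and math.isnan(ste)
        assert cls == "undefined"


class TestRecoveryFit:
    INTERVALS = (0.020, 0.050, 0.150, 0.350, 0.650, 1.150, 2.150, 4.150)

    def test_noiseless_self_consistency(self):
        k_off, epsc_inf, tau = 0.4, 0.8, 0.5
        t = np.asarray(self.INTERVALS)
        data = k_off + epsc_inf * (1 - np.exp(-t / tau))
        fit = fit_recovery(data, 1.0, t)
        assert fit.k_off == pytest.approx(k_off, abs=1e-6)
        assert fit.epsc_inf == pytest.approx(epsc_inf, abs=1e-6)
        assert fit.tau == pytest.approx(tau, abs=1e-6)

    def test_flat_data_degeneracy_is_flagged(self):
        fit = fit_recovery(np.full(8, 0.37), 1.0, self.INTERVALS)
        assert fit.k_off == pytest.approx(0.37)
        assert fit.epsc_inf == pytest.approx(0.0)
        assert not fit.tau_identifiable

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValidationError):
            fit_recovery([0.5, 0.6, 0.7], 1.0, [0.02, 0.05, 0.15])

    def test_end_to_end_recovery_measurement(self, config):
        proto = standard_train_protocol(recovery=True)
        trace, _, _ = simulate_experiment(SimParams(deterministic=True), proto)
        fit = analyze_recovery(trace, proto, config)
        assert fit.converged
        assert np.all(fit.fractions > 0)
        assert fit.fractions[-1] > fit.fractions[0]


class TestSucroseAnalysis:
    def test_pure_transient_integrates_fully(self):
        fs = 10000.0
        t = np.arange(int(6.0 * fs)) / fs
        y = np.where(t >= 0.5, 400.0 * np.exp(-(t - 0.5) / 0.8), 0.0)
        res = analyze_sucrose(CurrentTrace(-y, fs), window=(0.5, 5.5))
        expected = 400.0 * 0.8 * (1 - math.exp(-5.0 / 0.8))
        assert res.transient_charge == pytest.approx(expected, rel=0.02)

    def test_constant_current_has_zero_transient(self):
        fs = 10000.0
        y = np.full(int(6.0 * fs), 150.0)
        res = analyze_sucrose(CurrentTrace(-y, fs), window=(0.5, 5.5))
        assert res.transient_charge == pytest.approx(0.0, abs=1e-6)
        assert res.steady_state_current == pytest.approx(150.0)

    def test_window_must_fit_trace(self):
        trace = CurrentTrace(np.zeros(10000), 10000.0)
        with pytest.raises(ValidationError):
            analyze_sucrose(trace, window=(0.5, 5.5))
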