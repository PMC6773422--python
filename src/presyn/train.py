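"""Quantal analysis of high-frequency EPSC trains.

Implements the charge-based train workflow: per-stimulus peak amplitudes,
decomposition of each interstimulus charge into synchronous and asynchronous
(steady-state) components, back-extrapolation of the cumulative synchronous
charge to estimate the readily releasable pool (RRP), release probability
(first EPSC charge / RRP charge), the late-train cumulative-total slope as a
vesicle replenishment rate, paired-pulse and Amp10/Amp1 plasticity indices,
single-exponential recovery-from-depression fits and hypertonic-sucrose RRP
measurements.

Raw traces store inward currents as negative; all quantities reported here
are positive magnitudes (amplitudes in nA, charges in pC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .io import (
    AnalysisConfig,
    ConfigurationError,
    CurrentTrace,
    StimulusProtocol,
    ValidationError,
)

__all__ = [
    "TrainMetrics",
    "RecoveryFit",
    "SucroseResult",
    "measure_train",
    "estimate_rrp_train",
    "release_probability",
    "replenishment_rate",
    "plasticity_indices",
    "analyze_train",
    "fit_recovery",
    "analyze_recovery",
    "analyze_sucrose",
]


@dataclass
class TrainMetrics:
    """Per-stimulus measurements and derived pool/plasticity quantities."""

    amplitudes: np.ndarray          # nA, per stimulus
    total_charge: np.ndarray        # pC
    async_charge: np.ndarray        # pC
    sync_charge: np.ndarray         # pC
    cumulative_sync: np.ndarray     # pC
    cumulative_total: np.ndarray    # pC
    train_frequency: float
    quality_flags: np.ndarray = field(default_factory=lambda: np.asarray([]))
    # derived (filled by the estimator functions)
    ppr: float = math.nan
    ste_ratio: float = math.nan
    plasticity_class: str = ""
    steady_state_reached: bool = False
    rrp_charge: float = math.nan
    rrp_defined: bool = False
    pr: float = math.nan
    replenishment_rate_per_s: float = math.nan   # pC/s
    replenishment_per_stimulus: float = math.nan  # pC/stimulus
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_stimuli(self) -> int:
        return int(self.amplitudes.size)

    def to_dict(self) -> dict:
        return {
            "ppr": self.ppr,
            "ste_ratio": self.ste_ratio,
            "plasticity_class": self.plasticity_class,
            "steady_state_reached": self.steady_state_reached,
            "rrp_charge_pC": self.rrp_charge,
            "rrp_defined": self.rrp_defined,
            "pr": self.pr,
            "replenishment_rate_pC_per_s": self.replenishment_rate_per_s,
            "replenishment_pC_per_stimulus": self.replenishment_per_stimulus,
            **{f"diag_{k}": v for k, v in self.diagnostics.items()},
        }


@dataclass
class RecoveryFit:
    """Single-exponential recovery f(t) = k_off + epsc_inf * (1 - exp(-t/tau))."""

    intervals: np.ndarray
    fractions: np.ndarray
    k_off: float = math.nan
    epsc_inf: float = math.nan
    tau: float = math.nan
    rss: float = math.nan
    converged: bool = False
    tau_identifiable: bool = True

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.k_off + self.epsc_inf * (1.0 - np.exp(-t / self.tau))


@dataclass
class SucroseResult:
    """Hypertonic-sucrose RRP measurement."""

    transient_charge: float       # pC, steady-state-corrected integral
    steady_state_current: float   # pA (positive magnitude)
    pr_sucrose: float = math.nan  # evoked EPSC charge / transient charge


# ---------------------------------------------------------------------------
# OLS helper (shared by RRP and replenishment regressions)
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray):
    """Ordinary least squares y = a*x + b; returns (slope, intercept, r2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    sst = np.sum((y - ym) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / sst if sst > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def _detect_clipping(y: np.ndarray) -> bool:
    """Flag runs of >= 4 identical extreme samples (amplifier saturation)."""
    if y.size < 4:
        return False
    peak = np.max(np.abs(y))
    if peak == 0:
        return False
    at_rail = np.abs(np.abs(y) - peak) < 1e-12
    run = 0
    for v in at_rail:
        run = run + 1 if v else 0
        if run >= 4:
            return True
    return False


# ---------------------------------------------------------------------------
# Train measurement
# ---------------------------------------------------------------------------

def measure_train(
    trace: CurrentTrace,
    protocol: StimulusProtocol,
    config: Optional[AnalysisConfig] = None,
) -> TrainMetrics:
    """Measure per-stimulus amplitudes and charge components of an EPSC train.

    For each stimulus k the total charge is the integral of the sign-flipped,
    baseline-subtracted current over the interstimulus interval; the
    asynchronous charge is the steady-state current at the end of the
    interval (mean over the final ``steady_state_window``) times the interval
    duration; the synchronous charge is their difference.  Peak amplitudes
    are searched after blanking the stimulus artifact and measured against a
    local pre-stimulus baseline (or the pre-train baseline, configurable).
    """
    config = config or AnalysisConfig()
    if protocol.train_count < 2:
        raise ValidationError("train analysis needs at least 2 stimuli")
    isi = protocol.interstimulus_interval
    ap = np.asarray(protocol.ap_times[: protocol.train_count], dtype=float)
    trace.require_covers(ap[-1] + isi, "last interstimulus interval")

    fs = trace.sampling_rate
    dt = 1.0 / fs
    # global baseline: mean raw current over 1 ms preceding the first AP
    b0 = trace.index_at(ap[0] - config.baseline_window)
    b1 = trace.index_at(ap[0])
    if b1 <= b0:
        raise ValidationError("no pre-train baseline available before the first AP")
    baseline = float(np.mean(trace.samples[b0:b1]))
    y = -(trace.samples - baseline)  # sign-flipped, global-baseline-subtracted

    n_stim = ap.size
    amplitudes = np.empty(n_stim)
    total_charge = np.empty(n_stim)
    async_charge = np.empty(n_stim)
    quality = np.zeros(n_stim, dtype=bool)

    for k in range(n_stim):
        t_k = ap[k]
        i0 = trace.index_at(t_k)
        i1 = trace.index_at(t_k + isi)
        seg = y[i0:i1]
        quality[k] = _detect_clipping(seg)
        total_charge[k] = np.sum(seg) * dt  # pA*s == pC
        ss0 = trace.index_at(t_k + isi - config.steady_state_window)
        async_charge[k] = float(np.mean(y[ss0:i1])) * isi

        if config.amplitude_baseline == "local":
            lb0 = trace.index_at(t_k - config.baseline_window)
            local = float(np.mean(y[lb0:i0])) if lb0 < i0 else 0.0
        else:
            local = 0.0
        p0 = trace.index_at(t_k + config.artifact_blank)
        p1 = trace.index_at(t_k + min(config.amplitude_search_window, isi))
        amplitudes[k] = (float(np.max(y[p0:p1])) - local) / 1000.0  # pA -> nA

    sync_charge = total_charge - async_charge
    return TrainMetrics(
        amplitudes=amplitudes,
        total_charge=total_charge,
        async_charge=async_charge,
        sync_charge=sync_charge,
        cumulative_sync=np.cumsum(sync_charge),
        cumulative_total=np.cumsum(total_charge),
        train_frequency=protocol.train_frequency,
        quality_flags=quality,
    )


# ---------------------------------------------------------------------------
# Pool estimators
# ---------------------------------------------------------------------------

def estimate_rrp_train(
    metrics: TrainMetrics,
    config: Optional[AnalysisConfig] = None,
):
    """Back-extrapolate the cumulative synchronous charge to stimulus 0.

    An ordinary least-squares line through the last ``regression_points_sync``
    points of (stimulus index, cumulative synchronous charge) is extrapolated
    to stimulus 0; its y-intercept estimates the RRP charge with minimal
    refilling contribution.  Returns ``(rrp_charge, steady_state_reached)``;
    a negative intercept is reported as NaN (undefined), never clamped.
    """
    config = config or AnalysisConfig()
    m = config.regression_points_sync
    n = metrics.n_stimuli
    if n < m:
        raise ConfigurationError(
            f"train has {n} stimuli, fewer than the {m} regression points"
        )
    idx = np.arange(1, n + 1, dtype=float)
    slope, intercept, r2 = _ols(idx[-m:], metrics.cumulative_sync[-m:])

    # steady-state criterion: late-train synchronous charge stationary
    steady = False
    if n >= 10:
        late = float(np.mean(metrics.sync_charge[-5:]))
        prev = float(np.mean(metrics.sync_charge[-10:-5]))
        if prev > 0:
            steady = abs(late - prev) / prev < config.steady_state_tolerance
    metrics.diagnostics.update(
        rrp_slope=slope, rrp_intercept=intercept, rrp_r2=r2,
        rrp_regression_points=m,
    )
    if intercept < 0:
        metrics.rrp_charge = math.nan
        metrics.rrp_defined = False
    else:
        metrics.rrp_charge = intercept
        metrics.rrp_defined = True
    metrics.steady_state_reached = steady
    return metrics.rrp_charge, steady


def release_probability(metrics: TrainMetrics, rrp_charge: Optional[float] = None) -> float:
    """Release probability: first EPSC (synchronous) charge / RRP charge."""
    if rrp_charge is None:
        rrp_charge = metrics.rrp_charge
    if rrp_charge is None or not np.isfinite(rrp_charge) or rrp_charge <= 0:
        metrics.pr = math.nan
        return math.nan
    metrics.pr = float(metrics.sync_charge[0] / rrp_charge)
    return metrics.pr


def replenishment_rate(
    metrics: TrainMetrics,
    config: Optional[AnalysisConfig] = None,
    train_frequency: Optional[float] = None,
) -> float:
    """Late-train slope of the cumulative total charge, in pC/s.

    The OLS slope over the last ``regression_points_total`` points gives the
    replenishment in pC per stimulus; multiplying by the train frequency
    converts it to pC/s.  Both are stored on the metrics.
    """
    config = config or AnalysisConfig()
    freq = train_frequency if train_frequency is not None else metrics.train_frequency
    m = config.regression_points_total
    n = metrics.n_stimuli
    if n < m:
        raise ConfigurationError(
            f"train has {n} stimuli, fewer than the {m} regression points"
        )
    idx = np.arange(1, n + 1, dtype=float)
    slope, intercept, r2 = _ols(idx[-m:], metrics.cumulative_total[-m:])
    metrics.replenishment_per_stimulus = slope
    metrics.replenishment_rate_per_s = slope * freq
    metrics.diagnostics.update(
        repl_slope=slope, repl_intercept=intercept, repl_r2=r2,
        repl_regression_points=m,
    )
    return metrics.replenishment_rate_per_s


def plasticity_indices(metrics: TrainMetrics, noise_floor: float = 0.0):
    """Paired-pulse ratio, Amp10/Amp1 ratio and the STD/STE class.

    Short-term enhancement (STE) is strictly Amp10/Amp1 > 1; a ratio of
    exactly 1 classifies as depression (STD).
    """
    if metrics.n_stimuli < 10:
        raise ValidationError("plasticity indices need >= 10 measured stimuli")
    a1 = metrics.amplitudes[0]
    if not a1 > noise_floor:
        metrics.ppr = math.nan
        metrics.ste_ratio = math.nan
        metrics.plasticity_class = "undefined"
        return metrics.ppr, metrics.ste_ratio, metrics.plasticity_class
    metrics.ppr = float(metrics.amplitudes[1] / a1)
    metrics.ste_ratio = float(metrics.amplitudes[9] / a1)
    metrics.plasticity_class = "STE" if metrics.ste_ratio > 1.0 else "STD"
    return metrics.ppr, metrics.ste_ratio, metrics.plasticity_class


def analyze_train(
    trace: CurrentTrace,
    protocol: StimulusProtocol,
    config: Optional[AnalysisConfig] = None,
) -> TrainMetrics:
    """Full train workflow: measurement, RRP, Pr, replenishment, indices."""
    config = config or AnalysisConfig()
    metrics = measure_train(trace, protocol, config)
    estimate_rrp_train(metrics, config)
    release_probability(metrics)
    replenishment_rate(metrics, config)
    plasticity_indices(metrics)
    return metrics


# ---------------------------------------------------------------------------
# Recovery from depression
# ---------------------------------------------------------------------------

def _recovery_model(theta, t):
    k_off, epsc_inf, tau = theta
    return k_off + epsc_inf * (1.0 - np.exp(-t / tau))


def fit_recovery(
    test_amplitudes: Sequence[float],
    first_train_amplitude: float,
    intervals: Sequence[float],
) -> RecoveryFit:
    """Fit f(t) = k_off + epsc_inf * (1 - exp(-t/tau)) to recovery fractions.

    The recovery fraction at each interval is the test-pulse amplitude
    divided by the first train amplitude.  The three-parameter fit is run
    from a small grid of tau starts (0.1, 0.5, 2 s) and the best residual
    kept; flat data are reported with ``tau_identifiable=False`` rather than
    an arbitrary time constant.
    """
    t = np.asarray(intervals, dtype=float)
    amps = np.asarray(test_amplitudes, dtype=float)
    if t.size < 4:
        raise ValidationError("recovery fit needs at least 4 intervals")
    if not first_train_amplitude > 0:
        raise ValidationError("first_train_amplitude must be positive")
    frac = amps / first_train_amplitude
    fit = RecoveryFit(intervals=t, fractions=frac)

    spread = float(np.max(frac) - np.min(frac))
    if spread < 1e-9:
        fit.k_off = float(np.mean(frac))
        fit.epsc_inf = 0.0
        fit.tau = math.nan
        fit.rss = float(np.sum((frac - fit.k_off) ** 2))
        fit.converged = True
        fit.tau_identifiable = False
        return fit

    best = None
    for tau0 in (0.1, 0.5, 2.0):
        theta0 = np.array([float(np.min(frac)), spread, tau0])
        try:
            res = least_squares(
                lambda th: _recovery_model(th, t) - frac,
                theta0,
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if res.success and (best is None or rss < best[0]):
            best = (rss, res.x)
    if best is None:
        return fit  # converged stays False; fractions still carried
    fit.rss, (fit.k_off, fit.epsc_inf, fit.tau) = best[0], tuple(best[1])
    fit.converged = True
    # tau is meaningless when the exponential component vanished
    fit.tau_identifiable = abs(fit.epsc_inf) > 1e-8 * max(1.0, abs(fit.k_off))
    return fit


def analyze_recovery(
    trace: CurrentTrace,
    protocol: StimulusProtocol,
    config: Optional[AnalysisConfig] = None,
) -> RecoveryFit:
    """Measure post-train test-pulse amplitudes and fit the recovery curve."""
    config = config or AnalysisConfig()
    if not protocol.recovery_intervals:
        raise ValidationError("protocol defines no recovery intervals")
    metrics = measure_train(trace, protocol, config)
    fs = trace.sampling_rate
    dt = 1.0 / fs
    b0 = trace.index_at(protocol.ap_times[0] - config.baseline_window)
    b1 = trace.index_at(protocol.ap_times[0])
    baseline = float(np.mean(trace.samples[b0:b1]))
    y = -(trace.samples - baseline)
    amps = []
    for t_p in protocol.recovery_times:
        trace.require_covers(t_p + config.amplitude_search_window, "recovery pulse")
        lb0 = trace.index_at(t_p - config.baseline_window)
        i0 = trace.index_at(t_p)
        local = float(np.mean(y[lb0:i0])) if config.amplitude_baseline == "local" else 0.0
        p0 = trace.index_at(t_p + config.artifact_blank)
        p1 = trace.index_at(t_p + config.amplitude_search_window)
        amps.append((float(np.max(y[p0:p1])) - local) / 1000.0)
    return fit_recovery(amps, metrics.amplitudes[0], protocol.recovery_intervals)


# ---------------------------------------------------------------------------
# Hypertonic sucrose
# ---------------------------------------------------------------------------

def analyze_sucrose(
    trace: CurrentTrace,
    window: Optional[tuple] = None,
    config: Optional[AnalysisConfig] = None,
    epsc_charge: Optional[float] = None,
) -> SucroseResult:
    """RRP charge from a hypertonic sucrose response.

    The steady-state current (mean sign-flipped current over the final 10%
    of the application window) is subtracted before integrating; the
    remaining transient charge estimates the RRP.  If ``epsc_charge`` (the
    single-AP EPSC charge, pC) is given, ``pr_sucrose`` is the quotient of
    the two.
    """
    if window is None:
        window = tuple(trace.metadata.get("sucrose_window", ()))
        if len(window) != 2:
            raise ValidationError("no sucrose window given or stored on the trace")
    a, b = float(window[0]), float(window[1])
    if b - a < 1.0:
        raise ValidationError("sucrose window must be at least 1 s long")
    trace.require_covers(b, "sucrose application")
    dt = 1.0 / trace.sampling_rate
    i0, i1 = trace.index_at(a), trace.index_at(b)
    y = -trace.samples[i0:i1]
    tail = y[int(0.9 * y.size):]
    steady = float(np.mean(tail))
    charge = float(np.sum(y - steady) * dt)
    result = SucroseResult(
        transient_charge=max(charge, 0.0),
        steady_state_current=steady,
    )
    if epsc_charge is not None and result.transient_charge > 0:
        result.pr_sucrose = epsc_charge / result.transient_charge
    return result
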