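"""End-to-end orchestration: simulate -> analyze -> report.

Also hosts the reusable benchmark battery (parameter recovery, plasticity
phenotype sweeps, mini-detection operating point, recovery-fit Monte Carlo,
imaging calibration) that the command-line tools and the acceptance script
drive.  Every run writes a manifest from which it can be reproduced
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import simulate as sim
from .io import AnalysisConfig, StimulusProtocol, write_protocol, write_trace
from .imaging import (
    background_noise_sd,
    compute_dff,
    detect_responsive,
    dff_metrics,
    pair_with_train,
)
from .minis import detect_minis, mini_stats
from .train import analyze_recovery, analyze_sucrose, analyze_train, fit_recovery

__version__ = "0.1.0"

__all__ = [
    "standard_train_protocol",
    "percent_positive",
    "run_end_to_end",
    "sweep_jtrpc",
    "pool_parameter_recovery",
    "phenotype_panel",
    "mini_detection_benchmark",
    "recovery_fit_benchmark",
    "imaging_false_positive_rate",
    "imaging_train_correlation",
]


def standard_train_protocol(t0: float = 0.1, recovery: bool = False) -> StimulusProtocol:
    """The standard 20-Hz, 40-AP/2-s high-frequency train."""
    from .io import STANDARD_RECOVERY_INTERVALS

    return StimulusProtocol.train(
        frequency=20.0, count=40, t0=t0,
        recovery_intervals=STANDARD_RECOVERY_INTERVALS if recovery else (),
    )


def percent_positive(n_positive: int, n_total: int) -> float:
    """Percentage of positively scored cells in a count (0-100)."""
    if n_total <= 0 or n_positive < 0 or n_positive > n_total:
        raise ValueError("need 0 <= n_positive <= n_total with n_total > 0")
    return 100.0 * n_positive / n_total


# ---------------------------------------------------------------------------
# Run orchestration
# ---------------------------------------------------------------------------

def _manifest(out_dir: Path, seed, config: AnalysisConfig, params: sim.SimParams,
              stages: dict) -> dict:
    cfg_json = json.dumps(config.to_json(), sort_keys=True)
    man = {
        "command": " ".join(sys.argv),
        "seed": seed,
        "config": config.to_json(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "sim_params": {k: v for k, v in dataclasses.asdict(params).items()},
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": stages,
    }
    (out_dir / "manifest.json").write_text(json.dumps(man, indent=1, default=str))
    return man


def run_end_to_end(
    params: sim.SimParams,
    protocol: StimulusProtocol,
    config: Optional[AnalysisConfig] = None,
    seed: Optional[int] = None,
    out_dir="run_out",
) -> dict:
    """Simulate one experiment, analyze it, and write all result tables.

    Writes the trace (CSV + sidecar), the protocol, the ground truth, the
    train metrics and an estimated-vs-true comparison, plus a manifest.
    Partial failures are recorded per stage; earlier outputs are kept.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        params = replace(params, seed=seed)
    stages: dict = {}
    results: dict = {"out_dir": out_dir}
    try:
        trace, ca, truth = sim.simulate_experiment(params, protocol)
        write_trace(trace, out_dir / "trace.csv")
        write_protocol(protocol, out_dir / "protocol.json")
        np.savetxt(
            out_dir / "calcium_nM.csv",
            np.column_stack([ca.times, ca.concentration]),
            delimiter=",", header="time_s,calcium_nM", comments="",
        )
        truth_doc = {
            "stim_times": truth.stim_times.tolist(),
            "sync_quanta": truth.sync_quanta.tolist(),
            "true_rrp_charge_pC": truth.true_rrp_charge,
            "true_pr": truth.true_pr,
            "true_replenishment_flux_pC_per_s": truth.true_replenishment_flux,
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(truth_doc, indent=1))
        stages["simulate"] = "ok"
        results.update(trace=trace, ca=ca, truth=truth)
    except Exception as exc:  # pragma: no cover - error path
        stages["simulate"] = f"failed: {exc}"
        _manifest(out_dir, seed, config, params, stages)
        return results
    try:
        metrics = analyze_train(trace, protocol, config)
        pd.DataFrame(
            {
                "stimulus": np.arange(1, metrics.n_stimuli + 1),
                "amplitude_nA": metrics.amplitudes,
                "total_charge_pC": metrics.total_charge,
                "sync_charge_pC": metrics.sync_charge,
                "async_charge_pC": metrics.async_charge,
                "cumulative_sync_pC": metrics.cumulative_sync,
                "cumulative_total_pC": metrics.cumulative_total,
            }
        ).to_csv(out_dir / "train_metrics.csv", index=False)
        summary = metrics.to_dict()
        comparison = {
            "rrp_charge_pC": {"estimated": metrics.rrp_charge,
                              "true": truth.true_rrp_charge},
            "pr": {"estimated": metrics.pr, "true": truth.true_pr},
            "replenishment_pC_per_s": {
                "estimated": metrics.replenishment_rate_per_s,
                "true": truth.true_replenishment_flux,
            },
        }
        (out_dir / "summary.json").write_text(
            json.dumps({"summary": summary, "comparison": comparison},
                       indent=1, default=str)
        )
        stages["analyze"] = "ok"
        results.update(metrics=metrics, comparison=comparison)
    except Exception as exc:
        stages["analyze"] = f"failed: {exc}"
    if protocol.recovery_intervals:
        try:
            fit = analyze_recovery(trace, protocol, config)
            (out_dir / "recovery_fit.json").write_text(json.dumps({
                "k_off": fit.k_off, "epsc_inf": fit.epsc_inf, "tau_s": fit.tau,
                "rss": fit.rss, "fractions": fit.fractions.tolist(),
                "intervals_s": fit.intervals.tolist(),
            }, indent=1))
            stages["recovery"] = "ok"
            results["recovery_fit"] = fit
        except Exception as exc:
            stages["recovery"] = f"failed: {exc}"
    results["manifest"] = _manifest(out_dir, seed, config, params, stages)
    return results


# ---------------------------------------------------------------------------
# Benchmark battery
# ---------------------------------------------------------------------------

def sweep_jtrpc(
    j_values: Sequence[float],
    base_params: Optional[sim.SimParams] = None,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Deterministic sweep of the TRPC influx rate.

    One row per j_trpc value with the analysed plasticity and pool metrics;
    used to test that the STD -> STE switch is monotone in TRPC strength.
    """
    config = config or AnalysisConfig()
    if base_params is None:
        base_params = sim.SimParams(deterministic=True)
    protocol = standard_train_protocol()
    rows = []
    for j in j_values:
        params = replace(base_params, j_trpc=float(j), deterministic=True)
        trace, ca, truth = sim.simulate_experiment(params, protocol)
        m = analyze_train(trace, protocol, config)
        rows.append(dict(
            j_trpc=float(j),
            amp1_nA=m.amplitudes[0],
            ppr=m.ppr,
            ste_ratio=m.ste_ratio,
            plasticity_class=m.plasticity_class,
            async_charge_40_pC=m.async_charge[-1],
            sync_charge_40_pC=m.sync_charge[-1],
            replenishment_pC_per_s=m.replenishment_rate_per_s,
            rrp_charge_pC=m.rrp_charge,
        ))
    return pd.DataFrame(rows)


def phenotype_panel(config: Optional[AnalysisConfig] = None) -> dict:
    """Deterministic contrasts: TRPC loss/gain, EGTA buffering, TEA.

    Returns the analysed metrics for four conditions sharing the wild-type
    parameter set: TRPC-deficient (j_trpc = 0), strong TRPC5, strong TRPC5 +
    EGTA, and wild type +/- TEA.
    """
    config = config or AnalysisConfig()
    protocol = standard_train_protocol()

    def run(params):
        trace, _, _ = sim.simulate_experiment(params, protocol)
        return analyze_train(trace, protocol, config)

    det = dict(deterministic=True)
    wt = sim.SimParams(**det)
    return {
        "tko": run(sim.tko_params(**det)),
        "wt": run(wt),
        "trpc5": run(sim.trpc5_params(**det)),
        "trpc5_egta": run(sim.trpc5_params(egta_mode=True, **det)),
        "wt_tea": run(replace(wt, tea_mode=True)),
    }


def pool_parameter_recovery(
    n_sims: int = 200,
    seeds: Optional[Sequence[int]] = None,
    params: Optional[sim.SimParams] = None,
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Estimate RRP and Pr on stochastic pure-depletion trains.

    Each seed simulates a 20-Hz/40-AP train in the pure-depletion regime and
    runs the full charge analysis; the returned frame carries the per-seed
    relative RRP error and absolute Pr error against the generative truth.
    """
    config = config or AnalysisConfig()
    if seeds is None:
        seeds = range(1, n_sims + 1)
    if params is None:
        params = sim.pure_depletion_params()
    protocol = standard_train_protocol()
    rows = []
    for s in seeds:
        p = replace(params, seed=int(s), deterministic=False)
        trace, _, truth = sim.simulate_experiment(p, protocol)
        m = analyze_train(trace, protocol, config)
        rows.append(dict(
            seed=int(s),
            rrp_est=m.rrp_charge,
            rrp_true=truth.true_rrp_charge,
            rrp_rel_error=abs(m.rrp_charge - truth.true_rrp_charge) / truth.true_rrp_charge,
            pr_est=m.pr,
            pr_abs_error=abs(m.pr - truth.true_pr),
        ))
    return pd.DataFrame(rows)


def mini_detection_benchmark(
    n_seeds: int = 20,
    duration: float = 120.0,
    snr: float = 8.0,
    rate: float = 1.0,
    match_tol: float = 0.003,
    config: Optional[AnalysisConfig] = None,
    seed0: int = 0,
) -> pd.DataFrame:
    """Operating point of the mini detector on ground-truthed recordings.

    Quanta of fixed amplitude ``snr`` x noise SD arrive as a Poisson process;
    detected onsets are matched to true event times within ``match_tol``.
    Returns per-seed sensitivity and precision.
    """
    config = config or AnalysisConfig()
    q_mean = 24.0
    params = sim.SimParams(
        q_mean=q_mean, q_cv=0.0, noise_sd=q_mean / snr,
        mini_rate0=rate, async_gain=0.0, j_trpc=0.0,
    )
    rows = []
    for s in range(seed0 + 1, seed0 + n_seeds + 1):
        p = replace(params, seed=int(s))
        trace, _, truth = sim.simulate_minis(p, duration=duration)
        events = detect_minis(trace, config)
        det_onsets = np.asarray([e.onset for e in events])
        true_times = np.asarray(truth.mini_times)
        matched = np.zeros(det_onsets.size, dtype=bool)
        hits = 0
        for t in true_times:
            if det_onsets.size == 0:
                break
            d = np.abs(det_onsets - t)
            d[matched] = np.inf
            i = int(np.argmin(d))
            if d[i] <= match_tol:
                matched[i] = True
                hits += 1
        sens = hits / true_times.size if true_times.size else np.nan
        prec = matched.sum() / det_onsets.size if det_onsets.size else np.nan
        rows.append(dict(seed=s, n_true=true_times.size,
                         n_detected=det_onsets.size,
                         sensitivity=sens, precision=prec))
    return pd.DataFrame(rows)


def recovery_fit_benchmark(
    n_seeds: int = 100,
    noise_sd: float = 0.05,
    truth: tuple = (0.4, 0.8, 0.5),
    seed0: int = 0,
) -> dict:
    """Exactness and noise robustness of the recovery-curve fit.

    Fits the single-exponential recovery model to its own noiseless values
    at the eight standard intervals (parameter recovery should be exact to
    numerical precision) and to ``n_seeds`` noisy replicates, reporting the
    median relative error of the recovered time constant.
    """
    from .io import STANDARD_RECOVERY_INTERVALS

    k_off, epsc_inf, tau = truth
    t = np.asarray(STANDARD_RECOVERY_INTERVALS)
    clean = k_off + epsc_inf * (1.0 - np.exp(-t / tau))
    exact = fit_recovery(clean, 1.0, t)
    exact_err = max(
        abs(exact.k_off - k_off), abs(exact.epsc_inf - epsc_inf),
        abs(exact.tau - tau),
    )
    tau_errors = []
    for s in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed0, 10, s]))
        noisy = clean + rng.normal(0.0, noise_sd, t.size)
        fit = fit_recovery(noisy, 1.0, t)
        if fit.converged and fit.tau_identifiable:
            tau_errors.append(abs(fit.tau - tau) / tau)
    return {
        "exact_max_param_error": float(exact_err),
        "median_tau_rel_error": float(np.median(tau_errors)),
        "n_converged": len(tau_errors),
    }


def imaging_false_positive_rate(
    n_seeds: int = 20,
    config: Optional[AnalysisConfig] = None,
    seed0: int = 0,
) -> float:
    """Fraction of background ROIs wrongly flagged responsive at the 3-SD rule.

    Stacks are rendered from a real train-evoked calcium transient with
    photon noise; ROIs placed on background (non-synapse) tiles should pass
    the responsiveness threshold only at the false-positive rate of the
    max-statistic, a few percent.
    """
    config = config or AnalysisConfig()
    protocol = standard_train_protocol(t0=0.7)
    params = sim.SimParams(deterministic=True)
    ca = sim.simulate_calcium(params, protocol, duration=4.6)
    n_bg = 0
    n_fp = 0
    for s in range(seed0 + 1, seed0 + n_seeds + 1):
        stack, rois = sim.render_imaging(ca, n_synapses=8, seed=s)
        bg_sd = background_noise_sd(stack, exclude=rois, roi_size=config.dff_roi_size)
        size = config.dff_roi_size
        rows, cols = stack.frames.shape[1:]
        for r in range(0, rows - size + 1, size):
            for c in range(0, cols - size + 1, size):
                if any(r == er and c == ec for er, ec in rois):
                    continue
                rt = compute_dff(stack, (r, c), config, background_sd=bg_sd)
                detect_responsive([rt], config)
                n_bg += 1
                n_fp += int(rt.responsive)
    return n_fp / n_bg


def imaging_train_correlation(
    j_values: Sequence[float] = (0.0, 1500.0, 3000.0, 5000.0, 7000.0),
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Paired imaging + electrophysiology across a TRPC-strength sweep.

    For each j_trpc a deterministic experiment is simulated; the noise-free
    fluorescence stack yields the during-train dF/F0 slope and the train
    analysis the replenishment rate.  The returned table carries the
    Spearman rank correlation in ``table.attrs``.
    """
    config = config or AnalysisConfig()
    protocol = standard_train_protocol(t0=0.7)
    gcamp = sim.GCaMPParams(photon_noise=False)
    imaging = {}
    trains = {}
    for i, j in enumerate(j_values):
        params = sim.SimParams(j_trpc=float(j), deterministic=True)
        ca = sim.simulate_calcium(params, protocol, duration=4.6)
        truth = sim.simulate_pool(params, ca, protocol)
        trace = sim.render_current(truth, params, 4.6)
        stack, rois = sim.render_imaging(ca, n_synapses=4, gcamp=gcamp, seed=i)
        bg_sd = background_noise_sd(stack, exclude=rois)
        rt = compute_dff(stack, rois[0], config, background_sd=max(bg_sd, 1e-12))
        detect_responsive([rt], config)
        imaging[i] = dff_metrics(rt, config)
        trains[i] = analyze_train(trace, protocol, config)
    table, _ = pair_with_train(imaging, trains)
    table.insert(1, "j_trpc", list(map(float, j_values)))
    return table
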