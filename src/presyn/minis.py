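"""Detection and quantification of spontaneous miniature EPSCs.

Events are found by threshold crossings of the smoothed first derivative of
the sign-flipped current and accepted only if they pass both of the classic
criteria: peak amplitude above ``mini_amp_sd_mult`` (default 5) times the
baseline noise SD, and charge above ``mini_charge_min`` (default 25 fC).
The baseline noise SD is a robust (MAD-based) estimate on the detrended,
event-free signal.  Detection is deterministic for a given trace + config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import AnalysisConfig, CurrentTrace, ValidationError

__all__ = [
    "QuantalEvent",
    "MiniStats",
    "AgonistResponse",
    "baseline_noise_sd",
    "detect_minis",
    "mini_stats",
    "agonist_response",
]

_MAD_TO_SD = 1.4826


@dataclass
class QuantalEvent:
    """One detected quantal event (positive magnitudes)."""

    onset: float             # s
    peak_time: float         # s
    peak_amplitude: float    # pA
    rise_time_10_90: float   # ms
    decay_tau: float         # ms (time-to-1/e from the peak)
    charge: float            # fC


@dataclass
class MiniStats:
    """Summary statistics of a mini recording."""

    frequency: float                 # Hz
    n_events: int
    duration: float                  # s analysed
    amplitude_mean: float = math.nan
    amplitude_median: float = math.nan
    charge_mean: float = math.nan
    rise_time_mean: float = math.nan
    decay_tau_mean: float = math.nan
    interevent_intervals: np.ndarray = field(default_factory=lambda: np.asarray([]))

    def interevent_cdf(self):
        """Empirical CDF of interevent intervals: (sorted intervals, F)."""
        iei = np.sort(self.interevent_intervals)
        if iei.size == 0:
            return iei, iei
        return iei, np.arange(1, iei.size + 1) / iei.size


@dataclass
class AgonistResponse:
    """Response to an agonist application (e.g. Englerin A)."""

    baseline_current: float      # pA (median raw current in baseline window)
    max_inward_current: float    # pA magnitude relative to baseline
    freq_fold_change: float      # drug-window rate / baseline rate
    responder: bool
    fold_defined: bool = True


# ---------------------------------------------------------------------------
# Noise estimation
# ---------------------------------------------------------------------------

def _detrend(y: np.ndarray, fs: float, sigma_s: float = 0.01) -> np.ndarray:
    """Remove slow drift with a wide Gaussian low-pass (sigma 10 ms)."""
    return y - gaussian_filter1d(y, sigma_s * fs)


def baseline_noise_sd(
    trace: CurrentTrace,
    exclusion: Optional[np.ndarray] = None,
) -> float:
    """Robust baseline noise SD (pA) of the recording.

    Computed as 1.4826 x the median absolute deviation of the high-pass
    detrended signal, outside any excluded (detected-event) regions.
    """
    fs = trace.sampling_rate
    resid = _detrend(trace.samples, fs)
    if exclusion is not None:
        exclusion = np.asarray(exclusion, dtype=bool)
        if exclusion.shape != resid.shape:
            raise ValidationError("exclusion mask must match the trace length")
        resid = resid[~exclusion]
    if resid.size < 0.5 * fs:
        raise ValidationError("need >= 0.5 s of event-free trace for noise estimation")
    mad = float(np.median(np.abs(resid - np.median(resid))))
    return _MAD_TO_SD * mad


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def detect_minis(
    trace: CurrentTrace,
    config: Optional[AnalysisConfig] = None,
    noise_sd: Optional[float] = None,
) -> list:
    """Detect miniature EPSCs in a spontaneous recording.

    Candidate onsets come from upward threshold crossings of the smoothed
    derivative of the sign-flipped current; candidates closer than the
    refractory period merge.  Each candidate is measured against a local
    pre-onset baseline, and kept only if its peak amplitude exceeds
    ``mini_amp_sd_mult`` x noise SD *and* its charge (onset to return within
    one noise SD of baseline, capped at ``mini_charge_cap``) exceeds
    ``mini_charge_min`` fC.  Returns a list of :class:`QuantalEvent`.
    """
    config = config or AnalysisConfig()
    fs = trace.sampling_rate
    if fs < 5000:
        raise ValidationError("mini detection needs sampling_rate >= 5 kHz")
    if noise_sd is None:
        noise_sd = baseline_noise_sd(trace)
    if noise_sd <= 0:
        return []

    y = -trace.samples  # inward events positive
    y_s = gaussian_filter1d(y, config.mini_smooth_sigma * fs)
    dy = np.gradient(y_s) * fs  # pA/s

    # derivative threshold from the robust SD of the derivative itself
    dmad = float(np.median(np.abs(dy - np.median(dy)))) * _MAD_TO_SD
    thresh = config.mini_deriv_sd_mult * dmad
    above = dy > thresh
    starts = np.nonzero(above[1:] & ~above[:-1])[0] + 1

    refractory = int(config.mini_refractory * fs)
    base_n = max(int(0.002 * fs), 2)       # 2 ms local baseline
    gap_n = max(int(0.0005 * fs), 1)       # ending 0.5 ms before onset
    peak_n = int(0.010 * fs)               # peak search 10 ms
    cap_n = int(config.mini_charge_cap * fs)
    dt_ms = 1000.0 / fs

    events: list = []
    last_onset = -10 * refractory
    for i0 in starts:
        if i0 - last_onset < refractory:
            continue
        b1 = max(i0 - gap_n, 0)
        b0 = max(b1 - base_n, 0)
        if b1 <= b0:
            continue
        local = float(np.median(y_s[b0:b1]))
        p1 = min(i0 + peak_n, y.size)
        seg = y_s[i0:p1]
        if seg.size == 0:
            continue
        ip = int(np.argmax(seg))
        amp = float(seg[ip]) - local
        if amp <= config.mini_amp_sd_mult * noise_sd:
            continue
        # charge: onset until return within 1 SD of local baseline (capped)
        c1 = min(i0 + cap_n, y.size)
        rel = y_s[i0:c1] - local
        below = np.nonzero(rel[ip:] < noise_sd)[0]
        end = ip + below[0] if below.size else rel.size
        charge_fC = float(np.sum(rel[:end])) * dt_ms  # pA*ms == fC
        if charge_fC <= config.mini_charge_min:
            continue
        # kinetics
        rise = rel[: ip + 1]
        t10 = np.argmax(rise >= 0.1 * amp)
        t90 = np.argmax(rise >= 0.9 * amp)
        rise_ms = max(t90 - t10, 0) * dt_ms
        decay = rel[ip:end]
        under = np.nonzero(decay <= amp / math.e)[0]
        decay_ms = (under[0] if under.size else decay.size) * dt_ms
        last_onset = i0
        ev = QuantalEvent(
            onset=i0 / fs + trace.start_time,
            peak_time=(i0 + ip) / fs + trace.start_time,
            peak_amplitude=amp,
            rise_time_10_90=rise_ms,
            decay_tau=decay_ms,
            charge=charge_fC,
        )
        # two candidate onsets resolving to the same peak are one event;
        # the later onset (closest to the peak) is the accurate one
        if events and abs(ev.peak_time - events[-1].peak_time) < config.mini_refractory:
            events[-1] = ev
        else:
            events.append(ev)
    return events


def events_mask(trace: CurrentTrace, events: Sequence[QuantalEvent],
                pad: float = 0.01) -> np.ndarray:
    """Boolean mask covering detected events (for noise re-estimation)."""
    mask = np.zeros(trace.n_samples, dtype=bool)
    fs = trace.sampling_rate
    for ev in events:
        i0 = max(int((ev.onset - trace.start_time - 0.002) * fs), 0)
        i1 = min(int((ev.onset - trace.start_time + pad) * fs), mask.size)
        mask[i0:i1] = True
    return mask


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def mini_stats(events: Sequence[QuantalEvent], analysed_duration: float) -> MiniStats:
    """Frequency, amplitude and kinetic summaries of a set of events."""
    if analysed_duration <= 0:
        raise ValidationError("analysed_duration must be positive")
    n = len(events)
    stats = MiniStats(
        frequency=n / analysed_duration,
        n_events=n,
        duration=analysed_duration,
    )
    if n:
        amps = np.asarray([e.peak_amplitude for e in events])
        stats.amplitude_mean = float(np.mean(amps))
        stats.amplitude_median = float(np.median(amps))
        stats.charge_mean = float(np.mean([e.charge for e in events]))
        stats.rise_time_mean = float(np.mean([e.rise_time_10_90 for e in events]))
        stats.decay_tau_mean = float(np.mean([e.decay_tau for e in events]))
        onsets = np.sort([e.onset for e in events])
        stats.interevent_intervals = np.diff(onsets)
    return stats


def agonist_response(
    trace: CurrentTrace,
    baseline_window: tuple,
    drug_window: tuple,
    events: Sequence[QuantalEvent],
    config: Optional[AnalysisConfig] = None,
) -> AgonistResponse:
    """Quantify a drug application: holding-current shift and mini-rate fold.

    The maximum inward current is the sign-flipped, smoothed deviation from
    the baseline median, measured over the final quarter of the drug window
    (i.e. at the end of the application).  The frequency fold change is the
    event rate inside the drug window over the baseline rate; responders
    must reach ``responder_fold_threshold`` (default 1.2; a fold of 1.19 is
    a non-responder).
    """
    config = config or AnalysisConfig()
    (a0, a1), (d0, d1) = baseline_window, drug_window
    if min(a1 - a0, d1 - d0) < 5.0:
        raise ValidationError("baseline and drug windows must each span >= 5 s")
    if a0 < d1 and d0 < a1:
        raise ValidationError("baseline and drug windows must be disjoint")
    trace.require_covers(max(a1, d1), "drug application")

    fs = trace.sampling_rate
    smooth = gaussian_filter1d(trace.samples, 0.05 * fs)  # 50-ms smoothing
    base = float(np.median(trace.samples[trace.index_at(a0): trace.index_at(a1)]))
    tail0 = trace.index_at(d1 - 0.25 * (d1 - d0))
    tail1 = trace.index_at(d1)
    max_inward = float(np.max(-(smooth[tail0:tail1] - base)))

    onsets = np.asarray([e.onset for e in events])
    n_base = int(np.sum((onsets >= a0) & (onsets < a1)))
    n_drug = int(np.sum((onsets >= d0) & (onsets < d1)))
    rate_base = n_base / (a1 - a0)
    rate_drug = n_drug / (d1 - d0)
    if rate_base == 0:
        return AgonistResponse(
            baseline_current=base,
            max_inward_current=max_inward,
            freq_fold_change=math.nan,
            responder=False,
            fold_defined=False,
        )
    fold = rate_drug / rate_base
    return AgonistResponse(
        baseline_current=base,
        max_inward_current=max_inward,
        freq_fold_change=fold,
        responder=fold >= config.responder_fold_threshold,
    )
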