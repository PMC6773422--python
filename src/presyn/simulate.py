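"""Generative model of presynaptic Ca2+ dynamics, vesicle-pool kinetics and the
resulting patch-clamp and fluorescence recordings.

The model is deliberately compact.  Bulk presynaptic calcium follows

    dC/dt = -(C - c_rest)/tau_clear + j_trpc * Hill(C; EC50, n)  (+ drug terms)

with an instantaneous increment ``delta_c_ap`` at every action potential
(VGCC influx).  The second term is a Ca2+-activated TRPC conductance: TRPC5
opens in a dose-dependent way with bulk [Ca]i (EC50 ~ 635 nM), so Ca2+ entry
begets further Ca2+ entry, amplifying and prolonging the train-evoked
calcium transient.  Parameters are kept in the monostable regime, so calcium
always relaxes back to rest after stimulation.

The readily releasable pool (RRP) holds N vesicles.  Between APs it is
refilled at the Ca2+-dependent rate

    dN/dt = (k0 + k_ca * C) * (n_cap(C) - N),
    n_cap(C) = n_max * (1 + prime_gain * Hill(C - C_rest; EC50_prime, n))

Each AP releases Binomial(N, p_r) vesicles (expectation N*p_r in
deterministic mode).  The Ca2+-dependent capacity term lets sustained
calcium transiently overfill the pool above its resting size, which is what
converts depression into short-term enhancement when the TRPC pathway is
strong; at resting calcium n_cap equals n_max and the plain depletion-
refill model is recovered.  Asynchronous release is an inhomogeneous
Poisson process driven by supra-resting calcium; it consumes RRP vesicles.
Spontaneous minis share the quantal generator but do not touch the pool.

Pharmacological modes: ``egta_mode`` scales all free-Ca2+ increments and the
TRPC term by 1/(1+kappa) (slow chelation of bulk, not local, calcium),
``tea_mode`` scales the per-AP Ca2+ increment and the release probability
(AP broadening), ``englerin_mode`` adds a direct TRPC agonist current plus a
steady Ca2+ influx during its application window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .io import (
    ConfigurationError,
    CurrentTrace,
    ImagingStack,
    NumericalError,
    StimulusProtocol,
    ValidationError,
)

__all__ = [
    "SimParams",
    "GCaMPParams",
    "CaTrace",
    "GroundTruth",
    "hill_activation",
    "egta_capture_length",
    "resting_calcium",
    "simulate_calcium",
    "simulate_pool",
    "render_current",
    "simulate_experiment",
    "simulate_minis",
    "simulate_sucrose",
    "render_imaging",
    "tko_params",
    "trpc5_params",
    "pure_depletion_params",
]


# ---------------------------------------------------------------------------
# Parameters and containers
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Generative parameters; defaults describe a wild-type-like neuron."""

    # vesicle pool
    n_max: int = 100                # RRP capacity (vesicles)
    p_r: float = 0.3                # per-AP release probability per vesicle
    k0: float = 0.2                 # baseline replenishment rate (1/s)
    k_ca: float = 20.0              # Ca-dependent replenishment gain (1/s/uM)
    prime_gain: float = 4.0         # max fractional pool overfill at high Ca
    prime_ec50: float = 635.0       # nM supra-resting Ca for half overfill
    prime_hill: float = 2.0
    # calcium
    c_rest: float = 50.0            # resting [Ca]i (nM)
    delta_c_ap: float = 100.0       # per-AP bulk Ca increment (nM)
    tau_clear: float = 0.1          # Ca clearance time constant (s)
    j_trpc: float = 2000.0          # maximal TRPC Ca influx (nM/s)
    ec50_trpc: float = 635.0        # nM
    n_hill: float = 2.0
    # release machinery
    async_gain: float = 0.2         # async rate per nM supra-resting Ca (1/s/nM)
    mini_rate0: float = 1.5         # baseline mEPSC rate (Hz)
    sync_latency: float = 0.001     # s from AP to synchronous release
    sync_jitter: float = 0.0003     # s SD of release-time jitter (stochastic)
    # quantal kernel
    q_mean: float = 25.0            # mean quantal amplitude (pA)
    q_cv: float = 0.3               # lognormal CV of quantal amplitudes
    tau_rise: float = 0.0005        # s
    tau_decay: float = 0.004        # s
    noise_sd: float = 4.0           # recording noise (pA)
    # pharmacology
    egta_mode: bool = False
    egta_kappa: float = 9.0         # added buffering capacity kappa_E
    tea_mode: bool = False
    tea_f_ca: float = 1.2           # multiplies delta_c_ap
    tea_f_pr: float = 5.0 / 3.0     # multiplies p_r
    englerin_mode: bool = False
    englerin_amp: float = 500.0     # direct inward current (pA)
    englerin_ca_influx: float = 100.0  # nM/s during application
    # sucrose
    sucrose_rate: float = 2.0       # 1/s emptying rate under hypertonic challenge
    # numerics
    dt: float = 1e-4                # integration / sampling step (s)
    deterministic: bool = False     # expectation mode, no sampling
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0.0 < self.p_r <= 1.0):
            raise ValidationError("p_r must lie in (0, 1]")
        if self.ec50_trpc <= 0 or self.prime_ec50 <= 0:
            raise ValidationError("EC50 values must be positive")
        if self.n_hill < 1 or self.prime_hill < 1:
            raise ValidationError("Hill coefficients must be >= 1")
        for name in ("n_max", "k0", "k_ca", "prime_gain", "c_rest", "delta_c_ap",
                     "tau_clear", "j_trpc", "async_gain", "mini_rate0", "q_mean",
                     "q_cv", "noise_sd", "egta_kappa", "sucrose_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.tau_clear <= 0 or self.dt <= 0:
            raise ValidationError("tau_clear and dt must be positive")
        if self.tau_rise >= self.tau_decay:
            raise ValidationError("tau_rise must be smaller than tau_decay")
        if self.dt > 5e-4:
            raise ValidationError("integration step dt must be <= 0.5 ms")

    # -- derived quantities ------------------------------------------------

    @property
    def ca_scale(self) -> float:
        """Scaling of free-Ca2+ increments: 1/(1+kappa) under EGTA."""
        return 1.0 / (1.0 + self.egta_kappa) if self.egta_mode else 1.0

    @property
    def effective_delta_c(self) -> float:
        d = self.delta_c_ap * self.ca_scale
        if self.tea_mode:
            d *= self.tea_f_ca
        return d

    @property
    def effective_pr(self) -> float:
        p = self.p_r * (self.tea_f_pr if self.tea_mode else 1.0)
        return min(p, 1.0)

    @property
    def kernel_peak_time(self) -> float:
        r, d = self.tau_rise, self.tau_decay
        return r * d / (d - r) * math.log(d / r)

    @property
    def kernel_peak_factor(self) -> float:
        """Peak of exp(-t/tau_d) - exp(-t/tau_r); divides the kernel so a
        quantum of amplitude A peaks at A."""
        t = self.kernel_peak_time
        return math.exp(-t / self.tau_decay) - math.exp(-t / self.tau_rise)

    @property
    def quantal_charge_mean(self) -> float:
        """Mean charge of one quantum in pC (amplitude q_mean pA)."""
        return self.q_mean * (self.tau_decay - self.tau_rise) / self.kernel_peak_factor

    @property
    def true_rrp_charge(self) -> float:
        """RRP charge at rest: n_max * mean quantal charge (pC)."""
        return self.n_max * self.quantal_charge_mean


def tko_params(**kw) -> SimParams:
    """TRPC-deficient neuron: no Ca-activated TRPC entry."""
    return SimParams(j_trpc=0.0, **kw)


def trpc5_params(**kw) -> SimParams:
    """Strong TRPC5 expression: high Ca-activated Ca entry."""
    kw.setdefault("j_trpc", 7000.0)
    return SimParams(**kw)


def pure_depletion_params(**kw) -> SimParams:
    """Pure pool-depletion regime: no replenishment, no Ca-dependent release."""
    kw.setdefault("k0", 0.0)
    kw.setdefault("k_ca", 0.0)
    kw.setdefault("j_trpc", 0.0)
    kw.setdefault("async_gain", 0.0)
    kw.setdefault("mini_rate0", 0.0)
    return SimParams(**kw)


@dataclass
class GCaMPParams:
    """Forward model of the synaptically targeted fluorescent Ca2+ reporter."""

    kd: float = 700.0       # nM; chosen mid-range of simulated bulk Ca
    n_hill: float = 2.0
    f_rest: float = 100.0   # baseline fluorescence counts per pixel
    r_max: float = 5.0      # maximal fractional fluorescence increase
    photon_noise: bool = True


@dataclass
class CaTrace:
    """Bulk presynaptic [Ca]i (nM) on a uniform grid."""

    times: np.ndarray
    concentration: np.ndarray
    dt: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.times.shape != self.concentration.shape:
            raise ValidationError("times and concentration must match")
        if np.any(self.concentration < 0):
            raise ValidationError("calcium concentration must be >= 0")

    @property
    def duration(self) -> float:
        return self.times[-1] + self.dt


@dataclass
class GroundTruth:
    """Latent per-stimulus truths of one simulated experiment."""

    stim_times: np.ndarray            # train APs followed by recovery pulses
    n_train: int
    sync_quanta: np.ndarray           # vesicles released per stimulus
    occupancy: np.ndarray             # N(t) on the calcium grid
    async_rate: np.ndarray            # expected async rate (1/s) on the grid
    mini_rate: np.ndarray             # expected mini rate (Hz) on the grid
    async_times: np.ndarray           # sampled async event times (empty if det.)
    mini_times: np.ndarray            # sampled mini event times (empty if det.)
    repl_flux: np.ndarray             # replenishment flux (vesicles/s) on the grid
    true_rrp_charge: float            # pC
    true_pr: float
    true_replenishment_flux: float    # pC/s at the late-train steady state
    quantal_charge_mean: float        # pC
    protocol: Optional[StimulusProtocol] = None

    def __post_init__(self):
        if np.any(self.sync_quanta < -1e-9):
            raise ValidationError("released quanta must be >= 0")


# ---------------------------------------------------------------------------
# Closed-form utilities
# ---------------------------------------------------------------------------

def hill_activation(c, ec50: float, n: float):
    """Hill activation c^n / (c^n + ec50^n); fraction in [0, 1].

    ``c`` may be a scalar or array of concentrations (same units as ec50).
    """
    if ec50 <= 0:
        raise ValidationError("ec50 must be positive")
    if n < 1:
        raise ValidationError("Hill coefficient must be >= 1")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be >= 0")
    # c^n / (c^n + ec50^n) computed in log space to avoid overflow at small c
    with np.errstate(divide="ignore"):
        z = n * (np.log(np.maximum(c, 1e-300)) - math.log(ec50))
    out = np.where(c > 0, 1.0 / (1.0 + np.exp(np.clip(-z, -700, 700))), 0.0)
    return float(out) if out.ndim == 0 else out


def egta_capture_length(d_ca: float = 2.2e-6, tau_chel: float = 100e-6) -> float:
    """Mean Ca2+ diffusion distance before chelation, sqrt(6 D tau), in nm.

    ``d_ca`` is the Ca2+ diffusion coefficient in cm^2/s, ``tau_chel`` the
    chelation time constant in s.  With D = 2.2e-6 cm^2/s and tau = 100 us
    (about 1 mM EGTA) calcium travels ~363 nm before capture, i.e. well
    beyond typical active-zone dimensions.
    """
    if d_ca <= 0 or tau_chel <= 0:
        raise ValidationError("d_ca and tau_chel must be positive")
    r_cm = math.sqrt(6.0 * d_ca * tau_chel)
    return r_cm * 1e7  # cm -> nm


# ---------------------------------------------------------------------------
# Calcium dynamics
# ---------------------------------------------------------------------------

def _stimulus_times(protocol: StimulusProtocol) -> np.ndarray:
    """Train APs followed by any post-train recovery test pulses."""
    times = list(map(float, protocol.ap_times[: protocol.train_count]))
    if times and protocol.recovery_intervals:
        times.extend(map(float, protocol.recovery_times))
    return np.asarray(times)


def resting_calcium(params: SimParams) -> float:
    """Resting fixed point of the calcium ODE (nM).

    Solves C = c_rest + tau_clear * j_trpc_eff * Hill(C) by fixed-point
    iteration; in the monostable regime the map is a contraction.
    """
    j = params.j_trpc * params.ca_scale
    c = params.c_rest
    for _ in range(200):
        c_new = params.c_rest + params.tau_clear * j * hill_activation(
            c, params.ec50_trpc, params.n_hill
        )
        if abs(c_new - c) < 1e-10:
            return c_new
        c = c_new
    return c


def simulate_calcium(
    params: SimParams,
    protocol: StimulusProtocol,
    duration: Optional[float] = None,
) -> CaTrace:
    """Integrate bulk [Ca]i with fixed-step explicit Euler (deterministic).

    Each stimulus (train AP or recovery test pulse) increments C by the
    effective per-AP influx; drug windows labelled ``"EnglerinA"`` add a
    constant agonist-gated influx.  Raises :class:`NumericalError` if the
    trajectory diverges or goes negative (reduce ``dt``).
    """
    dt = params.dt
    if duration is None:
        duration = protocol.duration_needed() + 0.3
    if not math.isfinite(duration) or duration <= 0:
        raise ValidationError("protocol duration must be finite and positive")
    n = int(round(duration / dt))
    times = np.arange(n) * dt

    stim = _stimulus_times(protocol)
    stim_idx = np.round(stim / dt).astype(int)
    if np.any(stim_idx >= n):
        raise ValidationError("stimulus times extend beyond the simulated duration")
    increments = np.zeros(n)
    np.add.at(increments, stim_idx, params.effective_delta_c)

    drive = np.zeros(n)
    for label, a, b in protocol.drug_windows:
        if label.lower().startswith("englerin") and params.englerin_mode:
            i0, i1 = int(a / dt), min(int(b / dt), n)
            drive[i0:i1] += params.englerin_ca_influx * params.ca_scale

    j = params.j_trpc * params.ca_scale
    c0 = resting_calcium(params)
    conc = np.empty(n)
    c = c0
    inv_tau = 1.0 / params.tau_clear
    c_rest = params.c_rest
    ec50, nh = params.ec50_trpc, params.n_hill
    has_drive = bool(drive.any())
    # fast path: nothing perturbs calcium -> it stays at the fixed point
    if not stim.size and not has_drive:
        conc.fill(c0)
        return CaTrace(times=times, concentration=conc, dt=dt)
    inc = increments
    drv = drive
    ec50n = ec50 ** nh
    for i in range(n):
        c += inc[i]
        conc[i] = c
        cn = c ** nh if c > 0 else 0.0
        hill = cn / (cn + ec50n)
        c += dt * (-(c - c_rest) * inv_tau + j * hill + drv[i])
        if not (0.0 <= c < 1e7):
            raise NumericalError(
                "calcium integration unstable (reduce dt or influx rates)"
            )
    return CaTrace(times=times, concentration=conc, dt=dt)


# ---------------------------------------------------------------------------
# Vesicle-pool dynamics
# ---------------------------------------------------------------------------

def simulate_pool(
    params: SimParams,
    ca: CaTrace,
    protocol: StimulusProtocol,
) -> GroundTruth:
    """Evolve RRP occupancy against a calcium trace and draw release events.

    Deterministic mode propagates expectations (fractional quanta, release
    rates); stochastic mode samples binomial synchronous release and
    inhomogeneous-Poisson asynchronous/mini events with ``params.seed``.
    """
    stim = _stimulus_times(protocol)
    if stim.size and stim[-1] > ca.duration:
        raise ValidationError("calcium trace does not cover the protocol")
    det = params.deterministic
    if not det:
        if params.seed is None:
            raise ConfigurationError("stochastic simulation requires params.seed")
        rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0]))

    dt = ca.dt
    n = ca.times.size
    conc = ca.concentration
    c_ref = resting_calcium(params)
    stim_idx = np.round(stim / dt).astype(int)
    stim_set = {int(i): k for k, i in enumerate(stim_idx)}

    p_r = params.effective_pr
    k_ca_nm = params.k_ca / 1000.0  # 1/s per nM
    n_max = float(params.n_max)

    supra = np.maximum(conc - c_ref, 0.0)
    k_rep = params.k0 + k_ca_nm * conc
    n_cap = n_max * (
        1.0 + params.prime_gain
        * hill_activation(supra, params.prime_ec50, params.prime_hill)
    )

    occupancy = np.empty(n)
    async_rate = np.empty(n)
    sync_quanta = np.zeros(stim.size)
    async_times: list = []
    mini_times: list = []
    repl_flux = np.empty(n)  # vesicles/s entering the pool

    # fast path: no stimulation and no supra-resting calcium -> the pool
    # sits at capacity and only spontaneous minis occur
    if stim.size == 0 and (params.async_gain == 0 or not np.any(supra > 0)):
        occupancy.fill(n_max)
        async_rate.fill(0.0)
        repl_flux.fill(0.0)
        return _finish_ground_truth(
            params, ca, protocol, stim, sync_quanta, occupancy, async_rate,
            repl_flux, async_times, mini_times, supra,
            rng if not det else None,
        )

    N = n_max
    for i in range(n):
        if i in stim_set:
            k = stim_set[i]
            if det:
                released = N * p_r
            else:
                # stochastic rounding of the fractional occupancy keeps the
                # binomial expectation at N * p_r
                base = int(N)
                n_avail = base + int(rng.random() < (N - base)) if N > 0 else 0
                released = float(rng.binomial(n_avail, p_r))
            released = min(released, max(N, 0.0))
            sync_quanta[k] = released
            N -= released
        occupancy[i] = N
        a_rate = params.async_gain * supra[i] * max(N, 0.0) / n_max
        async_rate[i] = a_rate
        flux = k_rep[i] * (n_cap[i] - N)
        repl_flux[i] = max(flux, 0.0)
        consumed = 0.0
        if not det and a_rate > 0:
            n_ev = rng.poisson(a_rate * dt)
            n_ev = min(n_ev, int(max(N, 0.0)))
            if n_ev:
                t0 = ca.times[i]
                async_times.extend(t0 + rng.uniform(0.0, dt, n_ev))
                consumed = float(n_ev)
        elif det:
            consumed = min(a_rate * dt, max(N, 0.0))
        N += dt * flux - consumed

    return _finish_ground_truth(
        params, ca, protocol, stim, sync_quanta, occupancy, async_rate,
        repl_flux, async_times, mini_times, supra, rng if not det else None,
    )


def _finish_ground_truth(params, ca, protocol, stim, sync_quanta, occupancy,
                         async_rate, repl_flux, async_times, mini_times,
                         supra, rng):
    """Sample minis, summarise the replenishment flux and build the truth."""
    dt = ca.dt
    mini_rate = params.mini_rate0 + params.async_gain * supra * np.clip(
        occupancy, 0.0, None
    ) / params.n_max
    if rng is not None:
        counts = rng.poisson(mini_rate * dt)
        for i in np.nonzero(counts)[0]:
            mini_times.extend(ca.times[i] + rng.uniform(0.0, dt, counts[i]))

    # late-train replenishment flux (pC/s), averaged over the last 5
    # interstimulus intervals of the train
    q_charge = params.quantal_charge_mean
    if protocol.train_count >= 6:
        t_a = stim[protocol.train_count - 6]
        t_b = stim[protocol.train_count - 1]
        sel = (ca.times >= t_a) & (ca.times < t_b)
        flux_ss = float(np.mean(repl_flux[sel])) * q_charge
    elif repl_flux.size:
        flux_ss = float(np.mean(repl_flux)) * q_charge
    else:
        flux_ss = 0.0

    return GroundTruth(
        stim_times=stim,
        n_train=int(protocol.train_count),
        sync_quanta=sync_quanta,
        occupancy=occupancy,
        async_rate=async_rate,
        mini_rate=mini_rate,
        async_times=np.asarray(sorted(async_times)),
        mini_times=np.asarray(sorted(mini_times)),
        repl_flux=repl_flux,
        true_rrp_charge=params.true_rrp_charge,
        true_pr=params.effective_pr,
        true_replenishment_flux=flux_ss,
        quantal_charge_mean=q_charge,
        protocol=protocol,
    )


# ---------------------------------------------------------------------------
# Current rendering
# ---------------------------------------------------------------------------

def _quantal_kernel(params: SimParams, dt: float) -> np.ndarray:
    """Peak-normalised biexponential kernel sampled at dt, truncated at 8 tau."""
    t = np.arange(0.0, 8.0 * params.tau_decay, dt)
    k = np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise)
    return k / params.kernel_peak_factor


def render_current(
    truth: GroundTruth,
    params: SimParams,
    duration: float,
) -> CurrentTrace:
    """Forward model of the voltage-clamp recording.

    Every quantum contributes a peak-normalised biexponential kernel; the
    sign convention is inward-negative.  In deterministic mode synchronous
    quanta are placed at AP + latency with the mean quantal amplitude and
    asynchronous/mini release enters as its expected rate current; no noise
    is added.  In stochastic mode amplitudes are lognormal (mean ``q_mean``,
    CV ``q_cv``), release times are jittered, and Gaussian recording noise
    of SD ``noise_sd`` is added, all driven by ``params.seed``.
    """
    if params.tau_rise >= params.tau_decay:
        raise ValidationError("tau_rise must be smaller than tau_decay")
    dt = params.dt
    fs = 1.0 / dt
    n = int(round(duration / dt))
    det = params.deterministic
    if not det:
        if params.seed is None:
            raise ConfigurationError("stochastic rendering requires params.seed")
        rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 1]))
        sigma = math.sqrt(math.log(1.0 + params.q_cv ** 2))
        mu = math.log(params.q_mean) - 0.5 * sigma ** 2

    def draw_amps(count: int) -> np.ndarray:
        if params.q_cv == 0:
            return np.full(count, params.q_mean)
        return rng.lognormal(mu, sigma, count)

    impulses = np.zeros(n)

    # synchronous release
    for k, t_ap in enumerate(truth.stim_times):
        q = truth.sync_quanta[k]
        if q <= 0:
            continue
        if det:
            i = int(round((t_ap + params.sync_latency) / dt))
            if i < n:
                impulses[i] += q * params.q_mean
        else:
            m = int(round(q))
            t_ev = t_ap + params.sync_latency + rng.normal(0.0, params.sync_jitter, m)
            idx = np.round(t_ev / dt).astype(int)
            amps = draw_amps(m)
            ok = (idx >= 0) & (idx < n)
            np.add.at(impulses, idx[ok], amps[ok])

    # asynchronous + mini release
    if det:
        m = min(truth.async_rate.size, n)
        impulses[:m] += (truth.async_rate[:m] + truth.mini_rate[:m]) * dt * params.q_mean
    else:
        for times in (truth.async_times, truth.mini_times):
            if times.size:
                idx = np.round(np.asarray(times) / dt).astype(int)
                idx = idx[(idx >= 0) & (idx < n)]
                np.add.at(impulses, idx, draw_amps(idx.size))

    kernel = _quantal_kernel(params, dt)
    signal = fftconvolve(impulses, kernel)[:n]

    # direct agonist-gated current (smooth on/off ramps)
    metadata: dict = {"conditions": []}
    if params.egta_mode:
        metadata["conditions"].append("EGTA")
    if params.tea_mode:
        metadata["conditions"].append("TEA")
    if params.englerin_mode and truth.protocol is not None:
        t = np.arange(n) * dt
        for label, a, b in truth.protocol.drug_windows:
            if label.lower().startswith("englerin"):
                ramp = 1.0  # s
                env = 0.5 * (1 + np.tanh((t - a) / (ramp / 4))) * 0.5 * (
                    1 + np.tanh((b - t) / (ramp / 4))
                )
                signal = signal + params.englerin_amp * env
                metadata["conditions"].append("EnglerinA")
                metadata.setdefault("drug_windows", []).append([label, a, b])

    out = -signal
    if not det and params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, n)

    return CurrentTrace(samples=out, sampling_rate=fs, metadata=metadata)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def simulate_experiment(
    params: SimParams,
    protocol: StimulusProtocol,
    duration: Optional[float] = None,
):
    """Full forward model: calcium -> pool -> current trace.

    Returns ``(trace, ca, truth)``.  Identical (params, protocol, seed) give
    bit-identical outputs.
    """
    if duration is None:
        duration = protocol.duration_needed() + 0.3
    ca = simulate_calcium(params, protocol, duration)
    truth = simulate_pool(params, ca, protocol)
    trace = render_current(truth, params, duration)
    return trace, ca, truth


def simulate_minis(
    params: SimParams,
    duration: float = 60.0,
    protocol: Optional[StimulusProtocol] = None,
):
    """Spontaneous mEPSC recording (no evoked stimulation, TTX-like).

    ``protocol`` may carry drug windows (e.g. an Englerin A application);
    otherwise a silent protocol is used.  Returns ``(trace, ca, truth)``.
    """
    if protocol is None:
        protocol = StimulusProtocol(ap_times=np.asarray([]), train_count=0)
    return simulate_experiment(params, protocol, duration=duration)


def simulate_sucrose(
    params: SimParams,
    window: tuple = (0.5, 5.5),
    duration: float = 6.5,
) -> CurrentTrace:
    """Response to a 5-s hypertonic sucrose application.

    The pool empties at ``sucrose_rate`` while baseline replenishment k0
    refills it, producing a transient that decays to a steady-state
    replenishment-release plateau.  Release is rendered as its expected
    rate current (charge-exact); stochastic mode adds recording noise.
    """
    dt = params.dt
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    a, b = window
    N = float(params.n_max)
    flux = np.zeros(n)
    for i in range(n):
        if a <= t[i] < b:
            release = params.sucrose_rate * N
            flux[i] = release
            N += dt * (params.k0 * (params.n_max - N) - release)
        else:
            N += dt * params.k0 * (params.n_max - N)
    current = -flux * params.quantal_charge_mean  # pC/s == pA, inward negative
    if not params.deterministic and params.noise_sd > 0:
        if params.seed is None:
            raise ConfigurationError("stochastic rendering requires params.seed")
        rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 2]))
        current = current + rng.normal(0.0, params.noise_sd, n)
    return CurrentTrace(
        samples=current,
        sampling_rate=1.0 / dt,
        metadata={"sucrose_window": [a, b]},
    )


# ---------------------------------------------------------------------------
# Imaging forward model
# ---------------------------------------------------------------------------

def render_imaging(
    ca: CaTrace,
    n_synapses: int = 12,
    gcamp: Optional[GCaMPParams] = None,
    frame_rate: float = 5.0,
    seed: Optional[int] = None,
    shape: tuple = (64, 64),
    roi_size: int = 4,
    prestimulus_frames: int = 3,
):
    """Render a fluorescence stack reporting the simulated calcium.

    Synapse ROIs of ``roi_size`` x ``roi_size`` pixels are placed at random
    non-overlapping positions; their per-frame fluorescence is
    ``f_rest * (1 + r_max * Hill(C_frame))`` with the frame-averaged
    calcium, background pixels sit at ``f_rest``; Poisson photon noise is
    added when enabled.  Returns ``(stack, roi_origins)``.
    """
    if gcamp is None:
        gcamp = GCaMPParams()
    if frame_rate > 1.0 / ca.dt:
        raise ValidationError("frame_rate exceeds the calcium sampling rate")
    rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else int(seed), 3]))

    n_frames = int(ca.duration * frame_rate)
    per_frame = int(round(1.0 / (frame_rate * ca.dt)))
    c_frame = np.array([
        ca.concentration[i * per_frame: (i + 1) * per_frame].mean()
        for i in range(n_frames)
    ])

    rows, cols = shape
    cells_r, cells_c = rows // roi_size, cols // roi_size
    n_cells = cells_r * cells_c
    if n_synapses > n_cells // 2:
        raise ValidationError("too many synapses for the frame size")
    chosen = rng.choice(n_cells, size=n_synapses, replace=False)
    rois = [(int(c // cells_c) * roi_size, int(c % cells_c) * roi_size) for c in chosen]

    f_syn = gcamp.f_rest * (
        1.0 + gcamp.r_max * hill_activation(c_frame, gcamp.kd, gcamp.n_hill)
    )
    frames = np.full((n_frames, rows, cols), gcamp.f_rest, dtype=float)
    for fi in range(n_frames):
        for (r, c) in rois:
            frames[fi, r: r + roi_size, c: c + roi_size] = f_syn[fi]
    if gcamp.photon_noise:
        frames = rng.poisson(frames).astype(float)

    stack = ImagingStack(
        frames=frames,
        frame_rate=frame_rate,
        prestimulus_frames=prestimulus_frames,
    )
    return stack, rois
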