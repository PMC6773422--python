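# Methods

## Scope and design

`presyn` couples two halves: (i) an analysis suite implementing the
charge-based quantal workflow for high-frequency EPSC trains, spontaneous
mEPSCs, hypertonic-sucrose responses and presynaptic fluorescence stacks;
and (ii) a generative simulator of the same experiments with full access to
the latent state (pool occupancy, per-AP released quanta, event times,
calcium). The simulator exists to make the analysis testable: every
estimator is validated by parameter recovery against the generator's ground
truth, and the pharmacological switches reproduce the qualitative
short-term-plasticity contrasts the analysis should resolve. The simulator
is calibrated for direction and plausibility of effects, not to reproduce
any particular laboratory's absolute nA/pC magnitudes.

## Calcium model

Bulk (volume-averaged) presynaptic calcium follows

    dC/dt = −(C − c_rest)/τ_clear + j_trpc · H(C) + s(t),
    H(C) = Cⁿ / (Cⁿ + EC50ⁿ)

with an instantaneous increment ΔC_AP at every action potential (the
pooled effect of voltage-gated Ca²⁺ entry) and optional drug-gated source
terms s(t). The Hill term models a Ca²⁺-activated TRPC conductance: TRPC5
gating rises with submicromolar cytosolic calcium with EC50 ≈ 635 nM, so
VGCC-driven calcium opens TRPC channels whose influx further raises
calcium. This positive feedback amplifies the train-evoked transient and
slows its relaxation. Parameters are kept in the monostable regime
(j_trpc · max H′ < 1/τ_clear, i.e. j_trpc below ~9.7 µM/s at the default
τ_clear = 100 ms), so calcium always returns to its unique resting fixed
point after stimulation; the integrator refuses trajectories that go
negative or diverge.

Assumptions: a single well-mixed compartment (no nanodomains, no spatial
diffusion — the `egta_capture_length` utility √(6·D·τ) is a closed-form
estimate, not a PDE), linear clearance, and instantaneous TRPC gating.
Because gating is instantaneous, calcium *decays* monotonically (though
much more slowly) after the train rather than continuing to rise; a
reporter-level "post-train slope" in this model therefore measures
prolonged elevation, not continued influx.

## Vesicle pool

The readily releasable pool (RRP) holds N vesicles and refills between APs
as

    dN/dt = (k0 + k_ca·C) · (n_cap(C) − N),
    n_cap(C) = n_max · (1 + g · H(C − C_rest; EC50_prime, n))

Each AP releases Binomial(N, p_r) vesicles (expectation N·p_r in
deterministic mode, with stochastic rounding of fractional occupancy so the
expectation is exact). Asynchronous release is an inhomogeneous Poisson
process with rate `a·(C − C_rest)·N/n_max`; it consumes pool vesicles, so a
single ledger covers both release modes. Spontaneous minis share the
baseline-plus-calcium rate law but do not touch the pool.

The capacity term is the package's central modelling choice. A pure
depletion–refill pool bounded by n_max can only depress: occupancy never
exceeds its resting value, so Amp₁₀/Amp₁ ≤ 1 always. The observed switch
to short-term *enhancement* under strong Ca²⁺-dependent vesicle supply
requires transient overfilling of the pool; we represent this as a
capacity that grows with supra-resting calcium (Ca²⁺-dependent priming of
normally reluctant vesicles). At resting calcium n_cap = n_max exactly, so
the plain depletion model — and with k0 = k_ca = 0 the closed-form
geometric depletion n_max·p_r·(1−p_r)^(k−1) — is recovered, and the pool
is stationary at rest (the rest-stability tests hold to < 1% over 60 s).

## Pharmacological modes

- **EGTA** (slow chelator loading): all free-calcium increments — the
  per-AP step, the TRPC influx and any agonist influx — are scaled by
  1/(1+κ) with buffering capacity κ = 9 by default. Phasic (per-AP)
  release is untouched, since EGTA is too slow to intercept local
  nanodomain calcium; only the bulk signal and everything driven by it
  (asynchronous release, Ca²⁺-dependent refilling, overfilling) collapse.
- **TEA** (K⁺-channel block, AP broadening): multiplies the per-AP calcium
  increment by f_Ca = 1.2 and the release probability by f_pr = 5/3. The
  factors were chosen so the release-probability increase outweighs the
  replenishment boost from extra bulk calcium: the net phenotype is a
  larger first EPSC, a lower paired-pulse ratio and deeper depression,
  alongside increased asynchronous release and replenishment. With a much
  larger f_Ca the bulk-calcium boost would invert the depression
  direction, which is not how AP broadening behaves — its extra calcium
  acts mainly at the release face.
- **Englerin A** (TRPC agonist): a direct inward current with smooth
  on/off ramps plus a constant calcium influx during the application
  window, raising the mini rate through the shared calcium-dependent term.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| n_max | 100 | vesicles | typical cultured-synapse RRP scale |
| p_r | 0.3 | – | hippocampal per-vesicle release probability |
| k0 | 0.2 | s⁻¹ | slow Ca-independent refill (~5 s recovery) |
| k_ca | 20 | s⁻¹·µM⁻¹ | calcium-accelerated refill, ~10× k0 at train calcium |
| g (overfill gain) | 4 | – | max ~5× capacity at saturating calcium |
| EC50 (TRPC and priming) | 635 | nM | TRPC5 calcium activation midpoint |
| n (Hill) | 2 | – | unspecified by the activation data; configurable |
| c_rest | 50 | nM | resting [Ca]ᵢ |
| ΔC_AP | 100 | nM | per-AP bulk increment; 20-Hz plateau ≈ 250–300 nM |
| τ_clear | 0.1 | s | residual-calcium clearance |
| j_trpc | 2000 (wt) / 0 (tko) / 7000 (strong TRPC5) | nM/s | spans depression → enhancement while staying monostable |
| async_gain | 0.2 | s⁻¹·nM⁻¹ | late-train async ≈ 10–15% of synchronous charge |
| mini_rate0 | 1.5 | Hz | spontaneous rate in TTX |
| q_mean, q_cv | 25 pA, 0.3 | | lognormal quantal amplitudes; mean charge ≈ 135 fC |
| τ_rise, τ_decay | 0.5, 4 | ms | AMPA-receptor quantal kinetics |
| noise_sd | 4 | pA | whole-cell recording noise |
| dt | 0.1 | ms | explicit Euler step (see Numerics) |

Defaults were fixed once against the qualitative phenotype battery (the
depression→enhancement sweep and the EGTA/TEA contrasts) and are not meant
as measurements of any particular preparation.

## Analysis conventions

- Sign: traces store inward currents negative; all reported amplitudes and
  charges are positive magnitudes (nA, pC, fC).
- Charges integrate over each interstimulus interval `[t_k, t_{k+1})`; the
  asynchronous component is the steady-state current over the final 5 ms
  of the interval (long enough for the 4-ms quantal decay to die off at
  20 Hz) times the interval.
- Amplitudes are measured after a 1-ms artifact blank against a *local*
  1-ms pre-stimulus baseline (handles summation during trains); a
  pre-train global baseline is available by configuration.
- Both late-train regressions default to the last 5 cumulative points
  (4 is a documented alternative); every result logs the span used.
- The back-extrapolated RRP is only trusted when the late train is
  stationary: mean synchronous charge over stimuli 36–40 within 15% of
  stimuli 31–35. Negative intercepts are reported as undefined (NaN, with
  the intercept kept in the diagnostics), never clamped — clamping would
  bias group summaries toward zero.
- Amp₁₀/Amp₁ exactly 1 classifies as STD; enhancement is strictly > 1.
- Mini detection reproduces the two published criteria (5 × noise SD,
  > 25 fC) around a smoothed-derivative onset detector; the charge
  integration window (onset until return within 1 noise SD of the local
  baseline, capped at 50 ms) is our choice, as is the 2-ms refractory
  merge of overlapping candidates. Baseline noise is the MAD-based robust
  SD of the detrended trace outside detected events.
- Recovery fits run from three τ starts (0.1, 0.5, 2 s); flat data return
  k_off = mean, EPSC_∞ = 0 and an explicit "τ not identifiable" flag.
- Imaging slopes use 1-based data-point indices into the full acquired
  5-Hz series (including the 3 prestimulus frames), points 6–13 during
  and 14–20 after the 2-s train; whether such indices should instead count
  from stimulus onset is genuinely ambiguous, so the ranges are
  configurable.
- The imaging background SD is measured on ROI-sized background tiles
  over the prestimulus frames — the only epoch guaranteed signal-free —
  and rescaled by √((p+1)/(p−1)) for p prestimulus frames, because frames
  that enter F₀ have deflated ΔF/F₀ variance (1 − 1/p per frame) while the
  post-stimulus frames being thresholded have inflated variance (1 + 1/p).
  Without this correction the 3-SD responsiveness rule false-alarms at
  several times its nominal rate.

## Numerics

Fixed-step explicit Euler at dt = 0.1 ms for both calcium and pool ODEs;
all time constants are ≥ 10 ms, two orders above the step, and steps above
0.5 ms are rejected. Rendering convolves per-sample release impulses with
the peak-normalised biexponential kernel by FFT; quantal charge has the
closed form A·(τ_d − τ_r)/g_max with g_max the kernel peak factor, which
the tests check against numerical integration. All randomness flows from a
single user seed through named `SeedSequence` children (pool sampling,
rendering, sucrose noise, imaging), so identical inputs give bit-identical
traces and stacks.

## What the generator does and does not emulate

It emulates: train stimulation with depression or enhancement, synchronous
/ asynchronous charge structure, post-train recovery including transient
augmentation, Poisson minis with drug epochs, sucrose pool release with a
replenishment plateau, and reporter stacks with Poisson photon noise. It
does not emulate: conductance-based AP or VGCC biophysics, spatial calcium
diffusion, receptor desensitisation/saturation, series-resistance or
dendritic filtering artifacts, imaging bleaching or motion. Passing the
recovery benchmarks therefore shows the estimators are correct for data
matching these statistics, not that they are robust to every failure mode
of real recordings.

The fluorescence forward model uses a mid-affinity reporter (Kd = 700 nM,
n = 2) rather than a literal GCaMP6s Kd (~140 nM): at the simulator's bulk
calcium scale (50 → ~600 nM) a 140-nM sensor saturates during the train
and would flatten the during-train slope that the imaging metrics are
meant to resolve. Gain-type parameters (f_rest, r_max) cancel out of ΔF/F₀
by construction.

## Known limitations

- The back-extrapolation RRP estimator is biased low whenever
  replenishment accelerates during the train (by design it assumes a
  constant late-train refill rate); on strongly enhancing cells the
  intercept can be negative, which is reported as undefined. This mirrors
  the practice of restricting the estimator to cells that reach a
  steady-state response.
- Deterministic (expectation) mode renders asynchronous and mini release
  as their smooth rate current, so mini detection is only meaningful on
  stochastic traces.
- Recovery test-pulse fractions can be non-monotone in time when the pool
  transiently overfills after the train (augmentation followed by
  relaxation); the single-exponential fit is then a summary, not a
  mechanistic description.
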