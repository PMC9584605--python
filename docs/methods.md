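# Methods

This note documents the models, estimators, numerical choices and known
limitations of `stpkit`.

## Kinetic schemes of vesicle priming and release

Both schemes describe a fixed number `N_total` of release sites whose
occupancy states interconvert by first-order kinetics; the total site
count is conserved exactly by the model and to integrator tolerance by the
implementation (asserted at 10⁻⁶·`N_total` in the test suite).

**Single pool.**  Sites are empty (`N_e`) or occupied by a docked, primed,
fusion-competent SV (`N_o`):

    dN_o/dt = k_f(t)·N_e − k_b·N_o,   N_total = N_e + N_o

The backward (unpriming) rate `k_b` is constant; the forward (priming)
rate depends on the effective cytosolic [Ca²⁺] through a
Michaelis–Menten-like saturation

    k_f = (k_f,rest + σ·ΔCa) / (1 + ΔCa/K₀.₅),  ΔCa = [Ca²⁺] − [Ca²⁺]_rest

(`σ` in s⁻¹µM⁻¹, `K₀.₅` in µM measured above rest; both are user-facing in
µM and converted internally, where time is in seconds, concentrations in
nM and rates in 1/s).  At rest `k_f = k_f,rest`; the high-Ca²⁺ limit is
`σ·K₀.₅`.  The resting state is analytic: `N_o = N_total·k_f/(k_f+k_b)`
at basal [Ca²⁺].

**Sequential two-step.**  Empty sites (ES) accept SVs into a loosely
docked state (LS) which reversibly tightens into the fusion-competent
tightly docked state (TS): ES ⇌ LS ⇌ TS with Ca²⁺-dependent forward rates
`k₁`, `k₂` (same saturating form) and fixed backward rates `b₁`, `b₂`.
Only TS vesicles fuse.  The resting state is the unique steady state of
the linear chain, solved as a constrained linear system (which also
handles irreversible limits `b₁ = 0` or `b₂ = 0`).

**Effective calcium.**  [Ca²⁺] is a phenomenological *effective*
concentration driving priming, not a spatial model: it jumps by a constant
`delta_ca_ap` at each AP and decays mono-exponentially to the 50 nM
resting value with rate `k_Ca`.  The constant per-AP increment (linear
summation during trains) is the simplest scheme consistent with an
instantaneous rise; saturation or facilitation of the increments is not
modelled.

**Release probability.**  `P_r,j = P_r,1 · y_j^4.5 · z_j` with `y, z`
initialised to 1 at train onset.  Order of operations at the j-th AP:

1. evaluate `P_r,j` from the current `(y_j, z_j)`;
2. compute release from the pool immediately before the AP —
   deterministic (mean-field): `m_j = P_r,j · pool_j`; stochastic:
   `m_j ~ Binomial(round(pool_j), P_r,j)`;
3. move the released SVs to the empty state (vacated sites are
   immediately available for docking);
4. apply the [Ca²⁺] increment (it therefore accelerates priming during
   the *following* interval; P_r facilitation is carried entirely by `y`);
5. increment `y ← y + y_inc1·(y_max − y)`, decrement
   `z ← z − z_dec1·(z − z_min)`;
6. relax `y`, `z` exponentially toward 1 (closed form) and integrate the
   occupancy ODE to the next AP.

If the product form exceeds 1 (possible for extreme parameters), `P_r` is
clipped at 1 with a logged warning.

**Integration.**  [Ca²⁺], `y` and `z` have closed forms between APs; only
the occupancy ODE (with its time-varying forward rates) is integrated
numerically, using an adaptive embedded Runge–Kutta 4(5) scheme
(`scipy.integrate.solve_ivp`, rtol 10⁻⁸ / atol 10⁻¹⁰).  AP events are
handled by exact segmentation — each inter-AP interval is one integration
segment — so no event detection is needed.  Deterministic mode treats
occupancies as continuous mean-field quantities; stochastic mode
discretises only the release step, keeping inter-AP kinetics mean-field.
The mean of ≥1000 stochastic trains matches the deterministic train
within Monte-Carlo error.

## Quantal estimators

All three estimators consume per-stimulus amplitude vectors (nA, or SV
counts when the quantal size `q` is 1).

**EQ (initial-slope regression).**  Amplitude `a_j` is regressed on the
cumulative amplitude released before stimulus `j` over the first
`n_points` stimuli (default 4, configurable 3–6; EQ is only valid on the
near-linear initial depletion segment).  RRP = x-intercept; `P_r` is
reported as `a₁/RRP`, which for a pure depletion train equals the
negative slope.  A non-negative slope (no depression) is an error, not an
estimate.  On trains with replenishment EQ overestimates the resting
pool; only the sign of that bias is guaranteed.

**SMN (back-extrapolation).**  A straight line through the last
`ss_window` (default 10) points of the cumulative plot, extrapolated to
stimulus 0.  The uncorrected intercept contains replenishment accrued
before steady state.  The corrected variant reconstructs pool occupancy
under the current RRP estimate, assigns each inter-stimulus interval a
refill `s·v_j/v_ss` (`s`: steady-state slope; `v_j`: pool vacancy after
stimulus `j`; `v_ss`: steady-state vacancy — so refill equals `s` at
steady state and scales with vacated sites before it), subtracts the
accumulated refill from the cumulative plot and re-fits, iterating to
convergence (≤10 iterations, tolerance 10⁻⁶).  Both modes are exposed;
on simulated trains the corrected estimate is closer to the true resting
pool but still biased low.

**NpRf.**  Bounded least-squares fit (multi-start over a `p × R` grid) of
the three-parameter recursion

    a_j = p·n_j,  n_{j+1} = n_j − a_j + R·(N − (n_j − a_j))

pool `N`, release fraction `p`, per-interval refill fraction `R` of
vacated sites.  Self-consistency (data generated by the recursion) is
recovered to optimizer tolerance; `R = 0` reduces to geometric depletion
and reproduces the EQ slope.

**Train metrics.**  PPR = EPSC₂/EPSC₁; steady state = mean of the last 10
stimuli of a 50-stimulus train; depression ratio = EPSC_ss/EPSC₁.

**Effective EPSC duration** = charge/amplitude (pC/nA = ms): the width of
the square pulse with the same charge and peak, a release-synchronicity
proxy (valid as such only if mEPSC kinetics are unchanged).

**EPSC onset delay.**  A Boltzmann sigmoid `A/(1+exp((t₅₀−t)/k))` is
fitted to the rising flank; onset is the extreme-curvature point of its
leading edge, `t_onset = t₅₀ − k·ln(2+√3)`.  "Curvature" is the extremum
of the second *time*-derivative, which is unit-independent; geometric
curvature of a current-vs-time plot would depend on the axis scaling and
is not used.  Traces of either polarity are accepted (the curvature point
of the normalised sigmoid is amplitude- and sign-invariant).

## Recovery analysis

Fractional recovery of a test EPSC after a conditioning train is
`(EPSC_test1 − EPSC_cond,ss) / (EPSC_cond1 − EPSC_cond,ss)`; overshoot
above 1 is allowed.  Recovery time courses are fitted with
`A(1−e^(−t/τ))` and `A(1−(f·e^(−t/τ₁)+(1−f)·e^(−t/τ₂)))` by multi-start
nonlinear least squares (τ₁ ∈ {10, 50, 200} ms, τ₂ ∈ {0.5, 2, 5} s,
f ∈ {0.2, 0.5, 0.8}, A from the last data point; best RSS wins — the
bi-exponential surface is multimodal).  The nested-model F-test
`F = ((RSS_mono−RSS_bi)/2)/(RSS_bi/(n−4))` selects the bi-exponential
model at p < 0.05 unless a model is forced.  Fits are unweighted (no
per-point SEM weighting).  The weighted time constant is the
amplitude-fraction-weighted arithmetic mean
`τ_w = (1−f_slow)·τ_fast + f_slow·τ_slow`; published component/τ_w sets
are reproduced at printed precision by this definition except one case
that differs by one rounding unit (consistent with rounding of underlying
per-fit values), which is therefore not used as a reference value.
Synthetic recovery experiments use a logarithmic interval grid, default
12 points from 20 ms to 16 s.  At 2% amplitude noise the fit is unbiased:
the 100-replicate mean of every parameter is within 5% of truth, while
single-replicate scatter of the fast component (τ₁, f) exceeds 10% — an
identifiability property of bi-exponentials, not an implementation limit.

## Event analysis

**mEPSC detection.**  Baseline mean/SD come from an event-free window
(default: first 100 ms).  Samples deviating by more than
`baseline_sd_mult`·SD (default 5, admissible 4–6) in the chosen polarity
(default inward/negative) form candidate regions; candidate peaks closer
than `min_separation` with no return toward baseline between them (valley
above half threshold) are fragments of one event and are merged;
remaining peaks closer than `min_separation` are *overlapping events* and
all members are excluded.  Frequency = retained events / trace duration.
Event metrics: amplitude relative to a local median baseline, 10–90% rise
time and FWHM by linear interpolation; on the rising flank the *last*
crossing before the peak is used (noise can graze low levels much
earlier).

**Spike timing.**  Stimulus→AP matching is greedy-earliest within a 2 ms
window (calyceal delays are ~0.1–0.7 ms; 2 ms separates adjacent 500 Hz
stimuli); each AP is consumed once.  Jitter is the SD of delays over
successes.  Preceding activity of an AP is the sum of `exp(−Δt/τ)` over
earlier APs, τ = 30 ms by default (10 and 100 ms give qualitatively
similar rankings and are exposed).  Binned summaries use half-open
`[left, right)` bins so results are bit-reproducible.

## Synthetic data

Generators emulate: regular 50-AP trains at 50/500 Hz; paired
conditioning/test protocols over 20 ms–16 s; Gaussian amplitude noise on
trains; mEPSC traces as homogeneous Poisson events with bi-exponential
kernels (default rise 0.1 ms, decay 0.5 ms, −0.05 nA, 50 kHz sampling)
plus Gaussian noise; SAM-like spike patterns as inhomogeneous Poisson
processes, intensity `r·(1+depth·sin(2πf_m t))` with f_m ∈ [20, 2000] Hz,
generated by thinning with a 1 ms refractory period; and ground-truthed
AP responses whose delay grows linearly with kernel-weighted preceding
activity.  All generators are deterministic given their seed and emit
their ground truth alongside the data.

What they do *not* capture: correlated recording noise and drift,
series-resistance artefacts, quantal-size variability, receptor
saturation/desensitisation, and real in-vivo SAM spike templates (the
parametric surrogate only reproduces the high/low-activity interleaving
that the timing analyses exploit).  Passing tests therefore validate the
estimators' numerics and their behaviour under the models' own
assumptions, not robustness to every artefact of experimental data.

## Calibration

The objective is a weighted sum over datasets (50 Hz train, 500 Hz train,
fractional recovery) of mean squared *relative* errors — amplitude scales
differ severalfold between conditions and frequencies, so absolute errors
would let one dataset dominate.  Default weights are equal; missing
datasets are skipped with a warning.  Parameters are fitted per condition
or *shared* (single optimisation variable for all conditions — shared
values are identical across conditions by construction, mirroring
constraints such as the two-step scheme's common `P_r` and `N_total`
across phenotypes).  Optimisation is derivative-free bounded Nelder–Mead
from Latin-hypercube starts (the simulator is piecewise-smooth; no
gradients are provided); the best local optimum wins, bound-touching
solutions are flagged, and the whole procedure is deterministic given the
seed.  The parameter-recovery tests use two conditions with 15-AP trains
at 50 and 500 Hz, 8 starts and ≤300 function evaluations per start, which
recovers shared (P_r, N_total) to ≪5% and condition-specific priming
rates to ≪10% on noiseless targets in a few CPU-minutes.

## Shipped default calibrations

The defaults in `stpkit.defaults` are calibration products of this
package.  Anchors: control P_r = 0.08 with resting RRP 2150 SVs; mutant
(Rac1-deficient-like) P_r = 0.165 with RRP 2532 SVs; quantal sizes chosen
so the first EPSCs are ~1.3 and ~3 nA.  Effective-Ca²⁺ and P_r dynamics
are shared between phenotypes (increment 200 nM/AP, decay 50 s⁻¹;
`y_inc1` 0.035, `y_max` 2, `k_y` 50 s⁻¹, `z_dec1` 0.02, `z_min` 0.5,
`k_z` 2 s⁻¹).  The mutant priming rate is larger at sub-µM effective
[Ca²⁺] but saturates faster (smaller `σ·K₀.₅`), which makes the 50 Hz
steady state clearly larger in the mutant while the 500 Hz steady state —
replenishment-limited in both phenotypes — stays similar, and which,
combined with the stronger pool depletion at P_r = 0.165, removes
paired-pulse facilitation at 500 Hz.  The two-step defaults share `P_r`
(0.15) and `N_total` (3000) across phenotypes (resting TS pools 691 vs
1667 SVs) and differ only in priming-step kinetics; their facilitation
parameter (`y_inc1` 0.042) is calibrated separately from the single-pool
scheme.  In the two-step control the strong Ca²⁺-dependence of `k₂`
slightly overfills TS between 50 Hz stimuli, so the control 50 Hz train
ends marginally above its first EPSC — a known cosmetic limitation of
this calibration, not of the scheme.

## Problem sizes and tolerances used in the test suite

Conservation and steady-state checks run 50-AP trains at 500 Hz
(tolerances 10⁻⁶·`N_total` and 10⁻⁶ relative).  Stochastic/deterministic
agreement uses 1000 repetitions of a 10-AP train (3 SE).  The
bi-exponential noise study uses 100 replicates on a 16-point grid.  The
calibration recovery experiment uses the sizes stated above.  These sizes
were chosen so the full suite completes in a few minutes while leaving
every statistical criterion well-powered.

## Known limitations

* The effective-[Ca²⁺] build-up is linear in AP count; saturating
  summation would change high-frequency priming kinetics.
* No spatial Ca²⁺ diffusion, VGCC coupling, AP-waveform or
  endocytosis/site-clearance model.
* The SMN correction reproduces the *intent* of the published correction
  (replenishment scales with vacancy); the original's exact formula is
  not public, so corrected values are comparable in spirit, not digit
  by digit.
* Deterministic simulations are mean-field; binomial noise enters only at
  release events, so stochastic trains underestimate fluctuations caused
  by stochastic priming between APs.
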