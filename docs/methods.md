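# Methods

## Model and units

A single particle diffuses in 2D under an analytic potential, a Langevin
thermostat, and (optionally) a metadynamics bias. Potentials are expressed
in units of k_BT at 300 K with lengths in Å; the integrator is the only
place where mechanical units appear, via
k_BT = 2.494×10⁻⁴ g·Å²·fs⁻²·mol⁻¹ at 300 K. Forces in k_BT/Å are multiplied
by that constant before entering the equations of motion.

Two landscapes are built in:

- `two_wells`: V = A₁x² + A₂y² + B·exp(−Cx²) with A₁ = 10⁻³, A₂ = 10⁻²,
  B = 5, C = 1.3. A Gaussian ridge of ~5 k_BT (independent of y) splits a
  soft harmonic trap; the analytic minima are at x = ±2.599 Å. Trajectories
  start at (3, 0) Å — the conventional label of the right state rather than
  the exact stationary point — and stop at x ≤ −3 Å.
- `faradjian_elber`: V = A₁(x⁶ + y′⁶) + A₂·exp(−x²/σ₁²)[1 − B·exp(−y′²/σ₂²)]
  with y′ = 0.1y, A₁ = 1.2×10⁻⁵, A₂ = 12, B = 0.75, σ₁ = 1, σ₂ = 0.5.
  The ridge at x = 0 is ~12 k_BT for most y but only ~3 k_BT through the
  narrow saddle at y = 0, so the x-coordinate alone hides the gateway
  coordinate. Start (3, 0) Å, stop x < −1 Å.

Barrier summaries locate section minima/maxima by a dense 10⁻³ Å scan plus
bounded Brent refinement; with several interior maxima the highest one
between the outermost minima is reported.

## Integrator

BAOAB splitting (half kick, half drift, exact Ornstein–Uhlenbeck velocity
update with friction γ, half drift, half kick) at dt = 1 fs, γ = 0.01 fs⁻¹,
m = 40 g/mol. BAOAB was chosen for its superior configurational accuracy at
finite time step; the integrator identity is a package choice and the
dynamics are validated against discretization-independent oracles:
equipartition of position and velocity variances in a harmonic well,
the Einstein relation MSD = 2Dt with D = k_BT/(mγ) for a free particle,
and Boltzmann position statistics (χ²). Initial positions are fixed
(delta-distributed); initial velocities are Maxwell–Boltzmann. The stop
criterion is evaluated every step, the finest unambiguous convention.

Each trajectory draws from three independent Philox streams (thermal noise,
velocity initialization, reset times) spawned from one seed, so enabling
resetting does not perturb the noise sequence. Ensemble runs spawn
per-trajectory seeds from a base `SeedSequence`, making every trajectory
individually reproducible and all outputs bit-reproducible for a fixed
(config, seed).

## Resetting

Poisson resetting pre-samples the next reset time from Exp(r) and rounds it
up to a whole step; sharp resetting uses a fixed period. At a reset the
position returns to the start, velocities are redrawn, the metadynamics
bias (grid, hill log, and well-tempered history) is zeroed, and the
hill-deposition clock restarts; the first-passage clock keeps running. If a
first passage and a reset coincide on a step, the first passage wins. The
first-passage time is the total elapsed time across all resets.

## Well-tempered metadynamics

The CV is the linear projection s = x·cosθ + y·sinθ; θ = 0 is the optimal
CV of both models and rotations emulate suboptimal CVs (sinθ up to 0.407,
i.e. ~24°). Defaults follow the published setup: height 0.5 k_BT, bias
factor γ_B = 10, grid spacing 0.01 Å, σ = 1.3 Å (two wells) or 0.15 Å
(Faradjian–Elber); hill heights are scaled by exp(−V_b(s)/((γ_B−1)k_BT))
with V_b taken at the new centre at deposition time. A deposition "rate" in
hills/ns maps to pace = round(10⁶/(rate·dt)) steps (10⁴ ns⁻¹ ↔ every 100
steps).

Each hill adds its closed-form Gaussian to an energy grid and its
closed-form derivative to a parallel dV/ds grid, so force queries are O(1)
linear interpolations of the *analytic* hill-derivative sum — no finite
differencing of the energy grid, and interpolation error is bounded by
h·(Δgrid/σ)² ≈ 3×10⁻⁵ k_BT at the defaults. Hills are truncated at 6σ
(relative error < 2×10⁻⁸).

Default grid bounds are ±400 Å. This is deliberately far wider than the
±50–60 Å excursions of unbiased walkers: the tempered bias flattens the
soft trap ~γ_B-fold, and a small fraction of trajectories (~0.3% at the
fastest pace) "surf" their own bias wall to beyond 100 Å. A walker whose CV
still leaves the grid terminates with a distinct censoring code (`3`,
grid exit) and is reported and excluded from moment statistics, like
max-step censoring (default cap 10⁹ steps; sweep drivers use 10⁸). Both
censored counts appear in every summary, so silent loss is impossible.

## First-passage statistics

MFPT, standard deviation, SEM = std/√N and COV = std/MFPT are computed over
uncensored samples; the population convention (ddof = 0) keeps the COV of
an exponential at exactly 1 (switchable to ddof = 1). The MFPT under
Poisson resetting at rate r is predicted from resetting-free samples by the
renewal identity ⟨τ⟩_r = (1 − f̃(r))/(r·f̃(r)) with the empirical Laplace
transform f̃(r) = N⁻¹Σe^{−rτⱼ}; r = 0 is evaluated as the analytic limit
(the sample mean), and f̃ underflow raises rather than returning garbage.
Speedups are ratios of mean first-passage steps with delta-method SEMs.
The optimal-rate search evaluates a 32-points-per-decade log grid
(10⁻²–10⁴ ns⁻¹ by default) and refines the argmax by golden-section search
to 1% in rate; ties break to the smallest rate, and r* = 0 with speedup 1
is returned when no resetting helps. Censored samples are rejected by the
Laplace-transform operations — the estimator assumes complete first
passages; censored data belong to the survival pipeline below.

## Kinetics inference

Between resets a trajectory is an ordinary infrequent-MetaD segment, and
because the bias is zeroed at each reset, segments are independent. Each
segment accumulates the exposure integral τ* = Σ dt·exp(V_bias(s(t),t)/k_BT)
(the standard iMetaD acceleration factor; the exponent is clipped at 700 to
guard overflow). Segments ending by reset are right-censored at their τ*.
The survival of the rescaled times is estimated by the Kaplan–Meier
product-limit (via lifelines; events precede censorings at ties), and
S(t) = e^{−kt} is fitted by weighted least squares of ln S through the
origin, weighted by per-time event counts, on a short-time window — by
default from just above 0 up to where the number at risk falls below 20% of
all segments, the regime where over-deposition has not yet distorted the
rescaling. The fit reports R² and a Kolmogorov–Smirnov-style score
(1 − sup|S_KM − e^{−kt}|), both clipped to [0, 1]; a survival plateau from
an unreachable sub-population degrades both. Discarding censored segments
instead of product-limit weighting is available as a sensitivity switch.
The prediction error of an estimate is |⟨τ⟩_true − ⟨τ⟩_est|/⟨τ⟩_true.

`tradeoff_scan` maps the speedup-vs-error tradeoff: one branch lowers the
bias deposition rate without resetting, the other keeps the fastest rate
and shortens a sharp-resetting period.

Validity note: with the optimal CV, plain iMetaD rescaling reproduces the
unbiased FPT distribution at deposition rates ≲5 hills/ns on the two-wells
model (two-sample KS p ≈ 0.4 at 100/100 trajectories); at 20 hills/ns the
rescaled mean already overshoots ~2× — over-deposition sets in well below
the fastest pace used for sampling speedups, which is exactly the regime
the resetting-segmented inference is for.

## Synthetic ensembles

The statistics layer is exercised without simulation by seeded draws from
families with closed-form mean and COV: exponential (COV 1, invariant under
resetting), deterministic (COV 0, always slowed by resetting — the two
closed-form anchors of the renewal predictor), lognormal (finite interior
optimal rate when broad), and a two-exponential mixture (COV > 1; its
optimal rate diverges, since instant restarts exploit the fast component —
useful as a positive-slope case, not an argmax test). These emulate FPT
*samples* only; they carry none of the dynamics' features (no censoring
structure, no bias correlation), so tests built on them validate the
estimators, not the simulator.

## Scale choices

Test-suite and acceptance runs use hundreds of trajectories per condition
(baseline 800, COV ensembles 500, sweep points 200–300) against the
original study's 10⁴; all assertions use statistics-aware tolerances
(±20–25% or 3 combined/bootstrap SEM). Resetting-rate sweeps use fixed
log-ish grids — {5, 10, 25, 50, 70, 100, 200, 500} ns⁻¹ (resetting only)
and {30, 60, 125, 250, 500} ns⁻¹ (MetaD+SR) — bracketing the reported
optima; argmax values are therefore grid-resolved to roughly a factor of
√2–2. At this scale the unbiased two-wells MFPT comes out at 6.7–8.0 ns
across seeds (reference value 7.5 ns); speedup ratios inherit that
baseline's ~4% SEM.

## Known limitations

- Single particle, 2D, analytic potentials only; no solvent, constraints,
  or periodic boundaries.
- One linear CV; no multi-CV bias, adaptive widths, or OPES.
- No free-energy-surface reconstruction — reweighting under resetting is an
  open problem and deliberately out of scope.
- The exponential-survival inference assumes single-exponential kinetics;
  the R²/KS scores flag violations but the estimator does not model
  multi-state kinetics.
- Grid-exit ("surfing") censoring slightly truncates the extreme right tail
  of MetaD first-passage ensembles at the fastest deposition pace; the
  effect is sub-percent on the MFPT at the default ±400 Å bounds.
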