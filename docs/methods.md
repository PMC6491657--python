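# Methods

## Model

Cortisol concentration C(t) (μg/100 ml; time in minutes) obeys a scalar
constant-delay differential equation

    dC/dt = k1 · aⁿ C_d / (aⁿ + C_dⁿ) − k2 · C,      C_d = C(t − d),
    a(t)  = α cos((t − t_f)·2π/1440) + β,

a Hill-type secretion flux gated by the delayed concentration and modulated
by a 24-h cosine drive, plus first-order elimination.  Nominal constants:
k1 = 0.0666/min, k2 = 0.0333/min, α = 0.7 and β = 1 μg/100 ml, t_f = 250 min,
d = 70 min, n = 10.  The switch exponent n sets burst sharpness: values
below ~5 do not oscillate, values above ~20 destabilize; n = 10 gives the
physiological picture of roughly one secretion burst per delay period
(12–30 local maxima per cycle at 1-min sampling).  The trajectory is chaotic:
nearby parameter sets decorrelate within one to two cycles, which is what
defeats gradient-based least squares and motivates the observer approach.

Simulations start at t = 0 with a constant history C ≡ 1.7 μg/100 ml on
[−d, 0].  `beta > alpha` is enforced so the drive stays positive; the
sensitivity scan overrides this (`allow_nonpositive_drive`) since its α mesh
crosses β, where even n keeps aⁿ well defined.

## DDE integration

The engine advances by the method of steps on intervals [k·d, (k+1)·d], so
the delayed state is always read from completed segments (or the history).
Within a segment an embedded Runge–Kutta 2(3) pair steps adaptively
(`rel_tol` 1e−6, `abs_tol` 1e−8, `max_step` 1 min — resolving the sharp
secretion bursts); the continuous solution is the cubic Hermite interpolant
through the accepted steps, stored with one-sided derivatives at segment
boundaries where derivative discontinuities propagate.  A low-order pair is
deliberate: the n = 10 Hill switch makes high-order pairs waste effort near
quasi-discontinuities.  The engine is validated against an independent
fixed-step RK4 method-of-steps oracle (step 0.02 min, cubic-Hermite delayed
lookup): maximum relative disagreement over one cycle of the driver is below
1e−4.  States are not clipped to positivity; positivity is asserted in tests
so that integrator faults cannot hide behind clipping.

## Adaptive synchronization observer

A receiver replica with unknown rate constants is coupled to the observed
signal by adaptive linear feedback (state: C_r, ε, k1, k2; e = C_r − C_obs):

    dC_r/dt = k1 F(C_r(t−d), t) − k2 C_r + ε e
    dε/dt   = −Γ e²         (ε(0) = 0.1, monotone non-increasing)
    dk1/dt  = −δ₁ e F,      dk2/dt = +δ₂ e C_r

with F the Hill flux per unit k1.  Defaults Γ = δ₁ = δ₂ = 1; larger Γ/δ
converges faster (used during grid search, Γ/δ = 10) while Γ/δ = 1 gives the
most accurate final estimates.  The delayed term uses the receiver's own past
state — the two systems are coupled only through the feedback term — and
C_obs(t) between samples comes from shape-preserving (pchip) interpolation
of the (denoised) observations.  Initial guesses k1(0) = k2(0) = 0.01,
receiver history 1.7.

Run layout: dense and noisy scenarios run two circadian cycles and discard
the first (transient burn-in); the tracking RMSE is scored on the second
cycle on the observation grid, and estimates are the medians of the k-traces
over the last cycle.  The sparse scenario runs six cycles, discards five,
and takes medians over the whole trace.  A floor on the feedback gain
(`eps_min` = −30) guards the grid-search stage: receivers with structurally
wrong drive constants never synchronize, ε = −Γ∫e² then grows without bound
and the coupling becomes arbitrarily stiff; synchronizing configurations
stay above |ε| ≈ 8 and never touch the floor.

Why the median: once locked, the k-traces fluctuate about the generating
values (noise, interpolation error and replication artifacts repeatedly
excite the error); the median over a window is robust to those excursions.

## Baselines

**Nonlinear least squares** minimizes Σ(y_i − M(θ, t_i))² over (k1, k2) with
a bounded trust-region method, forward-difference Jacobian at the default
sqrt-machine-epsilon step, bounds (0, 1], ftol = xtol = 1e−10.  Started at
(0.01, 0.01) on noiseless dense data it converges to a local minimum near
(0.030, 0.017) with evaluation-cycle RMSE ≈ 0.21 — three orders of magnitude
above the observer's — and RMSE at the (0.01, 0.01) start itself is ≈ 0.92.
This failure is the point of the baseline, so no global restarts are added.

**Extended least squares** minimizes Σ (C_i − M_i)²/V_i + ln V_i with the
proportional variance model V = (σ·M)², σ profiled analytically per cell
(σ̂² = mean((C−M)²/M²)).  The (k1, k2) grid runs coarse-to-fine: step 0.01
over [0.01, 0.1]², then two decade refinements within ± one previous step
around the incumbent, reaching 1e−4 resolution in ~1000 model evaluations.
Residuals are scored over the first circadian cycle: parameter sensitivity
grows exponentially along the chaotic trajectory, so longer windows turn the
objective into an isolated spike at the truth surrounded by a deceptive
plateau (where the Σ ln V term rewards small predictions); one cycle keeps a
smooth basin while identifying both constants, and ELS then recovers
(0.0666, 0.0333) exactly at grid resolution on noiseless dense data.

## Grid search over (α, β)

The drive constants enter nonlinearly and are scanned on a rectangular mesh
(default step 0.1; the acceptance run uses the [0.5, 1.2]² window around the
physiological range).  Each cell fixes (α, β), runs the observer at
Γ/δ = 10, and scores the evaluation-cycle RMSE; the optimum is the argmin
(ties break to the first cell in row-major order), after which a final pass
at Γ/δ = 1 re-estimates (k1, k2).  Cells are independent and the reduction
is an explicit argmin, so evaluation order cannot change the result; cells
that fail (domain errors at α ≥ β with odd-power negative drives, or
integration failures) score +∞ with a logged warning.  On noiseless dense
data the argmin is exactly (0.7, 1.0).  The RMSE surface separation between
the true cell and distant cells is about 2× under these scan settings — the
adaptive rate constants partially compensate wrong drive constants — so the
minimum is correct but not dramatically deep.

## Synthetic data and scenarios

All observations are simulated from the model itself (there is no deposited
data): four scenarios cross sampling density (1-min dense vs 45-min sparse)
with proportional observation noise (0, 20, 50%), the noise drawn as
value·(1 + cv·z), z standard normal from a seeded generator (per-stage seeds
derive from one master seed by fixed offsets; negative values are kept).
Noisy series are wavelet-denoised before estimation: symlet-8 decomposition,
per-level universal threshold sqrt(2 ln N)·σ̂ with σ̂ from the median absolute
deviation of each detail level, soft thresholding (level 1 before parameter
estimation — preserving trajectory geometry — and level 4 before the grid
stage).  Sparse series are densified to a 5-min grid by monotone pchip
interpolation.

What the generator does *not* emulate: assay drift, missing samples,
between-subject variability, or model misspecification — every observation
comes from the very equation being fitted, so passing tests demonstrate
correct recovery under the stated noise/sampling conditions, not robustness
to structural error on real cortisol data.

## Known limitations

- With 20% proportional noise, level-1 wavelet denoising necessarily leaves
  ~0.15 RMS residual noise (thresholding level 1 can remove at most the
  finest half-band of white-noise power).  Driven by that residual, the
  δ = 1 update laws make the k-traces a mean-reverting random walk with
  per-cycle excursions of ±0.05–0.3 whose stationary distribution is biased
  high (the Hill saturation weakens the restoring force on the high side),
  and last-cycle medians land tens of percent from truth.  This behaviour is
  insensitive to solver tolerance, observation interpolation, denoising
  depth and run length; accuracies much below ~10% under such noise are not
  attainable from these update laws without additional stabilization.
- Sparse-scenario estimates are biased low by pchip densification distortion
  (RMS ≈ 0.09 vs the true trajectory) plus the initial-rise portion of the
  whole-trace median; percent errors are ~13–17%.
- The sensitivity scan's RMSE saturates for any large perturbation (chaotic
  decorrelation), so "sensitivity" orderings are meaningful locally (a
  ±100-min phase shift perturbs far less than rate-constant changes) rather
  than as global mesh maxima.
- Single constant delay only; no stiff/implicit stepping; no event handling
  beyond the delay breakpoints.
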