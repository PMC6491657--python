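# cortsync

Parameter estimation for a chaotic, circadian-driven cortisol secretion
model by **adaptive chaos synchronization**, with classical nonlinear and
extended least squares as baselines and an exhaustive grid search for the
nonlinearly-entering drive constants.

The package is for modellers of pulsatile endocrine systems (and nonlinear
dynamic systems in pharmacology more broadly) who need to recover rate
constants from a single measured time series when the underlying dynamics
are chaotic — a regime in which gradient-based least squares is notoriously
unreliable.

## The model

Cortisol concentration C(t) (μg/100 ml, t in minutes) follows a
delay-differential equation with Hill-type delayed feedback and first-order
elimination:

    dC/dt = k1 · a(t)ⁿ · C(t−d) / (a(t)ⁿ + C(t−d)ⁿ) − k2 · C(t)
    a(t)  = α · cos((t − t_f) · 2π/1440) + β

with nominal constants k1 = 0.0666/min, k2 = 0.0333/min, α = 0.7, β = 1
μg/100 ml, t_f = 250 min, d = 70 min, n = 10.  At these values the model is
chaotic and produces roughly one secretion burst per delay period on top of
the 24-h circadian envelope.

## The estimator

A *receiver* — a structural replica with unknown rate constants — is slaved
to the observed signal through adaptive linear feedback.  With
synchronization error e = C_r − C_obs:

    dC_r/dt = k1(t)·F(C_r(t−d), t) − k2(t)·C_r + ε(t)·e
    dε/dt   = −Γ e²,      dk1/dt = −δ₁ e · F,      dk2/dt = +δ₂ e · C_r

The feedback strength ε(t) is monotone non-increasing; the rate constants
follow delta-rule updates proportional to the error and are read off as the
median of their traces over an extraction window once the receiver locks on.
Drive constants (α, β) enter nonlinearly and are found by grid search with
the synchronization estimator evaluated in each cell.

## Worked example

```python
from cortsync import (CortisolParameters, SyncConfig, simulate_driver,
                      run_synchronization)

params = CortisolParameters.nominal()
obs = simulate_driver(params, n_cycles=2, sampling_interval=1.0)
cfg = SyncConfig(total_cycles=2, burn_in_cycles=1, extract_window="last_cycle")
res = run_synchronization(obs, cfg)
print(f"k1_hat = {res.k1_hat:.4f}  k2_hat = {res.k2_hat:.4f}  "
      f"rmse = {res.rmse_eval:.2e}")
```

prints

    k1_hat = 0.0682  k2_hat = 0.0338  rmse = 1.21e-04

i.e. the observer recovers the generating rate constants (0.0666, 0.0333)
to within ~2–3% from two days of noiseless 1-min samples, tracking the
chaotic trajectory to ~1e-4 μg/100 ml on the evaluation cycle.  For
comparison, local nonlinear least squares started from (0.01, 0.01) stays
trapped in a local minimum (RMSE ≈ 0.2–0.9 μg/100 ml on the same data) and
the extended-least-squares grid recovers (0.0666, 0.0333) exactly but needs
an exhaustive scan.

The same pipeline is scriptable from the shell:

    cortsync --out out simulate --cycles 2 --interval 1
    cortsync --out out estimate-cs out/simulated.csv
    cortsync --out out gridsearch out/simulated.csv --alpha 0.5 1.2 0.1 --beta 0.5 1.2 0.1

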