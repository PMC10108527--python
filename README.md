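# mudcrab

Fine-scale movement and behaviour analysis for acoustically tracked
estuarine animals, built around the workflow used for Giant Mud Crab
(*Scylla serrata*) tracked by a hyperbolic (time-difference-of-arrival)
positioning array: regularize irregular, noisy telemetry with a
continuous-time correlated random walk, classify movement into behavioural
states with a covariate-driven hidden Markov model, and quantify how
environmental drivers such as the tide shift the balance between
behaviours. It is aimed at movement ecologists and fisheries scientists
working with fine-scale acoustic telemetry (positions every few minutes,
metre-scale error) who want a tested, scriptable pipeline rather than a
one-off analysis.

## The model

Detections arrive at random 150–210 s transmission intervals with gaps.
Tracks are split at gaps longer than 4× the interpolation interval
Δ ∈ {5, 10, 15} min and segments with < 100 detections are dropped. Each
track is then a continuous-time correlated random walk: per axis the
velocity is Ornstein–Uhlenbeck, dv = −β v dt + σ dW, position its
integral, observed with Gaussian measurement error taken from a
fixed-position reference tag. The Kalman filter gives the exact
likelihood; the RTS smoother predicts positions on the Δ grid.

On that grid a hidden Markov model with N ∈ {2, 3} behavioural states
observes three conditionally independent streams per interval *t*:

* step length `l_t ~ zero-inflated Gamma(mean μ_i, sd σ_i, P(0) = π_i)`
* turning angle `φ_t ~ wrapped Cauchy(0, ρ_i)`
* RMS acceleration `a_t ~ zero-inflated Gamma` (missing intervals drop
  out of the likelihood)

for state *i*. State switching is a Markov chain whose off-diagonal
transition probabilities get multinomial-logit linear predictors in
time-varying covariates — tide height, Δ-tide (15-min backward
difference), their interaction, cyclic hour-of-day terms cos(2πt/24) and
sin(2πt/24), habitat — so the transition matrix Γ(t) varies interval by
interval while each row stays on the simplex. Individual heterogeneity
enters as a discrete random effect (K ∈ {1..4} transition-coefficient
sets with mixture weights). Fitting is penalized maximum likelihood
(Normal(0, 100) working-scale prior on the SD parameters, many random
restarts); model selection is by AIC; behavioural sequences come from the
Viterbi algorithm; equilibrium behaviour from the stationary distribution
πΓ = π as a function of covariates; model fit from randomized-quantile
pseudo-residuals. See `docs/methods.md` for the full account.

A synthetic-data module generates tide series, behavioural state chains,
state-dependent movement, tag transmissions with detection dropout and
positional error, and TDOA arrival times (Coppens sound speed, receiver
clock skew), so the entire pipeline is testable end to end without field
data.

## Worked example

Simulate six 500-interval tracks from the published two-state crab model
and refit it:

```python
import numpy as np
from mudcrab import fit_hmm, viterbi, occupancy, HMMData
from mudcrab.hmm import build_transition_matrices
from mudcrab.simulate import simulate_hmm_series

df = simulate_hmm_series(n_tracks=6, n_intervals=500, seed=42)
fit = fit_hmm(df, n_states=2, n_restarts=5, seed=0)
em = fit.params.emission
print(f"log-likelihood = {fit.loglik:.1f}   AIC = {fit.aic:.1f}")
print(f"state 1 (active):   step {em.step_mean[0]:.2f} ± {em.step_sd[0]:.2f} m, "
      f"rho = {em.angle_rho[0]:.2f}, accel {em.accel_mean[0]:.3f} m/s^2")
print(f"state 2 (inactive): step {em.step_mean[1]:.2f} ± {em.step_sd[1]:.2f} m, "
      f"rho = {em.angle_rho[1]:.2f}, accel {em.accel_mean[1]:.3f} m/s^2")
P = build_transition_matrices(fit.params.transition.beta, np.ones((1, 1)), 2)[0]
print("transition matrix:"); print(np.round(P, 3))
occ = occupancy(viterbi(fit, HMMData.from_table(df)))
print(f"Viterbi occupancy: state 1 = {occ[0]:.1%}, state 2 = {occ[1]:.1%}")
```

which prints

```
log-likelihood = -4507.8   AIC = 9047.5
state 1 (active):   step 14.29 ± 18.89 m, rho = 0.52, accel 0.589 m/s^2
state 2 (inactive): step 0.75 ± 0.92 m, rho = 0.71, accel 0.041 m/s^2
transition matrix:
[[0.922 0.078]
 [0.038 0.962]]
Viterbi occupancy: state 1 = 32.0%, state 2 = 68.0%
```

The estimator recovers the generating emissions (state 1: 13.98 ± 18.10 m
steps, ρ = 0.51, 0.59 m/s² acceleration; state 2: 0.75 ± 0.93 m, ρ = 0.70,
0.04 m/s²) and the sticky transition matrix [[0.91, 0.09], [0.04, 0.96]]
from 3,000 intervals; the decoded occupancy sits near the chain's
stationary distribution (0.31, 0.69). The two states differ in mean step
length and mean acceleration by more than an order of magnitude, so the
Viterbi decode tracks the generating state sequence closely.

The same workflow runs from the shell:

```sh
mudcrab simulate --outdir data --n-tags 2 --days 3 --seed 1
mudcrab run config.yaml --outdir out     # split → CTCRW → covariates → fit → decode
```

with `config.yaml` naming the detection/tide files and the analysis
settings (Δ, N, K range, covariate formulas, restart counts, seeds).

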