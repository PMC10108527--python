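# Methods

`mudcrab` implements a two-stage analysis of fine-scale acoustic telemetry
from slow-moving benthic animals — the motivating case is adult Giant Mud
Crab (*Scylla serrata*) tracked by a hyperbolic positioning array in a
shallow estuarine creek — together with a synthetic-data generator that
reproduces the statistical structure of such a study so every stage can be
validated without field data.

## Positioning and measurement error

Tags transmit at uniform random 150–210 s intervals; a detection heard on
three or more time-synchronized receivers is located by time-difference-
of-arrival multilateration (`positioning.tdoa_solve`), with arrival times
converted to distances through the Coppens (1981) shallow-water sound-speed
polynomial. Receiver clocks drift by up to seconds per day, so a
fixed-position synchronization tag is used to estimate a per-receiver
linear clock error (offset plus rate) that is removed before solving. A
fixed reference tag of known position provides the running audit of array
accuracy (`positioning.audit_reference_tag`): horizontal-error mean, SD,
median, IQR, fraction within 5 m, and the isotropic error covariance that
feeds the movement model. Positional error in such arrays is low (median
near 1 m) and right-skewed; the simulator's default is isotropic Gaussian
noise per axis (radial error then Rayleigh, median `sd * sqrt(2 ln 2)`),
with a log-normal radial option for skewness studies. The audit
characterizes whatever error the data actually contain.

## Track preparation (CTCRW)

Discrete-time HMMs need observations on an exact grid, while detections
arrive irregularly with gaps (missed detections, burial, emigration).
Detection series are first split wherever the gap between consecutive
detections exceeds 4 times the interpolation interval Δ ∈ {5, 10, 15} min
(strictly greater; interpolating across longer gaps would fabricate
straight constant-speed movement), and segments with fewer than 100
detections are discarded as uninformative and numerically fragile.

Each track is then modelled as a continuous-time correlated random walk:
per axis, velocity is an Ornstein–Uhlenbeck process with autocorrelation
decay `beta_ou` (1/h) and stochasticity `sigma` (m h^-1/2), position is its
integral, and observations add Gaussian measurement error with the
covariance from the reference-tag audit (per-detection covariances override
when present). The exact discrete-time transition and process covariance
give the likelihood through the Kalman filter (prediction-error
decomposition); `(beta_ou, sigma)` are estimated by maximum likelihood from
50 restarts, each a multiplicative log-normal (SD 0.5 on the log scale)
perturbation of a moment-based start, keeping the best likelihood.
Positions and prediction variances on the Δ grid come from the RTS
smoother with grid epochs inserted as prediction-only observations —
smoothing rather than filtering because within-track prediction should use
information from both sides. The grid is anchored at the first detection
time rounded up to a multiple of Δ; this anchoring and the smoother choice
are conventions of this implementation. The initial state is diffuse
(position pinned loosely to the first observation with variance 1e8 m²,
velocity variance 1e6), which makes the first epochs insensitive to
initialization; an exact Gaussian initial state can be supplied instead,
which is how the likelihood is verified against a directly assembled
joint-normal density.

## Observation streams and covariates

On the regular grid the HMM observes, per interval: step length (distance
between consecutive smoothed positions, m), turning angle (signed heading
change over three consecutive positions, radians in (−π, π], 0 = straight
ahead, exact reversals mapped to +π), and mean transmitted RMS
acceleration in [t, t+Δ) (m s⁻², missing when no transmission fell in the
interval — missing streams simply contribute no factor to the
likelihood). The first angle of every track is undefined, as is any angle
adjacent to a zero-length step.

Transition covariates: tide height (linear interpolation of the gauge
record, m above datum), Δ-tide (backward difference over a fixed 15-min
lag at every Δ, positive = flood), the daily harmonics cos(2πt/24) and
sin(2πt/24) of the local clock hour (diel behaviour follows solar time, so
the configured zone offset converts UTC epochs), and habitat category from
polygons dilated by a buffer equal to the array's median positional error
(default 1.26 m) to absorb edge effects, with overlaps resolved by the
fixed priority seagrass > mangrove > saltmarsh and anything else
unvegetated. The 15-min Δ-tide lag is deliberately independent of the
interpolation interval.

## The hidden Markov model

N ∈ {2, 3} behavioural states. Emissions, conditionally independent given
the state:

* step and acceleration: zero-inflated gamma — a point mass `zeromass` at
  exactly zero plus a gamma with mean/SD parameterization (shape =
  (mean/sd)², rate = mean/sd²); log links for mean and SD, logit for the
  zero mass;
* turning angle: wrapped Cauchy with mean direction fixed at 0
  (straight-line movement) and concentration ρ ∈ [0, 1) on a logit link.

Transitions: each off-diagonal entry of the N×N matrix gets a linear
predictor in the covariates through a multinomial logit link, keeping
every row on the simplex; the diagonal is the remainder. Tide height,
Δ-tide and their interaction enter formulas only together. Individual
heterogeneity is a discrete random effect: K ∈ {1..4} candidate
coefficient sets with mixture weights, each animal governed by one
(marginal likelihood by log-sum-exp over components per individual; K = 1
is the ordinary model).

The likelihood is the scaled forward recursion, batched across tracks
(tracks are independent; each starts from the stationary distribution of
its first transition matrix, matching the equilibrium interpretation of
the stationary-probability curves). A Normal(0, 100) prior on the
working-scale SD parameters keeps scale estimates off the boundary; it is
a numerical device, so AIC uses the unpenalized log-likelihood at the
penalized optimum. Optimization is L-BFGS-B on the working scale from 50
restarts (restart 0 = moment/quantile-split starts; others add standard
normal working-scale noise), keeping the lowest objective; the forward
recursion has a numba-compiled inner loop with a pure-numpy fallback, and
the two are verified equal in the tests. Label switching is resolved by
relabelling states in descending step-mean order, which makes state 1 the
"active/foraging" state by construction.

## Inference and diagnostics

* **Viterbi** decoding gives the global MAP state path (ties toward the
  lower state index); forward–backward gives smoothed per-interval state
  probabilities; occupancy summaries pool the Viterbi decodes.
* **Stationary state probabilities** solve πP = π at chosen covariate
  values; the curve for one covariate holds the others at fixed values
  (default: fix at the mean — averaging over observed covariate rows is
  available through the design argument). 95% CIs use the delta method
  with a finite-difference Jacobian of the stationary solve with respect
  to the transition coefficients, truncated to [0, 1].
* **Pseudo-residuals** are one-step-ahead probability integral transforms
  per stream mapped through the standard normal quantile; the zero atoms
  of step/acceleration use randomized quantile residuals (a seeded uniform
  draw within the atom's forecast mass), so a correctly specified model
  yields i.i.d. standard-normal residuals in all three streams.
* **Model selection** ranks fits by AIC (ties to fewer parameters) and
  refuses to compare fits of different data. Residual diagnostics report
  the KS distance from normality, the maximum |ACF| over lags 1–96, and a
  12-h periodicity score: the periodogram ordinate band at frequency
  1/12 h⁻¹ divided by the median of ~40 neighbouring ordinates (rescaled
  by ln 2 so white noise scores ≈ 1). The 12-h check replaces a visual
  judgement with a number; scores far above 1 flag un-modelled tidal
  periodicity.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical conditions of the motivating
study: transmissions at U(150, 210) s, Bernoulli detection thinning (an
optional two-state on/off process emulates temporally clustered burial
dropout, off by default), positional error with median ≈ 1.26 m, a
semidiurnal ~2 m tide (single sinusoid by default; a second constituent
can be added — any series with realistic range suffices for testing), and
a two-state behaviour chain with the published emission parameters
(state 1: step 13.98 ± 18.10 m/15 min, ρ = 0.51, accel 0.59 ± 0.63 m s⁻²;
state 2: step 0.75 ± 0.93, ρ = 0.70, accel 0.04 ± 0.02) and transition
matrix [[0.91, 0.09], [0.04, 0.96]]. The state-1 step zero mass is
reported only as "<< 0.001" in the source analysis; the generator uses
5 × 10⁻⁴. The detection probability and dropout structure of a real array
are not published; they are free parameters, not asserted values.
Acceleration is simulated directly at the interval level because tags
transmit only an RMS summary; no 5 Hz waveform is synthesized, there is no
acoustic propagation physics beyond a constant sound speed, and no
code-collision modelling. Headings accumulate turning angles from an
initial uniform heading. Dead-reckoned paths clip acceleration to the
tag's 0–3.4 m s⁻² range; the simulation-and-refit experiments sample the
emission streams directly, so no truncation bias enters parameter
recovery. Because the generator *is* the fitted model, passing recovery
tests demonstrates estimator correctness, not that real crab data satisfy
the model; measurement-induced state overlap, multipath error and
behavioural nonstationarity in real arrays are outside what these tests
can show.

## Numerical choices and problem sizes

Forward probabilities are renormalized each step with per-interval max-shifted
emissions, so extreme restart parameters degrade to −∞ likelihood rather
than overflow. Transition linear predictors are clipped at ±60 before
exponentiation. Stationary distributions come from a least-squares solve
of (Pᵀ−I, 1); reducible chains raise. Degenerate all-identical-position
tracks return `sigma` at its floor (1e-6 m h^-1/2 scale) with a warning
rather than failing. The simulation-and-refit experiment in the acceptance
script uses 20 tracks × 2,000 15-min intervals and 10 restarts, the size
at which every targeted parameter's Monte-Carlo error is comfortably
inside its tolerance; the test suite uses smaller replicas (6 × 300 for
unit-level checks, 12 × 400 for CTCRW recovery) chosen to keep the whole
suite fast while leaving each check statistically decisive. Zero-mass
atoms of order 10⁻³ and below are not recoverable to 10% at these sample
sizes (their binomial SE exceeds that), so they are checked for
consistency within 4 SE instead.

## Known limitations

* No continuous-time HMM: states are defined on the regular grid, and the
  regularization step is a separate stage rather than a joint model, so
  smoothing uncertainty is not propagated into the HMM.
* The discrete mixture over individuals captures between-animal
  heterogeneity only as a small number of types.
* The delta-method CIs for stationary curves rely on a quadratic
  approximation on the working scale and can be optimistic near parameter
  boundaries.
* The habitat overlap priority and the +π reversal convention are fixed
  conventions; analyses sensitive to either should be interpreted
  accordingly.
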