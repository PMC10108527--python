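"""Post-fit inference and diagnostics for the movement HMM.

Covers the global most-probable state path (Viterbi) with smoothed state
probabilities, equilibrium (stationary) state probabilities as functions of
covariates with delta-method confidence intervals, one-step-ahead
pseudo-residuals (randomized at the zero atoms so a correct model yields
standard-normal residuals), AIC model ranking, residual diagnostics
including a 12-h periodicity score, and Viterbi-based occupancy summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import wrapped_cauchy_cdf, zigamma_cdf
from .hmm import (
    FitResult,
    HMMData,
    HMMParams,
    TransitionModel,
    _emission_logprobs,
    _initial_distributions,
    build_transition_matrices,
    stationary_distribution,
)

__all__ = [
    "StateSequence",
    "viterbi",
    "forward_backward",
    "stationary_probabilities",
    "design_for_curve",
    "pseudo_residuals",
    "select_model",
    "enumerate_formulas",
    "residual_diagnostics",
    "spectral_peak_score",
    "occupancy",
]


@dataclass
class StateSequence:
    """Decoded states (1-based) and smoothed state probabilities per track."""

    track_id: str
    states: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        if len(self.states) and not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("state probabilities must sum to 1 per interval")


def _track_pieces(data: HMMData, params: HMMParams):
    """Per-track (logB, Gammas, delta) on the unpadded lengths."""
    if params.is_mixture:
        raise TypeError("decode against a fitted single-component transition model")
    logB = _emission_logprobs(data, params.emission)
    Gammas = build_transition_matrices(params.transition.beta, data.X, params.n_states)
    delta = _initial_distributions(Gammas[:, 0])
    for b in range(data.n_tracks):
        L = int(data.lengths[b])
        yield data.track_ids[b], logB[b, :L], Gammas[b, :L], delta[b]


def viterbi(fit: FitResult | HMMParams, data: HMMData) -> list[StateSequence]:
    """Global MAP state path per track, plus forward–backward probabilities.

    Dynamic programming in log space; ties break toward the lower state
    index (argmax returns the first maximizer).
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    gammas = forward_backward(params, data)
    out = []
    for (tid, logB, Gam, delta), gamma in zip(_track_pieces(data, params), gammas):
        T, N = logB.shape
        with np.errstate(divide="ignore"):
            logGam = np.log(np.clip(Gam, 1e-300, None))
            score = np.log(np.clip(delta, 1e-300, None)) + logB[0]
        back = np.zeros((T, N), dtype=int)
        for t in range(1, T):
            cand = score[:, None] + logGam[t]
            back[t] = np.argmax(cand, axis=0)
            score = cand[back[t], np.arange(N)] + logB[t]
        states = np.empty(T, dtype=int)
        states[-1] = int(np.argmax(score))
        for t in range(T - 2, -1, -1):
            states[t] = back[t + 1][states[t + 1]]
        out.append(StateSequence(tid, states + 1, gamma))
    return out


def forward_backward(params: HMMParams, data: HMMData) -> list[np.ndarray]:
    """Smoothed per-interval state probabilities, one (T, N) array per track."""
    out = []
    for _, logB, Gam, delta in _track_pieces(data, params):
        T, N = logB.shape
        m = logB.max(axis=1, keepdims=True)
        B = np.exp(logB - m)
        alpha = np.empty((T, N))
        a = delta * B[0]
        alpha[0] = a / a.sum()
        for t in range(1, T):
            a = (alpha[t - 1] @ Gam[t]) * B[t]
            alpha[t] = a / a.sum()
        beta = np.empty((T, N))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            b = Gam[t + 1] @ (B[t + 1] * beta[t + 1])
            beta[t] = b / b.sum()
        g = alpha * beta
        out.append(g / g.sum(axis=1, keepdims=True))
    return out


# --------------------------------------------------------------------------
# stationary state probabilities
# --------------------------------------------------------------------------


def design_for_curve(
    columns: tuple[str, ...],
    name: str,
    grid: np.ndarray,
    fixed: dict[str, float] | None = None,
) -> np.ndarray:
    """Design rows varying one covariate over ``grid``, others held fixed.

    Interaction columns ``a:b`` are rebuilt as the product of the per-part
    values, so the curve for a covariate entering an interaction moves both
    its main effect and the interaction term.
    """
    fixed = dict(fixed or {})
    grid = np.asarray(grid, dtype=float)
    G = len(grid)

    def part_value(p: str) -> np.ndarray:
        if p == name:
            return grid
        return np.full(G, float(fixed.get(p, 0.0)))

    cols = []
    for col in columns:
        if col == "intercept":
            cols.append(np.ones(G))
        elif ":" in col:
            v = np.ones(G)
            for p in col.split(":"):
                v = v * part_value(p)
            cols.append(v)
        else:
            cols.append(part_value(col))
    return np.column_stack(cols)


def stationary_probabilities(
    model: TransitionModel,
    design: np.ndarray,
    vcov_beta: np.ndarray | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Equilibrium state probabilities per design row, with optional CIs.

    Solves ``pi P = pi`` at every row. Confidence intervals use the delta
    method: a finite-difference Jacobian of the stationary solve with
    respect to the flattened transition coefficients, sandwiched with their
    covariance; bounds are truncated to [0, 1].
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    N = model.n_states
    P = build_transition_matrices(model.beta, design, N)
    probs = np.vstack([stationary_distribution(P[g]) for g in range(len(design))])
    rec = {f"p_state{n + 1}": probs[:, n] for n in range(N)}
    if vcov_beta is not None:
        z = stats.norm.ppf(0.5 + level / 2.0)
        b0 = model.beta.ravel()
        h = 1e-5
        sds = np.empty((len(design), N))
        for g in range(len(design)):
            J = np.empty((N, len(b0)))
            for j in range(len(b0)):
                bp = b0.copy(); bp[j] += h
                bm = b0.copy(); bm[j] -= h
                Pp = build_transition_matrices(bp.reshape(model.beta.shape), design[g], N)
                Pm = build_transition_matrices(bm.reshape(model.beta.shape), design[g], N)
                J[:, j] = (stationary_distribution(Pp) - stationary_distribution(Pm)) / (2 * h)
            sds[g] = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", J, vcov_beta, J), 0.0, None))
        for n in range(N):
            rec[f"lo_state{n + 1}"] = np.clip(probs[:, n] - z * sds[:, n], 0.0, 1.0)
            rec[f"hi_state{n + 1}"] = np.clip(probs[:, n] + z * sds[:, n], 0.0, 1.0)
    return pd.DataFrame(rec)


# --------------------------------------------------------------------------
# pseudo-residuals
# --------------------------------------------------------------------------


def pseudo_residuals(
    fit: FitResult | HMMParams, data: HMMData, seed: int = 0
) -> pd.DataFrame:
    """One-step-ahead forecast pseudo-residuals per observation stream.

    The probability integral transform of each observation under its
    forecast distribution (state weights = filtered probabilities pushed
    one step through the transition matrix) is mapped through the standard
    normal quantile. The zero atoms of step and acceleration get
    randomized quantile residuals: a seeded uniform draw inside the atom's
    forecast mass. Under a correctly specified model all three residual
    streams are i.i.d. standard normal.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    em = params.emission
    rng = np.random.default_rng(seed)
    rows = []
    for tid, logB, Gam, delta in _track_pieces(data, params):
        T, N = logB.shape
        m = logB.max(axis=1, keepdims=True)
        B = np.exp(logB - m)
        w = delta.copy()  # forecast weights before seeing time t
        b = data.track_ids.index(tid)
        for t in range(T):
            if t > 0:
                w = alpha @ Gam[t]
            rec = {"track_id": tid, "t_index": t}
            s = data.step[b, t]
            if np.isfinite(s):
                hi = float(w @ zigamma_cdf(s, em.step_mean, em.step_sd, em.step_zeromass))
                if s == 0.0:
                    hi = rng.uniform(0.0, hi)
                rec["step"] = stats.norm.ppf(np.clip(hi, 1e-12, 1 - 1e-12))
            a = data.angle[b, t]
            if np.isfinite(a):
                u = float(w @ wrapped_cauchy_cdf(a, em.angle_rho))
                rec["angle"] = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
            if em.has_accel and data.accel is not None:
                ac = data.accel[b, t]
                if np.isfinite(ac):
                    hi = float(w @ zigamma_cdf(ac, em.accel_mean, em.accel_sd, em.accel_zeromass))
                    if ac == 0.0:
                        hi = rng.uniform(0.0, hi)
                    rec["accel"] = stats.norm.ppf(np.clip(hi, 1e-12, 1 - 1e-12))
            rows.append(rec)
            a_post = w * B[t]
            alpha = a_post / a_post.sum()
    df = pd.DataFrame(rows)
    for col in ("step", "angle", "accel"):
        if col not in df.columns:
            df[col] = np.nan
    return df


# --------------------------------------------------------------------------
# model selection
# --------------------------------------------------------------------------

_TIDE_GROUP = ("tide_height", "dtide", "tide_height:dtide")


def enumerate_formulas(
    tide: bool = True,
    hour: bool = True,
    habitat: bool = False,
    water_temp: bool = False,
) -> list[tuple[str, ...]]:
    """All covariate formulas, with the tidal terms only entering together."""
    groups: list[tuple[str, ...]] = []
    if tide:
        groups.append(_TIDE_GROUP)
    if hour:
        groups.append(("hour_cos", "hour_sin"))
    if habitat:
        groups.append(("habitat",))
    if water_temp:
        groups.append(("water_temp",))
    out = []
    for r in range(len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            out.append(tuple(itertools.chain.from_iterable(combo)))
    return out


def select_model(candidates: list[FitResult]) -> pd.DataFrame:
    """Rank fitted candidates by AIC (ascending), ties by fewer parameters.

    All candidates must be fits of the same data (same rows); comparing
    fits across datasets is refused.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    sigs = {c.data_signature for c in candidates}
    if len(sigs) > 1:
        raise ValueError("candidates were fitted on differing data; AIC not comparable")
    rows = [
        {
            "formula": "+".join(c.formula) if c.formula else "(null)",
            "K": c.K,
            "n_states": c.n_states,
            "n_params": c.n_params,
            "loglik": c.loglik,
            "aic": c.aic,
        }
        for c in candidates
    ]
    df = pd.DataFrame(rows).sort_values(
        ["aic", "n_params", "formula"], kind="stable", ignore_index=True
    )
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


# --------------------------------------------------------------------------
# residual diagnostics
# --------------------------------------------------------------------------


def _acf(x: np.ndarray, nlags: int) -> np.ndarray:
    x = x[np.isfinite(x)]
    x = x - x.mean()
    denom = float(x @ x)
    return np.array(
        [1.0] + [float(x[:-k] @ x[k:]) / denom for k in range(1, min(nlags, len(x) - 1) + 1)]
    )


def spectral_peak_score(
    x: np.ndarray, dt_s: float, period_s: float = 12.0 * 3600.0, band: int = 1
) -> float:
    """Periodogram ordinate near 1/period relative to its neighbourhood.

    Missing values are replaced by the mean (zero after centring). The
    score normalizes the local band mean by the median of ~40 surrounding
    ordinates (rescaled so white noise scores about 1); a clear periodic
    component at the target frequency scores far above 1.
    """
    x = np.asarray(x, dtype=float)
    x = np.where(np.isfinite(x), x, np.nanmean(x))
    x = x - x.mean()
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=dt_s)
    k = int(np.argmin(np.abs(freqs - 1.0 / period_s)))
    lo, hi = max(k - band, 1), min(k + band, len(spec) - 1)
    peak = float(spec[lo:hi + 1].mean())
    neigh = np.concatenate([spec[max(k - 21, 1):lo], spec[hi + 1:hi + 22]])
    if len(neigh) == 0:
        return np.nan
    return peak / (float(np.median(neigh)) / np.log(2.0))


def residual_diagnostics(
    residuals: dict[float, pd.DataFrame], max_lag: int = 96
) -> pd.DataFrame:
    """Per-interval, per-stream residual summary across interpolation Δs.

    Columns: KS distance from standard normal, maximum absolute
    autocorrelation over lags 1..max_lag, and the 12-h spectral peak
    score. Used to choose among candidate interpolation intervals.
    """
    rows = []
    for dt_min, df in sorted(residuals.items()):
        for stream in ("step", "angle", "accel"):
            if stream not in df.columns:
                continue
            r = df[stream].to_numpy(dtype=float)
            rr = r[np.isfinite(r)]
            if len(rr) < 10:
                continue
            ks = stats.kstest(rr, "norm").statistic
            ac = _acf(r[np.isfinite(r)], max_lag)
            rows.append(
                {
                    "interval_min": dt_min,
                    "stream": stream,
                    "n": len(rr),
                    "ks_distance": float(ks),
                    "max_abs_acf": float(np.max(np.abs(ac[1:]))) if len(ac) > 1 else np.nan,
                    "peak12h_score": spectral_peak_score(r, dt_min * 60.0),
                }
            )
    return pd.DataFrame(rows)


def occupancy(decoded: list[StateSequence], n_states: int | None = None) -> np.ndarray:
    """Pooled fraction of intervals per Viterbi state across tracks."""
    if not decoded or all(len(d.states) == 0 for d in decoded):
        raise ValueError("no decoded states")
    allstates = np.concatenate([d.states for d in decoded])
    N = n_states or int(allstates.max())
    counts = np.bincount(allstates - 1, minlength=N)[:N]
    return counts / counts.sum()
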