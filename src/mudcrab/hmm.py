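"""Multivariate hidden Markov model for movement behaviour.

The model classifies regular-interval movement metrics — step length,
turning angle and RMS acceleration — into N latent behavioural states.
Emissions are zero-inflated gamma (step, acceleration; mean/SD
parameterization with a point mass at zero) and wrapped Cauchy (turning
angle; mean direction fixed at 0, concentration estimated). The latent
chain may be non-homogeneous: each off-diagonal transition probability gets
a multinomial-logit linear predictor in time-varying covariates, so the
realized N x N matrix varies interval by interval while every row still
sums to one. Individual heterogeneity is supported as a discrete random
effect: K candidate transition-coefficient sets with mixture weights, each
animal governed by one of them.

Fitting maximizes the likelihood from the scaled forward recursion (missing
streams simply drop out of the per-interval emission product), lightly
penalized by a Normal(0, 100) prior on the working-scale SD parameters to
keep scale estimates off the boundary, from many randomly perturbed starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, logsumexp

from .distributions import wrapped_cauchy_logpdf, zigamma_logpdf

_ETA_CLIP = 60.0  # linear predictors clipped here; expit/exp saturate anyway

__all__ = [
    "EmissionParams",
    "TransitionModel",
    "MixtureSpec",
    "HMMParams",
    "HMMData",
    "FitResult",
    "build_transition_matrices",
    "intercepts_for_matrix",
    "stationary_distribution",
    "forward_loglik",
    "mixture_loglik",
    "penalized_objective",
    "fit_hmm",
    "compute_vcov",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass
class EmissionParams:
    """State-dependent distribution parameters (arrays of length N).

    Step and acceleration are zero-inflated gamma (gamma mean/SD plus a
    zero mass in [0, 1)); the turning angle is wrapped Cauchy with mean 0
    and concentration ``angle_rho`` in [0, 1). ``accel_*`` may be None for
    a step/angle-only model.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    step_zeromass: np.ndarray
    angle_rho: np.ndarray
    accel_mean: np.ndarray | None = None
    accel_sd: np.ndarray | None = None
    accel_zeromass: np.ndarray | None = None

    def __post_init__(self):
        for name in ("step_mean", "step_sd", "step_zeromass", "angle_rho",
                     "accel_mean", "accel_sd", "accel_zeromass"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.atleast_1d(np.asarray(v, dtype=float)))
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.step_mean)

    @property
    def has_accel(self) -> bool:
        return self.accel_mean is not None

    def validate(self) -> None:
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("step mean/sd must be positive")
        if np.any(self.step_zeromass < 0) or np.any(self.step_zeromass >= 1):
            raise ValueError("step zeromass must lie in [0, 1)")
        if np.any(self.angle_rho < 0) or np.any(self.angle_rho >= 1):
            raise ValueError("angle concentration must lie in [0, 1)")
        if self.has_accel:
            if np.any(self.accel_mean <= 0) or np.any(self.accel_sd <= 0):
                raise ValueError("accel mean/sd must be positive")
            if np.any(self.accel_zeromass < 0) or np.any(self.accel_zeromass >= 1):
                raise ValueError("accel zeromass must lie in [0, 1)")

    def permuted(self, perm: np.ndarray) -> "EmissionParams":
        kw = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            kw[f.name] = None if v is None else v[perm]
        return EmissionParams(**kw)


def _offdiag_index(n_states: int) -> list[tuple[int, int]]:
    """Row-major ordering of the off-diagonal transition entries."""
    return [(i, j) for i in range(n_states) for j in range(n_states) if j != i]


@dataclass
class TransitionModel:
    """Multinomial-logit transition model.

    ``beta`` has one coefficient row per off-diagonal entry (row-major
    order) and one column per design column; ``columns`` names the design
    columns, the first of which is the intercept.
    """

    n_states: int
    columns: tuple[str, ...]
    beta: np.ndarray

    def __post_init__(self):
        self.columns = tuple(self.columns)
        self.beta = np.asarray(self.beta, dtype=float)
        n_off = self.n_states * (self.n_states - 1)
        if self.beta.shape != (n_off, len(self.columns)):
            raise ValueError(
                f"beta must have shape ({n_off}, {len(self.columns)}), got {self.beta.shape}"
            )

    def permuted(self, perm: np.ndarray) -> "TransitionModel":
        return TransitionModel(self.n_states, self.columns,
                               _permute_beta(self.beta, perm, self.n_states))


def _permute_beta(beta: np.ndarray, perm: np.ndarray, n_states: int) -> np.ndarray:
    """Reindex off-diagonal coefficient rows for a state relabelling."""
    pairs = _offdiag_index(n_states)
    pos = {p: k for k, p in enumerate(pairs)}
    out = np.empty_like(beta)
    for k, (i, j) in enumerate(pairs):
        out[k] = beta[pos[(perm[i], perm[j])]]
    return out


@dataclass
class MixtureSpec:
    """Discrete random effect: K transition-coefficient sets with weights."""

    n_states: int
    columns: tuple[str, ...]
    weights: np.ndarray
    betas: np.ndarray  # (K, n_off, p)

    def __post_init__(self):
        self.columns = tuple(self.columns)
        self.weights = np.asarray(self.weights, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if self.betas.shape[0] != len(self.weights):
            raise ValueError("one beta set per mixture component required")

    @property
    def K(self) -> int:
        return len(self.weights)

    def permuted(self, perm: np.ndarray) -> "MixtureSpec":
        betas = np.stack([_permute_beta(b, perm, self.n_states) for b in self.betas])
        return MixtureSpec(self.n_states, self.columns, self.weights.copy(), betas)


@dataclass
class HMMParams:
    """Complete parameter set: emissions plus transition structure."""

    n_states: int
    emission: EmissionParams
    transition: TransitionModel | MixtureSpec

    def __post_init__(self):
        if self.emission.n_states != self.n_states:
            raise ValueError("emission/state-count mismatch")
        if self.transition.n_states != self.n_states:
            raise ValueError("transition/state-count mismatch")

    @property
    def is_mixture(self) -> bool:
        return isinstance(self.transition, MixtureSpec)


# --------------------------------------------------------------------------
# data container and design matrices
# --------------------------------------------------------------------------


def build_design(table: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix: intercept plus the requested covariate terms.

    A term ``"a:b"`` is the elementwise product of columns ``a`` and ``b``;
    a categorical (object-dtype) column expands to dummies against its
    alphabetically first level.
    """
    cols: list[np.ndarray] = [np.ones(len(table))]
    names: list[str] = ["intercept"]
    for term in terms:
        if ":" in term:
            parts = term.split(":")
            v = np.ones(len(table))
            for p in parts:
                v = v * table[p].to_numpy(dtype=float)
            cols.append(v)
            names.append(term)
        elif table[term].dtype == object or isinstance(table[term].dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(table[term].astype(str)))
            for lev in levels[1:]:
                cols.append((table[term].astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(table[term].to_numpy(dtype=float))
            names.append(term)
    return np.column_stack(cols), tuple(names)


@dataclass
class HMMData:
    """Model-ready observations, padded and batched across tracks.

    ``step``, ``angle``, ``accel`` are (B, Tmax) with NaN for missing;
    ``X`` is (B, Tmax, p); ``mask`` marks valid intervals; tracks shorter
    than ``Tmax`` are right-padded.
    """

    track_ids: list[str]
    individuals: list[str]
    lengths: np.ndarray
    step: np.ndarray
    angle: np.ndarray
    accel: np.ndarray | None
    X: np.ndarray
    columns: tuple[str, ...]
    mask: np.ndarray = field(init=False)

    def __post_init__(self):
        B, T = self.step.shape
        self.mask = np.arange(T)[None, :] < self.lengths[:, None]

    @property
    def n_tracks(self) -> int:
        return len(self.track_ids)

    @property
    def n_obs(self) -> int:
        return int(self.lengths.sum())

    @property
    def has_accel(self) -> bool:
        return self.accel is not None

    def signature(self) -> tuple:
        """Fingerprint used to refuse comparing fits across datasets."""
        return (
            self.n_obs,
            round(float(np.nansum(self.step)), 6),
            round(float(np.nansum(self.angle)), 6),
            0.0 if self.accel is None else round(float(np.nansum(self.accel)), 6),
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame, formula: tuple[str, ...] = ()) -> "HMMData":
        if "track_id" not in table.columns:
            raise ValueError("model table requires a track_id column")
        X_all, names = build_design(table, tuple(formula))
        ids = list(dict.fromkeys(table["track_id"]))
        groups = [np.flatnonzero((table["track_id"] == tid).to_numpy()) for tid in ids]
        lengths = np.array([len(g) for g in groups])
        B, T = len(ids), int(lengths.max())
        step = np.full((B, T), np.nan)
        angle = np.full((B, T), np.nan)
        has_accel = "accel" in table.columns and table["accel"].notna().any()
        accel = np.full((B, T), np.nan) if has_accel else None
        X = np.zeros((B, T, X_all.shape[1]))
        X[:, :, 0] = 1.0
        for b, g in enumerate(groups):
            L = len(g)
            step[b, :L] = table["step"].to_numpy(dtype=float)[g]
            angle[b, :L] = table["angle"].to_numpy(dtype=float)[g]
            if has_accel:
                accel[b, :L] = table["accel"].to_numpy(dtype=float)[g]
            X[b, :L] = X_all[g]
        if "individual" in table.columns:
            ind = [str(table.loc[table["track_id"] == tid, "individual"].iloc[0]) for tid in ids]
        else:
            ind = [str(tid).rsplit("-", 1)[0] for tid in ids]
        return cls(list(map(str, ids)), ind, lengths, step, angle, accel, X, names)


# --------------------------------------------------------------------------
# transition matrices
# --------------------------------------------------------------------------


def build_transition_matrices(beta: np.ndarray, X: np.ndarray, n_states: int) -> np.ndarray:
    """Realized transition matrices from a multinomial-logit model.

    ``X`` has shape (..., p); returns (..., N, N). Off-diagonal entries are
    ``exp(eta_ij) / (1 + sum_{j != i} exp(eta_ij))`` with the diagonal as
    the remainder, so each row sums to one by construction.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    n_off = n_states * (n_states - 1)
    if beta.shape[0] != n_off:
        raise ValueError(f"expected {n_off} coefficient rows, got {beta.shape[0]}")
    if X.shape[-1] != beta.shape[1]:
        raise ValueError("design/coefficient dimension mismatch")
    eta = np.clip(X @ beta.T, -_ETA_CLIP, _ETA_CLIP)  # (..., n_off)
    shp = eta.shape[:-1]
    P = np.zeros(shp + (n_states, n_states))
    pairs = _offdiag_index(n_states)
    for i in range(n_states):
        ks = [k for k, (a, _) in enumerate(pairs) if a == i]
        e = np.exp(eta[..., ks])
        denom = 1.0 + e.sum(axis=-1)
        P[..., i, i] = 1.0 / denom
        for e_col, k in enumerate(ks):
            P[..., i, pairs[k][1]] = e[..., e_col] / denom
    return P


def intercepts_for_matrix(P: np.ndarray) -> np.ndarray:
    """Invert the logit link for a fixed matrix: eta_ij = log(P_ij / P_ii).

    Returns an (n_off, 1) coefficient array for an intercept-only model.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    return np.array([[np.log(P[i, j] / P[i, i])] for i, j in _offdiag_index(n)])


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Solve pi P = pi, sum(pi) = 1 by least squares."""
    n = P.shape[0]
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(pi < -1e-8) or not np.isfinite(pi).all():
        raise ValueError("no valid stationary distribution (reducible chain?)")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------


def _stream_cache(data: HMMData) -> dict:
    """Per-dataset sufficient statistics reused across likelihood calls.

    The zero-inflated-gamma log-density needs only log(x) and x for the
    positive part; the wrapped Cauchy needs only cos(theta). Caching them
    makes each optimizer evaluation a handful of vector operations.
    """
    cache = getattr(data, "_stream_cache", None)
    if cache is not None:
        return cache

    def gamma_parts(v):
        ok = np.isfinite(v)
        zero = ok & (v == 0.0)
        pos = ok & (v > 0.0)
        logv = np.zeros_like(v)
        logv[pos] = np.log(v[pos])
        vv = np.where(pos, v, 0.0)
        return {"zero": zero, "pos": pos, "logv": logv, "v": vv}

    cache = {"step": gamma_parts(data.step)}
    ang_ok = np.isfinite(data.angle)
    cache["angle"] = {"ok": ang_ok, "cos": np.where(ang_ok, np.cos(np.nan_to_num(data.angle)), 0.0)}
    if data.accel is not None:
        cache["accel"] = gamma_parts(data.accel)
    data._stream_cache = cache
    return cache


def _add_zigamma(out: np.ndarray, parts: dict, mean: float, sd: float, zm: float) -> None:
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    const = shape * np.log(rate) - gammaln(shape) + np.log1p(-zm)
    out += np.where(
        parts["zero"],
        np.log(zm),
        np.where(parts["pos"], const + (shape - 1.0) * parts["logv"] - rate * parts["v"], 0.0),
    )


def _emission_logprobs(data: HMMData, em: EmissionParams) -> np.ndarray:
    """(B, T, N) sum of per-stream log-densities; missing streams add 0."""
    B, T = data.step.shape
    N = em.n_states
    cache = _stream_cache(data)
    logB = np.zeros((B, T, N))
    ang = cache["angle"]
    for n in range(N):
        col = logB[..., n]
        _add_zigamma(col, cache["step"], em.step_mean[n], em.step_sd[n], em.step_zeromass[n])
        rho = em.angle_rho[n]
        col += np.where(
            ang["ok"],
            np.log1p(-rho**2) - np.log(2 * np.pi) - np.log1p(rho**2 - 2.0 * rho * ang["cos"]),
            0.0,
        )
        if em.has_accel and data.accel is not None:
            _add_zigamma(col, cache["accel"], em.accel_mean[n], em.accel_sd[n], em.accel_zeromass[n])
    logB[~data.mask] = 0.0
    return logB


def _initial_distributions(Gam0: np.ndarray) -> np.ndarray:
    """Per-track initial distribution = stationary law of the first matrix."""
    B, N = Gam0.shape[0], Gam0.shape[1]
    delta = np.empty((B, N))
    for b in range(B):
        try:
            delta[b] = stationary_distribution(Gam0[b])
        except (ValueError, np.linalg.LinAlgError):
            delta[b] = 1.0 / N
    return delta


try:  # JIT-compiled inner loop; the numpy recursion below is the fallback
    from numba import njit

    @njit(cache=False)
    def _forward_kernel(btil, m, Gam, delta, lengths):  # pragma: no cover - jitted
        B, T, N = btil.shape
        ll = np.zeros(B)
        a = np.empty(N)
        anew = np.empty(N)
        for b in range(B):
            L = lengths[b]
            c = 0.0
            for j in range(N):
                a[j] = delta[b, j] * btil[b, 0, j]
                c += a[j]
            if not (c > 0.0) or not np.isfinite(c):
                ll[b] = -np.inf
                continue
            llb = np.log(c) + m[b, 0]
            for j in range(N):
                a[j] /= c
            ok = True
            for t in range(1, L):
                c = 0.0
                for j in range(N):
                    s = 0.0
                    for i in range(N):
                        s += a[i] * Gam[b, t, i, j]
                    anew[j] = s * btil[b, t, j]
                    c += anew[j]
                if not (c > 0.0) or not np.isfinite(c):
                    ok = False
                    break
                llb += np.log(c) + m[b, t]
                for j in range(N):
                    a[j] = anew[j] / c
            ll[b] = llb if ok else -np.inf
        return ll

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _forward_ll(logB: np.ndarray, Gammas: np.ndarray, delta: np.ndarray,
                mask: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Per-track forward log-likelihoods; JIT kernel when available."""
    if _HAVE_NUMBA:
        m = logB.max(axis=2)
        btil = np.exp(logB - m[..., None])
        return _forward_kernel(
            np.ascontiguousarray(btil), m, np.ascontiguousarray(Gammas),
            np.ascontiguousarray(delta), lengths.astype(np.int64),
        )
    return _forward_batched(logB, Gammas, delta, mask)


def _forward_batched(logB: np.ndarray, Gammas: np.ndarray, delta: np.ndarray,
                     mask: np.ndarray) -> np.ndarray:
    """Scaled forward recursion over a padded batch; per-track log-likelihoods."""
    B, T, N = logB.shape
    m = logB.max(axis=2)
    btil = np.exp(logB - m[..., None])  # (B,T,N), max entry 1
    ll = np.zeros(B)
    alpha = delta * btil[:, 0]
    c = alpha.sum(axis=1)
    if np.any(c[mask[:, 0]] <= 0.0) or not np.isfinite(c).all():
        return np.full(B, -np.inf)
    ll += np.where(mask[:, 0], np.log(c) + m[:, 0], 0.0)
    alpha = alpha / c[:, None]
    for t in range(1, T):
        valid = mask[:, t]
        if not valid.any():
            break
        new = np.einsum("bi,bij->bj", alpha, Gammas[:, t]) * btil[:, t]
        c = new.sum(axis=1)
        bad = valid & ((c <= 0.0) | ~np.isfinite(c))
        if bad.any():
            return np.full(B, -np.inf)
        cs = np.where(c > 0, c, 1.0)
        ll += np.where(valid, np.log(cs) + m[:, t], 0.0)
        alpha = np.where(valid[:, None], new / cs[:, None], alpha)
    return ll


def forward_loglik(data: HMMData, params: HMMParams, per_track: bool = False):
    """Log-likelihood of the HMM under conditional independence of streams.

    Each track starts from the stationary distribution of its first
    transition matrix; tracks are independent, so the total is the sum of
    per-track forward log-likelihoods.
    """
    if params.is_mixture:
        raise TypeError("use mixture_loglik for MixtureSpec transitions")
    logB = _emission_logprobs(data, params.emission)
    Gammas = build_transition_matrices(params.transition.beta, data.X, params.n_states)
    delta = _initial_distributions(Gammas[:, 0])
    ll = _forward_ll(logB, Gammas, delta, data.mask, data.lengths)
    return ll if per_track else float(ll.sum())


def mixture_loglik(data: HMMData, params: HMMParams) -> float:
    """Marginal log-likelihood under the discrete random-effect mixture.

    Per individual m: ``log sum_k pi_k exp(ll_m | beta_k)`` with the tracks
    of one individual sharing a component (log-sum-exp stabilized).
    """
    mix = params.transition
    if not isinstance(mix, MixtureSpec):
        return forward_loglik(data, params)
    logB = _emission_logprobs(data, params.emission)
    lls = np.empty((mix.K, data.n_tracks))
    for k in range(mix.K):
        Gammas = build_transition_matrices(mix.betas[k], data.X, params.n_states)
        delta = _initial_distributions(Gammas[:, 0])
        lls[k] = _forward_ll(logB, Gammas, delta, data.mask, data.lengths)
    if not np.isfinite(lls).all():
        return -np.inf
    total = 0.0
    ind = np.asarray(data.individuals)
    logw = np.log(np.clip(mix.weights, 1e-300, None))
    for m in np.unique(ind):
        sel = ind == m
        total += logsumexp(logw + lls[:, sel].sum(axis=1))
    return float(total)


def total_loglik(data: HMMData, params: HMMParams) -> float:
    return mixture_loglik(data, params) if params.is_mixture else forward_loglik(data, params)


# --------------------------------------------------------------------------
# working-scale parameterization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamSpec:
    """Layout of the working-scale parameter vector."""

    n_states: int
    has_accel: bool
    n_design: int
    K: int = 1

    @property
    def n_off(self) -> int:
        return self.n_states * (self.n_states - 1)

    @property
    def n_emission(self) -> int:
        per_state = 3 + 1 + (3 if self.has_accel else 0)
        return per_state * self.n_states

    @property
    def size(self) -> int:
        n = self.n_emission + self.K * self.n_off * self.n_design
        if self.K > 1:
            n += self.K - 1
        return n

    def sd_indices(self) -> np.ndarray:
        """Indices of working-scale SD parameters (prior targets)."""
        N = self.n_states
        idx = list(range(N, 2 * N))  # log step_sd
        if self.has_accel:
            idx += list(range(4 * N, 5 * N))  # log accel_sd
        return np.array(idx)


def pack_params(params: HMMParams) -> tuple[np.ndarray, ParamSpec]:
    em = params.emission
    N = params.n_states
    spec = ParamSpec(
        N, em.has_accel,
        len(params.transition.columns),
        params.transition.K if params.is_mixture else 1,
    )
    parts = [np.log(em.step_mean), np.log(em.step_sd), logit(em.step_zeromass)]
    if em.has_accel:
        parts += [np.log(em.accel_mean), np.log(em.accel_sd), logit(em.accel_zeromass)]
    parts.append(logit(em.angle_rho))
    if params.is_mixture:
        mix = params.transition
        parts.append(np.log(mix.weights[1:]) - np.log(mix.weights[0]))
        parts.append(mix.betas.ravel())
    else:
        parts.append(params.transition.beta.ravel())
    return np.concatenate(parts), spec


def unpack_params(w: np.ndarray, spec: ParamSpec, columns: tuple[str, ...]) -> HMMParams:
    w = np.asarray(w, dtype=float)
    N = spec.n_states
    i = 0

    def take(n):
        nonlocal i
        out = w[i:i + n]
        i += n
        return out

    step_mean = np.exp(take(N))
    step_sd = np.exp(take(N))
    step_zm = _safe_expit(take(N))
    if spec.has_accel:
        accel_mean = np.exp(take(N))
        accel_sd = np.exp(take(N))
        accel_zm = _safe_expit(take(N))
    else:
        accel_mean = accel_sd = accel_zm = None
    rho = _safe_expit(take(N))
    em = EmissionParams(step_mean, step_sd, step_zm, rho, accel_mean, accel_sd, accel_zm)
    if spec.K > 1:
        wl = np.concatenate([[0.0], take(spec.K - 1)])
        weights = np.exp(wl - logsumexp(wl))
        betas = take(spec.K * spec.n_off * spec.n_design).reshape(
            spec.K, spec.n_off, spec.n_design)
        trans: TransitionModel | MixtureSpec = MixtureSpec(N, columns, weights, betas)
    else:
        beta = take(spec.n_off * spec.n_design).reshape(spec.n_off, spec.n_design)
        trans = TransitionModel(N, columns, beta)
    return HMMParams(N, em, trans)


def _safe_expit(x):
    return np.clip(expit(x), 1e-12, 1.0 - 1e-12)


def penalized_objective(w: np.ndarray, spec: ParamSpec, data: HMMData,
                        columns: tuple[str, ...], prior_sd: float = 100.0,
                        prior_all: bool = False) -> float:
    """Negative log-likelihood minus the Normal(0, prior_sd) log-prior.

    By default the prior covers only the working-scale SD parameters of the
    emission distributions (boundary avoidance for scale estimates); with
    ``prior_all`` it widens to every working parameter.
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        try:
            params = unpack_params(w, spec, columns)
            ll = total_loglik(data, params)
        except (ValueError, FloatingPointError):
            return np.inf
    if not np.isfinite(ll):
        return np.inf
    targets = w if prior_all else w[spec.sd_indices()]
    logprior = -0.5 * np.sum(targets**2) / prior_sd**2 \
        - len(targets) * (0.5 * np.log(2 * np.pi) + np.log(prior_sd))
    return -ll - logprior


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    params: HMMParams
    loglik: float
    penalized: float
    aic: float
    n_params: int
    n_obs: int
    formula: tuple[str, ...]
    K: int
    converged: bool
    boundary: bool
    restarts: list[dict]
    data_signature: tuple
    working: np.ndarray
    spec: ParamSpec

    @property
    def n_states(self) -> int:
        return self.params.n_states


def _moment_starts(data: HMMData, spec: ParamSpec, rng: np.random.Generator) -> np.ndarray:
    """Data-driven start: quantile (moment) split of each stream into N groups."""
    N = spec.n_states

    def split_stats(v):
        v = v[np.isfinite(v)]
        pos = v[v > 0]
        zm = np.clip(np.mean(v == 0) if len(v) else 0.01, 1e-3, 0.5)
        if len(pos) < 2 * N:
            means = np.linspace(0.5, 2.0, N)
            sds = means.copy()
        else:
            qs = np.quantile(pos, np.linspace(0, 1, N + 1))
            means, sds = [], []
            for a, b in zip(qs[:-1], qs[1:]):
                grp = pos[(pos >= a) & (pos <= b)]
                mu = float(np.mean(grp)) if len(grp) else float(np.mean(pos))
                sd = float(np.std(grp)) if len(grp) > 1 else mu
                means.append(max(mu, 1e-6))
                sds.append(max(sd, 1e-6))
            means, sds = np.array(means), np.array(sds)
        return means, sds, np.full(N, zm)

    sm, ss, sz = split_stats(data.step)
    parts = [np.log(sm), np.log(ss), logit(sz)]
    if spec.has_accel:
        am, asd, az = split_stats(data.accel)
        parts += [np.log(am), np.log(asd), logit(az)]
    parts.append(np.full(N, logit(0.5)))
    eta0 = np.zeros((spec.n_off, spec.n_design))
    eta0[:, 0] = np.log(0.1 / 0.9)  # sticky chain start
    if spec.K > 1:
        parts.append(np.zeros(spec.K - 1))
        base = np.tile(eta0.ravel(), spec.K)
        base += 0.25 * rng.standard_normal(base.size)  # break component symmetry
        parts.append(base)
    else:
        parts.append(eta0.ravel())
    return np.concatenate(parts)


def _canonicalize(params: HMMParams) -> HMMParams:
    """Relabel states so state 1 has the largest step mean."""
    perm = np.argsort(-params.emission.step_mean, kind="stable")
    if np.array_equal(perm, np.arange(params.n_states)):
        return params
    return HMMParams(params.n_states, params.emission.permuted(perm),
                     params.transition.permuted(perm))


def fit_hmm(
    data: HMMData | pd.DataFrame,
    n_states: int = 2,
    formula: tuple[str, ...] = (),
    K: int = 1,
    n_restarts: int = 50,
    seed: int = 0,
    maxiter: int = 500,
    prior_sd: float = 100.0,
    prior_all: bool = False,
) -> FitResult:
    """Fit the HMM by penalized maximum likelihood with random restarts.

    Restart 0 starts from moment-based values; each further restart adds
    standard-normal noise on the working scale. The best (lowest penalized
    objective) converged restart is returned with states relabelled so that
    state 1 has the largest step mean. AIC uses the unpenalized
    log-likelihood at the optimum.
    """
    if isinstance(data, pd.DataFrame):
        data = HMMData.from_table(data, formula)
    _, columns = _dummy_columns(data, formula)
    spec = ParamSpec(n_states, data.has_accel, len(columns), K)
    root = np.random.default_rng(seed)
    w0 = _moment_starts(data, spec, root)
    restarts: list[dict] = []
    best = None
    for r in range(max(1, n_restarts)):
        rseed = int(root.integers(2**31 - 1))
        rng = np.random.default_rng(rseed)
        w = w0.copy() if r == 0 else w0 + rng.standard_normal(spec.size)
        res = minimize(
            penalized_objective, w, args=(spec, data, columns, prior_sd, prior_all),
            method="L-BFGS-B", options={"maxiter": maxiter, "maxfun": 10**6},
        )
        rec = {"restart": r, "seed": rseed, "objective": float(res.fun),
               "success": bool(res.success), "nit": int(res.nit)}
        restarts.append(rec)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"no restart converged; log: {restarts}")
    params = _canonicalize(unpack_params(best.x, spec, columns))
    wbest, _ = pack_params(params)
    ll = total_loglik(data, params)
    n_par = spec.size
    em = params.emission
    boundary = bool(
        np.any(em.angle_rho > 1 - 1e-6)
        or np.any(em.step_zeromass < 1e-10) or np.any(em.step_zeromass > 1 - 1e-6)
        or (em.has_accel and (np.any(em.accel_zeromass < 1e-10)
                              or np.any(em.accel_zeromass > 1 - 1e-6)))
    )
    return FitResult(
        params=params, loglik=float(ll), penalized=float(best.fun),
        aic=float(-2.0 * ll + 2.0 * n_par), n_params=n_par, n_obs=data.n_obs,
        formula=tuple(formula), K=K, converged=bool(best.success),
        boundary=boundary, restarts=restarts, data_signature=data.signature(),
        working=wbest, spec=spec,
    )


def _dummy_columns(data: HMMData, formula: tuple[str, ...]) -> tuple[None, tuple[str, ...]]:
    # HMMData already expanded the design; reuse its recorded column names.
    if len(data.columns) < 1 or data.columns[0] != "intercept":
        raise ValueError("design must carry an intercept as first column")
    return None, data.columns


def compute_vcov(fit: FitResult, data: HMMData, step: float = 1e-4) -> np.ndarray:
    """Observed-information covariance of the working-scale parameters.

    Central-difference Hessian of the negative unpenalized log-likelihood
    at the optimum, pseudo-inverted for robustness near boundaries.
    """
    w = fit.working
    n = len(w)
    cols = fit.params.transition.columns

    def nll(v):
        p = unpack_params(v, fit.spec, cols)
        return -total_loglik(data, p)

    H = np.empty((n, n))
    f0 = nll(w)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            if i == j:
                H[i, i] = (nll(w + ei) - 2 * f0 + nll(w - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    nll(w + ei + ej) - nll(w + ei - ej)
                    - nll(w - ei + ej) + nll(w - ei - ej)
                ) / (4 * step**2)
    return np.linalg.pinv(H)
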