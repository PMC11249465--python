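"""Hidden Markov model of movement behaviour with temperature-driven switching.

Two latent behavioural states ("resting" and "traveling") generate step
lengths and turn angles on the regular 4-h grid: step lengths follow a gamma
distribution (parameterized by mean and SD per state) and turn angles a von
Mises distribution (mean direction and concentration per state).  State
transition probabilities follow a multinomial-logit model in ambient
temperature, optionally with a quadratic term::

    logit P(i -> j | x) = beta0_ij + beta1_ij * x [+ beta2_ij * x^2]

Each track segment is an independent time series sharing one parameter set;
the model is fitted by direct numerical maximization of the forward-algorithm
likelihood from many random restarts, compared across covariate formulations
by AICc, and decoded with the Viterbi algorithm.

State labels are resolved after fitting: state 1 is always the state with the
smaller fitted step mean (resting), state 2 the larger (traveling).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import gammaln, i0e, expit, logit

from .geo import great_circle_km, initial_bearing_rad, wrap_angle
from .regularize import RegularTrack

__all__ = [
    "MODEL_LABELS",
    "StepSeries",
    "HmmParams",
    "HmmFit",
    "Decoding",
    "steps_and_turns",
    "build_step_series",
    "treat_zero_steps",
    "hmm_loglik",
    "count_parameters",
    "fit_hmm",
    "aicc",
    "model_selection",
    "viterbi_decode",
    "stationary_distribution",
    "stationary_probs",
    "time_budget",
]

MODEL_LABELS = ("intercept_only", "temp", "temp2")
_N_COVARIATES = {"intercept_only": 0, "temp": 1, "temp2": 2}
_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class StepSeries:
    """Step lengths, turn angles and the temperature covariate per interval.

    ``data`` columns: ``segment_id, step_km, turn_rad, temp_c``.  The first
    interval of each segment has an undefined turn angle (NaN).  Segments are
    independent time series under shared parameters.
    """

    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    def segments(self):
        for seg_id, g in self.data.groupby("segment_id", sort=False):
            yield seg_id, g

    @property
    def n_obs(self) -> int:
        return len(self.data)


@dataclass
class HmmParams:
    """Natural-scale HMM parameters for N states (arrays indexed by state).

    ``beta12``/``beta21`` are the multinomial-logit coefficients of the
    off-diagonal transitions (intercept first, then one coefficient per
    covariate term) on the temperature scale the params are declared for.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    turn_mean: np.ndarray
    turn_conc: np.ndarray
    beta12: np.ndarray
    beta21: np.ndarray
    delta: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.step_mean)

    @property
    def n_covariates(self) -> int:
        return len(self.beta12) - 1

    def validate(self) -> None:
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("gamma step parameters must be positive")
        if np.any(self.turn_conc < 0):
            raise ValueError("von Mises concentration must be >= 0")
        if np.any(self.delta < 0) or not np.isclose(self.delta.sum(), 1.0):
            raise ValueError("initial distribution must be a probability vector")
        if len(self.beta12) != len(self.beta21):
            raise ValueError("transition coefficient vectors must have equal length")


@dataclass
class HmmFit:
    """A fitted HMM: parameters, likelihood, parameter count and AICc."""

    params: HmmParams  # on the raw temperature scale (deg C)
    params_std: HmmParams  # on the standardized (z-score) covariate scale
    temp_center: float
    temp_scale: float
    loglik: float
    K: int
    n_obs: int
    aicc: float
    model_label: str
    n_restarts_converged: int


@dataclass
class Decoding:
    """Viterbi path, posterior state probabilities, and time budget."""

    states: np.ndarray  # 1-based Viterbi states per interval
    posterior: np.ndarray  # (T, N) forward-backward probabilities
    segment_id: np.ndarray
    n_states: int = 2

    def time_budget(self) -> np.ndarray:
        return time_budget(self)


# ---------------------------------------------------------------------------
# step/turn construction


def steps_and_turns(track: RegularTrack, segment_id=None) -> StepSeries:
    """Derive step lengths and turn angles from a regular track.

    Step t is the great-circle distance (km) between grid points t and t+1;
    turn t is the change in bearing between consecutive steps, wrapped to
    (-pi, pi] (undefined for the first step).  The covariate is the
    temperature at the step's start point.  Grid points flagged
    ``temp_missing`` yield covariate-missing steps, which are dropped.
    """
    df = track.data
    if len(df) < 3:
        raise ValueError("steps and turns need at least 3 grid points")
    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    step = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    bearing = initial_bearing_rad(lon[:-1], lat[:-1], lon[1:], lat[1:])
    turn = np.full(len(step), np.nan)
    turn[1:] = wrap_angle(np.diff(bearing))
    if "temp_c" in df.columns:
        temp = df["temp_c"].to_numpy(dtype=float)[:-1]
        missing = df.get("temp_missing")
        if missing is not None:
            temp = np.where(missing.to_numpy()[:-1], np.nan, temp)
    else:
        temp = np.full(len(step), np.nan)
    seg_id = segment_id if segment_id is not None else f"{track.tag_id}:{track.segment_index}"
    data = pd.DataFrame(
        {"segment_id": seg_id, "step_km": np.atleast_1d(step), "turn_rad": turn, "temp_c": temp}
    )
    return StepSeries(data)


def build_step_series(tracks, drop_covariate_missing: bool = True) -> StepSeries:
    """Concatenate steps/turns of several regular tracks into one series.

    Covariate-missing intervals are dropped (not imputed) when any track
    carries a temperature covariate at all.
    """
    frames = [steps_and_turns(t).data for t in tracks]
    data = pd.concat(frames, ignore_index=True)
    temp = data["temp_c"].to_numpy(dtype=float)
    if drop_covariate_missing and np.isfinite(temp).any():
        data = data[np.isfinite(temp)]
    return StepSeries(data.reset_index(drop=True))


def treat_zero_steps(series: StepSeries) -> StepSeries:
    """Replace exact zero steps by half the minimum positive observed step.

    The fitted gamma has no mass at zero; this standard pre-treatment keeps
    the likelihood finite without zero-inflation parameters.
    """
    data = series.data.copy()
    step = data["step_km"].to_numpy(dtype=float)
    pos = step[step > 0]
    if (step == 0).any():
        if pos.size == 0:
            raise ValueError("all steps are zero; nothing to fit")
        data.loc[step == 0, "step_km"] = pos.min() / 2.0
    return StepSeries(data)


# ---------------------------------------------------------------------------
# densities and transition matrices


def _gamma_logpdf(x, mean, sd):
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    return shape * np.log(rate) + (shape - 1.0) * np.log(x) - rate * x - gammaln(shape)


def _vonmises_logpdf(theta, mu, kappa):
    # log I0(kappa) = log(i0e(kappa)) + kappa, stable for large kappa
    return kappa * np.cos(theta - mu) - _LOG_2PI - (np.log(i0e(kappa)) + kappa)


def _design_matrix(temp: np.ndarray, p: int) -> np.ndarray:
    X = np.ones((len(temp), p + 1))
    if p >= 1:
        X[:, 1] = temp
    if p >= 2:
        X[:, 2] = temp**2
    return X


def transition_matrices(params: HmmParams, temp: np.ndarray) -> np.ndarray:
    """Row-stochastic 2x2 transition matrices Gamma(x) per covariate value."""
    X = _design_matrix(np.asarray(temp, dtype=float), params.n_covariates)
    p12 = expit(X @ params.beta12)
    p21 = expit(X @ params.beta21)
    G = np.empty((len(X), 2, 2))
    G[:, 0, 0] = 1.0 - p12
    G[:, 0, 1] = p12
    G[:, 1, 0] = p21
    G[:, 1, 1] = 1.0 - p21
    return G


def _emission_logdensity(step, turn, params: HmmParams) -> np.ndarray:
    """(T, N) log emission density; undefined turns contribute step only."""
    T = len(step)
    N = params.n_states
    logb = np.empty((T, N))
    finite_turn = np.isfinite(turn)
    for s in range(N):
        logb[:, s] = _gamma_logpdf(step, params.step_mean[s], params.step_sd[s])
        vm = _vonmises_logpdf(turn[finite_turn], params.turn_mean[s], params.turn_conc[s])
        logb[finite_turn, s] += vm
    return logb


# ---------------------------------------------------------------------------
# numba forward / Viterbi kernels


@njit(cache=True)
def _forward_kernel(logb, lgamma, logdelta, seg_start):
    total = 0.0
    n_seg = seg_start.size - 1
    N = logb.shape[1]
    la = np.empty(N)
    tmp = np.empty(N)
    for k in range(n_seg):
        a = seg_start[k]
        b = seg_start[k + 1]
        for j in range(N):
            la[j] = logdelta[j] + logb[a, j]
        for t in range(a + 1, b):
            for j in range(N):
                m = -np.inf
                for i in range(N):
                    v = la[i] + lgamma[t, i, j]
                    if v > m:
                        m = v
                if m == -np.inf:
                    tmp[j] = -np.inf
                else:
                    s = 0.0
                    for i in range(N):
                        s += np.exp(la[i] + lgamma[t, i, j] - m)
                    tmp[j] = m + np.log(s) + logb[t, j]
            for j in range(N):
                la[j] = tmp[j]
        m = -np.inf
        for j in range(N):
            if la[j] > m:
                m = la[j]
        if m == -np.inf:
            return -np.inf
        s = 0.0
        for j in range(N):
            s += np.exp(la[j] - m)
        total += m + np.log(s)
    return total


@njit(cache=True)
def _viterbi_kernel(logb, lgamma, logdelta, seg_start, states):
    n_seg = seg_start.size - 1
    N = logb.shape[1]
    for k in range(n_seg):
        a = seg_start[k]
        b = seg_start[k + 1]
        T = b - a
        dp = np.empty((T, N))
        bp = np.zeros((T, N), np.int64)
        for j in range(N):
            dp[0, j] = logdelta[j] + logb[a, j]
        for t in range(1, T):
            for j in range(N):
                best = -np.inf
                arg = 0
                for i in range(N):
                    v = dp[t - 1, i] + lgamma[a + t, i, j]
                    if v > best:  # strict: ties resolve to the lower state
                        best = v
                        arg = i
                dp[t, j] = best + logb[a + t, j]
                bp[t, j] = arg
        best = -np.inf
        arg = 0
        for j in range(N):
            if dp[T - 1, j] > best:
                best = dp[T - 1, j]
                arg = j
        states[b - 1] = arg
        for t in range(T - 1, 0, -1):
            arg = bp[t, arg]
            states[a + t - 1] = arg


def _series_arrays(series: StepSeries):
    data = series.data
    step = data["step_km"].to_numpy(dtype=float)
    turn = data["turn_rad"].to_numpy(dtype=float)
    temp = data["temp_c"].to_numpy(dtype=float)
    seg = data["segment_id"].to_numpy()
    boundaries = np.flatnonzero(seg[1:] != seg[:-1]) + 1
    seg_start = np.concatenate([[0], boundaries, [len(seg)]]).astype(np.int64)
    return step, turn, temp, seg_start


def hmm_loglik(series: StepSeries, params: HmmParams) -> float:
    """Forward-algorithm log-likelihood of a step series under ``params``.

    Segments contribute independently.  Exact zero steps must be pre-treated
    (see :func:`treat_zero_steps`); an untreated zero raises, naming the
    interval.
    """
    params.validate()
    step, turn, temp, seg_start = _series_arrays(series)
    bad = np.flatnonzero(step <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive step at interval {int(bad[0])}; apply treat_zero_steps before fitting"
        )
    if params.n_covariates > 0 and not np.all(np.isfinite(temp)):
        raise ValueError("temperature covariate missing but required by the transition model")
    logb = _emission_logdensity(step, turn, params)
    G = transition_matrices(params, np.nan_to_num(temp))
    with np.errstate(divide="ignore"):
        lgamma = np.log(np.roll(G, 1, axis=0))  # lgamma[t] = log Gamma(x_{t-1})
        logdelta = np.log(params.delta)
    return float(_forward_kernel(logb, lgamma, logdelta, seg_start))


def count_parameters(n_states: int, model_label: str) -> int:
    """Number of free parameters K of an N-state model.

    2N gamma + 2N von Mises + N(N-1)(1+p) transition coefficients
    + (N-1) initial-distribution parameters, p = covariate terms (0, 1, 2).
    """
    if model_label not in MODEL_LABELS:
        raise ValueError(f"unknown model label {model_label!r}")
    p = _N_COVARIATES[model_label]
    N = n_states
    return 2 * N + 2 * N + N * (N - 1) * (1 + p) + (N - 1)


def aicc(loglik: float, K: int, n_obs: int) -> float:
    """Small-sample Akaike information criterion."""
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n_obs - K - 1)


# ---------------------------------------------------------------------------
# fitting


def _pack(params: HmmParams) -> np.ndarray:
    # von Mises (mean, concentration) -> unconstrained plane point
    # kappa * (cos mu, sin mu): avoids the flat log-kappa ridge at kappa -> 0
    a = params.turn_conc * np.cos(params.turn_mean)
    b = params.turn_conc * np.sin(params.turn_mean)
    return np.concatenate(
        [
            np.log(params.step_mean),
            np.log(params.step_sd),
            a,
            b,
            params.beta12,
            params.beta21,
            [logit(params.delta[0])],
        ]
    )


def _unpack(theta: np.ndarray, p: int) -> HmmParams:
    theta = np.clip(theta, -30.0, 30.0)
    k = 1 + p
    mu = np.exp(theta[0:2])
    sd = np.exp(theta[2:4])
    a = theta[4:6]
    b = theta[6:8]
    kappa = np.hypot(a, b)
    tmu = np.arctan2(b, a)
    beta12 = theta[8 : 8 + k]
    beta21 = theta[8 + k : 8 + 2 * k]
    d1 = expit(theta[8 + 2 * k])
    return HmmParams(mu, sd, tmu, kappa, beta12, beta21, np.array([d1, 1.0 - d1]))


def _order_states(params: HmmParams) -> HmmParams:
    """Relabel so state 1 has the smaller step mean (resting convention)."""
    if params.step_mean[0] <= params.step_mean[1]:
        return params
    sw = [1, 0]
    return HmmParams(
        params.step_mean[sw],
        params.step_sd[sw],
        params.turn_mean[sw],
        params.turn_conc[sw],
        params.beta21.copy(),
        params.beta12.copy(),
        params.delta[sw],
    )


def _betas_to_raw(beta: np.ndarray, m: float, s: float) -> np.ndarray:
    """Convert logit coefficients from z-scored temp to raw deg C."""
    out = np.zeros_like(beta)
    b0 = beta[0]
    b1 = beta[1] if len(beta) > 1 else 0.0
    b2 = beta[2] if len(beta) > 2 else 0.0
    out[0] = b0 - b1 * m / s + b2 * m * m / (s * s)
    if len(beta) > 1:
        out[1] = b1 / s - 2.0 * b2 * m / (s * s)
    if len(beta) > 2:
        out[2] = b2 / (s * s)
    return out


def _draw_start(theta_shape_p: int, step: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random restart start values (documented ranges; coefficients at 0)."""
    p = theta_shape_p
    lo, hi = np.percentile(step, [5.0, 95.0])
    lo = max(lo, 1e-6)
    hi = max(hi, lo * 1.001)
    means = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=2)))
    sds = means.copy()
    tmu = rng.choice([0.0, np.pi], size=2)
    kappa = np.exp(rng.uniform(np.log(0.1), np.log(5.0), size=2))
    dwell = rng.uniform(0.7, 0.99, size=2)
    b12 = np.zeros(1 + p)
    b21 = np.zeros(1 + p)
    b12[0] = logit(1.0 - dwell[0])
    b21[0] = logit(1.0 - dwell[1])
    return _pack(HmmParams(means, sds, tmu, kappa, b12, b21, np.array([0.5, 0.5])))


def fit_hmm(
    series: StepSeries,
    model_label: str = "temp",
    n_restarts: int = 50,
    seed: int = 0,
    n_states: int = 2,
    max_iter: int = 300,
) -> HmmFit:
    """Fit the HMM by direct likelihood maximization from random restarts.

    The temperature covariate is z-scored internally for numerical stability;
    the returned fit carries coefficients on both scales.  Deterministic for
    a given seed.  Raises if no restart converges.
    """
    if n_states != 2:
        raise NotImplementedError("only the two-state model is implemented")
    if model_label not in MODEL_LABELS:
        raise ValueError(f"unknown model label {model_label!r}")
    p = _N_COVARIATES[model_label]
    series = treat_zero_steps(series)
    step, turn, temp, seg_start = _series_arrays(series)
    if p > 0 and not np.all(np.isfinite(temp)):
        raise ValueError("temperature covariate required for this model but missing")

    if np.all(np.isfinite(temp)):
        m = float(np.mean(temp))
        s = float(np.std(temp)) or 1.0
        z = (temp - m) / s
    else:
        m, s = 0.0, 1.0
        z = np.zeros_like(step)
    X = _design_matrix(z, p)

    def nll(theta: np.ndarray) -> float:
        params = _unpack(theta, p)
        try:
            logb = _emission_logdensity(step, turn, params)
        except FloatingPointError:
            return 1e12
        eta12 = X @ params.beta12
        eta21 = X @ params.beta21
        p12 = expit(eta12)
        p21 = expit(eta21)
        G = np.empty((len(step), 2, 2))
        G[:, 0, 0] = 1.0 - p12
        G[:, 0, 1] = p12
        G[:, 1, 0] = p21
        G[:, 1, 1] = 1.0 - p21
        with np.errstate(divide="ignore"):
            lgamma = np.log(np.roll(G, 1, axis=0))
            logdelta = np.log(params.delta)
        ll = _forward_kernel(logb, lgamma, logdelta, seg_start)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    n_converged = 0
    diagnostics = []
    for r in range(n_restarts):
        theta0 = _draw_start(p, step, rng)
        try:
            res = minimize(
                nll,
                theta0,
                method="L-BFGS-B",
                options={"maxiter": max_iter, "gtol": 1e-6},
            )
        except (ValueError, FloatingPointError) as exc:  # pathological start
            diagnostics.append(f"restart {r}: {exc}")
            continue
        grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-3
        converged = bool(res.success or grad_ok)
        if converged:
            n_converged += 1
        else:
            diagnostics.append(f"restart {r}: {res.message}")
        if converged and np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            "no HMM restart converged; per-restart diagnostics: " + "; ".join(diagnostics[:10])
        )

    params_std = _order_states(_unpack(best.x, p))
    params_raw = replace(
        params_std,
        beta12=_betas_to_raw(params_std.beta12, m, s),
        beta21=_betas_to_raw(params_std.beta21, m, s),
    )
    loglik = -float(best.fun)
    K = count_parameters(n_states, model_label)
    n_obs = series.n_obs
    return HmmFit(
        params=params_raw,
        params_std=params_std,
        temp_center=m,
        temp_scale=s,
        loglik=loglik,
        K=K,
        n_obs=n_obs,
        aicc=aicc(loglik, K, n_obs),
        model_label=model_label,
        n_restarts_converged=n_converged,
    )


def model_selection(fits: list[HmmFit]) -> pd.DataFrame:
    """Rank fits by AICc; columns model, K, loglik, AICc, delta_AICc.

    All fits must be on the same data (checked via n_obs).
    """
    if len({f.n_obs for f in fits}) > 1:
        raise ValueError("model selection requires fits on identical data")
    rows = [
        {"model": f.model_label, "K": f.K, "loglik": f.loglik, "AICc": f.aicc} for f in fits
    ]
    table = pd.DataFrame(rows)
    table["delta_AICc"] = table["AICc"] - table["AICc"].min()
    return table.sort_values("delta_AICc", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# decoding and derived summaries


def _forward_backward(logb, lgamma, logdelta, seg_start):
    T, N = logb.shape
    post = np.empty((T, N))
    for k in range(len(seg_start) - 1):
        a, b = seg_start[k], seg_start[k + 1]
        n = b - a
        la = np.empty((n, N))
        la[0] = logdelta + logb[a]
        for t in range(1, n):
            prev = la[t - 1][:, None] + lgamma[a + t]
            mx = prev.max(axis=0)
            la[t] = mx + np.log(np.exp(prev - mx).sum(axis=0)) + logb[a + t]
        lb = np.zeros((n, N))
        for t in range(n - 2, -1, -1):
            nxt = lgamma[a + t + 1] + (logb[a + t + 1] + lb[t + 1])[None, :]
            mx = nxt.max(axis=1)
            lb[t] = mx + np.log(np.exp(nxt - mx[:, None]).sum(axis=1))
        lp = la + lb
        lp -= lp.max(axis=1, keepdims=True)
        pr = np.exp(lp)
        post[a:b] = pr / pr.sum(axis=1, keepdims=True)
    return post


def viterbi_decode(series: StepSeries, fit: HmmFit | HmmParams) -> Decoding:
    """Most-likely state path per segment plus posterior state probabilities.

    Ties in the dynamic program break toward the lower state index.
    """
    params = fit.params if isinstance(fit, HmmFit) else fit
    series = treat_zero_steps(series)
    step, turn, temp, seg_start = _series_arrays(series)
    logb = _emission_logdensity(step, turn, params)
    G = transition_matrices(params, np.nan_to_num(temp))
    with np.errstate(divide="ignore"):
        lgamma = np.log(np.roll(G, 1, axis=0))
        logdelta = np.log(params.delta)
    states = np.zeros(len(step), dtype=np.int64)
    _viterbi_kernel(logb, lgamma, logdelta, seg_start, states)
    post = _forward_backward(logb, lgamma, logdelta, seg_start)
    return Decoding(
        states=states + 1,
        posterior=post,
        segment_id=series.data["segment_id"].to_numpy(),
        n_states=params.n_states,
    )


def brute_force_loglik(series: StepSeries, params: HmmParams) -> float:
    """Exhaustive-enumeration log-likelihood (oracle; tractable for T <= ~12)."""
    step, turn, temp, seg_start = _series_arrays(series)
    logb = _emission_logdensity(step, turn, params)
    with np.errstate(divide="ignore"):
        G = transition_matrices(params, np.nan_to_num(temp))
    total = 0.0
    N = params.n_states
    for k in range(len(seg_start) - 1):
        a, b = seg_start[k], seg_start[k + 1]
        T = b - a
        terms = []
        for path in itertools.product(range(N), repeat=T):
            with np.errstate(divide="ignore"):
                lp = np.log(params.delta[path[0]]) + logb[a, path[0]]
                for t in range(1, T):
                    lp += np.log(G[a + t - 1, path[t - 1], path[t]]) + logb[a + t, path[t]]
            terms.append(lp)
        mx = max(terms)
        total += mx + np.log(sum(np.exp(t - mx) for t in terms))
    return float(total)


def brute_force_viterbi(series: StepSeries, params: HmmParams) -> np.ndarray:
    """Exhaustive argmax state path (oracle), ties toward lower indices."""
    step, turn, temp, seg_start = _series_arrays(series)
    logb = _emission_logdensity(step, turn, params)
    G = transition_matrices(params, np.nan_to_num(temp))
    N = params.n_states
    out = np.zeros(len(step), dtype=np.int64)
    for k in range(len(seg_start) - 1):
        a, b = seg_start[k], seg_start[k + 1]
        T = b - a
        best_lp = -np.inf
        best_path = None
        for path in itertools.product(range(N), repeat=T):
            with np.errstate(divide="ignore"):
                lp = np.log(params.delta[path[0]]) + logb[a, path[0]]
                for t in range(1, T):
                    lp += np.log(G[a + t - 1, path[t - 1], path[t]]) + logb[a + t, path[t]]
            if lp > best_lp:  # product() iterates lexicographically: ties keep lower path
                best_lp = lp
                best_path = path
        out[a:b] = np.array(best_path) + 1
    return out


def stationary_distribution(G: np.ndarray) -> np.ndarray:
    """Stationary distribution pi of one row-stochastic matrix (pi G = pi)."""
    N = G.shape[0]
    if np.any(np.isclose(G[~np.eye(N, dtype=bool)], 0.0)):
        raise ValueError("transition matrix is reducible or absorbing; no unique stationary law")
    A = np.vstack([G.T - np.eye(N), np.ones(N)])
    b = np.concatenate([np.zeros(N), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


def stationary_probs(fit: HmmFit | HmmParams, temp_grid) -> pd.DataFrame:
    """Long-run state occupancy pi(state | temp) along a temperature grid.

    Solves pi Gamma(x) = pi at each grid value; rows sum to 1.  For a fitted
    model this is the "stationary state probability" curve relating resting
    and traveling occupancy to ambient temperature.
    """
    params = fit.params if isinstance(fit, HmmFit) else fit
    temp_grid = np.asarray(temp_grid, dtype=float)
    G = transition_matrices(params, temp_grid)
    rows = [stationary_distribution(G[i]) for i in range(len(temp_grid))]
    pi = np.vstack(rows)
    return pd.DataFrame({"temp_c": temp_grid, "p_resting": pi[:, 0], "p_traveling": pi[:, 1]})


def time_budget(decoding: Decoding) -> np.ndarray:
    """Proportion of decoded intervals spent in each state (sums to 1)."""
    if len(decoding.states) == 0:
        raise ValueError("empty decoding")
    counts = np.bincount(decoding.states - 1, minlength=decoding.n_states)
    return counts / counts.sum()
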