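"""Gaussian mixture modelling of the Ks sample (EM + BIC model selection).

Duplication events leave peaks in the paralog Ks distribution.  Following
the classical finite-normal-mixture approach, the Ks sample is fit with
univariate Gaussian mixtures (unequal variances) for every component count
k in a range (1-10 by default), by expectation-maximization with multiple
restarts; the model with the lowest Bayesian information criterion

    BIC = -2 loglik + p ln(n),    p = 3k - 1

is selected, and its component means are reported as candidate duplication
peaks.  Means at or below a recency cutoff (Ks <= 0.1 by default) are
classified as current/recent duplications; the rest as ancient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

__all__ = ["MixtureModel", "fit_gmm", "select_mixture", "classify_peaks"]

SD_FLOOR = 1e-4

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureModel:
    """A fitted univariate Gaussian mixture, components sorted by mean."""

    k: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    loglik: float
    bic: float
    n: int
    loglik_trace: tuple[float, ...] = field(default=(), compare=False, repr=False)
    bic_table: Optional[dict[int, float]] = field(default=None, compare=False, repr=False)


@njit(cache=True)
def _em_kernel(x, w, mu, sd, tol, max_iter, sd_floor):  # pragma: no cover
    n = x.shape[0]
    k = w.shape[0]
    log_sqrt_2pi = 0.9189385332046727
    resp = np.empty((n, k))
    lconst = np.empty(k)
    trace = np.empty(max_iter + 1)
    prev = -np.inf
    t = 0
    while t < max_iter:
        for j in range(k):
            lconst[j] = np.log(w[j]) - np.log(sd[j]) - log_sqrt_2pi
        ll = 0.0
        for i in range(n):
            mx = -1e300
            for j in range(k):
                u = (x[i] - mu[j]) / sd[j]
                lp = lconst[j] - 0.5 * u * u
                resp[i, j] = lp
                if lp > mx:
                    mx = lp
            s = 0.0
            for j in range(k):
                s += np.exp(resp[i, j] - mx)
            li = mx + np.log(s)
            ll += li
            for j in range(k):
                resp[i, j] = np.exp(resp[i, j] - li)
        trace[t] = ll
        for j in range(k):
            nk = 0.0
            m1 = 0.0
            for i in range(n):
                nk += resp[i, j]
                m1 += resp[i, j] * x[i]
            if nk < 1e-300:
                nk = 1e-300
            w[j] = nk / n
            mu[j] = m1 / nk
            v = 0.0
            for i in range(n):
                d = x[i] - mu[j]
                v += resp[i, j] * d * d
            sdj = np.sqrt(v / nk)
            sd[j] = sdj if sdj > sd_floor else sd_floor
        t += 1
        bound = tol * (abs(ll) if abs(ll) > 1.0 else 1.0)
        if np.isfinite(prev) and ll - prev < bound:
            break
        prev = ll
    # log-likelihood of the final parameters
    for j in range(k):
        lconst[j] = np.log(w[j]) - np.log(sd[j]) - log_sqrt_2pi
    ll = 0.0
    for i in range(n):
        mx = -1e300
        for j in range(k):
            u = (x[i] - mu[j]) / sd[j]
            lp = lconst[j] - 0.5 * u * u
            resp[i, j] = lp
            if lp > mx:
                mx = lp
        s = 0.0
        for j in range(k):
            s += np.exp(resp[i, j] - mx)
        ll += mx + np.log(s)
    trace[t] = ll
    return w, mu, sd, ll, trace[: t + 1]


def _em(
    x: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    sd: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[float]]:
    w, mu, sd, ll, trace = _em_kernel(
        x.astype(np.float64),
        w.astype(np.float64),
        mu.astype(np.float64),
        sd.astype(np.float64),
        tol,
        max_iter,
        SD_FLOOR,
    )
    return w, mu, sd, float(ll), [float(v) for v in trace]


def _bic(loglik: float, k: int, n: int) -> float:
    p = 3 * k - 1
    return -2.0 * loglik + p * np.log(n)


def fit_gmm(
    values: Sequence[float], k: int, seed: int = 0, restarts: int = 10
) -> MixtureModel:
    """Fit a k-component Gaussian mixture by EM, best of ``restarts`` inits.

    The first initialization spreads means over the data quantiles; the
    remaining restarts jitter those means.  EM runs to a relative
    log-likelihood change below 1e-8 or 500 iterations.  Requires n >= 5k.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n < 5 * k:
        raise ValueError(f"insufficient data for k={k}: need n >= {5 * k}, have {n}")
    rng = np.random.default_rng(seed)
    base_mu = np.quantile(x, (np.arange(k) + 0.5) / k)
    sample_sd = max(float(np.std(x)), SD_FLOOR)
    best: Optional[tuple] = None
    for r in range(restarts):
        if r == 0:
            mu0 = base_mu.copy()
        else:
            mu0 = base_mu + rng.normal(0.0, sample_sd / max(k, 2), size=k)
        sd0 = np.full(k, max(sample_sd / k, SD_FLOOR))
        w0 = np.full(k, 1.0 / k)
        w, mu, sd, ll, trace = _em(x, w0, mu0, sd0)
        if best is None or ll > best[3]:
            best = (w, mu, sd, ll, trace)
    w, mu, sd, ll, trace = best
    order = np.argsort(mu)
    return MixtureModel(
        k=k,
        weights=tuple(float(v) for v in w[order]),
        means=tuple(float(v) for v in mu[order]),
        sds=tuple(float(v) for v in sd[order]),
        loglik=ll,
        bic=float(_bic(ll, k, n)),
        n=n,
        loglik_trace=tuple(trace),
    )


def select_mixture(
    values: Sequence[float],
    k_min: int = 1,
    k_max: int = 10,
    seed: int = 0,
    restarts: int = 10,
) -> MixtureModel:
    """Fit every feasible k in [k_min, k_max] and return the lowest-BIC model.

    Ties (|delta BIC| < 1e-6) are broken toward the smaller k.  The returned
    model carries the full k -> BIC table.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5 * k_min:
        raise ValueError(f"insufficient data for k={k_min}")
    seeds = np.random.SeedSequence(seed).spawn(k_max - k_min + 1)
    bic_table: dict[int, float] = {}
    best: Optional[MixtureModel] = None
    for i, k in enumerate(range(k_min, k_max + 1)):
        if len(x) < 5 * k:
            break
        sub_seed = int(seeds[i].generate_state(1)[0] % (2 ** 31))
        model = fit_gmm(x, k, seed=sub_seed, restarts=restarts)
        bic_table[k] = model.bic
        if best is None or model.bic < best.bic - 1e-6:
            best = model
    assert best is not None
    return MixtureModel(
        k=best.k,
        weights=best.weights,
        means=best.means,
        sds=best.sds,
        loglik=best.loglik,
        bic=best.bic,
        n=best.n,
        loglik_trace=best.loglik_trace,
        bic_table=bic_table,
    )


def classify_peaks(
    model: MixtureModel, recent_cutoff: float = 0.1
) -> tuple[list[float], list[float]]:
    """Partition component means into (recent, ancient) by the Ks cutoff.

    Means <= cutoff are current/recent duplications; the rest are candidate
    ancient duplication peaks.
    """
    recent = [m for m in model.means if m <= recent_cutoff]
    ancient = [m for m in model.means if m > recent_cutoff]
    return recent, ancient
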