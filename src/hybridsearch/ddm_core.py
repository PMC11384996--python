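"""Wiener drift-diffusion process: densities, simulation, likelihood, fitting.

The process starts at 0 between absorbing boundaries at +B and -B and
accumulates evidence with drift ``mu`` and diffusion coefficient ``sigma``
(evidence units per sqrt-second).  An observed response time is the boundary
crossing time plus a non-decision time ``t0``; trials that do not absorb by
``t_max`` are non-responses.  A small uniform contaminant mixture
(``contaminant_lambda``) makes the likelihood robust to outlier RTs.

First-passage-time densities use the standard small-time / large-time series
expansions with accuracy-matched truncation, switching at the point where the
cheaper series achieves the requested tolerance.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import differential_evolution

__all__ = [
    "DDMParams",
    "FitResult",
    "choice_probability",
    "mean_decision_time",
    "wfpt_density",
    "simulate",
    "robust_neg_log_likelihood",
    "fit",
]

# truncation tolerance for the infinite-series density, on the standardized
# (a=1) scale; the error on the physical scale is tolerance / a^2 < tolerance
_SERIES_EPS = 1e-10


@dataclass(frozen=True)
class DDMParams:
    """Parameters of a symmetric two-boundary Wiener diffusion.

    Attributes
    ----------
    mu : float
        Drift rate, evidence units per second.  Positive drift favours the
        upper boundary.
    boundary : float
        Boundary height B > 0; absorbing boundaries sit at +B and -B and the
        process starts at 0 (no starting-point bias).
    t0 : float
        Non-decision time in seconds (encoding + motor), 0 <= t0 < t_max.
    sigma : float
        Diffusion coefficient, evidence units per sqrt-second.  Fixed at 1 by
        convention; it only sets the evidence scale.
    contaminant_lambda : float
        Mixture weight in [0, 1) of a uniform contaminant process over
        response times in (t0, t_max] with a fair boundary coin.
    t_max : float
        Response deadline in seconds.
    """

    mu: float
    boundary: float
    t0: float = 0.0
    sigma: float = 1.0
    contaminant_lambda: float = 0.0
    t_max: float = 7.0

    def __post_init__(self) -> None:
        if not (self.boundary > 0):
            raise ValueError(f"boundary must be positive, got {self.boundary}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (0 <= self.contaminant_lambda < 1):
            raise ValueError(
                f"contaminant_lambda must be in [0, 1), got {self.contaminant_lambda}"
            )
        if not (self.t_max > 0):
            raise ValueError(f"t_max must be positive, got {self.t_max}")
        if not (0 <= self.t0 < self.t_max):
            raise ValueError(f"t0 must satisfy 0 <= t0 < t_max, got {self.t0}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood DDM fit."""

    params: DDMParams
    neg_log_likelihood: float
    n_evaluations: int
    converged: bool
    seed: int
    bounds: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "neg_log_likelihood": self.neg_log_likelihood,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "seed": self.seed,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# closed-form summaries
# ---------------------------------------------------------------------------

def choice_probability(params: DDMParams) -> float:
    """Probability that the process is absorbed at the upper boundary.

    Standard Wiener identity for a symmetric start:
    P(+B) = 1 / (1 + exp(-2 mu B / sigma^2)).
    """
    x = 2.0 * params.mu * params.boundary / params.sigma**2
    # logistic in a numerically safe form
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def mean_decision_time(params: DDMParams) -> float:
    """Expected boundary-crossing time (excludes t0), ignoring the deadline.

    (B/mu) tanh(mu B / sigma^2) for mu != 0, with continuous limit
    B^2/sigma^2 at mu = 0.
    """
    B, mu, s2 = params.boundary, params.mu, params.sigma**2
    x = mu * B / s2
    if abs(x) < 1e-8:
        return B * B / s2
    return (B / mu) * math.tanh(x)


# ---------------------------------------------------------------------------
# first-passage-time density
# ---------------------------------------------------------------------------

def _fpt_series(u: np.ndarray, eps: float = _SERIES_EPS) -> np.ndarray:
    """Zero-drift FPT density at the lower boundary on the standardized scale.

    ``u`` is decision time divided by a^2 for boundary separation a and unit
    diffusion, with relative start w = 1/2 (symmetric).  Small-time and
    large-time expansions are truncated to absolute error ``eps`` and the
    cheaper adequate series is used per element.
    """
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    pos = u > 0
    if not np.any(pos):
        return out
    up = u[pos]
    w = 0.5

    # required number of terms for each expansion (standard accuracy bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(np.maximum(-2.0 * up * np.log(2.0 * eps * np.sqrt(2.0 * np.pi * up)), 0.0))
        ks = np.where(2.0 * np.sqrt(2.0 * np.pi * up) * eps < 1.0, np.maximum(ks, np.sqrt(up) + 1.0), 2.0)
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.pi * up * eps), 0.0) / (np.pi**2 * up))
        kl = np.where(np.pi * up * eps < 1.0, np.maximum(kl, 1.0 / (np.pi * np.sqrt(up))), 1.0 / (np.pi * np.sqrt(up)))

    use_small = ks < kl
    vals = np.empty_like(up)

    if np.any(use_small):
        us = up[use_small]
        K = int(np.ceil(np.max(ks[use_small])))
        k = np.arange(-((K - 1) // 2), ((K - 1) // 2) + 1 + 1)  # symmetric window, K+ terms
        nodes = w + 2.0 * k[None, :]
        vals[use_small] = (
            np.sum(nodes * np.exp(-nodes**2 / (2.0 * us[:, None])), axis=1)
            / np.sqrt(2.0 * np.pi * us**3)
        )

    use_large = ~use_small
    if np.any(use_large):
        ul = up[use_large]
        K = int(np.ceil(np.max(kl[use_large])))
        k = np.arange(1, K + 1)
        vals[use_large] = np.pi * np.sum(
            k[None, :] * np.exp(-(k[None, :] ** 2) * np.pi**2 * ul[:, None] / 2.0)
            * np.sin(k[None, :] * np.pi * w),
            axis=1,
        )

    out[pos] = np.maximum(vals, 0.0)
    return out


def wfpt_density(t, params: DDMParams, upper: bool = True):
    """Defective first-passage-time density at the chosen boundary.

    Evaluated at observed time ``t`` (seconds); the diffusion runs for
    ``t - t0`` so the density is 0 for t <= t0.  The density is defective:
    integrating the upper density over all t gives ``choice_probability``.

    Accepts scalars or arrays; returns the same shape.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)

    tau = t_arr - params.t0
    # standardized geometry: boundary separation a = 2B/sigma, start w = 1/2
    a = 2.0 * params.boundary / params.sigma
    v = params.mu / params.sigma
    if upper:
        v = -v  # upper crossing == lower crossing of the sign-flipped process
    w = 0.5

    dens = np.zeros_like(tau)
    pos = tau > 0
    if np.any(pos):
        tp = tau[pos]
        f1 = _fpt_series(tp / a**2)
        dens[pos] = np.exp(-v * a * w - v**2 * tp / 2.0) * f1 / a**2
    if scalar:
        return float(dens[0])
    return dens


def _wfpt_density_multi(tau, a, v):
    """FPT density with per-element geometry, on the standardized scale.

    ``tau`` decision times, ``a`` boundary separations (2B/sigma) and ``v``
    signed drifts (positive toward the *opposite* boundary, i.e. already
    sign-flipped for upper crossings), all arrays of one shape.
    """
    tau = np.asarray(tau, dtype=float)
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if np.any(pos):
        tp, ap, vp = tau[pos], a[pos], v[pos]
        f1 = _fpt_series(tp / ap**2)
        out[pos] = np.exp(-vp * ap * 0.5 - vp**2 * tp / 2.0) * f1 / ap**2
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _simulate_arrays(
    mu,
    boundary,
    t0,
    *,
    sigma=1.0,
    contaminant_lambda=0.0,
    t_max=7.0,
    n: int | None = None,
    dt: float = 0.001,
    rng: np.random.Generator,
):
    """Euler-Maruyama simulation with per-path parameters.

    Increments are drift*dt + sigma*sqrt(dt)*N(0,1).  Between grid points a
    Brownian-bridge crossing test catches excursions beyond either boundary
    that return within the step, removing the O(sqrt(dt)) absorption bias of
    the bare scheme; crossing times are assigned at the step midpoint.

    ``mu``, ``boundary``, ``t0`` may be scalars or arrays of length n.
    Returns (upper, rt) where upper is a float array with 1.0 / 0.0 /
    NaN (non-response) and rt is the observed time (NaN for non-response).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    boundary = np.atleast_1d(np.asarray(boundary, dtype=float))
    t0 = np.atleast_1d(np.asarray(t0, dtype=float))
    if n is None:
        n = max(mu.size, boundary.size, t0.size)
    mu = np.broadcast_to(mu, (n,)).copy()
    boundary = np.broadcast_to(boundary, (n,)).copy()
    t0 = np.broadcast_to(t0, (n,)).copy()

    max_steps = int(np.ceil((t_max - np.min(t0)) / dt))
    x = np.zeros(n)
    alive = np.arange(n)
    upper = np.full(n, np.nan)
    dtime = np.full(n, np.nan)
    s2dt = sigma**2 * dt
    sq = sigma * math.sqrt(dt)
    deadline = t_max - t0  # per-path decision-time budget

    for step in range(1, max_steps + 1):
        if alive.size == 0:
            break
        xa = x[alive]
        ba = boundary[alive]
        xn = xa + mu[alive] * dt + sq * rng.standard_normal(alive.size)
        hit_up = xn >= ba
        hit_lo = xn <= -ba
        interior = ~(hit_up | hit_lo)
        if np.any(interior):
            x0 = xa[interior]
            x1 = xn[interior]
            bi = ba[interior]
            with np.errstate(over="ignore"):
                p_up = np.exp(-2.0 * (bi - x0) * (bi - x1) / s2dt)
                p_lo = np.exp(-2.0 * (bi + x0) * (bi + x1) / s2dt)
            u = rng.random(x0.size)
            bridged_up = u < p_up
            bridged_lo = (~bridged_up) & (u < p_up + p_lo)
            tmp_up = hit_up[interior]
            tmp_up[bridged_up] = True
            hit_up[interior] = tmp_up
            tmp_lo = hit_lo[interior]
            tmp_lo[bridged_lo] = True
            hit_lo[interior] = tmp_lo
        hit = hit_up | hit_lo
        x[alive] = xn
        t_now = (step - 0.5) * dt  # midpoint crossing-time assignment
        timed_out = (~hit) & (step * dt >= deadline[alive])
        if np.any(hit):
            idx = alive[hit]
            upper[idx] = hit_up[hit].astype(float)
            dtime[idx] = t_now
        # absorbed exactly at the deadline still counts as a response
        alive = alive[~hit & ~timed_out]

    rt = t0 + dtime
    responded = np.isfinite(rt)
    # crossings past the deadline (grid overshoot) are non-responses
    late = responded & (rt > t_max)
    upper[late] = np.nan
    rt[late] = np.nan

    if contaminant_lambda > 0:
        contaminated = rng.random(n) < contaminant_lambda
        if np.any(contaminated):
            m = int(np.sum(contaminated))
            rt[contaminated] = t0[contaminated] + rng.random(m) * (
                t_max - t0[contaminated]
            )
            upper[contaminated] = (rng.random(m) < 0.5).astype(float)
    return upper, rt


def simulate(params: DDMParams, n: int, dt: float = 0.005, seed: int = 0):
    """Simulate ``n`` trials; returns a list of (upper, rt) tuples.

    ``upper`` is True/False for the absorbed boundary and None (with rt None)
    for non-responses.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    upper, rt = _simulate_arrays(
        params.mu,
        params.boundary,
        params.t0,
        sigma=params.sigma,
        contaminant_lambda=params.contaminant_lambda,
        t_max=params.t_max,
        n=n,
        dt=dt,
        rng=rng,
    )
    out = []
    for u, t in zip(upper, rt):
        if math.isnan(t):
            out.append((None, None))
        else:
            out.append((bool(u), float(t)))
    return out


def _data_to_arrays(data):
    """Accept a list of (upper, rt) tuples or an (upper, rt) array pair."""
    if isinstance(data, tuple) and len(data) == 2:
        upper = np.asarray(data[0], dtype=bool)
        rt = np.asarray(data[1], dtype=float)
        return upper, rt
    pairs = [(u, t) for u, t in data if t is not None]
    upper = np.array([u for u, _ in pairs], dtype=bool)
    rt = np.array([t for _, t in pairs], dtype=float)
    return upper, rt


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def robust_neg_log_likelihood(params: DDMParams, data) -> float:
    """Negative log-likelihood with a uniform contaminant floor.

    Per trial: L = (1 - lambda) f_wfpt(rt | boundary) + lambda / (2 (t_max - t0)).
    Finite for lambda > 0; for lambda = 0 a zero-density trial yields +inf
    with a warning.
    """
    upper, rt = _data_to_arrays(data)
    if np.any(rt <= 0) or np.any(rt > params.t_max):
        raise ValueError("all rt must lie in (0, t_max]")
    lam = params.contaminant_lambda
    lik = np.empty_like(rt)
    for is_up in (True, False):
        mask = upper if is_up else ~upper
        if np.any(mask):
            lik[mask] = wfpt_density(rt[mask], params, upper=is_up)
    lik = (1.0 - lam) * lik
    if lam > 0:
        lik = lik + lam / (2.0 * (params.t_max - params.t0))
    if np.any(lik <= 0):
        warnings.warn(
            "zero-likelihood trial with contaminant_lambda=0; returning inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(-np.sum(np.log(lik)))


_DEFAULT_BOUNDS = {"mu": (-5.0, 5.0), "boundary": (0.1, 4.0), "t0": (0.0, 1.0)}


def fit(
    data,
    bounds: dict | None = None,
    seed: int = 0,
    *,
    contaminant_lambda: float = 0.02,
    sigma: float = 1.0,
    t_max: float = 7.0,
    maxiter: int = 300,
    workers: int = 1,
) -> FitResult:
    """Maximum-likelihood DDM fit by differential evolution.

    ``bounds`` maps parameter names among {"mu", "boundary", "t0",
    "contaminant_lambda"} to (low, high) intervals; parameters not listed are
    held fixed at their defaults.  The optimizer is rand/1/bin differential
    evolution with population >= 15 per free parameter, CR = 0.7, F drawn
    from [0.5, 1), convergence tolerance 1e-6, fully seeded.
    """
    upper, rt = _data_to_arrays(data)
    if rt.size == 0 or np.all(rt == rt[0]):
        raise ValueError("need non-degenerate response-time data to fit")
    if bounds is None:
        bounds = dict(_DEFAULT_BOUNDS)
    free = list(bounds)
    if rt.size < len(free):
        raise ValueError("fewer trials than free parameters")
    if rt.size < 50:
        warnings.warn("fewer than 50 trials; fit may be unstable", RuntimeWarning, stacklevel=2)
    for name, (lo, hi) in bounds.items():
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError(f"bounds for {name} must be finite")

    fixed = {
        "mu": 0.0,
        "boundary": 1.0,
        "t0": 0.3,
        "contaminant_lambda": contaminant_lambda,
    }
    n_eval = 0

    def build(theta):
        kw = dict(fixed)
        for name, value in zip(free, theta):
            kw[name] = value
        # keep t0 feasible: density is zero (floor only) above min rt anyway
        kw["t0"] = min(kw["t0"], t_max - 1e-6)
        return DDMParams(sigma=sigma, t_max=t_max, **kw)

    def objective(theta):
        nonlocal n_eval
        n_eval += 1
        params = build(theta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            val = robust_neg_log_likelihood(params, (upper, rt))
        return val if np.isfinite(val) else 1e12

    result = differential_evolution(
        objective,
        [bounds[name] for name in free],
        strategy="rand1bin",
        popsize=15,
        mutation=(0.5, 1.0),
        recombination=0.7,
        tol=1e-6,
        seed=seed,
        maxiter=maxiter,
        polish=True,
        workers=workers,
    )
    params = build(result.x)
    return FitResult(
        params=params,
        neg_log_likelihood=float(result.fun),
        n_evaluations=n_eval,
        converged=bool(result.success),
        seed=seed,
        bounds={k: tuple(v) for k, v in bounds.items()},
    )
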