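"""Condition-dependent DDM for hybrid search.

The mapping ties one diffusion process to each design cell: drift falls with
memory set size (multiplicative-inverse in ln MSS by default) and is offset
by scene context, the boundary grows linearly with visual set size, and
non-decision time is constant.  An extended variant lets the boundary and
non-decision time differ on target-absent trials.  All cells are fitted
jointly with one robust likelihood, so shared coefficients are genuinely
shared.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .ddm_core import (
    DDMParams,
    _simulate_arrays,
    _wfpt_density_multi,
    robust_neg_log_likelihood,
)

__all__ = ["HybridDDMSpec", "HybridFitResult", "map_condition", "fit_hybrid", "predict_rt_surface"]

DESIGN_LEVELS = (1, 2, 4, 8)


@dataclass(frozen=True)
class HybridDDMSpec:
    """Coefficients mapping (MSS, VSS, context, target presence) to DDMParams.

    drift    = mu0 / (1 + gamma * ln(MSS)) + delta * [context]   (default form)
               or mu0 / (1 + gamma * (MSS - 1)) + delta * [context]
    boundary = a0 + a1 * VSS      (a0_ta / a1_ta on target-absent trials when set)
    t0       = constant           (t0_ta on target-absent trials when set)

    On target-absent trials the stimulus-driven drift component points to the
    "absent" (lower) boundary, so its sign is flipped while the context offset
    keeps acting against the correct response.
    """

    mu0: float = 2.0
    gamma: float = 0.8
    delta: float = -0.4
    a0: float = 0.8
    a1: float = 0.15
    t0: float = 0.35
    contaminant_lambda: float = 0.02
    drift_form: str = "inverse_log_mss"  # or "inverse_mss"
    sigma: float = 1.0
    t_max: float = 7.0
    # extended (target-absent) parameters; None = shared with target-present
    a0_ta: float | None = None
    a1_ta: float | None = None
    t0_ta: float | None = None

    def __post_init__(self):
        if self.drift_form not in ("inverse_log_mss", "inverse_mss"):
            raise ValueError(f"unknown drift_form {self.drift_form!r}")
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.a0 <= 0 or self.a1 < 0:
            raise ValueError("boundary coefficients must give positive boundaries")

    def to_dict(self) -> dict:
        return asdict(self)


def map_condition(
    spec: HybridDDMSpec,
    mss: int,
    vss: int,
    context: bool,
    target_present: bool = True,
) -> DDMParams:
    """Instantiate the single-trial DDM for one design cell.

    The drift is signed toward the correct boundary ("present" = upper):
    positive on target-present trials, mirrored on target-absent trials.
    """
    if mss < 1 or vss < 1:
        raise ValueError("mss and vss must be >= 1")
    if spec.drift_form == "inverse_log_mss":
        base = spec.mu0 / (1.0 + spec.gamma * np.log(mss))
    else:
        base = spec.mu0 / (1.0 + spec.gamma * (mss - 1))
    offset = spec.delta if context else 0.0
    if target_present:
        mu = base + offset
        boundary = spec.a0 + spec.a1 * vss
        t0 = spec.t0
    else:
        mu = -(base + offset)
        a0 = spec.a0 if spec.a0_ta is None else spec.a0_ta
        a1 = spec.a1 if spec.a1_ta is None else spec.a1_ta
        boundary = a0 + a1 * vss
        t0 = spec.t0 if spec.t0_ta is None else spec.t0_ta
    return DDMParams(
        mu=float(mu),
        boundary=float(boundary),
        t0=float(t0),
        sigma=spec.sigma,
        contaminant_lambda=spec.contaminant_lambda,
        t_max=spec.t_max,
    )


@dataclass
class HybridFitResult:
    """Joint fit of the hybrid mapping across design cells."""

    spec: HybridDDMSpec
    neg_log_likelihood: float
    predictions: pd.DataFrame | None
    n_evaluations: int
    converged: bool
    seed: int
    bounds: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "spec": self.spec.to_dict(),
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


def _cell_data(trials, include_target_absent: bool):
    """Group answered trials into design cells with (upper, rt) arrays.

    "Present" responses map to the upper boundary.  Timeouts are excluded
    (recorded by the caller's provenance); target-absent cells appear only in
    the extended fit.
    """
    df = trials.data if hasattr(trials, "data") else trials
    df = df[df["response"] != "none"]
    if not include_target_absent:
        df = df[df["target_present"]]
    cells = []
    for key, sub in df.groupby(["mss", "vss", "context_present", "target_present"], sort=True):
        upper = (sub["response"] == "present").to_numpy()
        rt = sub["rt"].to_numpy(dtype=float)
        cells.append((key, upper, rt))
    return cells


def joint_neg_log_likelihood(spec: HybridDDMSpec, cells) -> float:
    """Sum of per-cell robust negative log-likelihoods under the mapping."""
    total = 0.0
    for (mss, vss, ctx, tp), upper, rt in cells:
        params = map_condition(spec, int(mss), int(vss), bool(ctx), bool(tp))
        total += robust_neg_log_likelihood(params, (upper, rt))
        if not np.isfinite(total):
            return float("inf")
    return total


def _flatten_cells(cells) -> dict:
    """Concatenate per-cell data into flat per-trial arrays for fast fitting."""
    mss, vss, ctx, tp, upper, rt = [], [], [], [], [], []
    for (m, v, c, t), up, r in cells:
        k = len(r)
        mss.append(np.full(k, m, dtype=float))
        vss.append(np.full(k, v, dtype=float))
        ctx.append(np.full(k, bool(c)))
        tp.append(np.full(k, bool(t)))
        upper.append(up)
        rt.append(r)
    return {
        "mss": np.concatenate(mss),
        "vss": np.concatenate(vss),
        "ctx": np.concatenate(ctx),
        "tp": np.concatenate(tp),
        "upper": np.concatenate(upper),
        "rt": np.concatenate(rt),
    }


def _joint_nll_fast(spec: HybridDDMSpec, flat: dict) -> float:
    """Vectorized equivalent of :func:`joint_neg_log_likelihood`."""
    mss, vss = flat["mss"], flat["vss"]
    ctx, tp = flat["ctx"], flat["tp"]
    upper, rt = flat["upper"], flat["rt"]
    if spec.drift_form == "inverse_log_mss":
        base = spec.mu0 / (1.0 + spec.gamma * np.log(mss))
    else:
        base = spec.mu0 / (1.0 + spec.gamma * (mss - 1.0))
    mu = base + spec.delta * ctx
    mu = np.where(tp, mu, -mu)
    a0 = spec.a0 if spec.a0_ta is None else spec.a0_ta
    a1 = spec.a1 if spec.a1_ta is None else spec.a1_ta
    boundary = np.where(tp, spec.a0 + spec.a1 * vss, a0 + a1 * vss)
    t0 = np.where(tp, spec.t0, spec.t0 if spec.t0_ta is None else spec.t0_ta)
    if np.any(boundary <= 0):
        return float("inf")
    tau = rt - t0
    a = 2.0 * boundary / spec.sigma
    v = np.where(upper, -mu, mu) / spec.sigma
    dens = _wfpt_density_multi(tau, a, v)
    lam = spec.contaminant_lambda
    lik = (1.0 - lam) * dens
    if lam > 0:
        lik = lik + lam / (2.0 * (spec.t_max - t0))
    if np.any(lik <= 0):
        return float("inf")
    return float(-np.sum(np.log(lik)))


_HYBRID_BOUNDS = {
    "mu0": (0.2, 5.0),
    "gamma": (0.0, 3.0),
    "delta": (-2.0, 2.0),
    "a0": (0.2, 3.0),
    "a1": (0.0, 0.8),
    "t0": (0.0, 1.0),
}
_TA_BOUNDS = {"a0_ta": (0.2, 3.0), "a1_ta": (0.0, 0.8), "t0_ta": (0.0, 1.0)}


def fit_hybrid(
    trials,
    template: HybridDDMSpec | None = None,
    free: tuple = ("mu0", "gamma", "delta", "a0", "a1", "t0"),
    bounds: dict | None = None,
    seed: int = 0,
    include_target_absent: bool = False,
    maxiter: int = 250,
    predict: bool = False,
    n_sims: int = 10000,
) -> HybridFitResult:
    """Jointly fit the mapping coefficients to answered trials.

    Target-present trials alone by default; set ``include_target_absent`` to
    fit the extended model (free target-absent boundary/non-decision
    parameters should then be added to ``free``).  With an empty ``free``
    tuple the template's likelihood is returned without optimization.
    Empty design cells are skipped with a warning.
    """
    template = template or HybridDDMSpec()
    cells = _cell_data(trials, include_target_absent)
    if not cells:
        raise ValueError("no answered trials to fit")
    n_expected = len(DESIGN_LEVELS) ** 2 * 2 * (2 if include_target_absent else 1)
    if len(cells) < n_expected:
        warnings.warn(
            f"{n_expected - len(cells)} design cell(s) empty; they are skipped",
            RuntimeWarning,
            stacklevel=2,
        )

    free = tuple(free)
    if not free:
        nll = joint_neg_log_likelihood(template, cells)
        preds = predict_rt_surface(template, n_sims=n_sims, seed=seed,
                                   include_target_absent=include_target_absent) if predict else None
        return HybridFitResult(template, nll, preds, 1, True, seed, {})

    defaults = dict(_HYBRID_BOUNDS)
    defaults.update(_TA_BOUNDS)
    bounds = {**{k: defaults[k] for k in free}, **(bounds or {})}
    flat = _flatten_cells(cells)
    n_eval = 0

    def build(theta) -> HybridDDMSpec:
        return replace(template, **dict(zip(free, theta)))

    def objective(theta):
        nonlocal n_eval
        n_eval += 1
        try:
            spec = build(theta)
        except ValueError:
            return 1e12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            val = _joint_nll_fast(spec, flat)
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
    )
    spec = build(result.x)
    preds = predict_rt_surface(spec, n_sims=n_sims, seed=seed,
                               include_target_absent=include_target_absent) if predict else None
    return HybridFitResult(
        spec=spec,
        neg_log_likelihood=float(result.fun),
        predictions=preds,
        n_evaluations=n_eval,
        converged=bool(result.success),
        seed=seed,
        bounds={k: tuple(v) for k, v in bounds.items()},
    )


def predict_rt_surface(
    spec: HybridDDMSpec,
    n_sims: int = 10000,
    seed: int = 0,
    dt: float = 0.005,
    include_target_absent: bool = False,
) -> pd.DataFrame:
    """Simulated per-cell response summaries over the design grid.

    For each {MSS, VSS, context(, target)} cell, ``n_sims`` trials are
    simulated and the mean correct-response RT, the "present"/"absent"
    response split, and the non-response rate are reported.
    """
    rng = np.random.default_rng(seed)
    rows = []
    targets = (True, False) if include_target_absent else (True,)
    for tp in targets:
        for ctx in (False, True):
            for mss in DESIGN_LEVELS:
                for vss in DESIGN_LEVELS:
                    params = map_condition(spec, mss, vss, ctx, tp)
                    upper, rt = _simulate_arrays(
                        params.mu,
                        params.boundary,
                        params.t0,
                        sigma=params.sigma,
                        contaminant_lambda=params.contaminant_lambda,
                        t_max=params.t_max,
                        n=n_sims,
                        dt=dt,
                        rng=rng,
                    )
                    responded = np.isfinite(rt)
                    correct_up = tp  # "present" is correct iff target present
                    correct_mask = responded & (upper == (1.0 if correct_up else 0.0))
                    rows.append(
                        {
                            "mss": mss,
                            "vss": vss,
                            "context_present": ctx,
                            "target_present": tp,
                            "mean_rt_correct": float(np.mean(rt[correct_mask]))
                            if np.any(correct_mask)
                            else np.nan,
                            "p_present_response": float(np.mean(upper[responded] == 1.0))
                            if np.any(responded)
                            else np.nan,
                            "p_correct": float(np.sum(correct_mask) / n_sims),
                            "p_nonresponse": float(np.mean(~responded)),
                            "n_sims": n_sims,
                        }
                    )
    return pd.DataFrame(rows)
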