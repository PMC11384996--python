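"""Per-participant set-size curves, mixed models, and model comparison.

Two complementary surfaces, mirroring how such experiments are analysed:

* per-participant ordinary least squares of mean RT on set size (linear) and
  on ln(set size) (logarithmic), aggregated as mean +- SEM across
  participants; and
* trial-level Gaussian random-intercept mixed models
  ``RT ~ set_size * Context + (1 | participant)`` fitted by maximum
  likelihood with the variance ratio profiled out, compared by
  likelihood-ratio tests and AIC.  A random-intercept logistic companion
  handles accuracy, with the marginal likelihood integrated by adaptive
  Gauss-Hermite quadrature.

Natural logarithms are used throughout (the base only rescales log-form
slopes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "CurveFit",
    "LMMResult",
    "LogisticMixedResult",
    "participant_setsize_curves",
    "aggregate_curves",
    "fit_random_intercept_lmm",
    "likelihood_ratio_test",
    "compare_forms_aic",
    "fit_random_intercept_logistic",
]


# ---------------------------------------------------------------------------
# per-participant curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurveFit:
    """One participant's RT-by-set-size regression (on cell means)."""

    participant_id: str
    axis: str  # "vss" or "mss"
    context: bool
    form: str  # "linear" or "log"
    slope: float  # s/item (linear) or s per log-unit (log)
    intercept: float  # seconds
    r_squared: float
    aic: float
    n_points: int


def _gaussian_aic(rss: float, n: int, k_mean_params: int) -> float:
    # k = mean parameters + 1 residual-variance parameter
    rss = max(rss, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return -2.0 * ll + 2.0 * (k_mean_params + 1)


def participant_setsize_curves(
    trials,
    axis: str = "vss",
    fixed_other: int | None = 4,
) -> list[CurveFit]:
    """Linear and logarithmic OLS fits of mean RT on set size, per participant.

    For each participant x context, the mean RT at each level of ``axis`` is
    computed with the *other* set size held at ``fixed_other`` (pass None to
    pool over it), then mean RT is regressed on the set size (linear form)
    and on its natural log (log form).  Input should already be filtered to
    answered, correct, target-present trials.  Participants with fewer than
    two distinct levels are skipped with a log entry.
    """
    if axis not in ("vss", "mss"):
        raise ValueError("axis must be 'vss' or 'mss'")
    other = "mss" if axis == "vss" else "vss"
    df = trials.data if hasattr(trials, "data") else trials
    if fixed_other is not None:
        df = df[df[other] == fixed_other]
    fits: list[CurveFit] = []
    for (pid, ctx), sub in df.groupby(["participant_id", "context_present"], sort=True):
        means = sub.groupby(axis)["rt"].mean()
        if len(means) < 2:
            logger.info(
                "participant_setsize_curves: %s (context=%s) skipped, <2 levels", pid, ctx
            )
            continue
        x_lin = means.index.to_numpy(dtype=float)
        y = means.to_numpy(dtype=float)
        for form, x in (("linear", x_lin), ("log", np.log(x_lin))):
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            rss = float(resid @ resid)
            tss = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - rss / tss if tss > 0 else 1.0
            fits.append(
                CurveFit(
                    participant_id=str(pid),
                    axis=axis,
                    context=bool(ctx),
                    form=form,
                    slope=float(slope),
                    intercept=float(intercept),
                    r_squared=float(r2),
                    aic=_gaussian_aic(rss, len(y), 2),
                    n_points=len(y),
                )
            )
    return fits


def aggregate_curves(fits: list[CurveFit]) -> pd.DataFrame:
    """Mean +- SEM of slope/intercept/R^2 per (axis, context, form)."""
    df = pd.DataFrame([f.__dict__ for f in fits])
    if df.empty:
        return df
    rows = []
    for (axis, ctx, form), sub in df.groupby(["axis", "context", "form"], sort=True):
        n = len(sub)
        row = {"axis": axis, "context": ctx, "form": form, "n": n}
        for col in ("slope", "intercept", "r_squared"):
            vals = sub[col].to_numpy()
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_sem"] = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaussian random-intercept mixed model (profiled maximum likelihood)
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    """Maximum-likelihood fit of y = X beta + b_group + eps."""

    fixed_effects: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p (Wald z)
    random_intercept_sd: float
    residual_sd: float
    icc: float
    log_likelihood: float
    aic: float
    n_obs: int
    n_groups: int
    formula: str = ""
    term_names: tuple = ()

    @property
    def n_params(self) -> int:
        return len(self.fixed_effects) + 2


def _design_matrix(
    df: pd.DataFrame,
    set_size: str | None,
    context: str | None,
    set_size_transform: str,
    interaction: bool,
):
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    ctx = None
    if context is not None:
        ctx = df[context].to_numpy(dtype=float)
        cols.append(ctx)
        names.append("context")
    if set_size is not None:
        s = df[set_size].to_numpy(dtype=float)
        if set_size_transform == "log":
            s = np.log(s)
            term = f"log({set_size})"
        elif set_size_transform == "identity":
            term = set_size
        else:
            raise ValueError(f"unknown set_size_transform {set_size_transform!r}")
        cols.append(s)
        names.append(term)
        if interaction and ctx is not None:
            cols.append(ctx * s)
            names.append(f"context:{term}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify the first aliased column for the error message
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"singular design matrix: term {names[j]!r} is aliased")
    return X, names


def _profile_pieces(Xg, yg, theta):
    """GLS quantities for V_i = I + theta J via the Woodbury identity."""
    p = Xg[0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for Xi, yi in zip(Xg, yg):
        ni = len(yi)
        w = theta / (1.0 + theta * ni)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        XtVX += Xi.T @ Xi - w * np.outer(sx, sx)
        XtVy += Xi.T @ yi - w * sx * sy
        ytVy += yi @ yi - w * sy * sy
        logdet += np.log1p(theta * ni)
    return XtVX, XtVy, ytVy, logdet


def _profile_loglik(theta, Xg, yg, n):
    XtVX, XtVy, ytVy, logdet = _profile_pieces(Xg, yg, theta)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - XtVy @ beta
    rss = max(rss, 1e-12)
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2, XtVX


def fit_random_intercept_lmm(
    data,
    response: str = "rt",
    group: str = "participant_id",
    set_size: str | None = "vss",
    context: str | None = "context_present",
    set_size_transform: str = "identity",
    interaction: bool = True,
) -> LMMResult:
    """ML fit of a Gaussian random-intercept model by profiling.

    The variance ratio theta = sigma_b^2 / sigma_e^2 is the only free
    dispersion parameter: given theta, the GLS coefficients and the residual
    variance have closed forms, so theta is found by one-dimensional bounded
    search.  ML (not REML) is used so likelihood-ratio tests across
    fixed-effect structures are valid.  AIC counts every fixed effect plus
    the two variance parameters; CIs and p-values are Wald (normal).
    """
    df = data.data if hasattr(data, "data") else data
    groups_idx = df.groupby(group, sort=True).indices
    if len(groups_idx) < 2:
        raise ValueError("need at least 2 groups")
    X, names = _design_matrix(df, set_size, context, set_size_transform, interaction)
    y = df[response].to_numpy(dtype=float)
    Xg = [X[idx] for idx in groups_idx.values()]
    yg = [y[idx] for idx in groups_idx.values()]
    n = len(y)

    res = optimize.minimize_scalar(
        lambda t: -_profile_loglik(t, Xg, yg, n)[0],
        bounds=(0.0, 100.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    theta = float(res.x)
    # the optimum can sit at the theta = 0 boundary
    ll0 = _profile_loglik(0.0, Xg, yg, n)[0]
    llt = -res.fun
    if ll0 >= llt:
        theta, llt = 0.0, ll0
    ll, beta, sigma2, XtVX = _profile_loglik(theta, Xg, yg, n)

    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    fixed = pd.DataFrame(
        {
            "term": names,
            "estimate": beta,
            "se": se,
            "ci_low": beta - 1.959963984540054 * se,
            "ci_high": beta + 1.959963984540054 * se,
            "p_value": pvals,
        }
    )
    sigma_e = float(np.sqrt(sigma2))
    sigma_b = float(np.sqrt(theta * sigma2))
    icc = theta / (1.0 + theta)
    k = len(names) + 2
    formula = f"{response} ~ {' * '.join(n for n in names[1:3]) if len(names) > 2 else (names[1] if len(names) > 1 else '1')} + (1|{group})"
    return LMMResult(
        fixed_effects=fixed,
        random_intercept_sd=sigma_b,
        residual_sd=sigma_e,
        icc=float(icc),
        log_likelihood=float(ll),
        aic=float(-2 * ll + 2 * k),
        n_obs=n,
        n_groups=len(groups_idx),
        formula=formula,
        term_names=tuple(names),
    )


def likelihood_ratio_test(null: LMMResult, full: LMMResult):
    """Chi-squared LRT between nested ML fits on the same data.

    Returns (chi2, df, p).  The null's terms must be a subset of the full's
    and both fits must use the same observations.
    """
    if null.n_obs != full.n_obs or null.n_groups != full.n_groups:
        raise ValueError("models were fitted on different data")
    if not set(null.term_names) <= set(full.term_names):
        raise ValueError("null model is not nested in the full model")
    df_diff = full.n_params - null.n_params
    if df_diff < 0:
        raise ValueError("null model has more parameters than the full model")
    chi2 = max(0.0, 2.0 * (full.log_likelihood - null.log_likelihood))
    p = 1.0 if df_diff == 0 and chi2 == 0 else float(stats.chi2.sf(chi2, max(df_diff, 1)))
    if df_diff == 0:
        p = 1.0 if chi2 <= 1e-10 else 0.0
    return float(chi2), int(df_diff), p


def compare_forms_aic(
    data,
    axis: str = "vss",
    response: str = "rt",
    group: str = "participant_id",
    context: str = "context_present",
) -> dict:
    """Fit the linear-term and log-term full mixed models; select by AIC."""
    linear = fit_random_intercept_lmm(
        data, response=response, group=group, set_size=axis,
        context=context, set_size_transform="identity",
    )
    logm = fit_random_intercept_lmm(
        data, response=response, group=group, set_size=axis,
        context=context, set_size_transform="log",
    )
    selected = "linear" if linear.aic <= logm.aic else "log"
    return {
        "axis": axis,
        "aic_linear": linear.aic,
        "aic_log": logm.aic,
        "selected": selected,
        "delta_aic": linear.aic - logm.aic,
        "linear": linear,
        "log": logm,
    }


# ---------------------------------------------------------------------------
# random-intercept logistic regression (adaptive Gauss-Hermite)
# ---------------------------------------------------------------------------

@dataclass
class LogisticMixedResult:
    """ML fit of logit P(y=1) = X beta + b_group, b ~ N(0, sigma_b^2)."""

    odds_ratios: pd.DataFrame  # term, coef, odds_ratio, ci_low, ci_high, p
    coefficients: np.ndarray
    random_intercept_sd: float
    log_likelihood: float
    aic: float
    n_obs: int
    n_groups: int
    term_names: tuple = ()


def _group_loglik_agq(beta, sigma, Xi, yi, nodes, weights):
    """Marginal log-likelihood of one group by adaptive Gauss-Hermite.

    The random effect is standardized, u ~ N(0,1), entering as sigma * u.
    The quadrature is centred at the mode of the integrand with its local
    curvature (Laplace scaling).
    """
    eta0 = Xi @ beta

    def neg_logg(u):
        eta = eta0 + sigma * u
        # -log p(y|u) - log phi(u), up to the constant
        return float(np.sum(np.logaddexp(0.0, eta) - yi * eta) + 0.5 * u * u)

    # Newton iterations for the mode
    u = 0.0
    for _ in range(25):
        eta = eta0 + sigma * u
        p = expit(eta)
        g = -sigma * np.sum(yi - p) + u
        h = sigma**2 * np.sum(p * (1 - p)) + 1.0
        step = g / h
        u -= step
        if abs(step) < 1e-10:
            break
    eta = eta0 + sigma * u
    p = expit(eta)
    h = sigma**2 * np.sum(p * (1 - p)) + 1.0
    tau = 1.0 / np.sqrt(h)

    z = u + np.sqrt(2.0) * tau * nodes
    eta_z = eta0[:, None] + sigma * z[None, :]
    log_py = np.sum(yi[:, None] * eta_z - np.logaddexp(0.0, eta_z), axis=0)
    log_int = log_py - 0.5 * z * z  # integrand: p(y|u) phi(u) sans 1/sqrt(2 pi)
    log_terms = np.log(weights) + nodes * nodes + log_int
    m = np.max(log_terms)
    return float(
        m + np.log(np.sum(np.exp(log_terms - m))) + np.log(np.sqrt(2.0) * tau) - 0.5 * np.log(2 * np.pi)
    )


def fit_random_intercept_logistic(
    data,
    response: str = "correct",
    group: str = "participant_id",
    set_size: str | None = "vss",
    context: str | None = "context_present",
    set_size_transform: str = "identity",
    interaction: bool = False,
    n_nodes: int = 21,
) -> LogisticMixedResult:
    """Random-intercept logistic regression via adaptive Gauss-Hermite.

    The per-group marginal likelihood is integrated with ``n_nodes``
    quadrature nodes recentred and rescaled at each group's posterior mode.
    Reports odds ratios with Wald CIs.  Raises on (quasi-)complete
    separation, detected as runaway coefficients.
    """
    df = data.data if hasattr(data, "data") else data
    X, names = _design_matrix(df, set_size, context, set_size_transform, interaction)
    y = df[response].to_numpy(dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("response must be binary 0/1")
    groups_idx = df.groupby(group, sort=True).indices
    Xg = [X[idx] for idx in groups_idx.values()]
    yg = [y[idx] for idx in groups_idx.values()]
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    p = X.shape[1]

    def nll(params):
        beta, log_sigma = params[:p], params[p]
        sigma = np.exp(log_sigma)
        return -sum(
            _group_loglik_agq(beta, sigma, Xi, yi, nodes, weights)
            for Xi, yi in zip(Xg, yg)
        )

    # start from pooled logistic coefficients
    from statsmodels.api import Logit

    with np.errstate(all="ignore"):
        try:
            start_beta = Logit(y, X).fit(disp=0, maxiter=200).params
        except Exception:
            start_beta = np.zeros(p)
    x0 = np.concatenate([start_beta, [np.log(0.5)]])
    res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    beta = res.x[:p]
    sigma_b = float(np.exp(res.x[p]))
    if np.any(np.abs(beta) > 30):
        raise ValueError("complete separation detected (diverging coefficients)")

    from statsmodels.tools.numdiff import approx_hess1

    H = approx_hess1(res.x, nll)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "term": names,
            "coef": beta,
            "odds_ratio": np.exp(beta),
            "ci_low": np.exp(beta - 1.959963984540054 * se),
            "ci_high": np.exp(beta + 1.959963984540054 * se),
            "p_value": pvals,
        }
    )
    ll = -float(res.fun)
    k = p + 1
    return LogisticMixedResult(
        odds_ratios=table,
        coefficients=beta,
        random_intercept_sd=sigma_b,
        log_likelihood=ll,
        aic=-2 * ll + 2 * k,
        n_obs=len(y),
        n_groups=len(groups_idx),
        term_names=tuple(names),
    )
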