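"""Working-memory capacity, signal-detection measures, and their link to search.

Cowan's K estimates change-detection capacity as K = N (H - FA) per set
size, averaged over the tested set sizes per participant.  The equal-variance
signal-detection measures are d' = z(H) - z(FA) and criterion
c = -(z(H) + z(FA)) / 2; extreme rates are handled by the log-linear
correction (0.5 added to each count, 1 to each total) before the quantile
transform.  Pearson correlations relate these per-participant measures to
hybrid-search RT slopes and intercepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CapacityMeasures",
    "cowan_k",
    "sdt_measures",
    "cdt_capacity",
    "gng_measures",
    "correlate_with_search",
]


@dataclass(frozen=True)
class CapacityMeasures:
    """Per-participant capacity and response-bias summary."""

    participant_id: str
    hit_rate: float
    fa_rate: float
    k: float | None
    d_prime: float
    criterion_c: float
    n_signal: int
    n_noise: int
    correction_applied: bool = False


def cowan_k(hit_rate, fa_rate, set_size):
    """Cowan's change-detection capacity estimate K = N (H - FA).

    Vectorized over its arguments.  Negative estimates are possible (below-
    chance responding) and are returned as-is with a log notice.
    """
    hit_rate = np.asarray(hit_rate, dtype=float)
    fa_rate = np.asarray(fa_rate, dtype=float)
    set_size = np.asarray(set_size, dtype=float)
    if np.any((hit_rate < 0) | (hit_rate > 1) | (fa_rate < 0) | (fa_rate > 1)):
        raise ValueError("rates must lie in [0, 1]")
    if np.any(set_size < 1):
        raise ValueError("set_size must be >= 1")
    k = set_size * (hit_rate - fa_rate)
    if np.any(k < 0):
        logger.info("cowan_k: negative capacity estimate(s) present")
    if k.ndim == 0:
        return float(k)
    return k


def sdt_measures(hits, fas, n_signal, n_noise, correction: str = "loglinear"):
    """Equal-variance SDT sensitivity and criterion from hit/false-alarm data.

    ``hits`` and ``fas`` may be counts (pass Python ints) or rates (pass
    floats in [0, 1]); rates are converted to counts via n_signal / n_noise.
    With ``correction="loglinear"`` 0.5 is added to each count and 1 to each
    total before the z-transform, which also keeps perfect rates finite; with
    ``correction="none"`` extreme rates raise.

    Returns (d_prime, criterion_c).
    """
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("n_signal and n_noise must be positive")

    def as_count(value, total, name):
        if isinstance(value, (int, np.integer)):
            count = float(value)
        else:
            value = float(value)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} rate must lie in [0, 1], got {value}")
            count = value * total
        if not 0.0 <= count <= total:
            raise ValueError(f"{name} count {count} exceeds its total {total}")
        return count

    hits = as_count(hits, n_signal, "hit")
    fas = as_count(fas, n_noise, "false-alarm")
    if correction == "loglinear":
        h = (hits + 0.5) / (n_signal + 1.0)
        f = (fas + 0.5) / (n_noise + 1.0)
    elif correction == "none":
        h = hits / n_signal
        f = fas / n_noise
        if h in (0.0, 1.0) or f in (0.0, 1.0):
            raise ValueError("extreme rate with correction='none'")
    else:
        raise ValueError(f"unknown correction {correction!r}")
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def cdt_capacity(cdt: pd.DataFrame, correction: str = "none") -> pd.DataFrame:
    """Per-participant K from a change-detection trial table.

    Expects columns participant_id, set_size, change_present, response_change.
    K is computed per set size from raw hit/false-alarm rates and averaged
    across set sizes.  Returns one row per participant with rates and K.
    """
    rows = []
    for pid, sub in cdt.groupby("participant_id", sort=True):
        ks, hs, fs = [], [], []
        for n_items, cell in sub.groupby("set_size"):
            sig = cell[cell["change_present"]]
            noi = cell[~cell["change_present"]]
            h = sig["response_change"].mean() if len(sig) else np.nan
            f = noi["response_change"].mean() if len(noi) else np.nan
            ks.append(cowan_k(h, f, n_items))
            hs.append(h)
            fs.append(f)
        rows.append(
            {
                "participant_id": str(pid),
                "hit_rate": float(np.nanmean(hs)),
                "fa_rate": float(np.nanmean(fs)),
                "k": float(np.nanmean(ks)),
            }
        )
    return pd.DataFrame(rows)


def gng_measures(gng: pd.DataFrame, correction: str = "loglinear") -> list[CapacityMeasures]:
    """Per-participant d' and criterion c from a go/no-go trial table.

    Go trials are the signal class (hits = responses on go trials); responses
    on no-go trials are false alarms, so liberal responding yields negative c.
    """
    out = []
    for pid, sub in gng.groupby("participant_id", sort=True):
        go = sub[sub["is_go"]]
        nogo = sub[~sub["is_go"]]
        hits = int(go["responded"].sum())
        fas = int(nogo["responded"].sum())
        extreme = hits in (0, len(go)) or fas in (0, len(nogo))
        d, c = sdt_measures(hits, fas, len(go), len(nogo), correction=correction)
        out.append(
            CapacityMeasures(
                participant_id=str(pid),
                hit_rate=hits / len(go),
                fa_rate=fas / len(nogo),
                k=None,
                d_prime=d,
                criterion_c=c,
                n_signal=len(go),
                n_noise=len(nogo),
                correction_applied=bool(extreme and correction != "none"),
            )
        )
    return out


def correlate_with_search(
    measures: pd.DataFrame,
    fits,
    measure_cols: tuple = ("k", "criterion_c"),
    stat_cols: tuple = ("slope", "intercept"),
) -> pd.DataFrame:
    """Pearson correlations of capacity/bias measures with search statistics.

    ``measures`` holds one row per participant (columns among
    ``measure_cols``); ``fits`` is a list of CurveFit or an equivalent
    DataFrame.  Correlations are computed per (axis, context, form) cell for
    each (measure, statistic) pair; cells with fewer than 4 matched
    participants or zero variance are skipped with a warning.

    Reports Pearson r, the two-sided p-value from the t transform, and r^2.
    """
    fit_df = fits if isinstance(fits, pd.DataFrame) else pd.DataFrame([f.__dict__ for f in fits])
    rows = []
    for (axis, ctx, form), sub in fit_df.groupby(["axis", "context", "form"], sort=True):
        merged = sub.merge(measures, on="participant_id", how="inner")
        for mcol in measure_cols:
            if mcol not in merged.columns:
                continue
            for scol in stat_cols:
                cell = merged[[mcol, scol]].dropna()
                if len(cell) < 4:
                    logger.warning(
                        "correlate_with_search: %s/%s in (%s, ctx=%s, %s) skipped, n<4",
                        mcol, scol, axis, ctx, form,
                    )
                    continue
                x = cell[mcol].to_numpy()
                y_arr = cell[scol].to_numpy()
                if np.std(x) == 0 or np.std(y_arr) == 0:
                    logger.warning(
                        "correlate_with_search: zero variance in (%s, ctx=%s, %s)",
                        axis, ctx, form,
                    )
                    continue
                r, p = stats.pearsonr(x, y_arr)
                rows.append(
                    {
                        "axis": axis,
                        "context": bool(ctx),
                        "form": form,
                        "measure": mcol,
                        "statistic": scol,
                        "n": len(cell),
                        "r": float(r),
                        "p_value": float(p),
                        "r_squared": float(r**2),
                    }
                )
    return pd.DataFrame(rows)
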