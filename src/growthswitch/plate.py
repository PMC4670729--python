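"""Growth-rate estimation from microplate absorbance kinetics.

Rates are obtained by ordinary least squares of ln(absorbance) against time
inside a policy-defined window: the *growing* policy uses the stretch where
the background-corrected absorbance lies between 0.05 (preculture polymerase
diluted out, several generations in) and 0.2 (above which oxygen transfer
limits growth); the *arrested* policy uses the late phase beyond 1000 min.
Log-linear OLS is equivalent to a nonlinear exponential fit on noise-free
data and has a closed form, which keeps the estimator reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ABS_TO_OD
from .types import ConditionSummary, GrowthFit, PlateSeries

__all__ = [
    "InsufficientDataError", "fit_growth_rate", "summarize_condition",
    "absorbance_to_od", "od_to_absorbance", "detect_escape",
    "correct_absorbance", "classify_policy",
]

GROWING_WINDOW = (0.05, 0.2)   # bounds on background-corrected absorbance
ARRESTED_T_START = 1000.0      # minutes


class InsufficientDataError(ValueError):
    """Raised when a fitting window holds fewer points than required."""


def _ols_loglinear(t: np.ndarray, a: np.ndarray):
    """Closed-form OLS of ln(a) on t; returns slope, intercept, SE, R^2."""
    y = np.log(a)
    n = len(t)
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    sxy = np.sum((t - tbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * t)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    se = np.sqrt(ss_res / (n - 2) / sxx) if n > 2 else 0.0
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(se), float(r2)


def correct_absorbance(series_df: pd.DataFrame, background: float | None = None,
                       blank: pd.DataFrame | None = None) -> np.ndarray:
    """Background-corrected absorbance for one well.

    Background is the median of the first three samples of a blank well if
    one is given, else the supplied constant (default 0: data already
    corrected).
    """
    a = series_df["absorbance"].to_numpy(dtype=float)
    if blank is not None:
        background = float(np.median(blank["absorbance"].to_numpy()[:3]))
    return a - (background or 0.0)


def fit_growth_rate(
    series: PlateSeries | pd.DataFrame,
    policy: str = "growing",
    background: float | None = None,
    window: tuple | None = None,
) -> GrowthFit:
    """Fit an exponential growth rate to a single-well series.

    ``policy`` is "growing" (0.05 < corrected A < 0.2) or "arrested"
    (t >= 1000 min). An explicit ``window`` of (t_start, t_end) minutes
    overrides the policy's selection rule.
    """
    df = series.df if isinstance(series, PlateSeries) else series
    if df["well"].nunique() != 1:
        raise ValueError("fit_growth_rate expects a single-well series")
    df = df.sort_values("time_min")
    t = df["time_min"].to_numpy(dtype=float)
    a = correct_absorbance(df, background)

    if window is not None:
        mask = (t >= window[0]) & (t < window[1])
        label = f"[{window[0]:g}, {window[1]:g}) min"
    elif policy == "growing":
        lo, hi = GROWING_WINDOW
        inside = (a > lo) & (a < hi)
        if not inside.any():
            raise InsufficientDataError(
                f"no samples with corrected absorbance in ({lo}, {hi})"
            )
        # longest contiguous run inside the band (noise can cause brief
        # one-sample crossings near the boundaries); half-open in time
        padded = np.concatenate([[False], inside, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        starts, ends = edges[::2], edges[1::2]
        k = int(np.argmax(ends - starts))
        mask = np.zeros_like(inside)
        mask[starts[k]:ends[k]] = True
        label = f"absorbance in ({lo}, {hi})"
    elif policy == "arrested":
        mask = t >= ARRESTED_T_START
        label = f"t >= {ARRESTED_T_START:g} min"
    else:
        raise ValueError(f"unknown window policy {policy!r}")

    if mask.sum() < 5:
        raise InsufficientDataError(
            f"window {label} holds {int(mask.sum())} points; need >= 5"
        )
    tw, aw = t[mask], a[mask]
    if np.any(aw <= 0):
        raise ValueError(
            f"non-positive corrected absorbance inside window {label}"
        )
    slope, intercept, se, r2 = _ols_loglinear(tw, aw)
    regime = "growing" if policy == "growing" else "arrested"
    if regime == "arrested" and slope < 0 and abs(slope) <= se:
        slope = 0.0   # negative slope indistinguishable from zero
    return GrowthFit(
        rate=slope, window=(float(tw[0]), float(tw[-1])),
        n_points=int(mask.sum()), se_rate=se, r_squared=r2,
        regime=regime, intercept=intercept,
    )


def classify_policy(series, background: float | None = None,
                    growing_min_abs: float = GROWING_WINDOW[1]) -> str:
    """Choose the window policy for a well: wells whose corrected absorbance
    never reaches the top of the exponential window are treated as arrested."""
    df = series.df if isinstance(series, PlateSeries) else series
    a = correct_absorbance(df.sort_values("time_min"), background)
    return "growing" if np.nanmax(a) >= growing_min_abs else "arrested"


def summarize_condition(fits: list[GrowthFit],
                        iptg_uM: float = np.nan) -> ConditionSummary:
    """Mean rate and 2 x SEM across replicate fits of one condition."""
    if len(fits) < 2:
        raise ValueError("summarize_condition needs at least 2 fits")
    rates = np.array([f.rate for f in fits], dtype=float)
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1))
    ci = 2.0 * sd / np.sqrt(len(rates))
    regimes = [f.regime for f in fits]
    majority = max(set(regimes), key=regimes.count)
    return ConditionSummary(
        iptg_uM=float(iptg_uM), mean_rate=mean, ci_halfwidth=ci,
        n_replicates=len(fits), regime=majority,
    )


def absorbance_to_od(a):
    """Convert plate absorbance to OD600 (factor 2.34 for these plates)."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("absorbance must be non-negative")
    out = ABS_TO_OD * a
    return float(out) if out.ndim == 0 else out


def od_to_absorbance(od):
    od = np.asarray(od, dtype=float)
    out = od / ABS_TO_OD
    return float(out) if out.ndim == 0 else out


def detect_escape(
    series: PlateSeries | pd.DataFrame,
    arrest_window_end: float,
    threshold_abs: float = 0.1,
    background: float | None = None,
    slope_window: float = 120.0,
) -> dict:
    """Flag a growth-arrested culture that resumed growth (an escaper).

    A well escapes if its background-corrected absorbance exceeds
    ``threshold_abs`` after ``arrest_window_end`` and the local slope of
    ln(absorbance) over the trailing ``slope_window`` minutes before the
    crossing is positive. Returns {"escaped", "t_escape"}.
    """
    df = series.df if isinstance(series, PlateSeries) else series
    if df["well"].nunique() != 1:
        raise ValueError("detect_escape expects a single-well series")
    df = df.sort_values("time_min")
    t = df["time_min"].to_numpy(dtype=float)
    a = correct_absorbance(df, background)
    if t[-1] <= arrest_window_end:
        raise InsufficientDataError("series ends before the arrest window end")
    late = t > arrest_window_end
    crossing = late & (a > threshold_abs)
    if not crossing.any():
        return {"escaped": False, "t_escape": None}
    k = int(np.argmax(crossing))
    t_escape = float(t[k])
    local = (t >= t_escape - slope_window) & (t <= t_escape)
    if local.sum() >= 3 and np.all(a[local] > 0):
        slope, *_ = _ols_loglinear(t[local], a[local])
        if slope <= 0:
            return {"escaped": False, "t_escape": None}
    return {"escaped": True, "t_escape": t_escape}
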