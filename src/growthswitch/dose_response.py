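"""Dose-response characterization of the growth switch.

Three complementary summaries of the same data: a threshold *bracket* (the
pair of adjacent tested IPTG levels between which growth switches on — never
interpolated, mirroring how such thresholds are reported), a Michaelis-Menten
fit of growth vs IPTG above the threshold (zero below it), and a Hill fit of
growth vs beta' concentration quantifying the ultrasensitivity of the switch.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .types import DoseResponseCurve, HillFit, MMFit, ThresholdBracket

__all__ = [
    "NoThresholdError", "AmbiguousThresholdError",
    "detect_threshold", "fit_mm_above_threshold", "fit_hill",
]


class NoThresholdError(ValueError):
    """All levels fall in one regime; no switch to bracket."""


class AmbiguousThresholdError(ValueError):
    """Regime classification is not monotone in the inducer level."""


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge from every start."""


def detect_threshold(
    curve: DoseResponseCurve,
    arrest_cutoff: float | None = None,
) -> ThresholdBracket:
    """Bracket the switching threshold between adjacent tested levels.

    ``lower`` is the largest level whose mean rate is below the arrest
    cutoff (default 0.2 x the maximum observed rate); ``upper`` the next
    tested level, which must reach at least half the maximum rate for the
    switch to count as sharp.
    """
    rates = curve.mean_rates
    if len(rates) < 3:
        raise ValueError("need at least 3 levels to bracket a threshold")
    vmax = float(np.max(rates))
    if vmax <= 0:
        raise NoThresholdError("all rates are zero; no growing regime")
    cutoff = arrest_cutoff if arrest_cutoff is not None else 0.2 * vmax
    arrested = rates < cutoff
    if not arrested.any():
        raise NoThresholdError("no level is classified arrested")
    if arrested.all():
        raise NoThresholdError("every level is classified arrested")
    k = int(np.nonzero(arrested)[0][-1])
    if arrested[:k].sum() != k:
        offending = curve.levels[np.nonzero(~arrested[:k])[0]]
        raise AmbiguousThresholdError(
            f"growing levels below arrested ones: {offending.tolist()}"
        )
    if k + 1 >= len(rates):
        raise NoThresholdError("largest tested level is still arrested")
    if rates[k + 1] < 0.5 * vmax:
        raise NoThresholdError(
            "no sharp switch: rate just above the bracket is below half-max"
        )
    return ThresholdBracket(
        lower=float(curve.levels[k]), upper=float(curve.levels[k + 1])
    )


def fit_mm_above_threshold(
    curve: DoseResponseCurve, bracket: ThresholdBracket
) -> MMFit:
    """Michaelis-Menten fit v*(I-lower)/((I-lower)+Km) above the threshold."""
    keep = curve.levels > bracket.lower
    if keep.sum() < 3:
        raise ValueError("need at least 3 levels strictly above the bracket")
    x = curve.levels[keep] - bracket.lower
    y = curve.mean_rates[keep]

    def resid(p):
        v, km = p
        return v * x / (x + km) - y

    p0 = [float(y.max()), float(np.median(x))]
    sol = least_squares(resid, p0, bounds=([0, 1e-9], [np.inf, np.inf]))
    if not sol.success:
        raise FitFailureError(f"MM fit failed: {sol.message}")
    return MMFit(vmax=float(sol.x[0]), Km=float(sol.x[1]),
                 threshold_used=float(bracket.lower))


def fit_hill(
    x,
    y,
    n_starts=(1.0, 2.0, 4.0, 8.0, 12.0, 16.0),
    n_bounds=(1.0, 20.0),
    vmax_fixed: float | None = None,
) -> HillFit:
    """Least-squares Hill fit of rate vs beta' concentration.

    Fits vmax * x^n / (x^n + K^n) in natural scale with multi-start over the
    exponent (near-switch data make log-linearization ill-conditioned).
    ``vmax_fixed`` pins the plateau to e.g. the wild-type rate; the default
    fits it freely.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("Hill fit needs at least 5 points")
    if np.any(x <= 0):
        raise ValueError("beta' levels must be positive")

    def model(p, xx):
        if vmax_fixed is None:
            v, k, n = p
        else:
            v = vmax_fixed
            k, n = p
        xn = np.power(xx / k, n)       # (x/K)^n is overflow-safe for large n
        return v * xn / (xn + 1.0)

    best = None
    y_max = float(y.max())
    k0 = float(np.median(x))
    for n0 in n_starts:
        if vmax_fixed is None:
            p0 = [y_max, k0, n0]
            lb = [1e-12, 1e-12, n_bounds[0]]
            ub = [np.inf, np.inf, n_bounds[1]]
        else:
            p0 = [k0, n0]
            lb = [1e-12, n_bounds[0]]
            ub = [np.inf, n_bounds[1]]
        try:
            sol = least_squares(
                lambda p: model(p, x) - y, p0, bounds=(lb, ub), xtol=1e-14,
                ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitFailureError("Hill fit failed to converge from every start")
    rss, p = best
    if vmax_fixed is None:
        v, k, n = p
    else:
        v, (k, n) = vmax_fixed, p
    return HillFit(n=float(n), K=float(k), vmax=float(v), rss=rss)
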