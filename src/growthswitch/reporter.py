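"""Reconstruction of the beta' concentration from mCherry fluorescence.

The fluorescent fusion only becomes visible after chromophore maturation, so
the measured per-biomass fluorescence rho = F/A tracks the *mature* reporter
pool. The immature pool is recovered from the maturation balance

    dm/dt = k_mat * i - (mu + delta) * m     =>
    iota = (drho/dt + (mu + delta) * rho) / k_mat,

with drho/dt from a GCV-smoothed cubic spline, and the total reporter
concentration is rho_total = rho + iota. ``delta`` is the slow first-order
depletion of the fusion pool; the default 0 treats the protein as stable, in
which case the steady-state closed form rho_total = rho * (1 + mu/k_mat)
holds exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .plate import InsufficientDataError, correct_absorbance
from .types import GrowthFit, PlateSeries, ReporterProfile, SteadyStateLevel

__all__ = [
    "correct_background", "reconstruct_total_reporter",
    "steady_state_concentration",
]


def fit_autofluorescence(control_df: pd.DataFrame) -> float:
    """Slope of fluorescence vs absorbance in an untagged control well."""
    a = control_df["absorbance"].to_numpy(dtype=float)
    f = control_df["fluorescence"].to_numpy(dtype=float)
    X = np.column_stack([a, np.ones_like(a)])
    coef, *_ = np.linalg.lstsq(X, f, rcond=None)
    return float(coef[0])


def correct_background(
    series: PlateSeries,
    control: PlateSeries | None = None,
    background: float | None = None,
    autofluo: float | None = None,
) -> PlateSeries:
    """Subtract medium blank and autofluorescence from a plate series.

    Autofluorescence is modeled as a_fit * A(t) with a_fit regressed from the
    untagged control strain; without a control the constant ``autofluo`` from
    configuration is used (with a warning). Negative corrected values are
    clipped to zero and the clip count reported as a warning.
    """
    if control is not None:
        ctrl = control.df
        a_fit = fit_autofluorescence(ctrl)
        if background is None:
            background = None  # caller may still pass a constant
    else:
        if autofluo is None:
            raise ValueError("need either a control series or an autofluo constant")
        warnings.warn(
            "no control well: falling back to configured autofluorescence "
            f"coefficient {autofluo}", stacklevel=2,
        )
        a_fit = float(autofluo)

    out = series.df.copy()
    corrected_rows = []
    n_clipped = 0
    for well, sub in out.groupby("well", sort=False):
        sub = sub.sort_values("time_min").copy()
        a_corr = correct_absorbance(sub, background)
        f_corr = sub["fluorescence"].to_numpy(dtype=float) - a_fit * sub[
            "absorbance"].to_numpy(dtype=float)
        n_clipped += int((a_corr < 0).sum() + (f_corr < 0).sum())
        sub["absorbance"] = np.maximum(a_corr, 0.0)
        sub["fluorescence"] = np.maximum(f_corr, 0.0)
        corrected_rows.append(sub)
    if n_clipped:
        warnings.warn(
            f"clipped {n_clipped} negative background-corrected values to 0",
            stacklevel=2,
        )
    result = pd.concat(corrected_rows, ignore_index=True)
    result.attrs["a_fit"] = a_fit
    out = PlateSeries(result, series.states)
    return out


def reconstruct_total_reporter(
    series: PlateSeries | pd.DataFrame,
    k_mat: float,
    mu: float | GrowthFit,
    deg_rate: float = 0.0,
    window: tuple | None = None,
    min_abs: float = 1e-4,
) -> ReporterProfile:
    """Maturation-corrected total reporter concentration for one well.

    ``series`` must already be background-corrected (absorbance ~ biomass,
    fluorescence ~ mature reporter amount). ``mu`` is the condition's fitted
    growth rate (0 for arrested wells); ``deg_rate`` an optional known
    depletion rate added to the dilution term.
    """
    if k_mat <= 0:
        raise ValueError("k_mat must be positive")
    df = series.df if isinstance(series, PlateSeries) else series
    if df["well"].nunique() != 1:
        raise ValueError("reconstruct_total_reporter expects a single well")
    df = df.sort_values("time_min")
    t = df["time_min"].to_numpy(dtype=float)
    a = df["absorbance"].to_numpy(dtype=float)
    f = df["fluorescence"].to_numpy(dtype=float)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, a, f = t[keep], a[keep], f[keep]
    usable = a > min_abs
    t, a, f = t[usable], a[usable], f[usable]
    if len(t) < 5:
        raise InsufficientDataError(
            "fewer than 5 usable samples for the reporter spline"
        )
    mu_val = mu.rate if isinstance(mu, GrowthFit) else float(mu)
    rho = f / a
    spline = make_smoothing_spline(t, rho)   # GCV-selected smoothing
    rho_s = spline(t)
    drho = spline.derivative()(t)
    iota = (drho + (mu_val + deg_rate) * rho_s) / k_mat
    rho_total = rho_s + iota
    return ReporterProfile(
        time=t, rho_raw=rho, rho_total=rho_total, mu_used=mu_val
    )


def steady_state_concentration(
    profile: ReporterProfile,
    window: tuple,
    iptg_uM: float = np.nan,
) -> SteadyStateLevel:
    """Median maturation-corrected concentration over the steady-state window
    (the same window used for the condition's growth fit)."""
    t = profile.time
    keep = (t >= window[0]) & (t <= window[1])
    if not keep.any():
        raise InsufficientDataError("empty steady-state window")
    return SteadyStateLevel(
        iptg_uM=float(iptg_uM),
        concentration=float(np.median(profile.rho_total[keep])),
    )


def aggregate_levels(levels: list[SteadyStateLevel],
                     iptg_uM: float = np.nan) -> SteadyStateLevel:
    """Replicate mean and 2 x SEM of steady-state concentrations."""
    vals = np.array([l.concentration for l in levels], dtype=float)
    n = len(vals)
    ci = 2.0 * vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return SteadyStateLevel(
        iptg_uM=float(iptg_uM), concentration=float(vals.mean()),
        ci_halfwidth=float(ci), n_replicates=n,
    )
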