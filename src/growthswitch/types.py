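"""Shared domain containers used across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

PLATE_COLUMNS = [
    "well", "time_min", "absorbance", "fluorescence",
    "strain", "medium", "iptg_uM", "replicate",
]

PRODUCTION_COLUMNS = [
    "time_min", "od600", "glucose_g_per_L", "glycerol_g_per_L",
    "strain", "replicate",
]


class PlateSeries:
    """Per-well absorbance/fluorescence time courses with condition metadata.

    Thin wrapper over a tidy long-format DataFrame (one observation per row,
    schema ``PLATE_COLUMNS``). ``states`` optionally carries the simulator's
    noise-free latent trajectories for oracle tests.
    """

    def __init__(self, df: pd.DataFrame, states: Optional[pd.DataFrame] = None):
        missing = [c for c in PLATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"plate data missing columns: {missing}")
        dup = df.duplicated(subset=["well", "time_min"])
        if dup.any():
            rows = df.index[dup].tolist()[:5]
            raise ValueError(f"duplicate (well, time) pairs at rows {rows}")
        for well, sub in df.groupby("well"):
            t = sub["time_min"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"time grid not strictly increasing in well {well!r}")
        self.df = df.reset_index(drop=True)
        self.states = states

    @property
    def wells(self) -> list:
        return sorted(self.df["well"].unique().tolist())

    def well(self, well_id) -> pd.DataFrame:
        sub = self.df[self.df["well"] == well_id]
        if sub.empty:
            raise KeyError(f"no such well {well_id!r}")
        return sub.sort_values("time_min").reset_index(drop=True)

    def well_states(self, well_id) -> pd.DataFrame:
        if self.states is None:
            raise ValueError("no latent states attached to this PlateSeries")
        return (
            self.states[self.states["well"] == well_id]
            .sort_values("time_min")
            .reset_index(drop=True)
        )

    def subset(self, **conditions) -> "PlateSeries":
        mask = pd.Series(True, index=self.df.index)
        for key, val in conditions.items():
            mask &= self.df[key] == val
        states = None
        if self.states is not None:
            wells = self.df.loc[mask, "well"].unique()
            states = self.states[self.states["well"].isin(wells)].reset_index(drop=True)
        return PlateSeries(self.df[mask].reset_index(drop=True), states)

    @staticmethod
    def concat(parts: list["PlateSeries"]) -> "PlateSeries":
        df = pd.concat([p.df for p in parts], ignore_index=True)
        st = [p.states for p in parts if p.states is not None]
        states = pd.concat(st, ignore_index=True) if st else None
        return PlateSeries(df, states)


@dataclass
class GrowthFit:
    """Exponential growth-rate estimate from one well."""
    rate: float                      # 1/min
    window: tuple                    # [t_start, t_end) in minutes
    n_points: int
    se_rate: float                   # 1/min
    r_squared: float
    regime: str                      # "growing" | "arrested"
    intercept: float = 0.0           # ln-absorbance at t=0

    def __post_init__(self):
        if self.n_points < 5:
            raise ValueError("growth fit needs at least 5 points")
        if self.se_rate < 0:
            raise ValueError("se_rate must be non-negative")
        if self.regime not in ("growing", "arrested"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class ConditionSummary:
    """Replicate summary of growth rates at one condition."""
    iptg_uM: float
    mean_rate: float
    ci_halfwidth: float              # 2 x SEM
    n_replicates: int
    regime: str = "growing"


@dataclass
class DoseResponseCurve:
    """(IPTG level -> mean rate +/- 2 SEM) table."""
    levels: np.ndarray               # uM, strictly increasing
    mean_rates: np.ndarray           # 1/min
    ci_halfwidths: np.ndarray        # 1/min

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        self.mean_rates = np.asarray(self.mean_rates, dtype=float)
        self.ci_halfwidths = np.asarray(self.ci_halfwidths, dtype=float)
        if not (len(self.levels) == len(self.mean_rates) == len(self.ci_halfwidths)):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")


@dataclass
class ThresholdBracket:
    """Adjacent tested IPTG levels bracketing the growth switch."""
    lower: float                     # uM, arrested side
    upper: float                     # uM, growing side


@dataclass
class HillFit:
    """Least-squares Hill fit of growth rate vs beta' concentration."""
    n: float
    K: float
    vmax: float
    rss: float

    def __post_init__(self):
        if self.n < 1 or self.K <= 0 or self.vmax <= 0:
            raise ValueError("invalid Hill parameters")

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        xn = x ** self.n
        return self.vmax * xn / (xn + self.K ** self.n)


@dataclass
class MMFit:
    """Michaelis-Menten fit above the IPTG threshold (0 at and below it)."""
    vmax: float                      # 1/min
    Km: float                        # uM
    threshold_used: float            # uM

    def predict(self, levels):
        levels = np.asarray(levels, dtype=float)
        shifted = levels - self.threshold_used
        out = np.where(
            shifted > 0, self.vmax * shifted / (shifted + self.Km), 0.0
        )
        return out


@dataclass
class ReporterProfile:
    """Maturation-corrected reporter concentration profile for one well."""
    time: np.ndarray                 # minutes
    rho_raw: np.ndarray              # RFU per absorbance unit (mature proxy)
    rho_total: np.ndarray            # maturation-corrected total
    mu_used: float                   # 1/min


@dataclass
class SteadyStateLevel:
    """Steady-state reporter concentration at one condition."""
    iptg_uM: float
    concentration: float             # RFU per absorbance unit
    ci_halfwidth: float = 0.0        # 2 x SEM across replicates
    n_replicates: int = 1


class ProductionSeries:
    """Substrate and product time courses from one production run."""

    def __init__(self, df: pd.DataFrame, states: Optional[pd.DataFrame] = None):
        missing = [c for c in PRODUCTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"production data missing columns: {missing}")
        t = df["time_min"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid not strictly increasing")
        if np.any(df["glycerol_g_per_L"].to_numpy() < 0):
            raise ValueError("negative glycerol concentration")
        self.df = df.reset_index(drop=True)
        self.states = states

    @property
    def time(self):
        return self.df["time_min"].to_numpy()

    @property
    def glucose(self):
        return self.df["glucose_g_per_L"].to_numpy()

    @property
    def glycerol(self):
        return self.df["glycerol_g_per_L"].to_numpy()


@dataclass
class YieldProfile:
    """Time-varying glycerol yield Y(t) = -(dgly/dt)/(dglc/dt) on a window."""
    time: np.ndarray                 # minutes, uniform grid inside the window
    Y: np.ndarray                    # g glycerol per g glucose; NaN where masked
    window: tuple                    # (t_start, t_end) minutes
    ci_halfwidth: Optional[np.ndarray] = None   # 2 x SEM across replicates

    def __post_init__(self):
        finite = self.Y[np.isfinite(self.Y)]
        if finite.size and (finite.min() < -0.05 or finite.max() > 1.1):
            import warnings
            warnings.warn(
                "yield outside the [0, 1.1] sanity band", stacklevel=2
            )


@dataclass
class LengthTrack:
    """One cell lineage's length-vs-time record."""
    cell_id: str
    times: np.ndarray                # minutes, constant frame interval
    lengths: np.ndarray              # um

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("frame grid must be strictly increasing and uniform")
        if np.any(self.lengths <= 0):
            raise ValueError("lengths must be positive")


@dataclass
class GenerationSegment:
    """One generation (between consecutive divisions) of a lineage."""
    cell_id: str
    birth_time: float                # minutes
    division_time: Optional[float]   # minutes, None if censored
    frames: np.ndarray               # frame indices into the track
    rate: float = np.nan             # 1/min elongation rate
    r_squared: float = np.nan
    censored: bool = False


@dataclass
class PopulationGrowthCurve:
    """Time-binned weighted mean elongation rate across cells."""
    bin_centers: np.ndarray          # minutes
    mean_rates: np.ndarray           # 1/min
    sd_rates: np.ndarray             # 1/min
    n_cells: np.ndarray              # cells contributing per bin
    bin_width: float = np.nan
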