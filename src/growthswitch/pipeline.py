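"""End-to-end analyses on simulated data, and the reproduction pipeline.

These functions wire the stages together exactly as the analysis is meant to
run on real exports: simulate (or load) -> background correction -> growth
fits -> condition summaries -> reporter reconstruction -> dose-response
characterization -> production yields -> lineage statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gsio
from .config import SimConfig, medium_config, production_config, write_config
from .dose_response import detect_threshold, fit_hill, fit_mm_above_threshold
from .lineage import (
    detect_arrest_and_recovery, population_growth_curve, segment_generations,
)
from .plate import classify_policy, fit_growth_rate, summarize_condition
from .production import average_yield_profiles, yield_from_series
from .reporter import (
    aggregate_levels, correct_background, reconstruct_total_reporter,
    steady_state_concentration,
)
from .simulate import (
    DEFAULT_IPTG_LEVELS, simulate_batch, simulate_dose_series,
    simulate_lineage, simulate_production,
)
from .types import DoseResponseCurve, PlateSeries

__all__ = [
    "rates_at_saturating_iptg", "analyze_dose_series", "run_dose_pipeline",
    "run_production_pipeline", "run_lineage_pipeline", "RunConfig",
    "run_pipeline",
]

ARREST_WINDOW = (1000.0, np.inf)


def rates_at_saturating_iptg(
    medium: str, seed: int, replicates: int = 5, duration: float = 1200.0
):
    """Replicate growth fits for one medium at saturating (1000 uM) IPTG."""
    config = medium_config(medium, seed=seed)
    plate = simulate_dose_series(
        config, iptg_levels=[1000.0], replicates=replicates, duration=duration
    )
    fits = []
    for well in plate.wells:
        fits.append(fit_growth_rate(
            plate.well(well), policy="growing", background=config.A_bg
        ))
    return summarize_condition(fits, iptg_uM=1000.0), fits


def analyze_dose_series(
    plate: PlateSeries,
    control: PlateSeries,
    config: SimConfig,
) -> dict:
    """Full dose-response analysis of a (simulated or loaded) plate.

    Returns the per-condition growth summaries, the threshold bracket, the
    Michaelis-Menten fit above threshold, the steady-state beta' levels, and
    the Hill fit of rate vs beta' concentration.
    """
    corrected = correct_background(plate, control, background=config.A_bg)
    levels = sorted(corrected.df["iptg_uM"].unique())

    summaries, ss_levels, pairs = [], [], []
    for level in levels:
        sub = corrected.subset(iptg_uM=level)
        fits, conc = [], []
        for well in sub.wells:
            wdf = sub.well(well)
            policy = classify_policy(wdf)
            fit = fit_growth_rate(wdf, policy=policy)
            fits.append(fit)
            mu = fit.rate if policy == "growing" else 0.0
            window = fit.window if policy == "growing" else (
                ARREST_WINDOW[0], float(wdf["time_min"].max())
            )
            profile = reconstruct_total_reporter(
                wdf, k_mat=config.k_mat, mu=mu, deg_rate=config.deg_rate
            )
            conc.append(steady_state_concentration(
                profile, window, iptg_uM=level
            ))
        summaries.append(summarize_condition(fits, iptg_uM=level))
        ss_levels.append(aggregate_levels(conc, iptg_uM=level))
        pairs.append((ss_levels[-1].concentration, summaries[-1].mean_rate))

    curve = DoseResponseCurve(
        levels=np.array(levels),
        mean_rates=np.array([s.mean_rate for s in summaries]),
        ci_halfwidths=np.array([s.ci_halfwidth for s in summaries]),
    )
    bracket = detect_threshold(curve)
    mm = fit_mm_above_threshold(curve, bracket)
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    hill = fit_hill(x[x > 0], y[x > 0])
    return {
        "curve": curve, "summaries": summaries, "steady_levels": ss_levels,
        "bracket": bracket, "mm": mm, "hill": hill,
        "hill_points": (x, y), "autofluo_fit": corrected.df.attrs.get("a_fit"),
    }


def run_dose_pipeline(
    medium: str = "M9-glc",
    seed: int = 0,
    replicates: int = 5,
    iptg_levels=DEFAULT_IPTG_LEVELS,
    duration: float = 1200.0,
) -> dict:
    """Simulate the reference dose series plus control and analyze it."""
    config = medium_config(medium, seed=seed)
    plate = simulate_dose_series(
        config, iptg_levels=iptg_levels, replicates=replicates,
        duration=duration,
    )
    control = simulate_batch(
        config.replace(seed=(seed * 7919 + 13) % (2 ** 31)),
        [(0.0, 1000.0)], duration, strain="W", well="ctrl",
    )
    out = analyze_dose_series(plate, control, config)
    out["plate"] = plate
    out["control"] = control
    out["config"] = config
    return out


def run_production_pipeline(
    seed: int = 0,
    replicates: int = 6,
    duration: float = 1100.0,
    noise_conc: float = 0.005,
) -> dict:
    """Replicate W-gly and R-gly production runs and their yield profiles.

    Reports the mean W-gly yield (the constant baseline), the maximum mean
    R-gly yield, and their ratio — the yield improvement achieved by
    switching growth off.
    """
    profiles = {}
    for strain in ("W-gly", "R-gly"):
        reps = []
        for rep in range(replicates):
            cfg = production_config(seed=(seed * 1009 + rep) % (2 ** 31))
            series = simulate_production(
                cfg, strain, duration=duration, noise_conc=noise_conc,
                replicate=rep,
            )
            reps.append(yield_from_series(series))
        profiles[strain] = average_yield_profiles(reps) if replicates > 1 \
            else reps[0]
    w_mean = float(np.nanmean(profiles["W-gly"].Y))
    r_max = float(np.nanmax(profiles["R-gly"].Y))
    return {
        "profiles": profiles,
        "w_yield": w_mean,
        "r_max_yield": r_max,
        "ratio": r_max / w_mean,
    }


def run_lineage_pipeline(
    seed: int = 0,
    n_cells: int = 100,
    removal_time: float = 480.0,
    readdition_time: float = 840.0,
    duration: float = 1320.0,
    bin_width: float = 30.0,
    frame_interval: float = 10.0,
) -> dict:
    """Inducer removal/re-addition lineage experiment and its analysis."""
    config = medium_config("M9-glc", seed=seed)
    schedule = [(0.0, 1000.0), (removal_time, 0.0), (readdition_time, 1000.0)]
    tracks, log = simulate_lineage(
        config, schedule, n_cells=n_cells, frame_interval=frame_interval,
        duration=duration,
    )
    pairs = []
    for tr in tracks:
        for seg in segment_generations(tr):
            pairs.append((seg, tr))
    curve = population_growth_curve(pairs, bin_width=bin_width)
    lags = detect_arrest_and_recovery(curve, removal_time, readdition_time)
    return {
        "tracks": tracks, "division_log": log, "curve": curve, "lags": lags,
        "schedule": schedule,
    }


@dataclasses.dataclass
class RunConfig:
    """Configuration of one reproduction run."""
    scenario: str = "repro"          # dose | production | lineage | repro
    medium: str = "M9-glc"
    seed: int = 0
    out_dir: str = "growthswitch-out"
    overrides: dict = dataclasses.field(default_factory=dict)

    _KNOWN = {"replicates", "duration", "n_cells", "bin_width", "noise_conc"}

    def __post_init__(self):
        from .config import MEDIA
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium calibration {self.medium!r}")
        if self.scenario not in ("dose", "production", "lineage", "repro"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        unknown = set(self.overrides) - self._KNOWN
        if unknown:
            raise ValueError(f"unknown override keys {sorted(unknown)}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(run: RunConfig) -> dict:
    """Execute a scenario end to end, writing every artifact plus a manifest."""
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ov = run.overrides
    results: dict = {"scenario": run.scenario, "seed": run.seed}
    artifacts: list[Path] = []

    def save_df(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        artifacts.append(path)

    if run.scenario in ("dose", "repro"):
        dose = run_dose_pipeline(
            medium=run.medium, seed=run.seed,
            replicates=int(ov.get("replicates", 5)),
            duration=float(ov.get("duration", 1200.0)),
        )
        gsio.write_plate_csv(dose["plate"], out / "plate.csv")
        artifacts.append(out / "plate.csv")
        save_df(pd.DataFrame(
            [(s.iptg_uM, s.mean_rate, s.ci_halfwidth, s.n_replicates, s.regime)
             for s in dose["summaries"]],
            columns=["iptg_uM", "mean_rate", "ci_halfwidth", "n", "regime"],
        ), "growth_rates.csv")
        save_df(pd.DataFrame(
            [(l.iptg_uM, l.concentration, l.ci_halfwidth)
             for l in dose["steady_levels"]],
            columns=["iptg_uM", "beta_prime_level", "ci_halfwidth"],
        ), "beta_prime_levels.csv")
        h, b, mm = dose["hill"], dose["bracket"], dose["mm"]
        results["dose"] = {
            "bracket_lower_uM": b.lower, "bracket_upper_uM": b.upper,
            "hill_n": h.n, "hill_K": h.K, "hill_vmax": h.vmax,
            "mm_vmax": mm.vmax, "mm_Km": mm.Km,
        }
    if run.scenario in ("production", "repro"):
        prod = run_production_pipeline(
            seed=run.seed, replicates=int(ov.get("replicates", 6)),
            noise_conc=float(ov.get("noise_conc", 0.01)),
        )
        for strain, prof in prod["profiles"].items():
            save_df(pd.DataFrame({
                "time_min": prof.time, "yield_g_per_g": prof.Y,
                "ci_halfwidth": prof.ci_halfwidth,
            }), f"yield_{strain}.csv")
        results["production"] = {
            "w_yield": prod["w_yield"], "r_max_yield": prod["r_max_yield"],
            "ratio": prod["ratio"],
        }
    if run.scenario in ("lineage", "repro"):
        lin = run_lineage_pipeline(
            seed=run.seed, n_cells=int(ov.get("n_cells", 100)),
            bin_width=float(ov.get("bin_width", 30.0)),
        )
        gsio.write_tracks_csv(
            lin["tracks"], out / "tracks.csv", lin["division_log"],
            out / "divisions.csv",
        )
        artifacts += [out / "tracks.csv", out / "divisions.csv"]
        c = lin["curve"]
        save_df(pd.DataFrame({
            "bin_center_min": c.bin_centers, "mean_rate": c.mean_rates,
            "sd_rate": c.sd_rates, "n_cells": c.n_cells,
        }), "population_growth.csv")
        results["lineage"] = lin["lags"]

    write_config(medium_config(run.medium, seed=run.seed), out / "config.ini")
    artifacts.append(out / "config.ini")
    manifest = {
        "scenario": run.scenario, "seed": run.seed, "medium": run.medium,
        "results": results,
        "artifacts": {p.name: _checksum(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
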