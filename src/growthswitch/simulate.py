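"""Mechanistic simulator of the RNA-polymerase growth switch.

State variables (see :mod:`growthswitch.config` for units):

``c``   beta' pool carried by the cells (a.u.); produced at a rate set by the
        IPTG-inducible promoter, removed by growth dilution plus a slow
        first-order depletion.
``i``   immature (dark) beta'-mCherry reporter, ``m`` mature reporter.
``B``   biomass in background-corrected absorbance units.
``glc`` substrate and ``gly`` glycerol in g/L.

The growth rate follows a Hill function of the beta' pool,
``mu(c) = mu_max * c^n / (c^n + K^n)``, which is the ultrasensitive coupling
that turns graded induction into an on/off growth switch. Induction is
``u(I) = I^h / (I^h + K_iptg^h)``; ``h = 1`` recovers a Michaelis-Menten
promoter, the default ``h`` reflects the effective cooperativity of the lac
system needed to place the switching threshold between adjacent tested IPTG
levels.

Substrate uptake is Monod, ``q = q_max * B * glc / (glc + K_glc)``; the part
of the uptake not invested in biomass can be routed to glycerol with branch
fraction ``f_branch``. Biomass formation is substrate-limited near glucose
exhaustion so that carbon is conserved exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import ABS_TO_OD, SimConfig
from .types import LengthTrack, PlateSeries, ProductionSeries

__all__ = [
    "mu_of_c", "induction", "integrate_states", "simulate_batch",
    "simulate_dose_series", "simulate_production", "simulate_lineage",
]

_GLC_EPS = 1e-9


def mu_of_c(c, config: SimConfig):
    """Hill growth law mu(c); non-decreasing in c, saturating at mu_max."""
    c = np.maximum(np.asarray(c, dtype=float), 0.0)
    cn = c ** config.hill_n
    return config.mu_max * cn / (cn + config.hill_K ** config.hill_n)


def induction(iptg_uM: float, config: SimConfig) -> float:
    """Fractional promoter activity u(I) in [0, 1]."""
    if iptg_uM < 0:
        raise ValueError("IPTG concentration must be non-negative")
    if iptg_uM == 0.0:
        return 0.0
    ih = iptg_uM ** config.iptg_hill
    return ih / (ih + config.K_iptg ** config.iptg_hill)


def _validate_schedule(schedule, duration):
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not schedule:
        raise ValueError("empty IPTG schedule")
    times = [t for t, _ in schedule]
    if times[0] != 0:
        raise ValueError("IPTG schedule must start at t=0")
    if any(t < 0 for t in times):
        raise ValueError("IPTG schedule times must be non-negative")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("IPTG schedule times must be strictly increasing")
    if any(level < 0 for _, level in schedule):
        raise ValueError("IPTG levels must be non-negative")


def _rhs(t, y, p_tx, config: SimConfig, fed: bool):
    c, i, m, B, glc, gly = y
    mu = mu_of_c(c, config) if fed else 0.0
    loss = mu + config.deg_rate
    dc = p_tx - loss * c
    di = p_tx - (config.k_mat + loss) * i
    dm = config.k_mat * i - loss * m
    if fed:
        monod = glc / (glc + config.K_glc)
        q_cap = config.q_max * B * monod
        demand = mu * B / config.Y_biomass_abs
        to_biomass = min(demand, q_cap)      # substrate-limited near exhaustion
        if config.f_branch > 0:
            # overexpressed production pathway pulls glycolysis at capacity;
            # uptake not invested in biomass overflows toward glycerol
            q = q_cap
        else:
            q = to_biomass + config.q_maint * B * monod
        dB = config.Y_biomass_abs * to_biomass
        dglc = -q
        dgly = config.f_branch * (q - to_biomass)
    else:
        dB, dglc, dgly = 0.0, 0.0, 0.0
    return [dc, di, dm, dB, dglc, dgly]


def integrate_states(
    config: SimConfig,
    iptg_schedule,
    duration: float,
    constitutive: bool = False,
    y0=None,
) -> pd.DataFrame:
    """Integrate the noise-free ODE system, sampled every ``dt_sample``.

    Returns a DataFrame with columns t, c, i, m, B, glc, gly, mu, iptg_uM.
    ``constitutive=True`` emulates the wild-type (W) strain whose rpoBC
    promoter is always fully active.
    """
    _validate_schedule(iptg_schedule, duration)
    t_grid = np.arange(0.0, duration + 0.5 * config.dt_sample, config.dt_sample)
    t_grid = t_grid[t_grid <= duration + 1e-9]

    if y0 is None:
        # preculture carry-over: reporter pool matches c0 and is fully matured
        y0 = [config.c0, 0.0, config.c0, config.A0, config.glc0, 0.0]
    y = np.array(y0, dtype=float)

    breaks = [t for t, _ in iptg_schedule if 0.0 < t < duration]
    seg_edges = [0.0] + breaks + [duration]
    levels = {t: lv for t, lv in iptg_schedule}

    rows = []
    fed = y[4] > _GLC_EPS
    current_level = iptg_schedule[0][1]
    record_t0 = True
    for t0, t1 in zip(seg_edges, seg_edges[1:]):
        if t0 in levels:
            current_level = levels[t0]
        u = 1.0 if constitutive else induction(current_level, config)
        p_tx = config.k_tx_max * u
        t_start = t0
        while t_start < t1 - 1e-12:
            def exhausted(t, yy, *_args):
                return yy[4] - _GLC_EPS
            exhausted.terminal = True
            exhausted.direction = -1
            events = [exhausted] if fed else None
            t_eval = t_grid[(t_grid >= t_start - 1e-9) & (t_grid <= t1 + 1e-9)]
            if not record_t0:
                t_eval = t_eval[t_eval > t_start + 1e-9]
            sol = solve_ivp(
                _rhs, (t_start, t1), y, method="LSODA",
                t_eval=t_eval if len(t_eval) else None,
                args=(p_tx, config, fed), events=events,
                rtol=1e-8, atol=1e-9, max_step=np.inf,
            )
            if not sol.success:
                raise RuntimeError(f"integration failed: {sol.message}")
            for tk, yk in zip(sol.t, sol.y.T):
                rows.append((tk, *np.maximum(yk, 0.0), current_level))
            if fed and sol.t_events and len(sol.t_events[0]):
                t_start = float(sol.t_events[0][0])
                y = np.maximum(sol.y_events[0][0], 0.0)
                y[4] = 0.0
                fed = False
            else:
                t_start = t1
                y = np.maximum(sol.y.T[-1] if len(sol.t) else sol.y[:, -1], 0.0)
                # ensure we carry the true endpoint state, not the last sample
                if len(sol.t) == 0 or abs(sol.t[-1] - t1) > 1e-9:
                    end = solve_ivp(
                        _rhs, (t_start if len(sol.t) == 0 else sol.t[-1], t1),
                        y, method="LSODA", args=(p_tx, config, fed),
                        rtol=1e-8, atol=1e-9,
                    )
                    y = np.maximum(end.y[:, -1], 0.0)
            record_t0 = False

    df = pd.DataFrame(
        rows, columns=["t", "c", "i", "m", "B", "glc", "gly", "iptg_uM"]
    )
    df = df.drop_duplicates(subset="t", keep="last").reset_index(drop=True)
    if np.any(df[["c", "i", "m", "B", "glc", "gly"]].to_numpy() < -1e-6):
        raise RuntimeError("integration produced a negative state")
    df["mu"] = np.where(df["glc"] > _GLC_EPS, mu_of_c(df["c"], config), 0.0)
    return df


def _observe(states: pd.DataFrame, config: SimConfig, rng) -> pd.DataFrame:
    """Map latent states to noisy plate-reader observations."""
    A_true = states["B"].to_numpy() + config.A_bg
    F_true = (
        config.phi * states["m"].to_numpy() * states["B"].to_numpy()
        + config.autofluo * A_true
    )
    n = len(A_true)
    if config.noise_abs > 0:
        A_obs = A_true * np.exp(config.noise_abs * rng.standard_normal(n))
    else:
        A_obs = A_true.copy()
    if config.noise_fluo > 0:
        F_obs = F_true + config.noise_fluo * rng.standard_normal(n)
    else:
        F_obs = F_true.copy()
    return pd.DataFrame(
        {"time_min": states["t"], "absorbance": A_obs, "fluorescence": F_obs}
    )


def simulate_batch(
    config: SimConfig,
    iptg_schedule,
    duration: float,
    strain: str = "R-mCherry",
    well: str = "A1",
    replicate: int = 0,
    keep_states: bool = False,
) -> PlateSeries:
    """Simulate one microplate well under an IPTG schedule.

    ``iptg_schedule`` is a list of (time_min, uM) pairs, times strictly
    increasing and starting at 0. Strains whose name starts with "W" express
    rpoBC constitutively (induction-independent). Strains without the
    "-mCherry" suffix carry no reporter (``phi`` is forced to 0), which makes
    them suitable autofluorescence controls.
    """
    constitutive = strain.startswith("W")
    cfg = config if "mCherry" in strain else config.replace(phi=0.0)
    states = integrate_states(cfg, iptg_schedule, duration, constitutive)
    rng = np.random.default_rng(cfg.seed)
    obs = _observe(states, cfg, rng)
    obs["well"] = well
    obs["strain"] = strain
    obs["medium"] = cfg.medium
    obs["iptg_uM"] = float(iptg_schedule[-1][1])
    obs["replicate"] = replicate
    states_df = None
    if keep_states:
        states_df = states.rename(columns={"t": "time_min"}).copy()
        states_df["well"] = well
    return PlateSeries(obs[[
        "well", "time_min", "absorbance", "fluorescence",
        "strain", "medium", "iptg_uM", "replicate",
    ]], states_df)


def _well_seed(base_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


DEFAULT_IPTG_LEVELS = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 100.0, 1000.0)


def simulate_dose_series(
    config: SimConfig,
    iptg_levels=DEFAULT_IPTG_LEVELS,
    replicates: int = 5,
    duration: float = 1200.0,
    strain: str = "R-mCherry",
    keep_states: bool = False,
) -> PlateSeries:
    """One well per (IPTG level, replicate), with replicate-specific seeds."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    iptg_levels = list(iptg_levels)
    if not iptg_levels:
        raise ValueError("empty IPTG level list")
    parts = []
    idx = 0
    for level in iptg_levels:
        for rep in range(replicates):
            cfg = config.replace(seed=_well_seed(config.seed, idx))
            parts.append(simulate_batch(
                cfg, [(0.0, float(level))], duration, strain=strain,
                well=f"{level:g}uM-r{rep}", replicate=rep,
                keep_states=keep_states,
            ))
            idx += 1
    return PlateSeries.concat(parts)


def simulate_production(
    config: SimConfig,
    strain: str,
    duration: float = 1100.0,
    noise_conc: float = 0.0,
    replicate: int = 0,
    keep_states: bool = False,
) -> ProductionSeries:
    """Shake-flask production run for the W-gly or R-gly strain.

    W-gly grows at constant rate until glucose exhaustion; R-gly (no IPTG)
    arrests as the preculture beta' pool dilutes out, while Monod uptake
    continues at maintenance level and is routed to glycerol.
    """
    if strain not in ("W-gly", "R-gly"):
        raise ValueError(f"unknown production strain {strain!r}")
    if config.glc0 <= 0:
        raise ValueError("production requires glc0 > 0")
    states = integrate_states(
        config, [(0.0, 0.0)], duration, constitutive=strain.startswith("W")
    )
    rng = np.random.default_rng(config.seed)
    od = ABS_TO_OD * states["B"].to_numpy()
    glc = states["glc"].to_numpy().copy()
    gly = states["gly"].to_numpy().copy()
    if noise_conc > 0:
        od = od * np.exp(0.01 * rng.standard_normal(len(od)))
        glc = np.maximum(glc + noise_conc * rng.standard_normal(len(glc)), 0.0)
        gly = np.maximum(gly + noise_conc * rng.standard_normal(len(gly)), 0.0)
    df = pd.DataFrame({
        "time_min": states["t"], "od600": od,
        "glucose_g_per_L": glc, "glycerol_g_per_L": gly,
        "strain": strain, "replicate": replicate,
    })
    return ProductionSeries(df, states if keep_states else None)


def simulate_lineage(
    config: SimConfig,
    iptg_schedule,
    n_cells: int = 100,
    frame_interval: float = 10.0,
    duration: float = 1500.0,
    L_div: float = 3.0,
    c_div_threshold: float = 1.0,
    div_noise_sd: float = 0.05,
    length_noise_sd: float = 0.02,
):
    """Mother-machine lineages under an IPTG schedule.

    Cells elongate as dL/dt = mu(c(t)) * L with the channel-wide beta' pool
    c(t); a cell divides (L -> L/2 with lognormal asymmetry noise) once it
    reaches ``L_div``, but division is blocked while c < ``c_div_threshold``
    (filamentation during polymerase depletion). Returns ``(tracks, log)``
    where ``log`` is a DataFrame of ground-truth division events.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    cfg = config.replace(dt_sample=frame_interval, glc0=1e9)  # perfused device
    states = integrate_states(cfg, iptg_schedule, duration)
    t = states["t"].to_numpy()
    mu = states["mu"].to_numpy()
    c = states["c"].to_numpy()
    rng = np.random.default_rng(config.seed)

    tracks, log_rows = [], []
    for cell in range(n_cells):
        cell_id = f"cell{cell:03d}"
        L = 0.5 * L_div * float(np.exp(0.1 * rng.standard_normal()))
        lengths = [L]
        for k in range(len(t) - 1):
            mu_k = mu[k]
            remaining = t[k + 1] - t[k]
            # divisions occur in continuous time within the frame interval
            while c[k] >= c_div_threshold:
                if L >= L_div:
                    t_to_cross = 0.0
                elif mu_k > 0:
                    t_to_cross = np.log(L_div / L) / mu_k
                    if t_to_cross > remaining + 1e-9:
                        break
                else:
                    break
                remaining -= min(t_to_cross, remaining)
                log_rows.append((cell_id, t[k + 1] - remaining))
                noise = div_noise_sd * rng.standard_normal() if div_noise_sd else 0.0
                L = 0.5 * max(L, L_div) * float(np.exp(noise))
            L = L * float(np.exp(mu_k * remaining))
            lengths.append(L)
        lengths = np.asarray(lengths)
        if length_noise_sd > 0:
            lengths = lengths * np.exp(
                length_noise_sd * rng.standard_normal(len(lengths))
            )
        tracks.append(LengthTrack(cell_id, t.copy(), lengths))
    log = pd.DataFrame(log_rows, columns=["cell_id", "division_time_min"])
    return tracks, log
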