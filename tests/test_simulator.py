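"""Simulator contracts: growth law, conservation, determinism, oracles."""

import numpy as np
import pandas as pd
import pytest

from growthswitch.config import SimConfig, medium_config
from growthswitch.plate import fit_growth_rate
from growthswitch.simulate import (
    induction, integrate_states, mu_of_c, simulate_batch,
    simulate_dose_series, simulate_production,
)


def rk4_oracle(config, iptg_uM, duration, dt=0.01, constitutive=False):
    """Independent fixed-step 4th-order integrator of the same ODE system.

    Re-derives the right-hand side from the model definition; shares no code
    with the adaptive integrator under test.
    """
    u = 1.0 if constitutive else (
        0.0 if iptg_uM == 0 else
        iptg_uM ** config.iptg_hill
        / (iptg_uM ** config.iptg_hill + config.K_iptg ** config.iptg_hill)
    )
    p = config.k_tx_max * u
    Yab = config.Y_biomass_abs

    def f(y):
        c, i, m, B, glc, gly = y
        if glc > 1e-9:
            mu = config.mu_max * c ** config.hill_n / (
                c ** config.hill_n + config.hill_K ** config.hill_n
            )
            monod = glc / (glc + config.K_glc)
            cap = config.q_max * B * monod
            demand = mu * B / Yab
            bio = min(demand, cap)
            q = cap if config.f_branch > 0 else bio + config.q_maint * B * monod
        else:
            mu, bio, q = 0.0, 0.0, 0.0
        loss = mu + config.deg_rate
        return np.array([
            p - loss * c,
            p - (config.k_mat + loss) * i,
            config.k_mat * i - loss * m,
            Yab * bio,
            -q,
            config.f_branch * (q - bio),
        ])

    y = np.array([config.c0, 0.0, config.c0, config.A0, config.glc0, 0.0])
    n = int(round(duration / dt))
    out_t, out_y = [0.0], [y.copy()]
    sample_every = int(round(config.dt_sample / dt))
    for k in range(1, n + 1):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.maximum(y, 0.0)
        if k % sample_every == 0:
            out_t.append(k * dt)
            out_y.append(y.copy())
    return np.array(out_t), np.array(out_y)


class TestGrowthLaw:
    def test_no_polymerase_no_growth(self):
        """With no carried-over polymerase and no inducer the culture is inert."""
        cfg = medium_config("M9-glc", c0=0.0, noise_abs=0.0, noise_fluo=0.0)
        series = simulate_batch(cfg, [(0.0, 0.0)], 400.0)
        a = series.df["absorbance"].to_numpy()
        assert np.allclose(a, cfg.A0 + cfg.A_bg, atol=1e-9)

    def test_constitutive_strain_grows_at_mu_max(self, ref_config):
        """The wild-type (constitutive) strain reaches mu_max regardless of IPTG."""
        series = simulate_batch(ref_config, [(0.0, 0.0)], 1200.0, strain="W")
        fit = fit_growth_rate(
            series.well("A1"), policy="growing", background=ref_config.A_bg
        )
        assert fit.rate == pytest.approx(ref_config.mu_max, rel=1e-3)

    def test_mu_monotone_in_c(self, ref_config):
        c = np.linspace(0, 5, 200)
        mu = mu_of_c(c, ref_config)
        assert np.all(np.diff(mu) >= 0)
        assert mu[-1] <= ref_config.mu_max

    def test_induction_monotone_and_bounded(self, ref_config):
        levels = [0, 10, 20, 30, 40, 50, 100, 1000]
        u = [induction(l, ref_config) for l in levels]
        assert u[0] == 0.0
        assert np.all(np.diff(u) > 0)
        assert u[-1] < 1.0


class TestAgainstIndependentIntegrator:
    def test_growth_rate_matches_rk4_oracle(self, ref_config):
        """Fitted window rate agrees with a fixed-step RK4 integration to 3
        significant digits on the reference fully induced run."""
        t, y = rk4_oracle(ref_config, 1000.0, 400.0)
        B = y[:, 3]
        mask = (B > 0.05) & (B < 0.2)
        slope = np.polyfit(t[mask], np.log(B[mask]), 1)[0]
        series = simulate_batch(ref_config, [(0.0, 1000.0)], 400.0)
        fit = fit_growth_rate(
            series.well("A1"), policy="growing", background=ref_config.A_bg
        )
        assert fit.rate == pytest.approx(slope, rel=1e-3)

    def test_latent_states_match_rk4_oracle(self, ref_config):
        t, y = rk4_oracle(ref_config, 30.0, 600.0)
        states = integrate_states(ref_config, [(0.0, 30.0)], 600.0)
        sub = states[states.t.isin(t)].reset_index(drop=True)
        for col, idx in (("c", 0), ("m", 2), ("B", 3)):
            ours = sub[col].to_numpy()
            theirs = y[np.isin(t, sub.t.to_numpy()), idx]
            assert np.allclose(ours, theirs, rtol=2e-3, atol=1e-8)

    def test_steady_state_c_nondecreasing_in_iptg(self, ref_config):
        """End-of-run beta' level is non-decreasing across inducer levels."""
        finals = []
        for level in [0, 10, 20, 30, 40, 50, 100, 1000]:
            _, y = rk4_oracle(ref_config, float(level), 800.0, dt=0.05)
            finals.append(y[-1, 0])
        assert np.all(np.diff(finals) >= -1e-9)
        states_finals = [
            integrate_states(ref_config, [(0.0, float(l))], 800.0).c.iloc[-1]
            for l in [0, 30, 1000]
        ]
        assert np.all(np.diff(states_finals) > 0)


class TestDoseSeries:
    def test_extreme_levels(self, ref_config):
        series = simulate_dose_series(ref_config, [0.0, 1000.0], replicates=1)
        assert len(series.wells) == 2
        high = fit_growth_rate(
            series.subset(iptg_uM=1000.0).well("1000uM-r0"),
            policy="growing", background=ref_config.A_bg,
        )
        assert high.rate == pytest.approx(ref_config.mu_max, rel=0.02)
        low = series.subset(iptg_uM=0.0).well("0uM-r0")
        a = low["absorbance"].to_numpy() - ref_config.A_bg
        late = low["time_min"].to_numpy() >= 1000
        slope = np.polyfit(low["time_min"][late], np.log(a[late]), 1)[0]
        assert abs(slope) < 1e-4

    def test_default_grid_shape_and_metadata(self, noisy_config):
        series = simulate_dose_series(noisy_config, replicates=5)
        assert len(series.wells) == 40
        meta = series.df.groupby("well").first()
        assert sorted(meta["iptg_uM"].unique()) == [
            0, 10, 20, 30, 40, 50, 100, 1000
        ]

    def test_seed_reproducibility_byte_identical(self, noisy_config):
        a = simulate_dose_series(noisy_config, [0.0, 30.0], replicates=2)
        b = simulate_dose_series(noisy_config, [0.0, 30.0], replicates=2)
        pd.testing.assert_frame_equal(a.df, b.df)
        assert a.df.to_csv() == b.df.to_csv()

    def test_different_seeds_same_noise_free_core(self, ref_config):
        a = simulate_dose_series(ref_config, [30.0], replicates=1)
        b = simulate_dose_series(
            ref_config.replace(seed=7), [30.0], replicates=1
        )
        assert np.allclose(
            a.df["absorbance"], b.df["absorbance"], rtol=0, atol=0
        )


class TestConservationAndReporter:
    def test_carbon_accounting(self, prod_config):
        """Glucose consumed >= glycerol formed + biomass-attributed glucose."""
        for strain in ("W-gly", "R-gly"):
            s = simulate_production(prod_config, strain, 900.0, keep_states=True)
            st = s.states
            consumed = prod_config.glc0 - st["glc"].to_numpy()
            biomass_glc = (
                st["B"].to_numpy() - prod_config.A0
            ) / prod_config.Y_biomass_abs
            slack = consumed - st["gly"].to_numpy() - biomass_glc
            assert np.all(slack >= -1e-6)

    def test_glucose_monotone_glycerol_monotone(self, prod_config):
        s = simulate_production(prod_config, "R-gly", 900.0)
        assert np.all(np.diff(s.glucose) <= 1e-12)
        assert np.all(np.diff(s.glycerol) >= -1e-12)

    def test_branch_closed_no_glycerol(self, prod_config):
        cfg = prod_config.replace(f_branch=0.0)
        s = simulate_production(cfg, "R-gly", 600.0)
        assert np.allclose(s.glycerol, 0.0)

    def test_fast_maturation_total_reporter_is_mature(self, ref_config):
        """k_mat >= 1/min: immature pool is negligible at steady state."""
        cfg = ref_config.replace(k_mat=1.0)
        st = integrate_states(cfg, [(0.0, 1000.0)], 600.0)
        late = st[st.t > 300]
        total = late.i + late.m
        assert np.allclose(late.m, total, rtol=0.02)

    def test_unknown_strain_rejected(self, prod_config):
        with pytest.raises(ValueError, match="unknown production strain"):
            simulate_production(prod_config, "X-gly", 100.0)


class TestScheduleValidation:
    @pytest.mark.parametrize("schedule, msg", [
        ([], "empty"),
        ([(5.0, 10.0)], "start at t=0"),
        ([(0.0, 10.0), (0.0, 20.0)], "strictly increasing"),
        ([(0.0, -5.0)], "non-negative"),
    ])
    def test_bad_schedules(self, ref_config, schedule, msg):
        with pytest.raises(ValueError, match=msg):
            integrate_states(ref_config, schedule, 100.0)

    def test_bad_duration(self, ref_config):
        with pytest.raises(ValueError, match="duration"):
            integrate_states(ref_config, [(0.0, 0.0)], -5.0)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimConfig(hill_n=0.5)
        with pytest.raises(ValueError):
            SimConfig(f_branch=1.5)
        with pytest.raises(ValueError):
            SimConfig(mu_max=-0.01)
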