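"""Lineage segmentation, elongation rates, population curve, recovery."""

import numpy as np
import pytest

from conftest import ols_normal_equations
from growthswitch.lineage import (
    detect_arrest_and_recovery, fit_elongation_rate, population_growth_curve,
    segment_generations,
)
from growthswitch.simulate import simulate_lineage
from growthswitch.types import LengthTrack, PopulationGrowthCurve


def track_from(lengths, dt=10.0, cell_id="c0"):
    lengths = np.asarray(lengths, dtype=float)
    return LengthTrack(cell_id, np.arange(len(lengths)) * dt, lengths)


class TestSegmentation:
    def test_programmed_halvings(self):
        """Halvings at frames 10 and 20 give 3 segments split exactly there."""
        L = np.ones(30)
        L[:10] = 2.0 ** (np.arange(10) / 10)
        L[10:20] = L[9] / 2 * 2.0 ** (np.arange(10) / 10)
        L[20:] = L[19] / 2 * 2.0 ** (np.arange(10) / 10)
        segs = segment_generations(track_from(L))
        assert len(segs) == 3
        assert [s.frames[0] for s in segs] == [0, 10, 20]
        assert segs[0].censored and segs[-1].censored and not segs[1].censored

    def test_filamenting_track_single_censored_segment(self):
        L = 2.0 * np.exp(0.001 * np.arange(50) * 10.0)
        segs = segment_generations(track_from(L))
        assert len(segs) == 1
        assert segs[0].censored
        assert segs[0].division_time is None

    def test_counts_match_simulator_division_log(self, ref_config):
        """Noise-free tracks: detected divisions equal the ground-truth log
        for every cell (seed 7, 100 cells)."""
        cfg = ref_config.replace(seed=7)
        tracks, log = simulate_lineage(
            cfg, [(0.0, 1000.0)], n_cells=100, frame_interval=10.0,
            duration=600.0, div_noise_sd=0.0, length_noise_sd=0.0,
        )
        for tr in tracks:
            segs = segment_generations(tr)
            n_detected = sum(1 for s in segs if s.division_time is not None)
            # segments shorter than 3 frames are dropped, never misassigned
            truth = (log.cell_id == tr.cell_id).sum()
            short = len(tr.times) - sum(len(s.frames) for s in segs)
            assert n_detected <= truth <= n_detected + (1 if short else 0)
        total_detected = sum(
            1 for tr in tracks for s in segment_generations(tr)
            if s.division_time is not None
        )
        assert total_detected >= 0.95 * len(log)

    def test_robust_to_length_noise(self, ref_config):
        cfg = ref_config.replace(seed=9)
        clean, log = simulate_lineage(
            cfg, [(0.0, 1000.0)], n_cells=20, frame_interval=10.0,
            duration=600.0, div_noise_sd=0.0, length_noise_sd=0.0,
        )
        noisy, _ = simulate_lineage(
            cfg, [(0.0, 1000.0)], n_cells=20, frame_interval=10.0,
            duration=600.0, div_noise_sd=0.0, length_noise_sd=0.05,
        )
        n_clean = sum(len(segment_generations(t)) for t in clean)
        n_noisy = sum(len(segment_generations(t)) for t in noisy)
        assert abs(n_noisy - n_clean) <= 0.1 * n_clean


class TestElongationRate:
    def test_exact_exponential(self):
        t = np.arange(0, 300, 10.0)
        track = LengthTrack("c0", t, 2.0 * np.exp(0.011 * t))
        seg = segment_generations(track)[0]
        assert seg.rate == pytest.approx(0.011, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 200, 10.0)
        L = 1.5 * np.exp(0.01 * t) * np.exp(0.02 * rng.standard_normal(len(t)))
        track = LengthTrack("c0", t, L)
        seg = segment_generations(track)[0]
        slope, _ = ols_normal_equations(t, np.log(L))
        assert seg.rate == pytest.approx(slope, abs=1e-12)

    def test_flat_segment_rate_zero(self):
        rng = np.random.default_rng(6)
        t = np.arange(0, 300, 10.0)
        L = 5.0 * np.exp(0.005 * rng.standard_normal(len(t)))
        track = LengthTrack("c0", t, L)
        seg = segment_generations(track)[0]
        assert abs(seg.rate) < 5e-4

    def test_deterministic_sizer_interdivision_time(self, ref_config):
        """Constant mu, division at 2x birth length, no noise: the
        inter-division time is ln(2)/mu exactly."""
        cfg = ref_config.replace(seed=1)
        tracks, log = simulate_lineage(
            cfg, [(0.0, 1000.0)], n_cells=1, frame_interval=10.0,
            duration=500.0, div_noise_sd=0.0, length_noise_sd=0.0,
        )
        times = np.sort(log["division_time_min"].to_numpy())
        gaps = np.diff(times)
        mu_ss = 0.012 * (1 - 2.142857 ** -10)   # induced steady-state rate
        assert np.allclose(gaps, np.log(2) / mu_ss, rtol=2e-3)


class TestPopulationCurve:
    def make_pairs(self, rates, n_frames=12, dt=10.0):
        pairs = []
        for k, r in enumerate(rates):
            t = np.arange(n_frames) * dt
            L = 1.0 * np.exp(r * t)
            tr = LengthTrack(f"c{k}", t, L)
            seg = segment_generations(tr)[0]
            pairs.append((seg, tr))
        return pairs

    def test_homogeneous_rates(self):
        curve = population_growth_curve(self.make_pairs([0.01] * 5), 30.0)
        assert np.allclose(curve.mean_rates, 0.01)
        assert np.allclose(curve.sd_rates, 0.0)

    def test_equal_weight_average(self):
        curve = population_growth_curve(self.make_pairs([0.01, 0.02]), 30.0)
        assert np.allclose(curve.mean_rates, 0.015)

    def test_invariant_to_ordering_and_split(self):
        pairs = self.make_pairs([0.005, 0.01, 0.02, 0.03])
        c1 = population_growth_curve(pairs, 30.0)
        c2 = population_growth_curve(list(reversed(pairs)), 30.0)
        assert np.allclose(c1.mean_rates, c2.mean_rates)
        assert np.allclose(c1.bin_centers, c2.bin_centers)

    def test_matches_brute_force_recomputation(self, ref_config):
        cfg = ref_config.replace(seed=3)
        tracks, _ = simulate_lineage(
            cfg, [(0.0, 1000.0)], n_cells=10, frame_interval=10.0,
            duration=400.0,
        )
        pairs = [(s, t) for t in tracks for s in segment_generations(t)]
        curve = population_growth_curve(pairs, bin_width=30.0)
        # brute force: every (frame, rate) pair binned by hand
        frames = []
        for seg, tr in pairs:
            if np.isfinite(seg.rate):
                frames += [(tt, seg.rate) for tt in tr.times[seg.frames]]
        for center, mean in zip(curve.bin_centers, curve.mean_rates):
            lo, hi = center - 15.0, center + 15.0
            vals = [r for tt, r in frames if lo <= tt < hi]
            assert mean == pytest.approx(np.mean(vals), abs=1e-12)


class TestArrestRecovery:
    def test_constructed_step_curve(self):
        """Step curve: lags equal the constructed offsets exactly."""
        centers = np.arange(15.0, 900.0, 30.0)
        rates = np.where(centers < 300, 0.012,
                         np.where(centers < 600, 0.001, 0.012))
        curve = PopulationGrowthCurve(
            centers, rates, np.zeros_like(rates),
            np.full(len(centers), 10), 30.0,
        )
        out = detect_arrest_and_recovery(curve, 300.0, 600.0)
        assert out["lag_to_decline"] == pytest.approx(315.0 - 300.0)
        assert out["lag_to_recovery"] == pytest.approx(615.0 - 600.0)

    def test_linear_scan_oracle_on_seeded_simulations(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            centers = np.arange(15.0, 900.0, 30.0)
            t_rm = float(rng.choice(np.arange(150, 350, 30)))
            t_add = float(rng.choice(np.arange(450, 700, 30)))
            base = 0.012 + 1e-4 * rng.standard_normal(len(centers))
            rates = np.where(
                (centers > t_rm + 20) & (centers < t_add + 40), 0.0005, base
            )
            curve = PopulationGrowthCurve(
                centers, rates, np.zeros_like(rates),
                np.full(len(centers), 10), 30.0,
            )
            out = detect_arrest_and_recovery(curve, t_rm, t_add)
            ref = rates[centers < t_rm].mean()
            scan_dec = next(
                c for c, r in zip(centers, rates)
                if c > t_rm and r < 0.9 * ref
            )
            scan_rec = next(
                c for c, r in zip(centers, rates)
                if c > t_add and r > 0.9 * ref
            )
            assert out["lag_to_decline"] == pytest.approx(scan_dec - t_rm)
            assert out["lag_to_recovery"] == pytest.approx(scan_rec - t_add)

    def test_events_outside_range_rejected(self):
        centers = np.arange(15.0, 300.0, 30.0)
        curve = PopulationGrowthCurve(
            centers, np.full(len(centers), 0.01),
            np.zeros(len(centers)), np.full(len(centers), 5), 30.0,
        )
        with pytest.raises(ValueError, match="outside the curve range"):
            detect_arrest_and_recovery(curve, 10.0, 500.0)


class TestArrestPhenotype:
    def test_filamentation_and_division_recovery(self, ref_config):
        """Inducer removal blocks division (cells elongate); re-addition
        restores it — zero ground-truth divisions in the arrested window."""
        cfg = ref_config.replace(seed=5)
        schedule = [(0.0, 1000.0), (480.0, 0.0), (840.0, 1000.0)]
        tracks, log = simulate_lineage(
            cfg, schedule, n_cells=30, frame_interval=10.0, duration=1200.0,
            div_noise_sd=0.0, length_noise_sd=0.0,
        )
        times = log["division_time_min"].to_numpy()
        arrested = (times > 480.0 + 120.0) & (times < 840.0 + 20.0)
        assert arrested.sum() == 0
        assert (times < 480.0).sum() > 0
        assert (times > 840.0 + 20.0).sum() > 0
        # cells elongate while arrested
        for tr in tracks[:5]:
            mid = (tr.times > 560) & (tr.times < 840)
            assert tr.lengths[mid][-1] >= tr.lengths[mid][0] - 1e-9
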