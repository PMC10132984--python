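"""MSD diffusion fitting and diffusing-cohesin encounter classification."""

import numpy as np
import pytest

from loopbarrier import synth
from loopbarrier.diffusion import (blocked_fraction, classify_diffusion_encounter,
                                   compute_msd, fit_diffusion)
from loopbarrier.kymo import SpotTrack
from loopbarrier.polymer import TetherGeometry

GEO = TetherGeometry(total_bp=26_123, end_to_end_um=6.0)
BIG = TetherGeometry(total_bp=500_000, end_to_end_um=100.0)


class TestComputeMSD:
    def test_ballistic_limit(self):
        v = 100.0  # bp/frame
        x = v * np.arange(200)
        lags, msd = compute_msd(x, 1.0, max_lag=10)
        np.testing.assert_allclose(msd, (v / 1000 * lags) ** 2, rtol=1e-9)

    def test_constant_position_zero(self):
        lags, msd = compute_msd(np.full(100, 123.0), 1.0, max_lag=10)
        assert np.all(msd == 0)

    def test_random_walk_linear_r2(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(0, 100, 10_000))
        lags, msd = compute_msd(x, 1.0, max_lag=10)
        fit = fit_diffusion(lags, msd)
        assert fit.r_squared > 0.99

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            compute_msd(np.zeros(5), 1.0, max_lag=10)


class TestFitDiffusion:
    def test_exact_line(self):
        tau = np.arange(1, 11) * 1.0
        msd = 0.64 * tau + 0.01
        fit = fit_diffusion(tau, msd)
        assert fit.d_kb2_s == pytest.approx(0.64, abs=1e-9)
        assert fit.offset_kb2 == pytest.approx(0.01, abs=1e-9)

    def test_degenerate_flagged(self):
        fit = fit_diffusion(np.arange(1, 11.0), np.full(10, 0.5))
        assert fit.degenerate and fit.d_kb2_s == 0.0

    def test_recovery_at_study_conditions(self):
        """500 tracks at D = 0.32 kb^2/s, 3.12 s frames, 26.1 kb DNA:
        mean fitted D within 0.32 +/- 0.1."""
        rng = np.random.default_rng(5)
        ds = []
        for _ in range(500):
            pos, _ = synth.gen_diffusion_track(0.32, GEO, n_frames=100,
                                               frame_interval_s=3.12,
                                               seed=rng)
            lags, msd = compute_msd(pos, 3.12, max_lag=10)
            ds.append(fit_diffusion(lags, msd).d_kb2_s)
        assert np.mean(ds) == pytest.approx(0.32, abs=0.1)

    def test_unbiased_far_from_boundaries(self):
        """On a long DNA (negligible end reflections) the 10-lag fit is
        unbiased within 10% across the relevant D range."""
        for d_true in (0.05, 0.32, 1.0):
            rng = np.random.default_rng(int(d_true * 100))
            ds = []
            for _ in range(300):
                pos, _ = synth.gen_diffusion_track(
                    d_true, BIG, n_frames=100, frame_interval_s=3.12,
                    start_bp=250_000, seed=rng)
                lags, msd = compute_msd(pos, 3.12, max_lag=10)
                ds.append(fit_diffusion(lags, msd).d_kb2_s)
            assert abs(np.mean(ds) - d_true) < 0.10 * d_true

    def test_boundary_flattening_bias_is_moderate(self):
        """Reflecting ends depress the 10-lag fit at the 26.1 kb study
        geometry; the shortfall stays below 20% of D."""
        rng = np.random.default_rng(9)
        ds = []
        for _ in range(300):
            pos, _ = synth.gen_diffusion_track(0.32, GEO, n_frames=100,
                                               frame_interval_s=3.12,
                                               seed=rng)
            lags, msd = compute_msd(pos, 3.12, max_lag=10)
            ds.append(fit_diffusion(lags, msd).d_kb2_s)
        assert abs(np.mean(ds) - 0.32) < 0.20 * 0.32


class TestClassification:
    SITE = 10_452.0
    THR = 871.0  # two pixel-equivalents at this geometry

    def test_impermeable_barrier_blocked(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pos, _ = synth.gen_diffusion_track(
                0.32, GEO, barrier_bp=self.SITE, pass_prob=0.0,
                start_bp=self.SITE + 2500, n_frames=200, seed=rng)
            call = classify_diffusion_encounter(pos, self.SITE, self.THR,
                                                hysteresis_bp=200)
            assert call.call in ("blocked", "excluded")
            assert call.call != "excluded" or call.reason in (
                "never-encounters", "unresolved-encounter")

    def test_permeable_fast_walker_passes_multiple(self):
        rng = np.random.default_rng(1)
        multi = 0
        for _ in range(20):
            pos, _ = synth.gen_diffusion_track(
                1.0, GEO, barrier_bp=self.SITE, pass_prob=1.0,
                start_bp=self.SITE + 1500, n_frames=300, seed=rng)
            call = classify_diffusion_encounter(pos, self.SITE, self.THR,
                                                hysteresis_bp=200)
            multi += call.call == "passed-multiple"
        assert multi >= 15

    def test_colocalized_from_start_excluded(self):
        pos = np.full(50, self.SITE + 100.0)
        call = classify_diffusion_encounter(pos, self.SITE, self.THR)
        assert call.call == "excluded"
        assert call.reason == "colocalized-from-start"

    def test_bleaching_excluded(self):
        track = SpotTrack(frame=np.arange(10), time_s=np.arange(10.0),
                          position_bp=np.full(10, 20_000.0),
                          intensity=np.ones(10),
                          present=np.array([True] * 5 + [False] * 5))
        call = classify_diffusion_encounter(track, self.SITE, self.THR)
        assert call.call == "excluded" and call.reason == "bleaching"

    def test_classes_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(2)
        for i in range(200):
            pos, _ = synth.gen_diffusion_track(
                0.32, GEO, barrier_bp=self.SITE,
                pass_prob=rng.choice([0.0, 0.5, 1.0]),
                start_bp=rng.uniform(0, 26_123), n_frames=40, seed=rng)
            call = classify_diffusion_encounter(pos, self.SITE, self.THR,
                                                hysteresis_bp=200)
            assert call.call in ("blocked", "passed-once",
                                 "passed-multiple", "excluded")
            if call.call == "passed-once":
                assert call.n_traversals == 1
            if call.call == "passed-multiple":
                assert call.n_traversals >= 2


class TestBlockedFraction:
    def _call(self, cls, reason=""):
        from loopbarrier.diffusion import DiffusionEncounterCall
        return DiffusionEncounterCall(call=cls, n_traversals=0,
                                      reason=reason)

    def test_zero_blocked(self):
        calls = [self._call("passed-once") for _ in range(10)]
        frac, (lo, hi), n = blocked_fraction(calls)
        assert frac == 0 and lo == 0 and n == 10

    def test_all_blocked(self):
        calls = [self._call("blocked") for _ in range(10)]
        frac, (lo, hi), n = blocked_fraction(calls)
        assert frac == 1 and hi == 1.0

    def test_excluded_removed_from_denominator(self):
        calls = ([self._call("blocked")] * 3
                 + [self._call("passed-once")] * 7
                 + [self._call("excluded", "bleaching")] * 5)
        frac, _, n = blocked_fraction(calls)
        assert n == 10 and frac == pytest.approx(0.3)

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            blocked_fraction([self._call("excluded", "bleaching")])

    def test_low_blocking_generator_recovered(self):
        """A weakly blocking roadblock (15% of tracks) is recovered
        within the Wilson CI at n = 106."""
        from loopbarrier.encounters import wilson_ci

        rng = np.random.default_rng(3)
        calls = []
        for _ in range(106):
            blocked = rng.random() < 0.15
            start = self.SITE_START(rng)
            pos, _ = synth.gen_diffusion_track(
                0.32, GEO, barrier_bp=10_452,
                pass_prob=0.0 if blocked else 1.0, start_bp=start,
                loc_noise_bp=100.0, n_frames=40, seed=rng)
            calls.append(classify_diffusion_encounter(
                pos, 10_452, 871, hysteresis_bp=250))
        frac, _, n = blocked_fraction(calls)
        lo, hi = wilson_ci(round(0.15 * 106), 106)
        assert lo <= frac <= hi

    @staticmethod
    def SITE_START(rng):
        return float(np.clip(10_452 + rng.choice([-1, 1])
                             * rng.uniform(1200, 2500), 0, 26_123))
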