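"""Encounter detection/classification, Wilson CIs, blocking-curve fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm, spearmanr

from loopbarrier import synth
from loopbarrier.encounters import (bin_by_force, classify_encounter,
                                    compare_rates_around_event,
                                    detect_encounters,
                                    fit_blocking_curve,
                                    force_at_blocking_level,
                                    rates_paired_test, shrink_stats,
                                    switch_fraction_by_force, wilson_ci)
from loopbarrier.kymo import track_ctcf, track_loop
from loopbarrier.synth import Scenario

THRESHOLD_BP = 1600.0


def run_pipeline(outcome_probs, seed, **kwargs):
    sc = Scenario(outcome_probs=outcome_probs, seed=seed, **kwargs)
    kym, truth = synth.gen_kymograph(sc)
    loop = track_loop(kym, sc.geometry)
    ctcf = track_ctcf(kym, sc.geometry)
    events = detect_encounters(loop, ctcf, sc.geometry, THRESHOLD_BP)
    return sc, truth, loop, ctcf, events


class TestDetectEncounters:
    def test_never_colocalized_empty(self):
        sc, truth, loop, ctcf, events = run_pipeline({}, seed=0)
        # residual probability mass -> loop grows through; force a
        # no-encounter case by never nucleating
        sc2 = Scenario(nucleation_time_s=1e9, n_frames=30, seed=0)
        kym, _ = synth.gen_kymograph(sc2)
        loop2 = track_loop(kym, sc2.geometry)
        ctcf2 = track_ctcf(kym, sc2.geometry)
        assert detect_encounters(loop2, ctcf2, sc2.geometry,
                                 THRESHOLD_BP) == []

    def test_blocked_event_duration_and_force(self):
        sc, truth, loop, ctcf, events = run_pipeline({"blocked": 1.0},
                                                     seed=1)
        assert len(events) == 1
        e = events[0]
        assert e.censored  # still co-localized at the movie end
        # force at the scripted encounter sits in the best-covered window
        assert 0.04 <= e.force_pn <= 0.08
        # duration spans from encounter to the end of the movie
        expected = (sc.n_frames - 1 - truth.encounter_frame) \
            * sc.frame_interval_s
        assert e.duration_s == pytest.approx(expected, abs=4 * 0.4)

    def test_missing_ctcf_track_rejected(self):
        sc, truth, loop, ctcf, _ = run_pipeline({"blocked": 1.0}, seed=2)
        with pytest.raises(ValueError):
            detect_encounters(loop, None, sc.geometry, THRESHOLD_BP)


class TestClassifyEncounter:
    @pytest.mark.parametrize("programmed,expected", [
        ("blocked", "blocked"), ("passed", "passed"),
        ("switch", "switch"), ("shrink", "shrink-after-release")])
    def test_programmed_outcomes_recovered(self, programmed, expected):
        hits = 0
        for seed in range(20):
            sc, truth, loop, ctcf, events = run_pipeline(
                {programmed: 1.0}, seed=seed)
            if not events:
                continue
            e = max(events, key=lambda e: e.end_frame - e.start_frame)
            hits += classify_encounter(e, loop, ctcf) == expected
        assert hits >= 19

    def test_outcomes_partition_events(self):
        """Every detected event carries exactly one outcome from the
        declared classes; counts sum to the number of events."""
        from loopbarrier.encounters import OUTCOMES

        n_events = 0
        counts = {}
        for seed in range(30):
            sc, truth, loop, ctcf, events = run_pipeline(
                {"blocked": 0.25, "passed": 0.25, "switch": 0.25,
                 "shrink": 0.25}, seed=seed)
            for e in events:
                out = classify_encounter(e, loop, ctcf)
                assert out in OUTCOMES
                assert e.outcome == out
                counts[out] = counts.get(out, 0) + 1
                n_events += 1
        assert sum(counts.values()) == n_events


class TestWilsonCI:
    @staticmethod
    def score_inversion_oracle(k, n, level=0.95):
        """Brute-force inversion of the score test."""
        z = norm.ppf(0.5 + level / 2)
        phat = k / n

        def stat(p):
            return (phat - p) / np.sqrt(p * (1 - p) / n)

        lo = 0.0 if k == 0 else brentq(lambda p: stat(p) - z, 1e-12,
                                       1 - 1e-12)
        hi = 1.0 if k == n else brentq(lambda p: stat(p) + z, 1e-12,
                                       1 - 1e-12)
        return lo, hi

    @pytest.mark.parametrize("k,n", [(0, 10), (5, 10), (10, 10), (3, 7),
                                     (50, 119), (1, 1000)])
    def test_matches_score_inversion(self, k, n):
        lo, hi = wilson_ci(k, n)
        olo, ohi = self.score_inversion_oracle(k, n)
        assert lo == pytest.approx(olo, abs=1e-6)
        assert hi == pytest.approx(ohi, abs=1e-6)

    def test_bounds_and_coverage_of_point(self):
        for k, n in [(0, 10), (4, 9), (9, 9)]:
            lo, hi = wilson_ci(k, n)
            assert 0 <= lo <= k / n <= hi <= 1

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestBinByForce:
    EDGES = np.array([0, 0.015, 0.026, 0.05, 0.072, 0.096, 0.119, 0.142])

    def test_half_open_convention(self):
        bins = bin_by_force(np.array([0.015]), np.array([True]), self.EDGES)
        assert bins.loc[1, "n"] == 1  # falls in [0.015, 0.026)
        assert bins.loc[0, "n"] == 0

    def test_printed_bin_counts_match(self):
        centers = [0.0075, 0.0205, 0.038, 0.061, 0.1075, 0.1305]
        ns = [17, 75, 72, 89, 40, 3]
        df = synth.gen_encounter_table(147, 0.125, centers, ns, seed=0)
        bins = bin_by_force(df["force_pn"].to_numpy(),
                            df["blocked"].to_numpy(), self.EDGES)
        # the empty 0.072-0.096 gap bin aside, counts land as printed
        got = bins[bins["n"] > 0]["n"].tolist()
        assert got == ns

    def test_empty_input_zero_bins(self):
        bins = bin_by_force(np.array([]), np.array([], dtype=bool),
                            self.EDGES)
        assert (bins["n"] == 0).all()

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_by_force(np.array([0.1]), np.array([True]),
                         np.array([0.0, 0.2, 0.1]))

    def test_low_n_flagged(self):
        bins = bin_by_force(np.array([0.01, 0.01]), np.array([True, False]),
                            np.array([0.0, 0.02]), min_n=3)
        assert bins["low_n"].iloc[0]


class TestFitBlockingCurve:
    EDGES = np.array([0, 0.015, 0.026, 0.05, 0.072, 0.096, 0.119, 0.142])

    def _noiseless_bins(self, a, f0):
        centers = np.array([0.0075, 0.0205, 0.038, 0.061, 0.1075, 0.1305])
        frac = a * (1 - np.exp(-centers / f0)) / 100.0
        return pd.DataFrame({
            "lo": centers - 0.002, "hi": centers + 0.002, "center": centers,
            "n": np.full(6, 100), "k": (frac * 100).round(),
            "fraction": frac, "ci_lo": frac, "ci_hi": frac,
            "low_n": np.zeros(6, dtype=bool)})

    def test_noiseless_exact_recovery(self):
        bins = self._noiseless_bins(147.0, 0.125)
        fit = fit_blocking_curve(bins=bins, method="wls")
        assert fit.amplitude_pct == pytest.approx(147.0, abs=1e-6)
        assert fit.f0_pn == pytest.approx(0.125, abs=1e-8)

    def test_all_zero_blocking_flagged(self):
        centers = np.array([0.01, 0.03, 0.06, 0.1])
        bins = pd.DataFrame({
            "lo": centers, "hi": centers + 0.01, "center": centers,
            "n": np.full(4, 50), "k": np.zeros(4),
            "fraction": np.zeros(4), "ci_lo": 0.0, "ci_hi": 0.1,
            "low_n": np.zeros(4, dtype=bool)})
        fit = fit_blocking_curve(bins=bins, method="wls")
        assert not fit.ok
        assert np.isnan(fit.f0_pn)

    def test_mle_close_to_wls_on_good_data(self):
        centers = [0.0075, 0.0205, 0.038, 0.061, 0.1075, 0.1305]
        df = synth.gen_encounter_table(147, 0.125, centers,
                                       [200] * 6, seed=1)
        bins = bin_by_force(df["force_pn"].to_numpy(),
                            df["blocked"].to_numpy(), self.EDGES)
        wls = fit_blocking_curve(bins=bins, method="wls")
        mle = fit_blocking_curve(forces_pn=df["force_pn"].to_numpy(),
                                 blocked=df["blocked"].to_numpy(),
                                 method="mle")
        assert wls.f0_pn == pytest.approx(0.125, abs=0.03)
        assert mle.f0_pn == pytest.approx(wls.f0_pn, rel=0.35)

    def test_fixed_amplitude_sharpens_f0(self):
        centers = [0.0075, 0.0205, 0.038, 0.061, 0.1075, 0.1305]
        ns = [17, 75, 72, 89, 40, 3]
        df = synth.gen_encounter_table(147, 0.125, centers, ns, seed=2)
        bins = bin_by_force(df["force_pn"].to_numpy(),
                            df["blocked"].to_numpy(), self.EDGES)
        fit = fit_blocking_curve(bins=bins, method="wls",
                                 fixed_amplitude=147.0)
        assert fit.amplitude_pct == 147.0
        assert fit.f0_pn == pytest.approx(0.125, abs=0.04)

    def test_too_few_bins_rejected(self):
        bins = self._noiseless_bins(147.0, 0.125).iloc[:2]
        with pytest.raises(ValueError):
            fit_blocking_curve(bins=bins, method="wls")


class TestForceAtBlockingLevel:
    def test_printed_n_terminal_fit_reaches_100pct_at_0p14(self):
        assert force_at_blocking_level(147, 0.125, 100) == pytest.approx(
            0.1425, abs=5e-4)

    def test_amplitude_at_level_unreachable(self):
        with pytest.raises(ValueError):
            force_at_blocking_level(100, 0.125, 100)

    def test_closed_form(self):
        assert force_at_blocking_level(200, 0.1, 100) == pytest.approx(
            -0.1 * np.log(0.5), abs=1e-12)

    def test_inverts_fit_exactly(self):
        a, f0, level = 147.0, 0.125, 100.0
        f = force_at_blocking_level(a, f0, level)
        assert a * (1 - np.exp(-f / f0)) == pytest.approx(level, abs=1e-9)


class TestShrinkStats:
    def test_programmed_single_step_35pct(self):
        mags, modes = [], []
        for seed in range(10):
            sc, truth, loop, ctcf, events = run_pipeline(
                {"shrink": 1.0}, seed=seed,
                shrink_mode="single-step")
            for e in events:
                classify_encounter(e, loop, ctcf)
            stats = shrink_stats([(e, loop) for e in events])
            mags.extend(stats.magnitudes_pct)
            modes.extend(stats.modes)
        assert np.median(mags) == pytest.approx(35.0, abs=5.0)
        assert modes.count("single-step") >= 0.8 * len(modes)

    def test_programmed_gradual_rate(self):
        rates, modes = [], []
        for seed in range(10):
            sc, truth, loop, ctcf, events = run_pipeline(
                {"shrink": 1.0}, seed=seed, shrink_mode="gradual",
                shrink_rate_kb_s=0.8, n_frames=240)
            for e in events:
                classify_encounter(e, loop, ctcf)
            stats = shrink_stats([(e, loop) for e in events])
            modes.extend(stats.modes)
            rates.extend(r for r in stats.gradual_rates_kb_s
                         if np.isfinite(r))
        assert modes.count("gradual") >= 0.8 * len(modes)
        assert np.median(rates) == pytest.approx(-0.8, abs=0.15)

    def test_no_shrink_events(self):
        stats = shrink_stats([])
        assert stats.fraction_shrinking == 0
        assert len(stats.magnitudes_pct) == 0


class TestSwitchFractionByForce:
    def test_no_switches_all_zero(self):
        sc, truth, loop, ctcf, events = run_pipeline({"blocked": 1.0},
                                                     seed=3)
        for e in events:
            classify_encounter(e, loop, ctcf)
        table = switch_fraction_by_force(events,
                                         np.array([0.0, 0.05, 0.1]))
        assert (table["k"] == 0).all()

    def test_single_bin_arithmetic(self):
        from loopbarrier.encounters import EncounterEvent

        events = []
        for i in range(10):
            e = EncounterEvent(start_frame=0, end_frame=5, duration_s=2.0,
                               force_pn=0.05, loop_bp_at_encounter=5000)
            e.outcome = "switch" if i < 3 else "blocked"
            events.append(e)
        table = switch_fraction_by_force(events, np.array([0.0, 0.1]))
        assert table["fraction"].iloc[0] == pytest.approx(0.3)
        lo, hi = wilson_ci(3, 10)
        assert table["ci_lo"].iloc[0] == pytest.approx(lo)
        assert table["ci_hi"].iloc[0] == pytest.approx(hi)

    def test_programmed_force_trend_recovered(self):
        """Switch probability decreasing with force comes out as a
        negative rank correlation across force bins."""
        from loopbarrier.encounters import EncounterEvent

        rng = np.random.default_rng(0)
        events = []
        for _ in range(600):
            f = rng.uniform(0, 0.12)
            e = EncounterEvent(start_frame=0, end_frame=5, duration_s=2.0,
                               force_pn=f, loop_bp_at_encounter=5000)
            p_switch = 0.6 * np.exp(-f / 0.03)
            e.outcome = "switch" if rng.random() < p_switch else "blocked"
            events.append(e)
        table = switch_fraction_by_force(
            events, np.linspace(0, 0.12, 7))
        rho, _ = spearmanr(table["center"], table["fraction"])
        assert rho < 0


class TestCompareRates:
    def _passing_track(self, seed, **kwargs):
        sc, truth, loop, ctcf, events = run_pipeline({"passed": 1.0},
                                                     seed=seed, **kwargs)
        for e in events:
            classify_encounter(e, loop, ctcf)
        return loop, events

    def test_identical_rates_nonsignificant(self):
        """Extrusion that continues at the programmed rate through the
        encounter shows no before/after difference (pause-free pass)."""
        pairs = []
        for seed in range(50):
            # nucleate far from the site so the pre-encounter window sits
            # in steady-state growth rather than just after nucleation
            loop, events = self._passing_track(
                seed, pass_pause_s=0.0, nucleation_bp=18_000, n_frames=220)
            for e in events:
                try:
                    before, after, diff = compare_rates_around_event(
                        e, loop, window=8)
                except ValueError:
                    continue
                pairs.append((before, after))
        assert len(pairs) >= 30
        diffs = [a - b for b, a in pairs]
        assert abs(np.median(diffs)) < 0.25
        _, p = rates_paired_test(pairs)
        assert p > 0.05

    def test_halved_rate_detected(self):
        """A 50% post-encounter slowdown is detected at n = 50 pairs."""
        rng = np.random.default_rng(1)
        pairs = [(1.0 + rng.normal(0, 0.1), 0.5 + rng.normal(0, 0.1))
                 for _ in range(50)]
        _, p = rates_paired_test(pairs)
        assert p < 0.05

    def test_insufficient_frames_raises(self):
        loop, events = self._passing_track(0)
        from loopbarrier.encounters import EncounterEvent

        e = EncounterEvent(start_frame=2, end_frame=len(loop.frame) - 2,
                           duration_s=1.0, force_pn=0.05,
                           loop_bp_at_encounter=5000)
        with pytest.raises(ValueError):
            compare_rates_around_event(e, loop, window=10)
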