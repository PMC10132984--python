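"""Canned reproduction studies at the assay's published conditions.

Each function regenerates synthetic data under the conditions the
experiments report (sample sizes, frame intervals, printed fit
parameters as generator truth), runs the corresponding analysis, and
returns the recovered quantity.  They are the single source for both
the acceptance script and the acceptance-style tests.
"""

from __future__ import annotations

import numpy as np

from . import diffusion, encounters, kinetics, kymo, polymer, stepping, synth

# Fig. 2g printed force bins (pN) and per-bin event counts, N-terminal
FORCE_BIN_EDGES = np.array([0.0, 0.015, 0.026, 0.05, 0.072, 0.096,
                            0.119, 0.142])
NT_BIN_CENTERS = [0.0075, 0.0205, 0.038, 0.061, 0.1075, 0.1305]
NT_BIN_NS = [17, 75, 72, 89, 40, 3]
NT_AMPLITUDE = 147.0       # percent
NT_F0 = 0.125              # pN
NT_BLOCK_FRACTION = 0.45   # best-covered 0.04-0.08 pN window
DIFFUSION_BLOCK_FRACTION = 0.64
RESIDENCE_FRAME_MIN = 10.15 / 60.0   # 10.15 s frames, in minutes


def offset_tension_31p8kb_4um() -> float:
    """WLC tension (pN) of a loop-free 31.8 kb DNA at 4 µm end-to-end."""
    geo = polymer.TetherGeometry(total_bp=31_800, end_to_end_um=4.0)
    return polymer.offset_tension(geo)


def force_at_full_blocking() -> float:
    """Force (pN) where the printed N-terminal fit reaches 100%."""
    return encounters.force_at_blocking_level(NT_AMPLITUDE, NT_F0, 100.0)


def f0_recovery(seed: int, n_seeds: int = 100,
                fixed_amplitude: float | None = None) -> np.ndarray:
    """Recovered F0 per seed from Bernoulli draws at the printed bins."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_seeds):
        df = synth.gen_encounter_table(NT_AMPLITUDE, NT_F0, NT_BIN_CENTERS,
                                       NT_BIN_NS,
                                       seed=int(rng.integers(2**31)))
        bins = encounters.bin_by_force(df["force_pn"].to_numpy(),
                                       df["blocked"].to_numpy(),
                                       FORCE_BIN_EDGES)
        fit = encounters.fit_blocking_curve(
            bins=bins, method="wls", fixed_amplitude=fixed_amplitude)
        out.append(fit.f0_pn)
    return np.asarray(out)


def diffusion_d_recovery(seed: int, n_tracks: int = 500,
                         d_true: float = 0.32) -> float:
    """Mean MSD-fitted D over tracks at 3.12 s frames on 26.1 kb DNA."""
    geo = polymer.TetherGeometry(total_bp=26_123, end_to_end_um=6.0)
    rng = np.random.default_rng(seed)
    ds = []
    for _ in range(n_tracks):
        pos, _ = synth.gen_diffusion_track(d_true, geo, n_frames=100,
                                           frame_interval_s=3.12, seed=rng)
        lags, msd = diffusion.compute_msd(pos, 3.12, max_lag=10)
        ds.append(diffusion.fit_diffusion(lags, msd).d_kb2_s)
    return float(np.mean(ds))


def step_size_recovery(seed: int, n_traces: int = 100) -> float:
    """Pooled median detected step (nm) from 50 Hz staircase traces.

    The generating step distribution has median 40 nm (the reported
    average cohesin step) with 2 nm Gaussian trace noise.
    """
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_traces):
        trace, _ = synth.gen_step_trace(
            step_size_nm=lambda r, n: np.clip(r.normal(40, 10, n), 12,
                                              None),
            dwell_rate_hz=1.0, n_steps=8, noise_sd_nm=2.0,
            sampling_rate_hz=50.0, seed=rng)
        pooled.extend(np.abs(stepping.detect_steps(trace).step_sizes_nm))
    return float(np.median(pooled))


def residence_time_recovery(seed: int, n_seeds: int = 100) -> np.ndarray:
    """Slow half-life (min) per seed from the fixed-fraction mixture.

    140 dwells per dataset from the 69%/31% mixture with half-lives
    1.2/29.2 min, left-truncated at one 10.15 s frame; fit with the fast
    weight fixed at 97/140.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_seeds):
        dw = synth.gen_dwell_times([0.69, 0.31], half_lives=[1.2, 29.2],
                                   n=140, frame_interval=RESIDENCE_FRAME_MIN,
                                   seed=int(rng.integers(2**31)))
        fit = kinetics.fit_exp_mixture(dw, n_components=2,
                                       fixed_weights=[97 / 140, 43 / 140])
        out.append(fit.half_lives[1])
    return np.asarray(out)


def bleach_half_life_recovery(seed: int, n_seeds: int = 100) -> np.ndarray:
    """On-glass half-life (min) per seed, 142 dwells, truth 77.3 min."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_seeds):
        dw = synth.gen_dwell_times([1.0], half_lives=[77.3], n=142,
                                   frame_interval=RESIDENCE_FRAME_MIN,
                                   seed=int(rng.integers(2**31)))
        fit = kinetics.fit_exp_mixture(dw, n_components=1)
        out.append(fit.half_lives[0])
    return np.asarray(out)


def pipeline_blocked_fraction(seed: int, n_molecules: int = 119,
                              p_block: float = NT_BLOCK_FRACTION,
                              colocal_threshold_bp: float = 1600.0
                              ) -> tuple[float, int]:
    """Full kymograph pipeline recovery of the loop-blocking fraction.

    Generates one encounter kymograph per molecule with the given
    per-encounter block probability (the remainder pass), then runs
    tracking, encounter detection and classification blind to the truth.
    Returns (blocked fraction among classified events, n classified).
    """
    rng = np.random.default_rng(seed)
    calls = []
    for _ in range(n_molecules):
        sc = synth.Scenario(
            outcome_probs={"blocked": p_block, "passed": 1.0 - p_block},
            seed=int(rng.integers(2**31)))
        km, _ = synth.gen_kymograph(sc)
        loop = kymo.track_loop(km, sc.geometry)
        ctcf = kymo.track_ctcf(km, sc.geometry)
        events = encounters.detect_encounters(loop, ctcf, sc.geometry,
                                              colocal_threshold_bp)
        if not events:
            continue
        ev = max(events, key=lambda e: e.end_frame - e.start_frame)
        calls.append(encounters.classify_encounter(ev, loop, ctcf))
    usable = [c for c in calls if c in ("blocked", "passed", "switch",
                                        "shrink-after-release")]
    k = sum(c == "blocked" for c in usable)
    return k / len(usable), len(usable)


def diffusion_blocked_fraction(seed: int, n_tracks: int = 264,
                               p_block: float = DIFFUSION_BLOCK_FRACTION
                               ) -> tuple[float, int]:
    """Diffusion-classifier recovery of the cohesin-blocking fraction.

    264 tracks on the 26,123 bp DNA (site at 10,452 bp), 40 frames at
    4 s, 100 bp localization noise; each track's barrier is impermeable
    with probability ``p_block`` and fully permeable otherwise.  Tracks
    launch 1.2-2.5 kb from the site on either side, emulating the
    curation to molecules whose cohesin actually meets CTCF within the
    movie.  The classifier sees positions only.  Returns (blocked
    fraction among usable calls, n usable).
    """
    geo = polymer.TetherGeometry(total_bp=26_123, end_to_end_um=6.0)
    site = 10_452.0
    thr = 2 * 0.1 * 26_123 / 6.0   # two pixel-equivalents in bp
    rng = np.random.default_rng(seed)
    calls = []
    for _ in range(n_tracks):
        blocked = rng.random() < p_block
        start = float(np.clip(site + rng.choice([-1, 1])
                              * rng.uniform(1200, 2500), 0, 26_123))
        pos, _ = synth.gen_diffusion_track(
            0.32, geo, barrier_bp=site,
            pass_prob=0.0 if blocked else 1.0, n_frames=40,
            frame_interval_s=4.0, start_bp=start, loc_noise_bp=100.0,
            seed=rng)
        calls.append(diffusion.classify_diffusion_encounter(
            pos, site, thr, hysteresis_bp=250.0))
    frac, _, n = diffusion.blocked_fraction(calls)
    return frac, n
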