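"""Synthetic single-molecule data with ground truth.

Every input the analysis consumes can be generated here under the assay
conditions of the experiments being modelled: a 31.8 kb doubly tethered
DNA with a single CTCF site at 9.7 kb imaged at 0.4 s intervals for the
loop-extrusion assay; a 26,123 bp DNA with the site at 10,452 bp for the
diffusion / residence-time assays (3.12–10.15 s intervals); 50 Hz
magnetic-tweezer traces with ~2 nm noise.  All generators are
deterministic given their seed and return ground-truth labels alongside
the observable.

The kymograph model renders the DNA channel as a uniform inter-tether
profile carrying the unlooped DNA plus a diffraction-limited Gaussian
spot carrying the looped fraction (photon conservation by construction),
and the CTCF channel as a Gaussian spot at the site.  Loop dynamics
follow a scripted program: nucleation, one-sided growth toward the CTCF
site, then a programmed encounter outcome (blocked / passed / switch /
shrink).  Spatial positions account for the loop shortening the
available contour: a genomic coordinate g maps to the unlooped-contour
coordinate u(g) (loop collapsed to a point) stretched over the fixed
tether span R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import DwellSet
from .kymo import Kymograph
from .polymer import TetherGeometry
from .stepping import StepTrace

LN2 = float(np.log(2.0))

OUTCOMES = ("blocked", "passed", "switch", "shrink")


@dataclass(frozen=True)
class NoiseModel:
    """Camera model: Poisson shot noise plus Gaussian read noise."""

    read_sd: float = 2.0
    shot: bool = True
    background: float = 5.0


@dataclass(frozen=True)
class Scenario:
    """One scripted loop-extrusion kymograph experiment.

    Defaults reproduce the loop assay: 31.8 kb DNA, CTCF site at 9.7 kb
    with the N terminus facing the longer end, 0.4 s frames, 0.1 µm
    pixels, 0.13 µm PSF sigma.  The tether span default of 3.2 µm puts
    the DNA tension at the scripted encounter (~5.3 kb loop) near
    0.06 pN, inside the best-covered force window of the assay.
    """

    geometry: TetherGeometry = field(
        default_factory=lambda: TetherGeometry(total_bp=31_800,
                                               end_to_end_um=3.2))
    ctcf_site_bp: float = 9_700.0
    ctcf_orientation: str = "N-toward-long-end"  # or "reversed"
    frame_interval_s: float = 0.4
    pixel_size_um: float = 0.1
    psf_sigma_um: float = 0.13
    n_frames: int = 200
    noise: NoiseModel = field(default_factory=NoiseModel)
    extrusion_rate_kb_s: float = 1.0
    nucleation_time_s: float = 4.0
    nucleation_bp: float = 15_000.0
    outcome_probs: dict = field(
        default_factory=lambda: {"passed": 1.0})
    pass_pause_s: float = 1.2
    colocal_dwell_s: float = 10.0     # stall dwell for shrink outcomes
    shrink_fraction: float = 0.35
    shrink_mode: str = "single-step"  # or "gradual"
    shrink_rate_kb_s: float = 1.0
    dna_photons: float = 20_000.0
    ctcf_photons: float = 600.0
    ctcf_bleach_frame: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ctcf_site_bp < self.geometry.total_bp:
            raise ValueError("ctcf_site_bp must lie inside the DNA")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        p = np.array(list(self.outcome_probs.values()), dtype=float)
        if np.any(p < 0) or p.sum() > 1 + 1e-9:
            raise ValueError("outcome probabilities must be in [0,1] and "
                             "sum to <= 1")
        for k in self.outcome_probs:
            if k not in OUTCOMES:
                raise ValueError(f"unknown outcome {k!r}")
        if self.ctcf_orientation not in ("N-toward-long-end", "reversed"):
            raise ValueError("unknown ctcf_orientation")


@dataclass
class GroundTruth:
    """Per-frame true state plus event labels for one synthetic kymograph."""

    per_frame: pd.DataFrame   # frame, time_s, loop_a_bp, loop_b_bp,
    #                           loop_size_bp, spot_um, ctcf_um
    outcome: str | None
    encounter_frame: int | None
    release_frame: int | None
    ctcf_site_bp: float


def _loop_timeline(sc: Scenario, rng: np.random.Generator):
    """Scripted loop boundaries a(t) <= b(t) in bp, plus event labels."""
    n = sc.n_frames
    dt = sc.frame_interval_s
    rate_bp = sc.extrusion_rate_kb_s * 1000.0
    g_c = sc.ctcf_site_bp
    p0 = sc.nucleation_bp
    if p0 <= g_c:
        raise ValueError("nucleation must start on the far side of the "
                         "CTCF site (nucleation_bp > ctcf_site_bp)")
    a = np.full(n, np.nan)
    b = np.full(n, np.nan)
    t_nuc = int(round(sc.nucleation_time_s / dt))
    # draw the programmed outcome; residual probability mass means the
    # loop simply keeps growing through the site without interacting
    names = list(sc.outcome_probs) + ["growing-through"]
    probs = list(sc.outcome_probs.values())
    probs.append(max(0.0, 1.0 - sum(probs)))
    outcome = str(rng.choice(names, p=np.array(probs) / sum(probs)))

    # cap loop size so the unlooped contour stays comfortably above R
    rise = sc.geometry.params.rise_per_bp_nm
    s_max = sc.geometry.total_bp - 1.15 * sc.geometry.end_to_end_um * 1000 / rise

    enc_frame = None
    rel_frame = None
    cur_a, cur_b = p0, p0
    state = "approach"
    hold_until = -1
    for t in range(n):
        if t < t_nuc:
            continue
        if state == "approach":
            cur_a = max(cur_a - rate_bp * dt, g_c)
            if cur_a <= g_c:
                enc_frame = t
                if outcome == "growing-through":
                    state = "grow-through"
                elif outcome == "passed":
                    state = "hold"
                    hold_until = t + int(round(sc.pass_pause_s / dt))
                    next_state = "pass-grow"
                elif outcome == "switch":
                    state = "hold"
                    hold_until = t + 2
                    next_state = "switch-grow"
                elif outcome == "shrink":
                    state = "hold"
                    hold_until = t + int(round(sc.colocal_dwell_s / dt))
                    next_state = "shrinking"
                else:  # blocked: stalled at the site for the rest
                    state = "blocked"
        elif state == "hold":
            if t >= hold_until:
                state = next_state
                if state == "shrinking":
                    rel_frame = t
                    size_before = cur_b - cur_a
                    shrink_target = cur_a + sc.shrink_fraction * size_before
                    if sc.shrink_mode == "single-step":
                        cur_a = shrink_target
                        state = "static"
                    # gradual handled below
        if state == "pass-grow":
            if cur_b - cur_a < s_max:
                cur_a = max(cur_a - rate_bp * dt, 200.0)
        elif state == "switch-grow":
            if cur_b - cur_a < s_max:
                cur_b = min(cur_b + rate_bp * dt,
                            sc.geometry.total_bp - 200.0)
        elif state == "grow-through":
            cur_a = max(cur_a - rate_bp * dt, 200.0)
        elif state == "shrinking":
            cur_a = min(cur_a + sc.shrink_rate_kb_s * 1000 * dt,
                        shrink_target)
            if cur_a >= shrink_target:
                state = "static"
        a[t], b[t] = cur_a, cur_b
    if outcome == "growing-through":
        outcome_label = None
    else:
        outcome_label = outcome if enc_frame is not None else None
    return a, b, outcome_label, enc_frame, rel_frame


def _spatial_um(g_bp: np.ndarray | float, a: float, b: float,
                sc: Scenario) -> np.ndarray | float:
    """Map genomic bp to µm along the tether with loop [a, b] collapsed."""
    total = sc.geometry.total_bp
    s = (b - a) if np.isfinite(a) else 0.0
    u = np.where(np.asarray(g_bp) < a, g_bp,
                 np.where(np.asarray(g_bp) > b, np.asarray(g_bp) - s, a)) \
        if np.isfinite(a) else np.asarray(g_bp, dtype=float)
    return u * sc.geometry.end_to_end_um / (total - s)


def gen_kymograph(scenario: Scenario) -> tuple[Kymograph, GroundTruth]:
    """Render a two-channel kymograph from a scripted Scenario.

    The DNA channel conserves total integrated intensity per frame up to
    the declared noise; the loop appears as a Gaussian intensity excess
    whose integral is dna_photons * loop_size / total_bp.  Raises a
    configuration error when the pixel grid is too coarse to resolve the
    tether span (fewer than 3 pixels).
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n_span = int(round(sc.geometry.end_to_end_um / sc.pixel_size_um))
    if n_span < 3:
        raise ValueError("pixel grid too coarse: tether spans < 3 pixels")
    margin = 6
    n_px = n_span + 2 * margin + 1
    lo, hi = margin, margin + n_span
    a, b, outcome, enc_frame, rel_frame = _loop_timeline(sc, rng)

    px = np.arange(n_px)
    sigma_px = sc.psf_sigma_um / sc.pixel_size_um
    dna = np.zeros((n_px, sc.n_frames))
    ctcf = np.zeros((n_px, sc.n_frames))
    spot_um = np.full(sc.n_frames, np.nan)
    ctcf_um = np.zeros(sc.n_frames)
    loop_size = np.zeros(sc.n_frames)
    total = sc.geometry.total_bp
    for t in range(sc.n_frames):
        s = (b[t] - a[t]) if np.isfinite(a[t]) else 0.0
        loop_size[t] = s
        base = sc.dna_photons * (1.0 - s / total) / n_span
        col = np.zeros(n_px)
        col[lo:hi] += base
        if s > 0:
            x_um = _spatial_um(a[t], a[t], b[t], sc)
            spot_um[t] = float(x_um)
            c = lo + x_um / sc.pixel_size_um
            g = np.exp(-0.5 * ((px - c) / sigma_px) ** 2)
            col += sc.dna_photons * (s / total) * g / g.sum()
        dna[:, t] = col
        x_ctcf = float(_spatial_um(sc.ctcf_site_bp, a[t], b[t], sc)
                       if np.isfinite(a[t])
                       else _spatial_um(sc.ctcf_site_bp, np.nan, np.nan, sc))
        ctcf_um[t] = x_ctcf
        if sc.ctcf_bleach_frame is None or t < sc.ctcf_bleach_frame:
            c = lo + x_ctcf / sc.pixel_size_um
            g = np.exp(-0.5 * ((px - c) / sigma_px) ** 2)
            ctcf[:, t] = sc.ctcf_photons * g / g.sum()

    for img in (dna, ctcf):
        img += sc.noise.background
        if sc.noise.shot:
            img[:] = rng.poisson(np.clip(img, 0, None)).astype(float)
        if sc.noise.read_sd > 0:
            img += rng.normal(0.0, sc.noise.read_sd, size=img.shape)

    frames = np.arange(sc.n_frames)
    truth = GroundTruth(
        per_frame=pd.DataFrame({
            "frame": frames, "time_s": frames * sc.frame_interval_s,
            "loop_a_bp": a, "loop_b_bp": b, "loop_size_bp": loop_size,
            "spot_um": spot_um, "ctcf_um": ctcf_um}),
        outcome=outcome, encounter_frame=enc_frame,
        release_frame=rel_frame, ctcf_site_bp=sc.ctcf_site_bp)
    kym = Kymograph(channels={"dna": dna, "ctcf": ctcf},
                    pixel_size_um=sc.pixel_size_um,
                    frame_interval_s=sc.frame_interval_s,
                    tether_px=(float(lo), float(hi)))
    return kym, truth


def gen_diffusion_track(d_kb2_s: float, geometry: TetherGeometry,
                        barrier_bp: float | None = None,
                        pass_prob: float = 1.0,
                        n_frames: int = 40,
                        frame_interval_s: float = 4.0,
                        start_bp: float | None = None,
                        loc_noise_bp: float = 0.0,
                        seed: int | np.random.Generator = 0
                        ) -> tuple[np.ndarray, dict]:
    """1-D diffusion on the tethered DNA with a partially permeable barrier.

    Positions (bp) follow a Gaussian random walk with per-frame variance
    D * dt (D in kb²/s, matching the MSD(τ)=Dτ convention of the
    analysis), reflecting at the DNA ends.  Each attempted barrier
    crossing succeeds with ``pass_prob``; failures reflect off the
    barrier.  ``loc_noise_bp`` adds i.i.d. Gaussian localization error
    to the reported positions (the true walk is unaffected).  Returns
    (positions_bp, truth) where truth records the number of crossing
    attempts and successes.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if d_kb2_s < 0:
        raise ValueError("D must be >= 0")
    total = geometry.total_bp
    step_sd = np.sqrt(d_kb2_s * frame_interval_s) * 1000.0
    if step_sd > total:
        raise ValueError("per-frame step distribution wider than the DNA")
    if barrier_bp is not None and not 0 < barrier_bp < total:
        raise ValueError("barrier must lie inside the DNA")
    pos = (float(start_bp) if start_bp is not None
           else float(rng.uniform(0, total)))
    out = np.empty(n_frames)
    out[0] = pos
    attempts = successes = 0
    for t in range(1, n_frames):
        prop = pos + rng.normal(0.0, step_sd) if step_sd > 0 else pos
        if barrier_bp is not None and pass_prob < 1.0 and \
                (pos - barrier_bp) * (prop - barrier_bp) < 0:
            attempts += 1
            if rng.random() < pass_prob:
                successes += 1
            else:
                prop = 2 * barrier_bp - prop  # reflect off the barrier
        # reflect at DNA ends (repeat in case of double reflection)
        for _ in range(10):
            if prop < 0:
                prop = -prop
            elif prop > total:
                prop = 2 * total - prop
            else:
                break
        pos = prop
        out[t] = pos
    observed = (out + rng.normal(0.0, loc_noise_bp, size=n_frames)
                if loc_noise_bp > 0 else out)
    return observed, {"crossing_attempts": attempts,
                      "crossings": successes, "start_bp": out[0],
                      "true_positions_bp": out}


def gen_dwell_times(weights, half_lives=None, rates=None, n: int = 100,
                    frame_interval: float = 0.0,
                    bleach_half_life: float | None = None,
                    observation_limit: float | None = None,
                    seed: int | np.random.Generator = 0) -> DwellSet:
    """Sample dwell times from an exponential mixture with optional
    photobleaching and right censoring.

    Give the components either as half-lives (ln2/k) or rates k (one of
    the two).  If ``bleach_half_life`` is set, each observed dwell is the
    minimum of the true dwell and an exponential bleaching draw.  Draws
    shorter than ``frame_interval`` are rejected (unobservable), so the
    returned set is left-truncated exactly as the fit assumes.  Dwells
    exceeding ``observation_limit`` are censored there.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if n <= 0:
        raise ValueError("n must be > 0")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    if (half_lives is None) == (rates is None):
        raise ValueError("give exactly one of half_lives or rates")
    k = (LN2 / np.asarray(half_lives, dtype=float) if rates is None
         else np.asarray(rates, dtype=float))
    if np.any(k <= 0):
        raise ValueError("rates must be > 0")
    kb = None if bleach_half_life is None else LN2 / bleach_half_life
    durations = np.empty(n)
    censored = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        comp = rng.choice(len(k), p=w)
        t = rng.exponential(1.0 / k[comp])
        if kb is not None:
            t = min(t, rng.exponential(1.0 / kb))
        if t < frame_interval:
            continue  # unobservable: shorter than one frame
        if observation_limit is not None and t >= observation_limit:
            durations[i] = observation_limit
            censored[i] = True
        else:
            durations[i] = t
        i += 1
    return DwellSet(durations=durations, censored=censored,
                    frame_interval=frame_interval)


def gen_step_trace(step_size_nm=40.0, dwell_rate_hz: float = 1.0,
                   n_steps: int = 10, noise_sd_nm: float = 2.0,
                   sampling_rate_hz: float = 50.0, force_pn: float = 0.4,
                   direction: int = -1,
                   seed: int | np.random.Generator = 0
                   ) -> tuple[StepTrace, dict]:
    """Magnetic-tweezer staircase: exponential dwells, noisy plateaus.

    ``step_size_nm`` may be a scalar, an array to resample from, or a
    callable ``f(rng, n) -> sizes``.  Loop extrusion shortens the tether,
    so the default direction is downward.  Returns the trace plus ground
    truth (true step times and signed sizes).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if noise_sd_nm < 0 or sampling_rate_hz <= 0 or dwell_rate_hz <= 0:
        raise ValueError("noise_sd_nm >= 0 and rates > 0 required")
    dwells = rng.exponential(1.0 / dwell_rate_hz, size=n_steps + 1)
    dwells = np.clip(dwells, 4.0 / sampling_rate_hz, None)
    times = np.cumsum(dwells)[:-1]
    if callable(step_size_nm):
        sizes = np.asarray(step_size_nm(rng, n_steps), dtype=float)
    elif np.ndim(step_size_nm) > 0:
        sizes = rng.choice(np.asarray(step_size_nm, dtype=float),
                           size=n_steps)
    else:
        sizes = np.full(n_steps, float(step_size_nm))
    sizes = direction * np.abs(sizes)
    duration = float(np.sum(dwells))
    n_samples = int(np.ceil(duration * sampling_rate_hz)) + 1
    t = np.arange(n_samples) / sampling_rate_hz
    y = np.zeros(n_samples)
    for st, sz in zip(times, sizes):
        y[t >= st] += sz
    if noise_sd_nm > 0:
        y = y + rng.normal(0.0, noise_sd_nm, size=n_samples)
    trace = StepTrace(extension_nm=y, sampling_rate_hz=sampling_rate_hz,
                      force_pn=force_pn)
    return trace, {"step_times_s": times, "step_sizes_nm": sizes}


def gen_encounter_table(amplitude_pct: float, f0_pn: float,
                        bin_centers_pn, n_per_bin,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Bernoulli blocked/passed outcomes from a saturating-exponential model.

    Per-event blocking probability is A(1 - exp(-F/F0))/100 clipped to
    [0, 1], evaluated at each bin-centre force, with the given number of
    events per bin.  Returns rows of (force_pn, blocked).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if amplitude_pct < 0 or f0_pn <= 0:
        raise ValueError("require A >= 0 and F0 > 0")
    centers = np.asarray(bin_centers_pn, dtype=float)
    ns = np.asarray(n_per_bin, dtype=int)
    if len(centers) != len(ns) or len(centers) == 0 or np.any(ns <= 0):
        raise ValueError("bin centres and per-bin n must be non-empty and "
                         "positive")
    rows = []
    for f, m in zip(centers, ns):
        p = np.clip(amplitude_pct * (1 - np.exp(-f / f0_pn)) / 100, 0, 1)
        blocked = rng.random(m) < p
        rows.append(pd.DataFrame({"force_pn": np.full(m, f),
                                  "blocked": blocked}))
    return pd.concat(rows, ignore_index=True)
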