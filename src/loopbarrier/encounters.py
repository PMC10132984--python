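"""Loop–CTCF encounter detection, outcome classification, blocking curves.

An encounter opens when the tracked loop spot co-localizes with the CTCF
spot (within a threshold in bp) and closes once they separate for two
consecutive frames.  The DNA tension at the opening frame follows from
the loop size via the worm-like chain (the DNA outside the loop carries
the tension).  Outcomes:

* ``blocked`` — loop growth stalls while co-localized;
* ``passed`` — loop keeps growing and CTCF stays with the loop spot,
  which continues along its pre-encounter direction (CTCF inside loop);
* ``switch`` — loop keeps growing while the joint loop+CTCF position
  migrates back against the approach direction (extrusion re-started on
  the side facing away from CTCF);
* ``shrink-after-release`` — the loop loses DNA after co-localization
  ends;
* ``growing-through`` / ``indeterminate`` — grazing contact or
  unresolvable tracks.

Blocking probability versus force is summarized in force bins with
Wilson binomial confidence intervals and fitted with the saturating
exponential P(F) = A (1 - exp(-F/F0)) on the percent scale, with A left
unconstrained above 100 — the convention of the assay this reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize
from scipy.stats import theilslopes, wilcoxon

from . import polymer
from .kymo import LoopTrack, SpotTrack
from .stepping import estimate_noise_sd

OUTCOMES = ("blocked", "passed", "switch", "shrink-after-release",
            "growing-through", "indeterminate")


@dataclass
class EncounterEvent:
    """One cohesin-loop–CTCF meeting."""

    start_frame: int
    end_frame: int               # last co-localized frame
    duration_s: float
    force_pn: float
    loop_bp_at_encounter: float
    censored: bool = False       # still co-localized at the movie end
    side: str | None = None      # "N" or "C" if the orientation is known
    outcome: str | None = None


@dataclass
class BlockingCurve:
    """Force-binned blocking fractions and the saturating-exponential fit."""

    bins: pd.DataFrame           # lo, hi, center, n, k, fraction, ci_lo, ci_hi
    amplitude_pct: float
    f0_pn: float
    covariance: np.ndarray | None
    method: str
    ok: bool = True


@dataclass
class ShrinkStats:
    """Loop-shrinkage statistics over a set of encounter events."""

    fraction_shrinking: float
    magnitudes_pct: np.ndarray
    modes: list[str]             # "single-step" or "gradual" per event
    gradual_rates_kb_s: np.ndarray


def detect_encounters(loop_track: LoopTrack, ctcf_track: SpotTrack,
                      geometry: polymer.TetherGeometry,
                      colocal_threshold_bp: float,
                      close_patience: int = 2,
                      min_loop_bp: float = 500.0) -> list[EncounterEvent]:
    """Find co-localization events between the loop spot and CTCF.

    An event opens at the first frame with both spots present, a loop of
    at least ``min_loop_bp``, and |loop − CTCF| <= threshold; it closes
    when separation persists for ``close_patience`` frames.  The force
    is evaluated at the opening frame from the loop size.
    """
    if ctcf_track is None:
        raise ValueError("CTCF track required")
    lp = np.asarray(loop_track.position_bp, dtype=float)
    cp = np.asarray(ctcf_track.position_bp, dtype=float)
    if len(lp) != len(cp):
        raise ValueError("tracks must share one time base")
    colocal = (np.isfinite(lp) & np.isfinite(cp)
               & (np.abs(lp - cp) <= colocal_threshold_bp)
               & (loop_track.loop_size_bp >= min_loop_bp))
    events: list[EncounterEvent] = []
    n = len(colocal)
    t = 0
    dt = float(loop_track.time_s[1] - loop_track.time_s[0]) if n > 1 else 0.0
    while t < n:
        if not colocal[t]:
            t += 1
            continue
        start = t
        last = t
        u = t + 1
        misses = 0
        while u < n:
            if colocal[u]:
                last = u
                misses = 0
            else:
                misses += 1
                if misses >= close_patience:
                    break
            u += 1
        censored = last >= n - close_patience
        loop_bp = float(loop_track.loop_size_bp[start])
        try:
            force = polymer.tension_at_encounter(loop_bp, geometry).force_pn
        except polymer.TautDNAError:
            force = np.nan
        events.append(EncounterEvent(
            start_frame=start, end_frame=last,
            duration_s=(last - start) * dt, force_pn=force,
            loop_bp_at_encounter=loop_bp, censored=censored))
        t = last + close_patience
    return events


def _robust_slope(y: np.ndarray, t: np.ndarray) -> float:
    ok = np.isfinite(y)
    if ok.sum() < 3:
        return np.nan
    return float(theilslopes(y[ok], t[ok])[0])


def classify_encounter(event: EncounterEvent, loop_track: LoopTrack,
                       ctcf_track: SpotTrack,
                       stall_threshold_kb_s: float = 0.1,
                       stall_window: int = 5,
                       settle_frames: int = 5,
                       growth_window: int = 15,
                       min_shrink_kb: float = 1.0,
                       pre_window: int = 10,
                       shrink_window: int = 30) -> str:
    """Assign an outcome to a detected encounter (also set on the event).

    Growth is judged by a robust slope of loop size over
    ``growth_window`` co-localized frames starting ``settle_frames``
    after the event opens, against ``stall_threshold_kb_s``.  The first
    frames are skipped because the event opens while the loop is still
    approaching within the co-localization threshold; a late window is
    avoided because even a passing loop eventually exhausts the DNA and
    flattens.
    growing events split into passed vs switch by whether the joint
    loop+CTCF spot keeps moving along the pre-encounter approach
    direction or reverses.  Closed events whose loop loses at least
    ``min_shrink_kb`` within ``shrink_window`` frames of release are
    shrink-after-release.  Track gaps inside the decision window give
    "indeterminate".
    """
    a, b = event.start_frame, event.end_frame
    size_kb = loop_track.loop_size_bp / 1000.0
    t_s = loop_track.time_s
    n = len(size_kb)
    n_colocal = b - a + 1

    if n_colocal < 2:
        return _set(event, "growing-through")

    start = a + settle_frames if n_colocal > settle_frames + 3 else a
    win = slice(start, min(start + growth_window, b + 1, n))
    seg = size_kb[win]
    if np.isnan(loop_track.position_bp[win]).mean() > 0.5:
        return _set(event, "indeterminate")
    if win.stop - win.start >= max(3, min(stall_window, n_colocal)):
        g = _robust_slope(seg, t_s[win])
    else:
        g = np.nan
    if not np.isfinite(g):
        return _set(event, "indeterminate")

    if g > stall_threshold_kb_s:
        # growing while co-localized: passed vs switch by direction
        pre = slice(max(0, a - pre_window), a)
        v_pre = _robust_slope(loop_track.position_bp[pre], t_s[pre])
        v_post = _robust_slope(loop_track.position_bp[win], t_s[win])
        if not np.isfinite(v_pre) or not np.isfinite(v_post):
            return _set(event, "passed")
        if v_pre * v_post < 0 and abs(v_post) > 1e-9:
            return _set(event, "switch")
        return _set(event, "passed")

    # stalled while co-localized; released events may shrink
    if not event.censored:
        after = slice(b + 1, min(n, b + 1 + shrink_window))
        if after.stop > after.start:
            before = np.nanmax(size_kb[max(a, b - 2):b + 1])
            lo = np.nanmin(size_kb[after])
            if np.isfinite(before) and np.isfinite(lo) and \
                    before - lo >= min_shrink_kb:
                return _set(event, "shrink-after-release")
    return _set(event, "blocked")


def _set(event: EncounterEvent, outcome: str) -> str:
    event.outcome = outcome
    return outcome


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    from statsmodels.stats.proportion import proportion_confint

    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    # the Wilson bounds are exactly 0/1 at the extremes; snap float error
    lo = 0.0 if k == 0 else float(lo)
    hi = 1.0 if k == n else float(hi)
    return lo, hi


def bin_by_force(forces_pn: np.ndarray, blocked: np.ndarray,
                 bin_edges_pn: np.ndarray, level: float = 0.95,
                 min_n: int = 3) -> pd.DataFrame:
    """Bin Bernoulli outcomes into half-open force bins [lo, hi).

    Returns one row per bin with counts, blocked fraction and Wilson CI;
    bins with fewer than ``min_n`` events are flagged ``low_n`` (the
    convention is to drop such bins from plots and fits).
    """
    edges = np.asarray(bin_edges_pn, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    f = np.asarray(forces_pn, dtype=float)
    blk = np.asarray(blocked, dtype=bool)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (f >= lo) & (f < hi)
        n = int(sel.sum())
        k = int(blk[sel].sum())
        ci = wilson_ci(k, n, level) if n > 0 else (np.nan, np.nan)
        rows.append({"lo": lo, "hi": hi, "center": 0.5 * (lo + hi),
                     "n": n, "k": k,
                     "fraction": k / n if n else np.nan,
                     "ci_lo": ci[0], "ci_hi": ci[1],
                     "low_n": n < min_n})
    return pd.DataFrame(rows)


def events_to_arrays(events: list[EncounterEvent]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(forces, blocked flags) from classified events (blocked outcome)."""
    f = np.array([e.force_pn for e in events])
    blk = np.array([e.outcome == "blocked" for e in events])
    return f, blk


def _saturating(f, a, f0):
    return a * (1.0 - np.exp(-f / f0))


def fit_blocking_curve(bins: pd.DataFrame | None = None,
                       forces_pn: np.ndarray | None = None,
                       blocked: np.ndarray | None = None,
                       method: str = "wls",
                       fixed_amplitude: float | None = None,
                       drop_low_n: bool = True) -> BlockingCurve:
    """Fit P_block(F) = A (1 - exp(-F/F0)) on the percent scale.

    ``method="wls"`` does per-bin weighted least squares on the blocked
    percentages (weights = per-bin n), mirroring the binned-figure fit
    and leaving A free to exceed 100.  ``method="mle"`` maximizes the
    Bernoulli likelihood on raw (force, blocked) events with the
    probability clipped to [0, 1].  ``fixed_amplitude`` holds A at a
    known value and fits F0 alone — A and F0 trade off strongly when
    the data barely reach saturation, so conditioning on A sharpens F0
    considerably.  A non-identifiable fit (e.g. all fractions equal) is
    returned with ``ok=False``.
    """
    if method == "wls":
        if bins is None:
            if forces_pn is None:
                raise ValueError("wls needs bins or raw events")
            raise ValueError("wls fitting requires binned data")
        use = bins[~bins["low_n"]] if drop_low_n else bins
        use = use[use["n"] > 0]
        if len(use) < 3:
            raise ValueError("need >= 3 usable bins")
        x = use["center"].to_numpy()
        y = use["fraction"].to_numpy() * 100.0
        w = use["n"].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            return BlockingCurve(bins=bins, amplitude_pct=float(y[0]),
                                 f0_pn=np.nan, covariance=None,
                                 method="wls", ok=False)
        try:
            if fixed_amplitude is not None:
                popt, pcov = curve_fit(
                    lambda f, f0: _saturating(f, fixed_amplitude, f0),
                    x, y, p0=(np.median(x),), sigma=1.0 / np.sqrt(w),
                    absolute_sigma=False, bounds=([1e-4], [10.0]),
                    maxfev=20000)
                return BlockingCurve(bins=bins,
                                     amplitude_pct=float(fixed_amplitude),
                                     f0_pn=float(popt[0]), covariance=pcov,
                                     method="wls")
            popt, pcov = curve_fit(
                _saturating, x, y, p0=(100.0, np.median(x)),
                sigma=1.0 / np.sqrt(w), absolute_sigma=False,
                bounds=([0.0, 1e-4], [1000.0, 10.0]), maxfev=20000)
        except RuntimeError:
            return BlockingCurve(bins=bins, amplitude_pct=np.nan,
                                 f0_pn=np.nan, covariance=None,
                                 method="wls", ok=False)
        return BlockingCurve(bins=bins, amplitude_pct=float(popt[0]),
                             f0_pn=float(popt[1]), covariance=pcov,
                             method="wls")
    if method == "mle":
        if forces_pn is None or blocked is None:
            raise ValueError("mle needs raw (forces, blocked) events")
        f = np.asarray(forces_pn, dtype=float)
        blk = np.asarray(blocked, dtype=bool)

        def nll(theta):
            if fixed_amplitude is not None:
                a, f0 = fixed_amplitude, np.exp(theta[0])
            else:
                a, f0 = np.exp(theta)
            p = np.clip(_saturating(f, a, f0) / 100.0, 1e-9, 1 - 1e-9)
            return -(np.log(p[blk]).sum() + np.log(1 - p[~blk]).sum())

        x0 = (np.log([max(np.median(f), 1e-3)]) if fixed_amplitude is not None
              else np.log([100.0, max(np.median(f), 1e-3)]))
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-10,
                                "maxiter": 20000})
        if fixed_amplitude is not None:
            a, f0 = fixed_amplitude, float(np.exp(res.x[0]))
        else:
            a, f0 = np.exp(res.x)
        return BlockingCurve(bins=bins, amplitude_pct=float(a),
                             f0_pn=float(f0), covariance=None,
                             method="mle", ok=bool(res.success))
    raise ValueError(f"unknown method {method!r}")


def force_at_blocking_level(amplitude_pct: float, f0_pn: float,
                            level_pct: float = 100.0) -> float:
    """Force where the fitted curve reaches ``level_pct`` blocking.

    Inverts A (1 - exp(-F/F0)) = level: F = -F0 ln(1 - level/A).  The
    level is unreachable when A <= level (the curve saturates below it).
    """
    if f0_pn <= 0:
        raise ValueError("F0 must be > 0")
    if amplitude_pct <= level_pct:
        raise ValueError(
            f"blocking level {level_pct}% unreachable: amplitude "
            f"{amplitude_pct}% saturates at or below it")
    return float(-f0_pn * np.log(1.0 - level_pct / amplitude_pct))


def shrink_stats(events_with_tracks: list[tuple[EncounterEvent, LoopTrack]],
                 single_step_frames: int = 1,
                 shrink_window: int = 30) -> ShrinkStats:
    """Shrinkage magnitude (% of looped DNA lost) and mode per event.

    Magnitude = (size before release − minimum size after) / size before,
    evaluated on a 3-frame running median of the tracked size so that
    the extreme statistics are not inflated by per-frame tracking noise.
    The mode is single-step when the loss completes within one frame
    interval, else gradual, with a robust shrink rate fitted over the
    shrinking stretch.
    """
    from scipy.ndimage import median_filter

    mags, modes, rates = [], [], []
    n_shrink = 0
    for event, track in events_with_tracks:
        if event.outcome != "shrink-after-release":
            continue
        n_shrink += 1
        raw = track.loop_size_bp / 1000.0
        smooth = median_filter(raw, size=5, mode="nearest")
        noise = estimate_noise_sd(raw)
        t_s = track.time_s
        a, b = event.start_frame, event.end_frame
        stop = min(len(raw), b + 1 + shrink_window)
        # the loop stalls at its pre-release plateau while co-localized;
        # medians rather than extremes keep tracking noise out of the
        # magnitude
        before = float(np.nanmedian(smooth[max(a, b - 4):b + 1]))
        after = slice(b + 1, stop)
        lo_idx = after.start + int(np.nanargmin(smooth[after]))
        lo_val = float(smooth[lo_idx])
        total_drop = before - lo_val
        mags.append(100.0 * total_drop / before)
        tol = max(0.15 * total_drop, 2.0 * noise)
        # shrinkage can begin before co-localization formally closes:
        # anchor at the last frame still near the plateau
        on_plateau = np.flatnonzero(smooth[a:lo_idx] >= before - tol)
        start = a + int(on_plateau[-1]) if len(on_plateau) else b
        # mode judged on the raw series: smoothing smears a one-frame
        # drop over several frames
        drops = -np.diff(raw[start:lo_idx + 1])
        if len(drops) and drops.max() >= 0.8 * total_drop:
            modes.append("single-step")
            rates.append(np.nan)
        else:
            modes.append("gradual")
            # fit only the shrinking stretch: plateau departure to first
            # arrival near the minimum (the tail after arrival is flat)
            arrived = np.flatnonzero(smooth[after] <= lo_val + tol)
            end = after.start + int(arrived[0]) if len(arrived) else lo_idx
            seg = slice(start, max(end, start + 3) + 1)
            rates.append(_robust_slope(smooth[seg], t_s[seg]))
    frac = n_shrink / len(events_with_tracks) if events_with_tracks else 0.0
    return ShrinkStats(fraction_shrinking=frac,
                       magnitudes_pct=np.asarray(mags),
                       modes=modes,
                       gradual_rates_kb_s=np.asarray(rates))


def switch_fraction_by_force(events: list[EncounterEvent],
                             bin_edges_pn: np.ndarray,
                             level: float = 0.95) -> pd.DataFrame:
    """Fraction of switch outcomes per force bin, with Wilson CIs."""
    f = np.array([e.force_pn for e in events])
    sw = np.array([e.outcome == "switch" for e in events])
    return bin_by_force(f, sw, bin_edges_pn, level=level)


def compare_rates_around_event(event: EncounterEvent, loop_track: LoopTrack,
                               window: int = 10, skip_frames: int = 5
                               ) -> tuple[float, float, float]:
    """Absolute extrusion rate before vs after one encounter (kb/s).

    Robust slopes of loop size over ``window`` frames before the
    encounter opens and over ``window`` frames starting ``skip_frames``
    after it opens (a passing loop keeps CTCF co-localized to the movie
    end, so the post-encounter rate is taken just after the passage
    rather than after co-localization ends).  The absolute value makes a
    direction switch comparable to continued growth.  Raises when either
    side has fewer than ``window`` frames.
    """
    size = loop_track.loop_size_bp / 1000.0
    t_s = loop_track.time_s
    a = event.start_frame
    start_after = a + skip_frames
    if a - window < 0 or start_after + window > len(size):
        raise ValueError("insufficient frames around the event")
    before = abs(_robust_slope(size[a - window:a], t_s[a - window:a]))
    after = abs(_robust_slope(size[start_after:start_after + window],
                              t_s[start_after:start_after + window]))
    return before, after, after - before


def rates_paired_test(pairs: list[tuple[float, float]]):
    """Cohort-level paired Wilcoxon test on (rate_before, rate_after)."""
    before = np.array([p[0] for p in pairs])
    after = np.array([p[1] for p in pairs])
    ok = np.isfinite(before) & np.isfinite(after)
    d = after[ok] - before[ok]
    if np.allclose(d, 0):
        return np.nan, 1.0
    stat, p = wilcoxon(before[ok], after[ok])
    return float(stat), float(p)
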