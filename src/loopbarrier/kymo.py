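"""Kymograph quantification: spot detection, loop/CTCF tracking, rates.

A kymograph is a position x time intensity image of one doubly tethered
DNA, with one channel per dye (DNA stain, labelled CTCF).  An extruded
loop appears in the DNA channel as a diffraction-limited spot of excess
intensity riding on the uniform inter-tether signal; since the stain
reports DNA content, the looped DNA fraction equals the spot's excess
intensity divided by the total DNA intensity:

    loop_size_bp = total_bp * (I_spot - I_uniform) / I_total.

Positions are converted from micrometres to base pairs with the mean
density total_bp / R (R = tether end-to-end length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import theilslopes

from .polymer import TetherGeometry
from .stepping import estimate_noise_sd, pelt_changepoints, _merge_small_steps


@dataclass
class Kymograph:
    """Multi-channel position x time intensity grids with calibration.

    ``channels`` maps a name ("dna", "ctcf") to a 2-D array of shape
    (n_pixels, n_frames).  ``tether_px`` are the pixel coordinates of the
    two anchor points; all channels share shape and calibration.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    frame_interval_s: float
    tether_px: tuple[float, float]

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        (shape,) = shapes
        lo, hi = self.tether_px
        if not (0 <= lo < hi <= shape[0] - 1):
            raise ValueError("tether positions must lie inside the grid")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def n_pixels(self) -> int:
        return next(iter(self.channels.values())).shape[0]


@dataclass
class LoopTrack:
    """Per-frame loop position (bp), size (bp) and intensity fraction."""

    frame: np.ndarray
    time_s: np.ndarray
    position_bp: np.ndarray          # NaN where no loop spot
    loop_size_bp: np.ndarray         # 0 where no loop spot
    intensity_fraction: np.ndarray
    flag: np.ndarray                 # "", "no-spot", "multi-spot", "gap"
    total_bp: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame, "time_s": self.time_s,
            "position_bp": self.position_bp,
            "loop_size_bp": self.loop_size_bp,
            "intensity_fraction": self.intensity_fraction,
            "flag": self.flag})


@dataclass
class SpotTrack:
    """Per-frame position of one diffraction-limited particle."""

    frame: np.ndarray
    time_s: np.ndarray
    position_bp: np.ndarray
    intensity: np.ndarray
    present: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame, "time_s": self.time_s,
            "position_bp": self.position_bp, "intensity": self.intensity,
            "present": self.present})


def detect_spots(profile: np.ndarray, min_snr: float = 5.0,
                 window_px: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Find diffraction-limited spots in one kymograph column.

    Local maxima above median + min_snr * MAD are kept and refined to
    sub-pixel precision by an intensity centroid over ``window_px``
    pixels each side.  Returns (positions_px, intensities) sorted by
    position; an all-flat profile yields empty arrays.
    """
    p = np.asarray(profile, dtype=float)
    if len(p) < 5:
        raise ValueError("profile must have >= 5 pixels")
    med = np.median(p)
    mad = np.median(np.abs(p - med))
    thr = med + min_snr * mad
    interior = np.arange(1, len(p) - 1)
    is_max = (p[interior] >= p[interior - 1]) & (p[interior] >= p[interior + 1])
    cand = interior[is_max & (p[interior] > thr)]
    # collapse plateaus / neighbours: keep strongest within window
    positions, intensities = [], []
    used = np.zeros(len(p), dtype=bool)
    for i in cand[np.argsort(p[cand])[::-1]]:
        if used[i]:
            continue
        lo, hi = max(0, i - window_px), min(len(p), i + window_px + 1)
        used[lo:hi] = True
        w = np.clip(p[lo:hi] - med, 0, None)
        if w.sum() <= 0:
            continue
        positions.append(float(np.average(np.arange(lo, hi), weights=w)))
        intensities.append(float(w.sum()))
    order = np.argsort(positions)
    return np.asarray(positions)[order], np.asarray(intensities)[order]


def _link(prev: float | None, positions: np.ndarray, intensities: np.ndarray,
          max_jump_px: float) -> int | None:
    """Nearest-neighbour pick; ties on distance go to highest intensity."""
    if len(positions) == 0:
        return None
    if prev is None:
        return int(np.argmax(intensities))
    d = np.abs(positions - prev)
    ok = d <= max_jump_px
    if not ok.any():
        return None
    dmin = d[ok].min()
    near = ok & (d <= dmin + 0.5)
    idx = np.flatnonzero(near)
    return int(idx[np.argmax(intensities[idx])])


def track_loop(kym: Kymograph, geometry: TetherGeometry,
               dna_channel: str = "dna", min_snr: float = 5.0,
               max_jump_px: float = 5.0, max_gap_frames: int = 3,
               spot_window_px: int = 4) -> LoopTrack:
    """Track the loop spot in the DNA channel and size it by intensity.

    Per frame the column background (median outside the tether span) is
    subtracted, the brightest linkable spot inside the span is located,
    and the loop size follows from the spot's excess over the uniform
    inter-tether level times total_bp.  Frames without a spot get loop
    size 0; linking is nearest-neighbour with a maximum jump, bridging
    gaps of up to ``max_gap_frames`` frames.
    """
    if dna_channel not in kym.channels:
        raise ValueError(f"channel {dna_channel!r} missing")
    img = np.asarray(kym.channels[dna_channel], dtype=float)
    lo, hi = int(round(kym.tether_px[0])), int(round(kym.tether_px[1]))
    n_px, n_frames = img.shape
    frames = np.arange(n_frames)
    pos_bp = np.full(n_frames, np.nan)
    size_bp = np.zeros(n_frames)
    frac = np.zeros(n_frames)
    flags = np.array([""] * n_frames, dtype=object)
    prev: float | None = None
    gap = 0
    for t in frames:
        col = img[:, t].copy()
        outside = np.concatenate((col[:lo], col[hi + 1:]))
        bg = np.median(outside) if len(outside) else 0.0
        col -= bg
        span = col[lo:hi + 1]
        total = span.sum()
        if total <= 0:
            flags[t] = "no-spot"
            prev, gap = (prev, gap + 1) if gap < max_gap_frames else (None, 0)
            continue
        positions, intensities = detect_spots(col, min_snr=min_snr)
        inside = (positions >= lo) & (positions <= hi)
        positions, intensities = positions[inside], intensities[inside]
        if len(positions) > 1:
            flags[t] = "multi-spot"
        j = _link(prev, positions, intensities, max_jump_px)
        if j is None:
            flags[t] = flags[t] or "no-spot"
            if prev is not None:
                gap += 1
                if gap > max_gap_frames:
                    prev, gap = None, 0
            continue
        c = positions[j]
        gap = 0
        prev = c
        wlo = max(lo, int(round(c)) - spot_window_px)
        whi = min(hi, int(round(c)) + spot_window_px)
        mask = np.ones(hi - lo + 1, dtype=bool)
        mask[wlo - lo:whi - lo + 1] = False
        level = np.median(span[mask]) if mask.any() else 0.0
        excess = span[~mask].sum() - level * (~mask).sum()
        f = max(excess, 0.0) / total
        frac[t] = f
        size_bp[t] = f * geometry.total_bp
        pos_um = (c - lo) * kym.pixel_size_um
        pos_um = min(max(pos_um, 0.0), geometry.end_to_end_um)
        pos_bp[t] = pos_um * geometry.total_bp / geometry.end_to_end_um
    return LoopTrack(frame=frames, time_s=frames * kym.frame_interval_s,
                     position_bp=pos_bp, loop_size_bp=size_bp,
                     intensity_fraction=frac, flag=flags,
                     total_bp=geometry.total_bp)


def track_ctcf(kym: Kymograph, geometry: TetherGeometry,
               channel: str = "ctcf", min_snr: float = 5.0,
               max_jump_px: float = 5.0, max_gap_frames: int = 3) -> SpotTrack:
    """Track the labelled-CTCF spot frame by frame (detection + linking)."""
    if channel not in kym.channels:
        raise ValueError(f"channel {channel!r} missing")
    img = np.asarray(kym.channels[channel], dtype=float)
    lo, hi = int(round(kym.tether_px[0])), int(round(kym.tether_px[1]))
    n_frames = img.shape[1]
    frames = np.arange(n_frames)
    pos_bp = np.full(n_frames, np.nan)
    inten = np.zeros(n_frames)
    present = np.zeros(n_frames, dtype=bool)
    prev: float | None = None
    gap = 0
    for t in frames:
        col = img[:, t] - np.median(img[:, t])
        positions, intensities = detect_spots(col, min_snr=min_snr)
        inside = (positions >= lo - 1) & (positions <= hi + 1)
        positions, intensities = positions[inside], intensities[inside]
        j = _link(prev, positions, intensities, max_jump_px)
        if j is None:
            if prev is not None:
                gap += 1
                if gap > max_gap_frames:
                    prev, gap = None, 0
            continue
        c = positions[j]
        prev, gap = c, 0
        present[t] = True
        inten[t] = intensities[j]
        pos_um = (c - lo) * kym.pixel_size_um
        pos_um = min(max(pos_um, 0.0), geometry.end_to_end_um)
        pos_bp[t] = pos_um * geometry.total_bp / geometry.end_to_end_um
    return SpotTrack(frame=frames, time_s=frames * kym.frame_interval_s,
                     position_bp=pos_bp, intensity=inten, present=present)


def count_bleach_steps(intensity_trace: np.ndarray,
                       sensitivity: float = 2.0,
                       min_step_sd_mult: float = 2.0) -> tuple[int, float]:
    """Count downward bleaching steps in a fluorophore intensity trace.

    Change points come from the same penalized least-squares detector
    used for tweezer traces; only downward plateau jumps count.  Returns
    (n_steps, mean intensity before the first bleach step) — the trace
    is assumed background-subtracted, and the pre-bleach mean is over
    all frames preceding the first downward change point.
    """
    y = np.asarray(intensity_trace, dtype=float)
    if len(y) < 10:
        raise ValueError("trace must have >= 10 frames")
    if y.max() <= 0:
        raise ValueError("non-positive intensity trace")
    sigma = estimate_noise_sd(y)
    scale = max(sigma, 1e-9 * max(1.0, float(np.ptp(y))), 1e-12)
    penalty = sensitivity * scale**2 * np.log(len(y))
    cps = pelt_changepoints(y, penalty)
    cps = _merge_small_steps(y, cps, min_step_sd_mult * sigma)
    bounds = [0] + cps + [len(y)]
    means = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    jumps = np.diff(means)
    down = [cps[i] for i in range(len(cps)) if jumps[i] < 0]
    first = down[0] if down else len(y)
    return len(down), float(y[:first].mean())


def extrusion_rate(loop_track: LoopTrack, window: int = 11) -> np.ndarray:
    """Rolling robust (Theil–Sen) slope of loop size vs time, in kb/s.

    Centered windows of ``window`` frames; edges and windows containing
    gaps give NaN.  Positive = growth, negative = shrinkage.
    """
    if window < 3:
        raise ValueError("window must be >= 3 frames")
    size_kb = loop_track.loop_size_bp / 1000.0
    t = loop_track.time_s
    n = len(size_kb)
    if n < window:
        raise ValueError(f"track of {n} frames shorter than window {window}")
    half = window // 2
    rates = np.full(n, np.nan)
    for i in range(half, n - half):
        ys = size_kb[i - half:i + half + 1]
        ts = t[i - half:i + half + 1]
        if np.any(np.isnan(ys)):
            continue
        rates[i] = theilslopes(ys, ts)[0]
    return rates
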