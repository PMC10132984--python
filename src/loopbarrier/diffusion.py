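"""MSD diffusion analysis and classification of diffusing-cohesin encounters.

The diffusion coefficient of a particle on DNA is estimated from the
time-averaged mean squared displacement with overlapping windows and a
linear regression MSD(τ) = Dτ + o restricted to the first ten time lags;
the intercept o absorbs static localization error, and larger lags are
excluded because reflection at the DNA ends flattens the MSD curve.
Note that D in this convention is the raw MSD slope (kb²/s).

Encounters between diffusing cohesin and site-bound CTCF are classified
from the cohesin position trace alone: blocked (reaches the site, never
crosses), passed once (exactly one side change), passed multiple times,
or excluded for the reasons used when curating the experiment (never
encounters the site, co-localized from the start, bleaching).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kymo import SpotTrack

CLASSES = ("blocked", "passed-once", "passed-multiple", "excluded")


@dataclass
class DiffusionFit:
    """Linear MSD fit: D (kb²/s), intercept o (kb²), lags used, residuals."""

    d_kb2_s: float
    offset_kb2: float
    n_lags: int
    residuals: np.ndarray
    r_squared: float
    degenerate: bool = False


@dataclass
class DiffusionEncounterCall:
    """Outcome of one diffusing-cohesin track meeting CTCF."""

    call: str                      # one of CLASSES
    n_traversals: int
    reason: str = ""               # exclusion reason when call == "excluded"
    side_faced: str | None = None  # "N-terminal"/"C-terminal" if known


def compute_msd(positions_bp: np.ndarray | SpotTrack, frame_interval_s: float,
                max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over overlapping windows, in kb² vs lag time (s)."""
    if isinstance(positions_bp, SpotTrack):
        positions_bp = positions_bp.position_bp
    x = np.asarray(positions_bp, dtype=float) / 1000.0  # kb
    if len(x) < max_lag + 1:
        raise ValueError(f"track of {len(x)} frames too short for "
                         f"max_lag {max_lag}")
    lags = np.arange(1, max_lag + 1)
    msd = np.array([np.mean((x[lag:] - x[:-lag]) ** 2) for lag in lags])
    return lags * frame_interval_s, msd


def fit_diffusion(lag_times_s: np.ndarray, msd_kb2: np.ndarray,
                  n_lags: int = 10) -> DiffusionFit:
    """Ordinary least squares of MSD(τ) = Dτ + o over the first n_lags."""
    tau = np.asarray(lag_times_s, dtype=float)[:n_lags]
    m = np.asarray(msd_kb2, dtype=float)[:n_lags]
    if len(tau) < n_lags:
        raise ValueError(f"need >= {n_lags} MSD points, got {len(tau)}")
    if np.allclose(m, m[0]):
        return DiffusionFit(d_kb2_s=0.0, offset_kb2=float(m[0]),
                            n_lags=n_lags, residuals=np.zeros_like(m),
                            r_squared=1.0, degenerate=True)
    coef = np.polyfit(tau, m, 1)
    pred = np.polyval(coef, tau)
    resid = m - pred
    ss_tot = np.sum((m - m.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return DiffusionFit(d_kb2_s=float(coef[0]), offset_kb2=float(coef[1]),
                        n_lags=n_lags, residuals=resid, r_squared=float(r2))


def classify_diffusion_encounter(
        track: SpotTrack | np.ndarray, ctcf_position_bp: float,
        colocal_threshold_bp: float,
        hysteresis_bp: float | None = None,
        min_visits: int = 2,
        ctcf_present: bool = True) -> DiffusionEncounterCall:
    """Classify one cohesin track against a fixed CTCF position.

    A traversal is scored when the particle settles more than
    ``hysteresis_bp`` beyond the site on the other side, suppressing
    flicker from localization noise; set the hysteresis to a small
    multiple of the localization-error scale of the tracks (default:
    one co-localization threshold).  Blocked means the particle entered
    the co-localization zone on at least ``min_visits`` separate
    occasions (the bouncing-back signature of a real barrier) without
    ever traversing it; a single grazing touch cannot be told from a
    passer that happened not to cross and is excluded as unresolved.
    """
    if hysteresis_bp is None:
        hysteresis_bp = colocal_threshold_bp
    if isinstance(track, SpotTrack):
        if not np.all(track.present):
            return DiffusionEncounterCall(
                call="excluded", n_traversals=0, reason="bleaching")
        x = np.asarray(track.position_bp, dtype=float)
    else:
        x = np.asarray(track, dtype=float)
    if not ctcf_present:
        return DiffusionEncounterCall(call="excluded", n_traversals=0,
                                      reason="bleaching")
    d = x - ctcf_position_bp
    if abs(d[0]) <= colocal_threshold_bp:
        return DiffusionEncounterCall(call="excluded", n_traversals=0,
                                      reason="colocalized-from-start")
    side = np.sign(d[0])
    traversals = 0
    visits = 0
    in_zone = False
    for di in d[1:]:
        if abs(di) <= colocal_threshold_bp:
            if not in_zone:
                visits += 1
            in_zone = True
        else:
            in_zone = False
        if np.sign(di) != side and abs(di) > hysteresis_bp:
            traversals += 1
            side = np.sign(di)
    if traversals == 0:
        if visits >= min_visits:
            return DiffusionEncounterCall(call="blocked", n_traversals=0)
        if visits > 0:
            return DiffusionEncounterCall(call="excluded", n_traversals=0,
                                          reason="unresolved-encounter")
        return DiffusionEncounterCall(call="excluded", n_traversals=0,
                                      reason="never-encounters")
    call = "passed-once" if traversals == 1 else "passed-multiple"
    return DiffusionEncounterCall(call=call, n_traversals=traversals)


def blocked_fraction(calls: list[DiffusionEncounterCall],
                     level: float = 0.95
                     ) -> tuple[float, tuple[float, float], int]:
    """Blocked fraction among non-excluded calls, with a Wilson CI.

    Returns (fraction, (lo, hi), n_usable); raises if every call was
    excluded.
    """
    from .encounters import wilson_ci

    usable = [c for c in calls if c.call != "excluded"]
    if not usable:
        raise ValueError("no usable (non-excluded) calls")
    k = sum(c.call == "blocked" for c in usable)
    n = len(usable)
    return k / n, wilson_ci(k, n, level=level), n
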