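"""Step detection on magnetic-tweezer traces and the encounter Monte Carlo.

Loop extrusion under a constant-force magnetic tweezer appears as a
descending (or ascending, sign is irrelevant here) staircase in the bead
Z position.  Steps are recovered by fitting a piecewise-constant signal
with a penalized residual-sum-of-squares criterion, solved exactly by the
PELT pruned dynamic program.  Detected step sizes per clamped force feed
both the force-resolved step-size distributions and a Monte Carlo asking
how often a cohesin taking such steps would land within a small window of
a CTCF site — testing whether smaller steps at higher tension could by
themselves raise the encounter (and hence blocking) frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StepTrace:
    """Uniformly sampled extension trace at one clamped force."""

    extension_nm: np.ndarray
    sampling_rate_hz: float
    force_pn: float

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.force_pn <= 0:
            raise ValueError("force_pn must be > 0")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.extension_nm)) / self.sampling_rate_hz


@dataclass
class StepList:
    """Steps of one trace: change-point times, sizes, and inter-step dwells."""

    step_times_s: np.ndarray
    step_sizes_nm: np.ndarray
    dwell_times_s: np.ndarray
    change_points: np.ndarray  # sample indices (start of new plateau)
    plateau_means_nm: np.ndarray
    noise_sd_nm: float


def estimate_noise_sd(y: np.ndarray) -> float:
    """Robust noise s.d. from the MAD of first differences.

    Differencing removes the piecewise-constant signal except at the few
    change points, which the median absorbs; /sqrt(2) undoes the variance
    doubling of the difference.
    """
    d = np.diff(np.asarray(y, dtype=float))
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _segment_costs(s1: np.ndarray, s2: np.ndarray,
                   starts: np.ndarray, end: int) -> np.ndarray:
    """RSS of segments y[starts:end] from cumulative sums (vectorized)."""
    n = end - starts
    tot = s1[end] - s1[starts]
    return (s2[end] - s2[starts]) - tot * tot / n


def pelt_changepoints(y: np.ndarray, penalty: float,
                      min_size: int = 2) -> list[int]:
    """Exact penalized least-squares change-point positions via PELT.

    Minimizes sum of per-segment RSS plus ``penalty`` per change point.
    Returns sorted interior change points (indices where a new plateau
    starts).  PELT's pruning is lossless for this cost, so the result
    equals an exhaustive dynamic program over all partitions.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    candidates = np.array([0], dtype=int)
    for t in range(min_size, n + 1):
        mature = t - candidates >= min_size
        cand = candidates[mature]
        if len(cand) == 0:  # pragma: no cover - min_size guard
            continue
        base = f[cand] + _segment_costs(s1, s2, cand, t)
        best = int(np.argmin(base))
        f[t] = base[best] + penalty
        prev[t] = cand[best]
        # lossless pruning: drop mature starts that can never win again;
        # starts younger than min_size are kept untouched
        keep = base <= f[t]
        candidates = np.concatenate(
            (cand[keep], candidates[~mature], [t]))
    # backtrack
    cps: list[int] = []
    t = n
    while t > 0:
        cp = int(prev[t])
        if cp > 0:
            cps.append(cp)
        t = cp
    return sorted(cps)


def dp_changepoints_oracle(y: np.ndarray, penalty: float,
                           min_size: int = 2) -> list[int]:
    """Naive O(n^2) optimal-partitioning dynamic program (no pruning).

    Reference implementation used to verify :func:`pelt_changepoints`;
    keep for traces of at most a few thousand samples.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for t in range(min_size, n + 1):
        starts = np.arange(0, t - min_size + 1)
        costs = f[starts] + _segment_costs(s1, s2, starts, t) + penalty
        best = int(np.argmin(costs))
        f[t] = costs[best]
        prev[t] = starts[best]
    cps: list[int] = []
    t = n
    while t > 0:
        cp = int(prev[t])
        if cp > 0:
            cps.append(cp)
        t = cp
    return sorted(cps)


def detect_steps(trace: StepTrace, sensitivity: float = 2.0,
                 min_step_sd_mult: float = 2.0) -> StepList:
    """Detect steps in an extension trace by exact penalized change-points.

    The penalty is ``sensitivity * sigma^2 * ln(n)`` with sigma the robust
    noise estimate (sensitivity 2.0 is the classical BIC-type choice for
    a Gaussian mean-shift model).  Plateau differences smaller than
    ``min_step_sd_mult * sigma`` are merged away and not reported.

    Requires at least 50 samples.
    """
    y = np.asarray(trace.extension_nm, dtype=float)
    n = len(y)
    if n < 50:
        raise ValueError(f"trace has {n} < 50 samples")
    sigma = estimate_noise_sd(y)
    # floor so noiseless staircases still get a usable penalty scale
    scale = max(sigma, 1e-9 * max(1.0, float(np.ptp(y))), 1e-12)
    penalty = sensitivity * scale**2 * np.log(n)
    cps = pelt_changepoints(y, penalty)
    cps = _merge_small_steps(y, cps, min_step_sd_mult * sigma)
    bounds = np.concatenate(([0], cps, [n])).astype(int)
    means = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    sizes = np.diff(means)
    times = np.asarray(cps, dtype=float) / trace.sampling_rate_hz
    dwells = np.diff(np.concatenate(([0.0], times)))
    return StepList(step_times_s=times, step_sizes_nm=sizes,
                    dwell_times_s=dwells, change_points=np.asarray(cps, int),
                    plateau_means_nm=means, noise_sd_nm=sigma)


def _merge_small_steps(y: np.ndarray, cps: list[int],
                       min_step: float) -> list[int]:
    """Iteratively drop the change point with the smallest plateau jump."""
    cps = list(cps)
    while cps:
        bounds = [0] + cps + [len(y)]
        means = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        jumps = np.abs(np.diff(means))
        i = int(np.argmin(jumps))
        if jumps[i] >= min_step:
            break
        cps.pop(i)
    return cps


def step_distribution_by_force(
        steplists_by_force: dict[float, list[StepList]],
        geometry_params=None, min_steps: int = 20) -> pd.DataFrame:
    """Pool detected steps per clamped force and summarize in nm and bp.

    Returns one row per force with the pooled median, IQR and count; the
    bp conversion divides by the force-dependent relative extension
    (see :func:`loopbarrier.polymer.step_nm_to_bp`).  Groups with fewer
    than ``min_steps`` steps are skipped.
    """
    from . import polymer

    rows = []
    for force, steplists in sorted(steplists_by_force.items()):
        sizes = np.abs(np.concatenate(
            [sl.step_sizes_nm for sl in steplists]
            or [np.empty(0)]))
        if len(sizes) < min_steps:
            continue
        q1, med, q3 = np.percentile(sizes, [25, 50, 75])
        rows.append({
            "force_pn": force,
            "n_steps": len(sizes),
            "median_nm": med,
            "iqr_nm": q3 - q1,
            "median_bp": polymer.step_nm_to_bp(med, force, geometry_params),
            "iqr_bp": polymer.step_nm_to_bp(q3 - q1, force, geometry_params),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EncounterSimConfig:
    """Monte Carlo of cohesin landing and stepping along a CTCF-bearing DNA.

    A cohesin binds at a uniformly sampled integer position on a DNA of
    ``dna_length_bp`` and advances in steps drawn from an empirical step
    distribution until it passes the CTCF coordinate or runs off an end.
    Any visited position within ``threshold_bp`` of the CTCF site counts
    the repetition as an encounter.
    """

    dna_length_bp: int = 10_000
    ctcf_position_bp: int = 7_000
    threshold_bp: int = 50
    n_reps: int = 500
    directionality: str = "one-sided-toward"  # |one-sided-random|two-sided
    max_steps: int | None = None  # 0 = landing only, no extrusion steps

    def __post_init__(self) -> None:
        if not 0 < self.ctcf_position_bp < self.dna_length_bp:
            raise ValueError("ctcf_position_bp must lie inside the DNA")
        if self.threshold_bp <= 0:
            raise ValueError("threshold_bp must be > 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.directionality not in (
                "one-sided-toward", "one-sided-random", "two-sided"):
            raise ValueError(f"unknown directionality {self.directionality!r}")


def _walk_encounters(start: int, direction: int, steps_bp: np.ndarray,
                     cfg: EncounterSimConfig, rng: np.random.Generator) -> bool:
    pos = start
    ctcf = cfg.ctcf_position_bp
    if abs(pos - ctcf) <= cfg.threshold_bp:
        return True
    n_taken = 0
    while 0 <= pos <= cfg.dna_length_bp:
        if cfg.max_steps is not None and n_taken >= cfg.max_steps:
            return False
        n_taken += 1
        side = np.sign(pos - ctcf)
        pos += direction * int(rng.choice(steps_bp))
        if abs(pos - ctcf) <= cfg.threshold_bp:
            return True
        if np.sign(pos - ctcf) != side:  # passed CTCF: rep terminates
            return False
    return False


def simulate_ctcf_encounters(config: EncounterSimConfig,
                             step_dist_bp: dict[float, np.ndarray],
                             seed: int | np.random.Generator = 0
                             ) -> pd.DataFrame:
    """Encounter fraction per force, given per-force step-size samples.

    ``step_dist_bp`` maps force (pN) to an array of empirical step sizes
    in bp (sampled with replacement).  A repetition counts as an
    encounter when cohesin visits any position within ``threshold_bp`` of
    the CTCF site before passing it or reaching a DNA end.  With the
    default one-sided-toward rule, cohesin steps toward increasing
    coordinate and both DNA orientations are averaged; the alternatives
    pick a random single direction per rep or step both ways alternately.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rows = []
    for force in sorted(step_dist_bp):
        steps = np.asarray(step_dist_bp[force], dtype=float)
        steps = np.round(np.abs(steps)).astype(int)
        if len(steps) == 0:
            raise ValueError(f"empty step distribution for force {force}")
        if np.all(steps == 0) and config.max_steps != 0:
            raise ValueError(f"all-zero step sizes for force {force}: stall")
        hits = 0
        for _ in range(config.n_reps):
            start = int(rng.integers(0, config.dna_length_bp + 1))
            if config.directionality == "one-sided-toward":
                # average over the two DNA orientations
                hit = _walk_encounters(start, +1, steps, config, rng)
                hit2 = _walk_encounters(
                    config.dna_length_bp - start, +1, steps,
                    _mirror(config), rng)
                hits += 0.5 * (hit + hit2)
            elif config.directionality == "one-sided-random":
                d = 1 if rng.random() < 0.5 else -1
                hits += _walk_encounters(start, d, steps, config, rng)
            else:  # two-sided: two boundaries stepping outward alternately
                hits += (_walk_encounters(start, +1, steps, config, rng)
                         or _walk_encounters(start, -1, steps, config, rng))
        rows.append({"force_pn": force, "n_reps": config.n_reps,
                     "encounter_fraction": hits / config.n_reps})
    return pd.DataFrame(rows)


def _mirror(cfg: EncounterSimConfig) -> EncounterSimConfig:
    return EncounterSimConfig(
        dna_length_bp=cfg.dna_length_bp,
        ctcf_position_bp=cfg.dna_length_bp - cfg.ctcf_position_bp,
        threshold_bp=cfg.threshold_bp, n_reps=cfg.n_reps,
        directionality=cfg.directionality, max_steps=cfg.max_steps)
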