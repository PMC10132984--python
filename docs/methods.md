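# Methods

This note documents the models, estimators, and study conditions the
package implements, the choices made where the design was open, and what
the synthetic-data validation does and does not demonstrate.

## DNA mechanics (polymer)

Tension in a doubly tethered DNA is computed with the Marko–Siggia
interpolation of the inextensible worm-like chain,

    F(x) = (kBT/Lp) · [ 1/(4(1−x)²) − 1/4 + x ],   x = R / L_contour,

with defaults Lp = 50 nm, helical rise 0.34 nm/bp, T = 310 K
(kBT = 4.28 pN·nm; the loop assays run at 37 °C).  All three constants
are configurable because intercalating stains (Sytox) soften the chain
and lengthen the contour.  When a loop of `s` bp has been extruded, the
contour entering the extension fraction is that of the `total_bp − s`
unlooped base pairs, while the end-to-end span R is fixed by the tether
points; a loop large enough to pull the unlooped contour below R raises
a taut-DNA error rather than diverging numerically.  With these defaults
a loop-free 31.8 kb DNA at R = 4 µm carries 0.064 pN — consistent, within
the uncertainty of the stain-modified constants, with the ~0.07 pN offset
tension reported for that geometry.

The inverse (extension at a force) is obtained by root bracketing on the
monotone force curve with a round-trip error below 1e−6 pN.  Positions
are converted between µm and bp with the mean density `total_bp / R`,
the convention used in the source analyses.  Magnetic-tweezer extension
steps convert to base pairs as `Δbp = Δnm / (rise · x(F))`; a 40 nm step
maps to ≈100–200 bp over most of the 0.1–1 pN range probed (≈240 bp at
the lowest force).  The model is not meant for forces above ~10 pN
(enthalpic stretching) or for supercoiled DNA.

## Synthetic data (synth)

The generator's defaults are the assay conditions: 31.8 kb DNA with a
single CTCF site at 9.7 kb (N terminus toward the longer arm), 0.4 s
frames, 0.1 µm pixels, and a 0.13 µm PSF sigma for the loop assay; the
26,123 bp DNA with the site at 10,452 bp, 3.12–10.15 s frames, for the
diffusion and residence-time assays; 50 Hz sampling and 2 nm Gaussian
noise for the tweezer traces.  Pixel size and PSF are conventional values
for the described 63×/1.46 NA HILO setup (the papers do not print them).

**Kymographs.** The DNA channel distributes the stain signal uniformly
between the tether points and adds a Gaussian spot carrying exactly the
looped fraction of the total intensity, so photons are conserved per
frame by construction; the CTCF channel is a Gaussian spot at the site.
Camera noise is Poisson shot noise plus Gaussian read noise on a constant
background.  Loop dynamics follow a scripted program — nucleation on the
long arm (default 15 kb), one-sided growth at 1 kb/s toward the site, and
a programmed outcome at the encounter: *blocked* (stall at the site),
*passed* (a short pause, then growth continues with CTCF inside the
loop), *switch* (growth resumes on the far boundary, so the joint
loop+CTCF spot migrates back against the approach direction), or *shrink*
(a stall dwell, then loss of 35 % of the looped DNA in one frame or
gradually at a set rate).  Spatial positions account for the loop
collapsing its genomic interval to a point on the tether.  The default
tether span of 3.2 µm puts the scripted encounter (~5.3 kb loop) at
≈0.06 pN, inside the assay's best-covered 0.04–0.08 pN force window.
What the kymograph model deliberately omits: transverse DNA fluctuations,
drift, uneven illumination, channel misregistration, and two-sided or
intermittent extrusion.  Validation against these synthetics therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to every instrumental artefact of real movies.

**Diffusion tracks.** A Gaussian random walk in bp with per-frame
variance D·Δt, reflecting at the DNA ends.  D follows the MSD(τ) = Dτ
convention of the analysis (the slope *is* D), so generator and estimator
share one definition.  A barrier is modelled per crossing attempt:
passage with probability `pass_prob`, otherwise reflection about the
site.  Reported positions optionally carry i.i.d. Gaussian localization
error (`loc_noise_bp`).

**Dwell times.** Mixture-of-exponentials draws; with a bleaching
half-life the observed dwell is the minimum of unbinding and bleaching
draws; draws shorter than one frame are rejected (unobservable), which
matches the left truncation the fit assumes; an observation limit
right-censors with a flag.

**Tweezer traces.** Staircases with exponential inter-step dwells
(clamped to ≥4 samples so steps are resolvable at all), step sizes from a
scalar, an empirical sample, or a callable, plus Gaussian noise.

## Kymograph quantification (kymo)

Spots are local maxima above `median + min_snr·MAD` of the column,
refined by an intensity centroid (±3 px).  Loop size uses the
intensity-fraction estimator: after subtracting the per-column background
(median outside the tether span), the spot's excess over the uniform
inter-tether level, divided by the total in-span intensity, times
`total_bp`.  Frames without a linkable spot get loop size 0 and a flag.
Linking is nearest-neighbour with a 5 px/frame jump limit and gaps up to
3 frames bridged; distance ties go to the brighter spot.  On noiseless
synthetics the size error is <100 bp and the position error under one
pixel; over seeded noisy kymographs the estimator's mean size bias is
below 2 % of `total_bp` with per-frame scatter of ~170 bp at the default
photon budget.  Extrusion rates are rolling Theil–Sen slopes of loop size
(kb/s); photobleaching steps are counted with the same change-point
detector used for tweezer traces, restricted to downward jumps.

## Encounter analysis (encounters)

An encounter opens when loop spot and CTCF spot co-localize within a
threshold (default 2 pixel-equivalents in bp, ≈1.6 kb at the default
geometry) and closes after 2 consecutive separated frames; the force is
the WLC tension at the opening frame's loop size.  Classification:

* growth is judged by a Theil–Sen slope of loop size over 15 co-localized
  frames starting 5 frames after opening — the first frames are skipped
  because the event opens while the loop is still approaching inside the
  threshold, and a late window is avoided because even a passing loop
  eventually exhausts the DNA and flattens; the stall threshold is
  0.1 kb/s;
* growing events split into *passed* vs *switch* by whether the joint
  spot continues along the pre-encounter approach direction or reverses;
* closed events whose loop loses ≥1 kb within 30 frames of release are
  *shrink-after-release*; magnitude uses plateau medians and a smoothed
  minimum (extreme statistics over noisy frames would otherwise inflate
  it), and the single-step/gradual call is made on the raw series;
* zero-length contacts are *growing-through*; track gaps in the decision
  window give *indeterminate*.

On ambiguity the precedence is passed > switch > blocked > shrink, except
that a closed, stalled event that then shrinks is scored shrink (a shrink
event necessarily stalls first, so a literal blocked-over-shrink rule
would make the class unreachable).  On 300 scripted molecules mixing all
four programs the classifier made zero errors; this reflects the scripted
dynamics' clean separation, not a guarantee for marginal real events.

Blocking statistics use half-open force bins with Wilson score intervals
(the binomial CI method is a package choice; the Wilson bounds are exact
0/1 at k = 0/n).  Bins with n < 3 are flagged and dropped from fits, the
source convention.  The saturating exponential `A(1 − e^(−F/F0))` is
fitted to blocked percentages by weighted least squares (weights = per-bin
n) with A free to exceed 100 % — reproducing the convention of the
published fits (147 % and 115 %) — or by raw-event Bernoulli maximum
likelihood with the probability clipped to [0, 1].  Both routes exist
because which one the source used is not recorded.  A and F0 are strongly
anti-correlated when the data barely reach saturation: at the printed bin
sizes the free fit's F0 has a seed-to-seed IQR of ~0.09–0.20 pN, while
holding A at a known value sharpens F0 to ±0.02 pN; `fixed_amplitude`
exposes this conditional fit.  `force_at_blocking_level` inverts the
curve in closed form and refuses levels at or above the amplitude.

The before/after extrusion-rate comparison takes absolute Theil–Sen
slopes over windows before the event opens and shortly after (a passing
loop keeps CTCF co-localized to the movie end, so "after" anchors at the
passage, not at separation), with a cohort-level paired Wilcoxon test.

## Diffusing-cohesin classification (diffusion)

MSD uses overlapping windows; the fit is ordinary least squares over the
first ten lags only, because reflection at the DNA ends flattens longer
lags.  The intercept absorbs localization error.  At the 26.1 kb study
geometry (100-frame tracks at 3.12 s), reflection depresses the fitted D
by ~14 % of its value at D = 0.32 kb²/s — within the ±0.1 recovery band —
while on a long DNA the estimator is unbiased within a few percent across
D = 0.05–1 kb²/s.

Track classification counts barrier traversals with hysteresis: a
traversal requires settling beyond `hysteresis_bp` on the far side
(default one threshold; for tracks whose localization error is known, a
small multiple of that scale — 250 bp at the 100 bp noise of the study
conditions).  *Blocked* requires at least `min_visits = 2` separate
entries into the co-localization zone (default 2 pixel-equivalents,
~870 bp) without a traversal — the bouncing-back signature of a real
barrier; a single grazing touch cannot be told from a passer that
happened not to cross and is excluded as unresolved, alongside the other
exclusions (co-localized from the start, never encounters, bleaching).
These constants were set by confusion-matrix simulation against ground
truth: with one-visit blocking, permeable tracks that touch the zone but
happen never to cross inflate the blocked fraction by ~7 points at 4 s
frames.  `blocked_fraction` drops exclusions from the denominator and
returns a Wilson CI.

## Dwell-time kinetics (kinetics)

Exponential mixtures are fitted by direct maximum likelihood
(Nelder–Mead on log-rates and weight logits) with the likelihood
left-truncated at one frame interval — events shorter than a frame are
never observed, and at 10.15 s frames ignoring this biases the fast rate —
and right-censored survival terms for molecules outliving the
acquisition.  The fixed-fraction variant holds the weights (e.g. the
97/140 fast fraction assigned from event positions) and fits only the
rates.  Means (τ = 1/k) and half-lives (ln2/k) are both first-class
because both conventions circulate.  Model selection is by BIC with ties
to fewer components; on n = 20 samples it correctly retreats to one
component.  The bleaching control fits the on-glass set with a single
exponential and subtracts rates (`k_true = k_obs − k_bleach`), flagging
components with `k_obs < 2·k_bleach` as bleach-limited and refusing the
correction when `k_obs ≤ k_bleach`.  With the published constants
(29.2 min observed, 77.3 min bleaching) the corrected half-life is
46.9 min and the component is not bleach-limited.  Survival curves are
Kaplan–Meier (lifelines).

## Step detection and the encounter Monte Carlo (stepping)

Steps are change points of a piecewise-constant fit minimizing
`Σ RSS + β·(#changes)`, solved exactly by PELT; the pruning is lossless
for this cost, and the tests verify equality with an exhaustive O(n²)
dynamic program on ≤500-sample traces.  The penalty is
`β = 2·σ̂²·ln n` (the classical BIC-type choice for a Gaussian mean-shift
model) with σ̂ the MAD of first differences /√2; plateau jumps below
2σ̂ are merged away.  On flat noisy traces the false-step rate is ~0.5 %;
noiseless staircases are recovered exactly; at the tweezer conditions
(50 Hz, 2 nm noise, 40 nm median steps) the pooled detected median is
within 1 nm of truth.

The encounter Monte Carlo places cohesin uniformly on a 10 kb DNA with
CTCF at 7 kb, advances it by steps drawn from the empirical per-force
distribution, and counts a repetition as an encounter if any visited
position comes within 50 bp of the site; 500 repetitions per force.
Directionality is configurable (default: one-sided stepping with both
DNA orientations averaged; alternatives: random single direction,
two-sided) because the source does not specify it; a repetition ends on
passing the site or reaching a DNA end.  With stepping disabled the
fraction reduces to the exact landing probability 101/10001.

## Validation studies and their conditions

The acceptance studies (`loopbarrier.studies`, `scripts/acceptance.py`)
use the published values as generator truth and require blind recovery:

* F0 recovery: Bernoulli outcomes at the six printed bin centres with the
  printed per-bin n (296 events), 100 seeds; the free fit's median F0 is
  reported.
* Step recovery: 100 traces, 8 steps each, median 40 nm, 2 nm noise.
* Residence times: 140-dwell datasets from the 69 %/31 % mixture with
  half-lives 1.2/29.2 min (10.15 s frames), fast weight fixed at 97/140;
  on-glass, 142 single-exponential dwells at 77.3 min.
* Diffusion coefficient: 500 tracks of 100 frames at 3.12 s, D = 0.32.
* Loop pipeline: 119 one-encounter kymographs, per-encounter block
  probability 0.45 (the remainder pass), full tracking + classification.
* Diffusion pipeline: 264 tracks of 40 frames at 4 s with 100 bp
  localization noise, launched 1.2–2.5 kb from the site on either side
  (emulating the curation to molecules whose cohesin actually meets CTCF
  within the movie); per-track barrier impermeable with probability 0.64.

Problem sizes mirror the published sample sizes; track and movie lengths
are the package's choices where the sources leave them open.

## Known limitations

* The scripted loop dynamics are one-sided and deterministic between
  events; real extrusion is bursty and can be bidirectional.
* The WLC constants under intercalating stain are uncertain at the
  ±20–30 % level, which propagates directly into absolute tensions.
* The diffusion classifier's blocked/unresolved boundary is intrinsically
  ambiguous for single grazing touches at coarse frame intervals; its
  calibration is specific to the stated noise and frame rate.
* The binned blocking-curve fit's amplitude is poorly identified below
  saturation; prefer the inverted 100 %-blocking force or the
  fixed-amplitude fit when comparing F0 across conditions.
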