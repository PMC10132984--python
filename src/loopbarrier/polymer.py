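"""Worm-like-chain (WLC) mechanics for doubly tethered DNA.

In the loop-extrusion assay a DNA molecule of ``total_bp`` base pairs is
tethered at both ends a fixed distance ``R`` (the end-to-end length) apart.
As cohesin reels DNA into a loop, the contour length available outside the
loop shrinks while ``R`` stays fixed, so the relative extension — and with
it the DNA tension — rises.  Tension is obtained from the relative
extension with the Marko–Siggia interpolation formula

    F(x) = (kBT / Lp) * [ 1/(4 (1 - x)^2) - 1/4 + x ],    x = R / L_contour

which is accurate to a few percent over the sub-piconewton range probed
here.  The same model converts magnetic-tweezer extension changes (nm)
into base pairs at a given clamped force.

All forces are in pN, lengths in nm/µm/bp as declared per argument, and
temperatures in K.  The module is pure and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

#: Boltzmann constant in pN·nm/K.
BOLTZMANN_PN_NM = 0.0138064852


class OverstretchedError(ValueError):
    """Relative extension at or beyond the inextensible-WLC limit (x >= 1)."""


class TautDNAError(ValueError):
    """The DNA outside the loop is shorter than the tether span."""


@dataclass(frozen=True)
class WLCParams:
    """Mechanical constants of the worm-like chain.

    Defaults are the community-standard values for B-form dsDNA at the
    37 °C used in the loop assays: persistence length 50 nm, helical rise
    0.34 nm/bp.  Intercalating dyes (Sytox) perturb both, which is why
    they are configurable.
    """

    persistence_length_nm: float = 50.0
    rise_per_bp_nm: float = 0.34
    temperature_k: float = 310.0

    def __post_init__(self) -> None:
        if self.persistence_length_nm <= 0:
            raise ValueError("persistence_length_nm must be > 0")
        if self.rise_per_bp_nm <= 0:
            raise ValueError("rise_per_bp_nm must be > 0")
        if self.temperature_k <= 0:
            raise ValueError("temperature_k must be > 0")

    @property
    def thermal_energy_pn_nm(self) -> float:
        """kBT in pN·nm."""
        return BOLTZMANN_PN_NM * self.temperature_k


@dataclass(frozen=True)
class TetherGeometry:
    """A doubly tethered DNA: total length in bp and tether span R in µm."""

    total_bp: float
    end_to_end_um: float
    params: WLCParams = field(default_factory=WLCParams)

    def __post_init__(self) -> None:
        if self.total_bp <= 0:
            raise ValueError("total_bp must be > 0")
        if self.end_to_end_um <= 0:
            raise ValueError("end_to_end_um must be > 0")
        if self.end_to_end_um > self.contour_length_um:
            raise ValueError(
                f"end-to-end length {self.end_to_end_um} µm exceeds contour "
                f"length {self.contour_length_um:.3f} µm"
            )

    @property
    def contour_length_um(self) -> float:
        return self.total_bp * self.params.rise_per_bp_nm / 1000.0


@dataclass(frozen=True)
class TensionEstimate:
    """DNA tension inferred from loop size and tether geometry."""

    force_pn: float
    extension_fraction: float
    unlooped_bp: float


def wlc_force(extension_fraction: float, params: WLCParams | None = None) -> float:
    """Marko–Siggia force (pN) at relative extension x = R/L in [0, 1).

    Strictly increasing in x with F(0) = 0; raises
    :class:`OverstretchedError` at x >= 1 and ``ValueError`` for x < 0.
    """
    params = params or WLCParams()
    x = float(extension_fraction)
    if x < 0:
        raise ValueError(f"extension_fraction must be >= 0, got {x}")
    if x >= 1:
        raise OverstretchedError(
            f"extension_fraction {x} >= 1: inextensible WLC diverges"
        )
    kbt_over_lp = params.thermal_energy_pn_nm / params.persistence_length_nm
    return kbt_over_lp * (0.25 / (1.0 - x) ** 2 - 0.25 + x)


def wlc_extension(force_pn: float, params: WLCParams | None = None,
                  tol: float = 1e-6) -> float:
    """Numerically invert :func:`wlc_force`: relative extension at a force.

    Root-bracketing on the monotone force curve; the round-trip error
    ``wlc_force(wlc_extension(F)) - F`` is below ``tol`` (pN).
    """
    params = params or WLCParams()
    f = float(force_pn)
    if f < 0:
        raise ValueError(f"force must be >= 0, got {f}")
    if f == 0:
        return 0.0
    lo, hi = 0.0, 1.0 - 1e-12
    # shrink the upper bracket away from the divergence
    while wlc_force(min(hi, 1 - 1e-12), params) < f:  # pragma: no cover
        hi = 1 - (1 - hi) / 10
    return float(brentq(lambda x: wlc_force(x, params) - f, lo, hi,
                        xtol=1e-12, rtol=8.9e-16))


def tension_at_encounter(loop_bp: float, geometry: TetherGeometry,
                         params: WLCParams | None = None) -> TensionEstimate:
    """DNA tension when a loop of ``loop_bp`` has been extruded.

    The extension fraction is the tether span divided by the contour
    length of the DNA *outside* the loop; the force follows from the WLC.
    Raises :class:`TautDNAError` when the unlooped contour is no longer
    than the tether span (the loop cannot physically be that large).
    """
    params = params or geometry.params
    if loop_bp < 0:
        raise ValueError("loop_bp must be >= 0")
    if loop_bp >= geometry.total_bp:
        raise ValueError("loop_bp must be < total_bp")
    unlooped_bp = geometry.total_bp - loop_bp
    unlooped_contour_um = unlooped_bp * params.rise_per_bp_nm / 1000.0
    if unlooped_contour_um <= geometry.end_to_end_um:
        raise TautDNAError(
            f"unlooped contour {unlooped_contour_um:.3f} µm <= tether span "
            f"{geometry.end_to_end_um} µm: loop of {loop_bp} bp is impossible"
        )
    x = geometry.end_to_end_um / unlooped_contour_um
    return TensionEstimate(force_pn=wlc_force(x, params),
                           extension_fraction=x, unlooped_bp=unlooped_bp)


def offset_tension(geometry: TetherGeometry,
                   params: WLCParams | None = None) -> float:
    """Tension of the tether before any loop is extruded (loop_bp = 0)."""
    return tension_at_encounter(0.0, geometry, params).force_pn


def position_to_bp(position_um: float, geometry: TetherGeometry) -> float:
    """Convert a position along the tether (µm from the labelled end) to bp.

    Uses the mean base-pair density total_bp / R, i.e. positions in
    micrometres are multiplied by the average number of base pairs per
    micrometre of tether span.
    """
    r = geometry.end_to_end_um
    if not 0 <= position_um <= r:
        raise ValueError(f"position {position_um} µm outside [0, {r}] µm")
    return position_um * geometry.total_bp / r


def bp_to_position(bp: float, geometry: TetherGeometry) -> float:
    """Inverse of :func:`position_to_bp`."""
    if not 0 <= bp <= geometry.total_bp:
        raise ValueError(f"bp {bp} outside [0, {geometry.total_bp}]")
    return bp * geometry.end_to_end_um / geometry.total_bp


def step_nm_to_bp(step_nm: float, force_pn: float,
                  params: WLCParams | None = None) -> float:
    """Convert a tweezer extension step (nm) to base pairs at a fixed force.

    At clamped force F the DNA is stretched to a fraction x(F) of its
    contour, so one base pair contributes rise * x(F) nm of extension.
    """
    params = params or WLCParams()
    if force_pn <= 0:
        raise ValueError("force must be > 0 for a defined nm/bp conversion")
    if step_nm < 0:
        raise ValueError("step_nm must be >= 0")
    x = wlc_extension(force_pn, params)
    return step_nm / (params.rise_per_bp_nm * x)
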