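"""Channel geometries for inside-out cross-flow ultrafiltration.

Three membrane conduit shapes are supported:

``CM``
    Hollow cylindrical (tubular/hollow-fiber) membrane of inner radius ``R``.
``FMM``
    Two parallel flat membrane sheets at vertical distance ``2R`` (both
    walls permeable), width ``W``.
``FMS``
    One flat membrane sheet on top of an impermeable flat substrate sheet,
    channel height ``2R``, width ``W``.

The transversal coordinate convention is ``y = 0`` at the centerline, the
(upper) membrane wall at ``y = +R`` and — for FMS — the substrate at
``y = −R``; the axial coordinate runs over ``z ∈ [0, L]`` with the inlet at
``z = 0``.

Each kind carries a fixed set of dimensionless coefficients (λ1, λ2,
hydraulic radius RH, cross-averaged parabola Ūout, membrane-to-cross-section
area ratio M/A, universality factor c) that parametrize the outer
(bulk-flow) solution; :func:`geometry_coefficients` returns them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError

__all__ = [
    "KINDS",
    "ChannelGeometry",
    "GeometryCoefficients",
    "geometry_coefficients",
    "hydraulic_permeability",
    "resolve_Lp",
    "effective_permeability_K",
    "outer_velocity_factors",
]

KINDS = ("CM", "FMM", "FMS")


@dataclass(frozen=True)
class ChannelGeometry:
    """Membrane channel shape and dimensions (SI).

    Exactly one of ``Lp`` or the pair ``(kappa, h)`` must be given: the
    hydraulic permeability is either a direct membrane datum or derived from
    the mean Darcy permeability ``kappa`` and membrane thickness ``h``
    (with the logarithmic curvature correction for CM).

    ``W`` (sheet width, flat kinds) defaults to 1 m; all reported
    per-channel indicators are W-independent.
    """

    kind: str
    R: float
    L: float
    W: float = 1.0
    h: float | None = None
    kappa: float | None = None
    Lp: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"unknown geometry kind {self.kind!r}; expected one of {KINDS}")
        if not (self.R > 0 and self.L > 0 and self.W > 0):
            raise ConfigError("R, L, W must all be positive")
        has_lp = self.Lp is not None
        has_kh = self.kappa is not None or self.h is not None
        if has_lp and has_kh:
            raise ConfigError("give either Lp or (kappa, h), not both")
        if not has_lp:
            if self.kappa is None or self.h is None:
                raise ConfigError("membrane permeability requires Lp or both kappa and h")
            if self.kappa <= 0 or self.h <= 0:
                raise DomainError("kappa and h must be positive")
        elif self.Lp < 0:
            raise DomainError("Lp must be non-negative")
        if self.R / self.L > 0.01:
            warnings.warn(
                f"aspect ratio R/L = {self.R / self.L:.3g} > 0.01: the thin-channel "
                "expansion may be inaccurate",
                stacklevel=2,
            )
        if self.kind in ("FMM", "FMS") and self.R / self.W > 0.01:
            warnings.warn(
                "channel half-height R is not small against the sheet width W; "
                "side-wall effects are neglected",
                stacklevel=2,
            )


@dataclass(frozen=True)
class GeometryCoefficients:
    """Geometry-dependent constants of the outer solution (SI where dimensional)."""

    kind: str
    lambda1: float
    lambda2: float
    RH: float              # hydraulic radius (m)
    Ubar_out: float        # cross-sectional average of the parabola Uout
    M_over_A: float        # membrane-to-cross-section area ratio (dimensionless, ~L/R)
    K_over_Kstar: float    # K^2 in units of K*^2 = eta_s*Lp*L^2/R^3, = lambda1*lambda2*(R/RH)^3
    c: float               # universality coefficient entering gamma0
    A: float               # cross-section area (m^2)
    M: float               # lumen-side membrane area (m^2)
    H: float | None        # curvature-corrected membrane thickness (m), if h given


def geometry_coefficients(geom: ChannelGeometry) -> GeometryCoefficients:
    """Constant coefficient set for the given channel kind.

    CM:  (λ1, λ2, RH, Ūout, M/A) = (1, 2,  R/2, 1/2, 2L/R),   c = 1/8
    FMM: (2, 3/2, R, 2/3, L/R),   c = 1/3
    FMS: (2, 3/4, R, 2/3, L/(2R)), c = 2/3

    ``K_over_Kstar`` records the squared-permeability scaling
    λ1·λ2·(R/RH)³ = {16, 3, 3/2}, i.e. K² in units of ηs·Lp·L²/R³.

    Areas: A = πR² and M = 2πRL for CM; A = 2RW (height 2R × width W) with
    M = 2WL (FMM) or WL (FMS) for the flat kinds.  Note the identity
    λ2 = RH·M/(L·A·Ūout) ties the table together.
    """
    R, L, W = geom.R, geom.L, geom.W
    if geom.kind == "CM":
        H = R * np.log1p(geom.h / R) if geom.h is not None else None
        return GeometryCoefficients(
            "CM", 1.0, 2.0, R / 2.0, 0.5, 2.0 * L / R, 16.0, 1.0 / 8.0,
            np.pi * R**2, 2.0 * np.pi * R * L, H,
        )
    if geom.kind == "FMM":
        return GeometryCoefficients(
            "FMM", 2.0, 1.5, R, 2.0 / 3.0, L / R, 3.0, 1.0 / 3.0,
            2.0 * R * W, 2.0 * W * L, geom.h,
        )
    return GeometryCoefficients(
        "FMS", 2.0, 0.75, R, 2.0 / 3.0, L / (2.0 * R), 1.5, 2.0 / 3.0,
        2.0 * R * W, W * L, geom.h,
    )


def hydraulic_permeability(geom: ChannelGeometry, eta_s: float) -> float:
    """Hydraulic permeability Lp = κ/(ηs·H) in m/(Pa·s) from Darcy data.

    H is the curvature-corrected thickness: ``R·ln(1 + h/R)`` for CM (the
    logarithmic correction matters because h and R are comparable in UF)
    and plain ``h`` for the flat kinds.
    """
    if geom.kappa is None or geom.h is None:
        raise ConfigError("hydraulic_permeability needs kappa and h on the geometry")
    if geom.kind == "CM":
        H = geom.R * np.log1p(geom.h / geom.R)
    else:
        H = geom.h
    return geom.kappa / (eta_s * H)


def resolve_Lp(geom: ChannelGeometry, eta_s: float) -> float:
    """Hydraulic permeability, whichever way it was specified."""
    if geom.Lp is not None:
        return geom.Lp
    return hydraulic_permeability(geom, eta_s)


def effective_permeability_K(geom: ChannelGeometry, eta_s: float) -> float:
    """Dimensionless effective permeability K = sqrt(λ1·λ2·ηs·Lp·L²/RH³).

    K measures the overall solvent permeability relative to the axial
    Poiseuille resistance; K² ≪ 1 means the axial pressure profile stays
    nearly linear.  The squared ratio K²/(ηs·Lp·L²/R³) = λ1λ2(R/RH)³ equals
    {16, 3, 3/2} for {CM, FMM, FMS} (``GeometryCoefficients.K_over_Kstar``).
    """
    c = geometry_coefficients(geom)
    Lp = resolve_Lp(geom, eta_s)
    return float(np.sqrt(c.lambda1 * c.lambda2 * eta_s * Lp * geom.L**2 / c.RH**3))


def outer_velocity_factors(geom: ChannelGeometry, y):
    """Outer (bulk) velocity shape factors (Uout, Vout) at transversal position y.

    Uout(y) = 1 − (y/R)² for every kind.  The transversal factor is fixed by
    incompressibility and the wall normalization Vout(R) = 1:

    * CM:  Vout = 2t − t³          (t = y/R ≥ 0; max at t = sqrt(2/3))
    * FMM: Vout = (3t − t³)/2      (odd in y)
    * FMS: Vout = (3t − t³ + 2)/4  (vanishes at the substrate t = −1)

    For CM/FMM negative y is accepted and treated by (anti)symmetry:
    Uout is even, Vout odd.
    """
    y = np.asarray(y, dtype=float)
    t = y / geom.R
    if np.any(np.abs(t) > 1.0 + 1e-12):
        raise DomainError("transversal coordinate outside the channel, |y| > R")
    u = 1.0 - t**2
    if geom.kind == "CM":
        v = 2.0 * t - t**3
    elif geom.kind == "FMM":
        v = 0.5 * (3.0 * t - t**3)
    else:
        v = 0.25 * (3.0 * t - t**3 + 2.0)
    return u, v
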