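"""Outer (bulk-flow) solution: axial pressure, permeate flux, centerline velocity.

Outside the thin concentration-polarization layer the flow is a lubrication
(Poiseuille-like) flow whose axial pressure profile obeys the linear
two-point problem

    P''(z) = (K/L)^2 * ( P(z) - Pperm - Pi(phi_w(z)) ),

with K the dimensionless effective permeability, subject to the outlet
pressure P(L) = PL and the inlet centerline-velocity condition
P'(0) = -lambda1*eta_s*u0/RH^2.  The permeate flux follows pointwise from
the Darcy-Starling relation vw = Lp*(P - Pperm - Pi(phi_w)) and the
centerline velocity from u0(z) = -RH^2/(lambda1*eta_s)*P'(z).

The ODE is solved exactly: cosh/sinh homogeneous solutions plus a
variation-of-parameters particular integral evaluated with cumulative
Simpson quadrature, so the homogeneous (phi_b = 0) limit matches the
closed form to machine precision and u0(z) is an analytic derivative
(no numerical differentiation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson, simpson

from .dispersion import DispersionModel, osmotic_pressure
from .errors import ConfigError, FlowExhaustionError
from .geometry import (
    ChannelGeometry,
    effective_permeability_K,
    geometry_coefficients,
    resolve_Lp,
)

__all__ = [
    "OperatingConditions",
    "ResolvedConditions",
    "PressureSolution",
    "resolve_conditions",
    "linearized_pressure",
    "solve_pressure",
    "centerline_velocity",
]

ATM = 101325.0


@dataclass(frozen=True)
class OperatingConditions:
    """Operating inputs of a UF run: feed, inlet velocity, pressures.

    Exactly one of ``u0`` (centerline inlet velocity) / ``ubar0``
    (cross-section averaged inlet velocity) must be given, and exactly one
    of ``TMP_lin`` (channel-length-averaged linearized transmembrane
    pressure) / ``Pperm`` (permeate-side pressure).  The outlet pressure
    ``PL`` defaults to 1 atm.
    """

    phi_b: float
    u0: float | None = None
    ubar0: float | None = None
    PL: float = ATM
    TMP_lin: float | None = None
    Pperm: float | None = None

    def __post_init__(self) -> None:
        if (self.u0 is None) == (self.ubar0 is None):
            raise ConfigError("give exactly one of u0 (centerline) or ubar0 (cross average)")
        given = self.u0 if self.u0 is not None else self.ubar0
        if not given > 0:
            raise ConfigError("inlet velocity must be positive")
        if (self.TMP_lin is None) == (self.Pperm is None):
            raise ConfigError("give exactly one of TMP_lin or Pperm")
        if self.TMP_lin is not None and not self.TMP_lin > 0:
            raise ConfigError("linearized TMP must be positive")


@dataclass(frozen=True)
class ResolvedConditions:
    """Operating conditions with all alternatives resolved to canonical form."""

    phi_b: float
    u0: float          # centerline inlet velocity (m/s)
    ubar0: float       # cross-section averaged inlet velocity (m/s)
    PL: float          # outlet pressure (Pa)
    Pperm: float       # permeate pressure (Pa)
    TMP_lin: float     # length-averaged linearized TMP (Pa)
    P_l0: float        # inlet pressure of the linearized (Lp=0) profile (Pa)
    Lp: float          # hydraulic permeability (m/(Pa s))


def resolve_conditions(
    geom: ChannelGeometry, model: DispersionModel, ops: OperatingConditions
) -> ResolvedConditions:
    """Fill in the dependent operating quantities.

    The parabolic inlet profile ties ubar0 = Ubar_out * u0.  The linearized
    (impermeable-channel) inlet pressure is P_l0 = u0*lambda1*eta_s*L/RH^2 + PL
    and the linearized TMP is <dTP_l> = (P_l0 + PL)/2 - Pperm, inverted for
    Pperm when the TMP is the given input.
    """
    c = geometry_coefficients(geom)
    if ops.u0 is not None:
        u0 = ops.u0
        ubar0 = c.Ubar_out * u0
    else:
        ubar0 = ops.ubar0
        u0 = ubar0 / c.Ubar_out
    P_l0 = u0 * c.lambda1 * model.eta_s * geom.L / c.RH**2 + ops.PL
    if ops.TMP_lin is not None:
        tmp = ops.TMP_lin
        pperm = 0.5 * (P_l0 + ops.PL) - tmp
    else:
        pperm = ops.Pperm
        tmp = 0.5 * (P_l0 + ops.PL) - pperm
        if tmp <= 0:
            raise ConfigError(
                f"permeate pressure {pperm} Pa gives non-positive linearized TMP {tmp} Pa"
            )
    return ResolvedConditions(
        phi_b=ops.phi_b, u0=u0, ubar0=ubar0, PL=ops.PL, Pperm=pperm,
        TMP_lin=tmp, P_l0=P_l0, Lp=resolve_Lp(geom, model.eta_s),
    )


def linearized_pressure(
    geom: ChannelGeometry, model: DispersionModel, ops: OperatingConditions, z=None
):
    """Linearized (Hagen-Poiseuille) pressure bookkeeping.

    Returns ``(P_l0, tmp_profile, tmp_avg, Pperm)`` where ``tmp_profile`` is
    the linearized transmembrane pressure dTP_l(z) = P_l(z) - Pperm on the
    requested axial nodes (outlet-anchored linear profile), ``tmp_avg`` its
    channel-length average, and ``Pperm`` the permeate pressure consistent
    with the inputs.
    """
    rc = resolve_conditions(geom, model, ops)
    if z is None:
        z = np.linspace(0.0, geom.L, 129)
    z = np.asarray(z, dtype=float)
    P_lin = rc.P_l0 - (rc.P_l0 - rc.PL) * z / geom.L
    return rc.P_l0, P_lin - rc.Pperm, rc.TMP_lin, rc.Pperm


@dataclass
class PressureSolution:
    """Axial pressure/flux/velocity profiles of the outer solution."""

    z: np.ndarray        # axial nodes (m)
    P: np.ndarray        # lumen pressure (Pa)
    vw: np.ndarray       # permeate flux through the membrane wall (m/s, outward > 0)
    u0_z: np.ndarray     # centerline axial velocity (m/s)
    TMP_actual: float    # <P> - Pperm (Pa)
    Pperm: float
    K: float             # dimensionless effective permeability

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"z": self.z, "P": self.P, "vw": self.vw, "u0": self.u0_z})


def solve_pressure(
    geom: ChannelGeometry,
    model: DispersionModel,
    ops: OperatingConditions,
    phi_w,
    z=None,
    check_exhaustion: bool = True,
) -> PressureSolution:
    """Solve the axial pressure problem for a given wall-concentration profile.

    Parameters
    ----------
    phi_w
        Wall volume fraction profile on the axial nodes ``z`` (defaults to a
        uniform 129-node grid on [0, L]).
    check_exhaustion
        Raise :class:`FlowExhaustionError` if the centerline velocity drops
        to zero anywhere (disabled inside the fixed-point iteration, where
        transient exhaustion of an unconverged iterate is harmless).

    Returns the exact solution of P'' = (K/L)^2 (P - Pperm - Pi(phi_w(z)))
    with P(L) = PL and the centerline inlet-velocity slope condition;
    vw and u0(z) follow analytically.
    """
    rc = resolve_conditions(geom, model, ops)
    c = geometry_coefficients(geom)
    if z is None:
        z = np.linspace(0.0, geom.L, 129)
    z = np.asarray(z, dtype=float)
    phi_w = np.broadcast_to(np.asarray(phi_w, dtype=float), z.shape)
    L = geom.L
    Pi_w = osmotic_pressure(phi_w, model)
    K = effective_permeability_K(geom, model.eta_s)
    slope0 = -c.lambda1 * model.eta_s * rc.u0 / c.RH**2   # P'(0)

    if K == 0.0:
        Q = (rc.PL - rc.Pperm) + slope0 * (z - L)
        Qp = np.full_like(z, slope0)
    else:
        k = K / L
        ch, sh = np.cosh(k * z), np.sinh(k * z)
        C = cumulative_simpson(ch * Pi_w, x=z, initial=0.0)
        S = cumulative_simpson(sh * Pi_w, x=z, initial=0.0)
        part = -k * (sh * C - ch * S)          # particular integral, part(0)=part'(0)=0
        dpart = -(k**2) * (ch * C - sh * S)
        B = slope0 / k
        A = (rc.PL - rc.Pperm - B * np.sinh(K) - part[-1]) / np.cosh(K)
        Q = A * ch + B * sh + part
        Qp = k * (A * sh + B * ch) + dpart

    P = Q + rc.Pperm
    vw = rc.Lp * (Q - Pi_w)
    u0_z = -(c.RH**2) / (c.lambda1 * model.eta_s) * Qp
    if check_exhaustion and np.any(u0_z <= 0.0):
        raise FlowExhaustionError(
            "axial centerline velocity reaches zero inside the channel: "
            "the permeate drain exhausts the axial feed at these operating conditions"
        )
    tmp_actual = float(simpson(Q, x=z) / L)
    return PressureSolution(z=z, P=P, vw=vw, u0_z=u0_z, TMP_actual=tmp_actual,
                            Pperm=rc.Pperm, K=K)


def centerline_velocity(psol: PressureSolution) -> np.ndarray:
    """Centerline axial velocity profile u0(z) of a pressure solution (m/s)."""
    return psol.u0_z
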