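"""Global process indicators, dimensionless groups and validity reporting.

The efficiency of a cross-flow UF operating point is summarized by

* the length-averaged permeate flux <vw> and wall osmotic pressure <Pi>,
* the solvent recovery beta = Qperm/Q0 = M<vw>/(A*ubar0), i.e. the fraction
  of the feed volume recovered as permeate,
* the concentration factor alpha = 1/(1 - beta) (outlet enrichment),
* the transversal Peclet number PeR = R*Lp*<dTP_l>/D0 whose inverse is the
  boundary-layer smallness parameter (CP-layer thickness delta_CP = R/PeR),
* the pure-solvent recovery beta0 = (M/A)*Lp*TMP/ubar0 (the phi_b = 0 line
  that beta approaches at small TMP or large inlet velocity).

Remarkably, beta is governed by only three dimensionless variables:
PeR, beta0/PeR = M*D0/(A*R*ubar0) and
gamma0/PeR = (9c/2)*(phi_b*Lp*eta_s*R/a^2)*(beta0/PeR), with the geometry
factor c = {1/8, 1/3, 2/3} for {CM, FMM, FMS}.  The identity
beta = <vw>*(R/D0)*(beta0/PeR) ties the reduced permeate flux to beta.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.integrate import simpson

from .dispersion import DispersionModel, osmotic_pressure, single_particle_peclet, viscosity
from .errors import DomainError, FlowExhaustionError
from .geometry import ChannelGeometry, geometry_coefficients
from .outer import OperatingConditions, resolve_conditions
from .solver import SolutionState

__all__ = [
    "IndicatorReport",
    "solvent_recovery",
    "beta0",
    "concentration_factor",
    "peclet_transversal",
    "universality_variables",
    "validity_report",
    "compute_indicators",
]

#: Default dispersion mass density for the Reynolds number (dilute aqueous feed).
RHO_DEFAULT = 1000.0


@dataclass
class IndicatorReport:
    """Global indicators of one converged operating point (SI units)."""

    vw_mean: float            # <vw> (m/s)
    Pi_mean: float            # <Pi(phi_w)> (Pa)
    TMP: float                # linearized TMP input (Pa)
    TMP_actual: float         # <P> - Pperm of the solved profile (Pa)
    beta: float
    beta0: float
    alpha: float
    PeR: float
    PeR_rounded: int
    eps_delta: float          # 1/PeR
    delta_CP: float           # R/PeR (m)
    beta0_over_PeR: float
    gamma0_over_PeR: float
    Pea: float                # shear Peclet at the inlet wall
    Re: float                 # channel Reynolds number
    phi_w_outlet: float
    validity: dict

    def to_dict(self) -> dict:
        return asdict(self)


def solvent_recovery(state: SolutionState) -> float:
    """Solvent recovery beta = Qperm/Q0 = M*<vw>/(A*ubar0).

    Cross-checked internally against 1 - QL/Q0 from the outlet centerline
    velocity (the two agree to quadrature precision by construction of the
    outer solve).
    """
    c = geometry_coefficients(state.geom)
    vw_mean = simpson(state.pressure.vw, x=state.z) / state.geom.L
    b = c.M_over_A * vw_mean / state.resolved.ubar0
    if b >= 1.0:
        raise FlowExhaustionError(f"solvent recovery beta = {b:.3f} >= 1")
    return float(b)


def beta0(geom: ChannelGeometry, model: DispersionModel,
          ops: OperatingConditions) -> float:
    """Pure-solvent recovery beta0 = (M/A)*Lp*TMP/ubar0 (phi_b = 0 prediction).

    Linear in TMP; the geometry enters only through M/A, hence the exact
    4:2:1 ratio of CM:FMM:FMS at equal TMP, ubar0, R, L, Lp.
    """
    rc = resolve_conditions(geom, model, ops)
    c = geometry_coefficients(geom)
    return float(c.M_over_A * rc.Lp * rc.TMP_lin / rc.ubar0)


def concentration_factor(beta: float) -> float:
    """Concentration factor alpha = 1/(1 - beta) (outlet-to-feed enrichment)."""
    if not 0.0 <= beta < 1.0:
        raise DomainError(f"beta must lie in [0, 1), got {beta}")
    return 1.0 / (1.0 - beta)


def peclet_transversal(geom: ChannelGeometry, model: DispersionModel,
                       ops: OperatingConditions) -> float:
    """Transversal Peclet number PeR = R*Lp*<dTP_l>/D0.

    Ratio of the transversal diffusion time R^2/D0 to the advection time
    R/(Lp*<dTP_l>); its inverse is the boundary-layer smallness parameter.
    """
    rc = resolve_conditions(geom, model, ops)
    return float(geom.R * rc.Lp * rc.TMP_lin / model.D0)


def universality_variables(geom: ChannelGeometry, model: DispersionModel,
                           ops: OperatingConditions) -> tuple[float, float]:
    """The TMP-independent pair (beta0/PeR, gamma0/PeR).

    beta0/PeR = M*D0/(A*R*ubar0) and
    gamma0/PeR = (9c/2)*(phi_b*Lp*eta_s*R/a^2)*(beta0/PeR).
    Together with PeR itself these three variables determine beta.
    """
    rc = resolve_conditions(geom, model, ops)
    c = geometry_coefficients(geom)
    b0_per = c.M_over_A * model.D0 / (geom.R * rc.ubar0)
    g0_per = (4.5 * c.c) * (ops.phi_b * rc.Lp * model.eta_s * geom.R / model.a**2) * b0_per
    return float(b0_per), float(g0_per)


def validity_report(geom: ChannelGeometry, model: DispersionModel,
                    ops: OperatingConditions, beta: float | None = None,
                    rho: float = RHO_DEFAULT) -> dict:
    """Boolean validity flags of the boundary-layer model (report-only).

    Checks: strong Brownian motion (Pea <= 0.1 at the inlet wall shear rate
    2*u0/R), small aspect ratio R/L, laminar flow (Re <= 2000), negligible
    inertia on the channel length (Re*R/L < 0.1), small feed concentration
    (phi_b*PeR < 1) and — when a solution is supplied — significant
    permeation beta >= 1/PeR.
    """
    rc = resolve_conditions(geom, model, ops)
    c = geometry_coefficients(geom)
    shear = 2.0 * rc.u0 / geom.R
    pea = single_particle_peclet(shear, model)
    per = peclet_transversal(geom, model, ops)
    re = 4.0 * c.RH * rc.ubar0 * rho / float(viscosity(ops.phi_b, model))
    flags = {
        "strong_brownian_motion": bool(pea <= 0.1),
        "small_aspect_ratio": bool(geom.R / geom.L <= 0.01),
        "laminar_flow": bool(re <= 2000.0),
        "no_inertial_effects": bool(re * geom.R / geom.L < 0.1),
        "small_feed_concentration": bool(ops.phi_b * per < 1.0),
    }
    if beta is not None:
        flags["significant_permeation"] = bool(beta >= 1.0 / per)
    return flags


def compute_indicators(state: SolutionState, rho: float = RHO_DEFAULT) -> IndicatorReport:
    """Assemble the full indicator report for a converged solution."""
    geom, model, ops = state.geom, state.model, state.ops
    rc = state.resolved
    z = state.z
    vw_mean = float(simpson(state.pressure.vw, x=z) / geom.L)
    pi_mean = float(simpson(osmotic_pressure(state.phi_w, model), x=z) / geom.L)
    b = solvent_recovery(state)
    b0 = beta0(geom, model, ops)
    per = peclet_transversal(geom, model, ops)
    b0_per, g0_per = universality_variables(geom, model, ops)
    shear = 2.0 * rc.u0 / geom.R
    c = geometry_coefficients(geom)
    re = 4.0 * c.RH * rc.ubar0 * rho / float(viscosity(ops.phi_b, model))
    return IndicatorReport(
        vw_mean=vw_mean,
        Pi_mean=pi_mean,
        TMP=rc.TMP_lin,
        TMP_actual=state.pressure.TMP_actual,
        beta=b,
        beta0=b0,
        alpha=concentration_factor(b),
        PeR=per,
        PeR_rounded=int(round(per)),
        eps_delta=1.0 / per if per > 0 else np.inf,
        delta_CP=geom.R / per if per > 0 else np.inf,
        beta0_over_PeR=b0_per,
        gamma0_over_PeR=g0_per,
        Pea=float(single_particle_peclet(shear, model)),
        Re=float(re),
        phi_w_outlet=float(state.phi_w[-1]),
        validity=validity_report(geom, model, ops, beta=b, rho=rho),
    )
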