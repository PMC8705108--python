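"""Fixed-point solver for the wall concentration profile phi_w(z).

The wall profile is the one unknown closing the matched boundary-layer
solution.  It is pinned down by cross-sectional particle-flux conservation:
with longitudinal diffusion neglected (an O(1/PeR^2) contribution),

    Jz_bar(z) = cross average of phi(y,z)*u(y,z) = Jz_bar0 = phi_b * ubar0

for every z, since the membrane retains all particles.  The solver iterates

  1. pressure / permeate-flux / centerline-velocity profiles from the
     current phi_w (outer problem, exact linear ODE solve),
  2. matched concentration and velocity fields, cross-section flux Jz_bar
     (inner problem, film parametrization),
  3. damped Newton update of the CP-layer amplitude

     phi_w - phi_b  <-  (phi_w - phi_b) + omega * (Jz_bar0 - Jz_bar) / S,

     where S is the cross average of exp(-E)*u — the analytic sensitivity
     of Jz_bar to the amplitude, since the amplitude multiplies exp(-E)
     in the matched concentration field,

until the flux-conservation residual max_z |Jz_bar/Jz_bar0 - 1| falls
below tolerance.  The update direction is the physical feedback: where
the axial flux falls short of the inlet value, the excess flux carried by
the CP layer — controlled by the wall concentration — must grow to make
up exactly the deficit.

The wall value at the inlet itself is pinned to the feed concentration,
phi_w(0) = phi_b (no CP layer has developed at z = 0), and the conserved
reference flux Jz_bar0 is the solution's own inlet value Jz_bar(0); it
equals the nominal phi_b*ubar0 up to the O(1/PeR) matching correction of
the concentration ansatz (a fraction of a percent at PeR ~ 78).

Safeguards (inactive at interior fixed points): the per-step ratio is
clipped to [1/3, 3], and phi_w is capped so the wall osmotic pressure
stays below the local transmembrane pressure of the previous iterate —
early iterates at strong-permeation conditions would otherwise transiently
exhaust the axial flow before the osmotic back-pressure has built up.

Everything is deterministic; identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dispersion import (
    PHI_FREEZING,
    DispersionModel,
    phi_at_osmotic_pressure,
)
from .errors import (
    ConvergenceError,
    FlowExhaustionError,
    FreezingError,
    PermeateReversalError,
)
from .geometry import ChannelGeometry
from .inner import InnerNumerics, MatchedFields, cross_section_averages
from .outer import (
    OperatingConditions,
    PressureSolution,
    ResolvedConditions,
    resolve_conditions,
    solve_pressure,
)

__all__ = ["Numerics", "SolutionState", "inlet_flux", "cross_section_flux", "solve"]


@dataclass(frozen=True)
class Numerics:
    """Numerical controls of the fixed-point solve."""

    n_z: int = 129                 # uniform axial nodes (Simpson-compatible: odd)
    tol: float = 1e-6              # sup-norm relative flux-conservation residual
    max_iter: int = 500
    omega: float = 0.5             # under-relaxation exponent of the multiplicative update
    ratio_clip: float = 3.0        # per-step bound on the update ratio
    freeze_margin: float = 1e-3    # keep phi_w below phi_f by this margin
    pi_ceiling: float = 0.99       # cap Pi(phi_w) at this fraction of local TMP
    inner: InnerNumerics = field(default_factory=InnerNumerics)


@dataclass
class SolutionState:
    """Converged (or best-effort) solution bundle of one UF operating point."""

    geom: ChannelGeometry
    model: DispersionModel
    ops: OperatingConditions
    resolved: ResolvedConditions
    numerics: Numerics
    z: np.ndarray
    phi_w: np.ndarray
    pressure: PressureSolution
    Jz_bar: np.ndarray            # cross-section averaged axial particle flux density
    Jz_ex_bar: np.ndarray         # excess part, Jz_bar - phi_b * u_bar
    u_bar: np.ndarray             # cross average of the matched axial velocity
    phi_bar: np.ndarray           # cross average of the concentration field
    Jz_bar0: float                # inlet value phi_b * ubar0
    residual_history: list
    iterations: int
    converged: bool

    _fields: MatchedFields | None = None

    @property
    def fields(self) -> MatchedFields:
        """Lazy pointwise evaluator of the matched 2-D fields."""
        if self._fields is None:
            self._fields = MatchedFields(
                self.geom, self.model, self.z, self.phi_w,
                np.maximum(self.pressure.vw, 0.0), self.pressure.u0_z,
                self.numerics.inner,
            )
        return self._fields

    def to_frame(self):
        """Axial profiles as a tidy DataFrame (SI columns)."""
        import pandas as pd

        jz0 = self.Jz_bar0 if self.Jz_bar0 > 0 else 1.0
        return pd.DataFrame({
            "z_m": self.z,
            "phi_w": self.phi_w,
            "P_Pa": self.pressure.P,
            "vw_m_s": self.pressure.vw,
            "u0_m_s": self.pressure.u0_z,
            "Jz_ex_over_Jz0": self.Jz_ex_bar / jz0,
        })


def inlet_flux(ops: OperatingConditions, geom: ChannelGeometry,
               model: DispersionModel) -> float:
    """Inlet cross-section averaged axial particle flux Jz_bar0 = phi_b * ubar0.

    Fixed by the inlet boundary conditions alone: uniform feed concentration
    across a parabolic velocity profile.
    """
    rc = resolve_conditions(geom, model, ops)
    return ops.phi_b * rc.ubar0


def cross_section_flux(state: SolutionState, z) -> np.ndarray:
    """Cross-section averaged axial particle flux at axial position(s) z."""
    return np.interp(np.asarray(z, dtype=float), state.z, state.Jz_bar)


def _final_checks(psol: PressureSolution, phi_w, numerics: Numerics):
    if np.any(psol.u0_z <= 0.0):
        raise FlowExhaustionError(
            "converged solution has vanishing axial flow inside the channel "
            "(permeate drain exhausts the feed); reduce TMP or raise the inlet velocity"
        )
    if np.any(psol.vw < 0.0):
        raise PermeateReversalError(
            "converged solution has locally reversed permeate flux "
            "(wall osmotic pressure exceeds the transmembrane pressure)"
        )
    if np.max(phi_w) >= PHI_FREEZING - 2.0 * numerics.freeze_margin:
        raise FreezingError(
            f"wall concentration reached the freezing transition "
            f"(max phi_w = {np.max(phi_w):.4f}): cake formation, outside the "
            "fluid-state model"
        )


def solve(
    geom: ChannelGeometry,
    model: DispersionModel,
    ops: OperatingConditions,
    numerics: Numerics | None = None,
) -> SolutionState:
    """Solve one steady-state cross-flow UF operating point.

    Raises
    ------
    FreezingError
        phi_w would reach the hard-sphere freezing transition (cake
        formation) — typically too large a TMP for the particle size.
    FlowExhaustionError
        The axial flow is exhausted by the permeate drain.
    PermeateReversalError
        Locally negative permeate flux at the fixed point.
    ConvergenceError
        Fixed point not reached within ``max_iter``.
    """
    numerics = numerics or Numerics()
    rc = resolve_conditions(geom, model, ops)
    if rc.Lp > 0.0 and rc.PL - rc.Pperm <= 0.0:
        # vw(L) = Lp*(PL - Pperm - Pi) <= Lp*(PL - Pperm): reversal is certain
        raise PermeateReversalError(
            "outlet pressure does not exceed the permeate pressure "
            f"(PL - Pperm = {rc.PL - rc.Pperm:.1f} Pa): the permeate flux "
            "reverses near the outlet; the TMP is too small against the "
            "axial pressure drop"
        )
    z = np.linspace(0.0, geom.L, numerics.n_z)
    phi_b = model.phi_b

    def build_state(phi_w, psol, av, history, iters, converged):
        jz = av["Jz_bar"]
        return SolutionState(
            geom=geom, model=model, ops=ops, resolved=rc, numerics=numerics,
            z=z, phi_w=phi_w, pressure=psol,
            Jz_bar=jz, Jz_ex_bar=jz - phi_b * av["u_bar"],
            u_bar=av["u_bar"], phi_bar=av["phi_bar"], Jz_bar0=float(jz[0]),
            residual_history=history, iterations=iters, converged=converged,
        )

    # trivial operating points: pure solvent or impermeable membrane
    if phi_b == 0.0 or rc.Lp == 0.0:
        phi_w = np.full_like(z, phi_b)
        psol = solve_pressure(geom, model, ops, phi_w, z)
        av = cross_section_averages(phi_w, np.maximum(psol.vw, 0.0), psol.u0_z,
                                    model, geom, numerics.inner)
        return build_state(phi_w, psol, av, [0.0], 1, True)

    # gentle ramp above phi_b; the inlet node carries no CP layer
    phi_w = phi_b * (1.0 + 0.5 * z / geom.L)
    omega = numerics.omega
    prev_res = np.inf
    history: list[float] = []
    freezing_bound = False

    for it in range(1, numerics.max_iter + 1):
        psol = solve_pressure(geom, model, ops, phi_w, z, check_exhaustion=False)
        vw_eff = np.maximum(psol.vw, 0.0)
        av = cross_section_averages(phi_w, vw_eff, psol.u0_z, model, geom,
                                    numerics.inner)
        jz = av["Jz_bar"]
        jz0 = jz[0]               # conserved reference: the solution's inlet flux
        res = float(np.max(np.abs(jz / jz0 - 1.0)))
        history.append(res)
        if res <= numerics.tol:
            _final_checks(psol, phi_w, numerics)
            return build_state(phi_w, psol, av, history, it, True)

        if res > prev_res:
            omega = max(omega / 2.0, 1.0 / 64.0)
        prev_res = res

        gain = av["layer_gain"]
        step = np.where(gain > 0.0, (jz0 - jz) / np.where(gain > 0.0, gain, 1.0),
                        0.0)
        delta = phi_w - phi_b
        delta_new = delta + omega * step
        # per-step growth cap against overshoot from a nearly flat start
        delta_new = np.minimum(delta_new,
                               np.maximum(numerics.ratio_clip * delta,
                                          10.0 * phi_b))
        delta_new[0] = 0.0        # no CP layer at the inlet

        # osmotic-pressure ceiling from the previous iterate's local TMP
        q = psol.P - psol.Pperm
        pi_cap = phi_at_osmotic_pressure(numerics.pi_ceiling * np.maximum(q, 0.0),
                                         model)
        ceiling = np.minimum(PHI_FREEZING - numerics.freeze_margin,
                             np.maximum(pi_cap, phi_b))
        freezing_bound = bool(
            np.any(phi_b + delta_new >= PHI_FREEZING - numerics.freeze_margin)
        )
        phi_w = np.clip(phi_b + delta_new, phi_b, ceiling)

    if freezing_bound:
        raise FreezingError(
            "wall concentration is driven to the freezing transition "
            "(cake formation): lower the TMP or increase the inlet velocity"
        )
    raise ConvergenceError(
        f"flux-conservation fixed point not converged after {numerics.max_iter} "
        f"iterations (last residual {history[-1]:.3e})"
    )
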