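"""Concentration-polarization layer: inner solution and matched fields.

Inside the thin CP layer the transversal advection-diffusion balance
integrates to a generalized film model.  With the dimensionless film
exponent

    E(y, z) = vw(z) * Int_y^R dy' / D(phi(y', z)),

the matched (inner + outer) concentration field is

    phi = (phi_w - phi_b) * exp(-E) + phi_b * (1 - E*exp(-E)),

which equals phi_w at the wall (E = 0) and relaxes to the bulk feed value
phi_b for E >> 1.  The axial velocity is u = u0(z) * U(y, z) with the
viscosity-weighted longitudinal factor

    U(y) = (1 + y/R) * Int_y^R eta^-1 dy' / Int_0^R eta^-1 dy',

which reduces exactly to the parabola 1 - (y/R)^2 for constant viscosity,
and the transversal velocity is v = vw(z) * Vout(y).

Because phi depends on y only through E, the layer is parametrized by E
itself: y(E) = R - (1/vw) * Int_0^E D(phi(E')) dE' (the film ODE
dE/dy = -vw/D in inverse form).  All cross-sectional quadratures are
evaluated on a fixed E grid, vectorized over the axial nodes, with the
bulk region beyond the grid (where phi - phi_b ~ 1e-16) handled by exact
low-order polynomial quadrature.  For FMM the layer is solved on [0, R]
and mirrored; for FMS the single layer sits at the top membrane wall and
the substrate side is pure bulk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .dispersion import DispersionModel, gradient_diffusion, viscosity
from .errors import DomainError
from .geometry import ChannelGeometry, outer_velocity_factors

__all__ = [
    "InnerNumerics",
    "matched_concentration",
    "cross_section_averages",
    "MatchedFields",
]


@dataclass(frozen=True)
class InnerNumerics:
    """Discretization of the film-exponent grid and bulk quadrature.

    The E grid is dense on [0, e_split] where the concentration varies
    (decay scale E ~ 1) and coarser on the tail up to e_max, beyond which
    the matched field is bulk to ~1e-16.  n_bulk=5 gives composite Simpson,
    exact for the cubic bulk integrands.
    """

    n_e_layer: int = 321
    e_split: float = 8.0
    n_e_tail: int = 81
    e_max: float = 40.0
    n_bulk: int = 5

    def e_grid(self) -> np.ndarray:
        head = np.linspace(0.0, self.e_split, self.n_e_layer)
        tail = np.linspace(self.e_split, self.e_max, self.n_e_tail)[1:]
        return np.concatenate([head, tail])


def matched_concentration(E, phi_w, phi_b):
    """Matched asymptotic volume fraction at film exponent E.

    phi = (phi_w - phi_b)*exp(-E) + phi_b*(1 - E*exp(-E)).  E=0 gives the
    wall value, E -> inf the bulk feed value; the -phi_b*E*exp(-E) term is
    the multiplicative matching correction in the layer/bulk transition.
    """
    E = np.asarray(E, dtype=float)
    ee = np.exp(-E)
    return (phi_w - phi_b) * ee + phi_b * (1.0 - E * ee)


def _take(arr, idx):
    return np.take_along_axis(arr, idx[:, None], axis=1)[:, 0]


def _cum_at_level(y, E, pairs, level):
    """Evaluate cumulative-trapezoid integrals at the E where y crosses ``level``.

    ``y`` is (Nz, NE), non-increasing along axis 1.  ``pairs`` is a list of
    (integrand, cumulative) arrays of the same shape.  Returns
    (crossed, values): per row, the cumulative value at the crossing when
    the level is reached inside the grid, else the full-grid value.
    The partial cell is integrated with the trapezoid rule on the linearly
    interpolated integrand (second-order consistent with the full rule).
    """
    nz, ne = y.shape
    idx = (y > level).sum(axis=1)          # first index at/below level; ne if none
    crossed = idx < ne
    i1 = np.clip(idx, 1, ne - 1)
    i0 = i1 - 1
    y0, y1 = _take(y, i0), _take(y, i1)
    dy = y0 - y1
    theta = np.where(dy > 0, (y0 - level) / np.where(dy > 0, dy, 1.0), 0.0)
    theta = np.clip(theta, 0.0, 1.0)
    dE = E[i1] - E[i0]
    out = []
    for g, G in pairs:
        g0, g1 = _take(g, i0), _take(g, i1)
        gs = g0 + theta * (g1 - g0)
        Gs = _take(G, i0) + 0.5 * theta * dE * (g0 + gs)
        out.append(np.where(crossed, Gs, G[:, -1]))
    return crossed, out


def _bulk_simpson(f_nodes, span):
    """Composite Simpson on n uniformly spaced nodes over ``span`` (exact for cubics)."""
    n = f_nodes.shape[-1]
    w = np.zeros(n)
    w[0::2] += 1.0
    w[1::2] += 4.0
    w[2:-1:2] += 1.0
    w /= 3.0
    h = span / (n - 1)
    return (f_nodes * w).sum(axis=-1) * h


def cross_section_averages(
    phi_w,
    vw,
    u0_z,
    model: DispersionModel,
    geom: ChannelGeometry,
    numerics: InnerNumerics | None = None,
):
    """Cross-section averaged axial flux and companions for every axial node.

    Parameters
    ----------
    phi_w, vw, u0_z
        Wall volume fraction, permeate flux and centerline velocity on the
        axial grid (arrays of equal length).  ``vw`` entries must be >= 0;
        a zero entry means no CP layer at that node (uniform bulk field).

    Returns
    -------
    dict with per-node arrays:
        ``Jz_bar``      cross average of phi*u (axial particle flux density),
        ``u_bar``       cross average of u (matched field, not the outer parabola),
        ``phi_bar``     cross average of phi,
        ``layer_gain``  cross average of exp(-E)*u — the sensitivity of
                        Jz_bar to the layer amplitude phi_w - phi_b (the
                        amplitude multiplies exp(-E) in the matched field),
                        used by the solver's Newton update,
        ``I0``          Int_0^R eta^-1 dy (normalizer of the U factor).

    The cross-sectional measure is (2/R^2) Int_0^R . y dy for CM,
    (1/R) Int_0^R . dy for FMM (symmetric half-channel) and
    (1/2R) Int_-R^R . dy for FMS.
    """
    numerics = numerics or InnerNumerics()
    phi_w = np.asarray(phi_w, dtype=float)
    vw = np.asarray(vw, dtype=float)
    u0_z = np.asarray(u0_z, dtype=float)
    if np.any(vw < 0):
        raise DomainError("cross_section_averages requires non-negative permeate flux")
    R = geom.R
    phi_b = model.phi_b
    is_cm = geom.kind == "CM"
    y_lo = -R if geom.kind == "FMS" else 0.0
    norm = {"CM": R * R / 2.0, "FMM": R, "FMS": 2.0 * R}[geom.kind]
    eta_b = float(viscosity(phi_b, model))

    E = numerics.e_grid()
    inv_vw = np.where(vw > 0, 1.0 / np.where(vw > 0, vw, 1.0), 0.0)[:, None]

    phi = matched_concentration(E[None, :], phi_w[:, None], phi_b)
    D = gradient_diffusion(phi, model)
    eta = viscosity(phi, model)

    s = cumulative_trapezoid(D, E, axis=1, initial=0.0) * inv_vw      # wall distance
    y = R - s
    Iw = cumulative_trapezoid(D / eta, E, axis=1, initial=0.0) * inv_vw

    wgt = y if is_cm else np.ones_like(y)
    meas = D * inv_vw
    f_u = (1.0 + y / R) * Iw * wgt * meas
    f_flux = phi * f_u
    f_gain = np.exp(-E)[None, :] * f_u
    f_phi = phi * wgt * meas
    iw_pair = (D / eta * inv_vw, Iw)
    pairs = [
        (f_flux, cumulative_trapezoid(f_flux, E, axis=1, initial=0.0)),
        (f_u, cumulative_trapezoid(f_u, E, axis=1, initial=0.0)),
        (f_phi, cumulative_trapezoid(f_phi, E, axis=1, initial=0.0)),
        (f_gain, cumulative_trapezoid(f_gain, E, axis=1, initial=0.0)),
        iw_pair,
    ]
    crossed, (F_flux, F_u, F_phi, F_gain, Iw_lvl) = _cum_at_level(y, E, pairs, y_lo)

    y_cut = y[:, -1]
    Iw_max = Iw[:, -1]

    # I0 = Int_0^R eta^-1 dy: bulk-linear continuation when the layer ends
    # above the centerline, otherwise the layer value at y = 0.
    if y_lo < 0.0:
        _, (Iw_at_0,) = _cum_at_level(y, E, [iw_pair], 0.0)
    else:
        Iw_at_0 = Iw_lvl
    I0 = np.where(y_cut > 0.0, Iw_max + np.maximum(y_cut, 0.0) / eta_b, Iw_at_0)

    # bulk region y in [y_lo, y_cut] for rows whose layer grid ends above y_lo
    has_bulk = ~crossed & (y_cut > y_lo)
    span = np.where(has_bulk, y_cut - y_lo, 0.0)
    t = np.linspace(0.0, 1.0, numerics.n_bulk)
    yb = y_lo + span[:, None] * t[None, :]
    Ib = Iw_max[:, None] + (y_cut[:, None] - yb) / eta_b
    wb = yb if is_cm else np.ones_like(yb)
    g_flux = phi_b * (1.0 + yb / R) * Ib * wb
    g_u = (1.0 + yb / R) * Ib * wb
    g_phi = phi_b * np.ones_like(yb) * wb
    B_flux = np.where(has_bulk, _bulk_simpson(g_flux, span), 0.0)
    B_u = np.where(has_bulk, _bulk_simpson(g_u, span), 0.0)
    B_phi = np.where(has_bulk, _bulk_simpson(g_phi, span), 0.0)

    denom = I0 * norm
    return {
        "Jz_bar": u0_z * (F_flux + B_flux) / denom,
        "u_bar": u0_z * (F_u + B_u) / denom,
        "phi_bar": (F_phi + B_phi) / norm,
        # exp(-E) is ~1e-18 beyond the grid: no bulk contribution to the gain
        "layer_gain": u0_z * F_gain / denom,
        "I0": I0,
    }


class MatchedFields:
    """Pointwise evaluator of the matched concentration and velocity fields.

    Wraps converged axial profiles (phi_w, vw, u0) and reconstructs
    phi(y, z), u(y, z), v(y, z), the film exponent E(y, z) and the
    longitudinal velocity factor U(y, z) at arbitrary positions.  Axial
    interpolation of the wall profiles is linear; the transversal structure
    is rebuilt per requested z from the film parametrization.

    For CM and FMM the fields are (mirror) symmetric: y may be given in
    [-R, R] and is folded to [0, R] (v changes sign, being odd).  For FMS
    the full asymmetric channel [-R, R] is used as-is.
    """

    def __init__(self, geom, model, z_grid, phi_w, vw, u0_z,
                 numerics: InnerNumerics | None = None):
        self.geom = geom
        self.model = model
        self.z_grid = np.asarray(z_grid, dtype=float)
        self.phi_w = np.asarray(phi_w, dtype=float)
        self.vw = np.asarray(vw, dtype=float)
        self.u0_z = np.asarray(u0_z, dtype=float)
        self.numerics = numerics or InnerNumerics()
        self._E = self.numerics.e_grid()
        self._eta_b = float(viscosity(model.phi_b, model))
        self._D_b = float(gradient_diffusion(model.phi_b, model))

    # -- per-z layer reconstruction -------------------------------------------------

    def _at_z(self, z: float):
        zg = self.z_grid
        pw = float(np.interp(z, zg, self.phi_w))
        vw = float(np.interp(z, zg, self.vw))
        u0 = float(np.interp(z, zg, self.u0_z))
        E = self._E
        phi = matched_concentration(E, pw, self.model.phi_b)
        D = gradient_diffusion(phi, self.model)
        eta = viscosity(phi, self.model)
        if vw > 0:
            s = cumulative_trapezoid(D, E, initial=0.0) / vw
            Iw = cumulative_trapezoid(D / eta, E, initial=0.0) / vw
        else:
            s = np.zeros_like(E)
            Iw = np.zeros_like(E)
        return pw, vw, u0, s, Iw

    def _E_of_s(self, s_req, s_grid, vw):
        """Film exponent at wall distance s (linear bulk continuation)."""
        E = np.interp(s_req, s_grid, self._E)
        tail = s_req > s_grid[-1]
        if np.any(tail):
            E = np.where(tail, self._E[-1] + (s_req - s_grid[-1]) * vw / self._D_b, E)
        return E

    def _fold(self, y):
        y = np.asarray(y, dtype=float)
        if np.any(np.abs(y) > self.geom.R * (1 + 1e-12)):
            raise DomainError("|y| > R")
        if self.geom.kind == "FMS":
            return y, np.ones_like(y)
        return np.abs(y), np.sign(y) + (y == 0)

    def film_exponent(self, y, z: float):
        """E(y, z) = vw(z) * Int_y^R dy'/D(phi)."""
        y_eff, _ = self._fold(y)
        _, vw, _, s, _ = self._at_z(z)
        return self._E_of_s(self.geom.R - y_eff, s, vw)

    def phi(self, y, z: float):
        """Particle volume fraction phi(y, z)."""
        pw, vw, _, s, _ = self._at_z(z)
        y_eff, _ = self._fold(y)
        E = self._E_of_s(self.geom.R - y_eff, s, vw)
        return matched_concentration(E, pw, self.model.phi_b)

    def dphi_dy(self, y, z: float):
        """Analytic transversal concentration gradient (chain rule through E)."""
        pw, vw, _, s, _ = self._at_z(z)
        y_eff, sgn = self._fold(y)
        E = self._E_of_s(self.geom.R - y_eff, s, vw)
        phi = matched_concentration(E, pw, self.model.phi_b)
        phi_b = self.model.phi_b
        ee = np.exp(-E)
        dphi_dE = -(pw - phi_b) * ee - phi_b * (1.0 - E) * ee
        dE_dy = -vw / gradient_diffusion(phi, self.model)
        return sgn * dphi_dE * dE_dy

    def U_factor(self, y, z: float):
        """Longitudinal velocity factor U(y, z); 1 at the centerline, 0 at walls."""
        pw, vw, _, s, Iw = self._at_z(z)
        R = self.geom.R
        y_eff, _ = self._fold(y)
        s_req = R - y_eff
        I_y = np.interp(s_req, s, Iw)
        tail = s_req > s[-1]
        if np.any(tail):
            I_y = np.where(tail, Iw[-1] + (s_req - s[-1]) / self._eta_b, I_y)
        s0 = R  # wall distance of the centerline
        I0 = Iw[-1] + (s0 - s[-1]) / self._eta_b if s0 > s[-1] else np.interp(s0, s, Iw)
        return (1.0 + np.asarray(y, dtype=float) / R if self.geom.kind == "FMS"
                else 1.0 + y_eff / R) * I_y / I0

    def u(self, y, z: float):
        """Axial velocity u(y, z) = u0(z) * U(y, z) (m/s)."""
        _, _, u0, _, _ = self._at_z(z)
        return u0 * self.U_factor(y, z)

    def v(self, y, z: float):
        """Transversal velocity v(y, z) = vw(z) * Vout(y) (m/s, toward the wall > 0)."""
        _, vw, _, _, _ = self._at_z(z)
        y = np.asarray(y, dtype=float)
        if self.geom.kind == "FMS":
            _, vout = outer_velocity_factors(self.geom, y)
        else:
            _, vout_abs = outer_velocity_factors(self.geom, np.abs(y))
            vout = np.where(y >= 0, vout_abs, -vout_abs)
        return vw * vout

    def transversal_particle_flux(self, y, z: float):
        """phi*v - D(phi)*dphi/dy; vanishes at the membrane wall (retention)."""
        phi = self.phi(y, z)
        return phi * self.v(y, z) - gradient_diffusion(phi, self.model) * self.dphi_dy(y, z)

    def to_grid(self, y, z):
        """Gridded export: DataFrame of (y, z, phi, u, v) over the given 1-D axes."""
        import pandas as pd

        rows = []
        for zi in np.asarray(z, dtype=float):
            rows.append(pd.DataFrame({
                "y": np.asarray(y, dtype=float),
                "z": zi,
                "phi": self.phi(y, zi),
                "u": self.u(y, zi),
                "v": self.v(y, zi),
            }))
        return pd.concat(rows, ignore_index=True)
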