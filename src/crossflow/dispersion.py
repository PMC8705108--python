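"""Constitutive properties of mono-disperse Brownian hard-sphere dispersions.

This module supplies the equilibrium osmotic pressure and the short-time
transport correlations that drive the concentration-polarization solver:

* Carnahan-Starling osmotic pressure ``Π(φ)``,
* inverse osmotic compressibility factor ``1/S(φ)``,
* short-time sedimentation coefficient ``Ksed(φ)``,
* gradient (collective) diffusion coefficient ``D(φ) = D0·Ksed/S``,
* short-time self-diffusion ``Ds(φ)/D0`` and the two-part shear viscosity
  ``η(φ) = η∞(φ) + Δη(φ)``.

All correlations are accurate analytic fits for fluid-state hard spheres and
are used up to the freezing transition volume fraction ``φf ≈ 0.494``; above
it the dispersion crystallizes (cake formation) and a :class:`DomainError`
is raised rather than extrapolating.

Everything is SI.  Functions accept scalars or numpy arrays in ``φ``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "KB",
    "PHI_FREEZING",
    "DispersionModel",
    "osmotic_pressure",
    "inverse_compressibility",
    "sedimentation_coefficient",
    "gradient_diffusion",
    "short_time_self_diffusion",
    "viscosity",
    "single_particle_peclet",
    "phi_at_osmotic_pressure",
]

#: Boltzmann constant (J/K), 2019 SI definition.
KB = 1.380649e-23

#: Hard-sphere freezing transition volume fraction.
PHI_FREEZING = 0.494


@dataclass(frozen=True)
class DispersionModel:
    """Particle + solvent parameters of a hard-sphere feed dispersion.

    Parameters
    ----------
    a
        Particle hard-core radius (m).
    phi_b
        Feed (bulk/inlet) particle volume fraction.
    T
        Temperature (K).  Default 293.15 K (water at room temperature).
    eta_s
        Newtonian solvent shear viscosity (Pa*s).  Default 1.0e-3 (water).
    """

    a: float
    phi_b: float = 0.0
    T: float = 293.15
    eta_s: float = 1.0e-3
    phi_f: float = field(default=PHI_FREEZING, init=False)

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise DomainError(f"particle radius must be positive, got a={self.a}")
        if not self.T > 0:
            raise DomainError(f"temperature must be positive, got T={self.T}")
        if not self.eta_s > 0:
            raise DomainError(f"solvent viscosity must be positive, got eta_s={self.eta_s}")
        if not (0.0 <= self.phi_b < PHI_FREEZING):
            raise DomainError(
                f"feed volume fraction must lie in [0, {PHI_FREEZING}), got phi_b={self.phi_b}"
            )

    @property
    def Va(self) -> float:
        """Particle volume (4π/3)a³ (m³)."""
        return (4.0 * np.pi / 3.0) * self.a**3

    @property
    def D0(self) -> float:
        """Stokes-Einstein single-particle diffusion coefficient kBT/(6πηs a) (m²/s)."""
        return KB * self.T / (6.0 * np.pi * self.eta_s * self.a)


def _check_phi(phi, upper: float, what: str):
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0.0) or np.any(phi > upper):
        raise DomainError(
            f"{what}: volume fraction outside [0, {upper}] — "
            "cake/freezing regime, fluid-state correlations do not apply"
        )
    return phi


def osmotic_pressure(phi, model: DispersionModel):
    """Carnahan-Starling equilibrium osmotic pressure Π(φ) in Pa.

    Π = (kBT/Va)·φ·(1 + φ + φ² − φ³)/(1 − φ)³, strictly increasing on
    [0, φf].  The dilute limit is van't Hoff, Π → n·kBT with n = φ/Va.
    """
    phi = _check_phi(phi, PHI_FREEZING, "osmotic_pressure")
    Z = (1.0 + phi * (1.0 + phi * (1.0 - phi))) / (1.0 - phi) ** 3
    return (KB * model.T / model.Va) * phi * Z


def inverse_compressibility(phi):
    """Inverse osmotic compressibility factor 1/S(φ) = (1/kBT)·dΠ/dn.

    Carnahan-Starling-type expression
    [(1+2φ)² + φ³(φ−4)] / (1−φ)⁴; equals 1 at infinite dilution.
    """
    phi = _check_phi(phi, 1.0 - 1e-12, "inverse_compressibility")
    return ((1.0 + 2.0 * phi) ** 2 + phi**3 * (phi - 4.0)) / (1.0 - phi) ** 4


def _ksed_raw(phi):
    poly = 1.0 + phi * (-3.348 + phi * (7.426 + phi * (-10.034 + phi * 5.882)))
    return 1.0 - 6.5464 * phi * poly


def sedimentation_coefficient(phi):
    """Short-time sedimentation coefficient Ksed(φ) of hard spheres.

    ``Ksed = 1 − 6.5464·φ·(1 − 3.348φ + 7.426φ² − 10.034φ³ + 5.882φ⁴)``,
    which reduces to the Batchelor dilute law 1 − 6.5464φ + 21.92φ² and
    decreases monotonically from 1 on [0, φf], staying positive.
    """
    phi = _check_phi(phi, PHI_FREEZING, "sedimentation_coefficient")
    k = _ksed_raw(phi)
    if np.any(k <= 0.0):
        raise DomainError("sedimentation_coefficient: non-positive value (outside fit range)")
    return k


def gradient_diffusion(phi, model: DispersionModel):
    """Gradient (collective) diffusion coefficient D(φ) = D0·Ksed(φ)/S(φ) (m²/s).

    Short-time form; grows monotonically with volume fraction because the
    thermodynamic driving force 1/S grows faster than the hydrodynamic
    hindrance Ksed decays.
    """
    phi = _check_phi(phi, PHI_FREEZING, "gradient_diffusion")
    return model.D0 * _ksed_raw(phi) * inverse_compressibility(phi)


def short_time_self_diffusion(phi):
    """Reduced short-time self-diffusion coefficient Ds(φ)/D0.

    ``Ds/D0 = 1 − 1.8315·φ·(1 + 0.12φ − 0.70φ²)``, in (0, 1], with the
    exact dilute slope −1.8315.
    """
    phi = _check_phi(phi, PHI_FREEZING, "short_time_self_diffusion")
    ds = 1.0 - 1.8315 * phi * (1.0 + phi * (0.12 - 0.70 * phi))
    if np.any(ds <= 0.0):
        raise DomainError("short_time_self_diffusion: non-positive value")
    return ds


def viscosity(phi, model: DispersionModel):
    """Dispersion shear viscosity η(φ) = η∞(φ) + Δη(φ) in Pa·s.

    High-frequency part (with the Saito-type function Ŝ(φ) = φ(1 + 0.95φ − 2.15φ²))::

        η∞/ηs = 1 + (5/2)·φ·(1 + Ŝ) / (1 − φ(1 + Ŝ))

    and shear-relaxation part::

        Δη/ηs = (D0/Ds(φ)) · 12φ²(1 − 7.085φ + 20.182φ²) / (5(1 − φ/0.64))

    η(0) = ηs, Einstein slope 5/2, monotone increasing on [0, φf].
    """
    phi = _check_phi(phi, PHI_FREEZING, "viscosity")
    s_hat = phi * (1.0 + phi * (0.95 - 2.15 * phi))
    x = phi * (1.0 + s_hat)
    eta_inf = 1.0 + 2.5 * x / (1.0 - x)
    ds = short_time_self_diffusion(phi)
    d_eta = (1.0 / ds) * 12.0 * phi**2 * (1.0 + phi * (-7.085 + 20.182 * phi)) / (
        5.0 * (1.0 - phi / 0.64)
    )
    return model.eta_s * (eta_inf + d_eta)


def single_particle_peclet(shear_rate: float, model: DispersionModel) -> float:
    """Single-particle shear Peclet number Pea = γ̇·a²/D0 (dimensionless).

    Pea ≪ 1 is the near-equilibrium condition under which the equilibrium
    constitutive expressions above are valid; it scales as a³ at fixed shear
    rate.  Used for validity reporting only.
    """
    if shear_rate < 0:
        raise DomainError("shear rate must be non-negative")
    return shear_rate * model.a**2 / model.D0


# precomputed inversion grid for the (monotone) Carnahan-Starling pressure,
# used by the solver's osmotic-pressure ceiling safeguard
_PHI_GRID = np.linspace(0.0, PHI_FREEZING, 2048)


def phi_at_osmotic_pressure(Pi, model: DispersionModel):
    """Volume fraction at which Π(φ) equals ``Pi`` (inverse of the CS pressure).

    Monotone table inversion, clipped to [0, φf]; pressures above Π(φf)
    return φf.  Used as a safeguard bound, not in the converged physics.
    """
    table = (KB * model.T / model.Va) * _PHI_GRID * (
        (1.0 + _PHI_GRID * (1.0 + _PHI_GRID * (1.0 - _PHI_GRID))) / (1.0 - _PHI_GRID) ** 3
    )
    return np.interp(np.asarray(Pi, dtype=float), table, _PHI_GRID)
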