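"""Run configuration, builtin benchmark scenarios, sweep and collapse drivers.

A :class:`RunConfig` bundles the four ingredient objects of a run
(dispersion model, channel geometry, operating conditions, numerics) and
can be loaded from a YAML file with blocks ``dispersion``, ``geometry``,
``operating`` and optional ``numerics``.

The builtin scenarios encode a benchmark suite around one reference
membrane (R = 0.5 mm, L = 0.5 m, Lp = 6.7e-10 m/(Pa s)) carrying an
aqueous hard-sphere dispersion:

* ``ref-CM / ref-FMM / ref-FMS`` (aliases ``fig6a-*``): a = 3.13 nm
  particles, feed phi_b = 1e-3, TMP = 16 kPa, equal cross-averaged inlet
  velocity ubar0 = 3.40e-2 m/s in all three geometries (centerline
  u0 = {6.80, 5.09, 5.09}e-2 m/s).
* ``fig6a-FMM2 / fig6b-FMM2``: FMM operated at the same inlet wall shear
  rate (same u0) as the CM case instead of the same ubar0.
* ``fig6b-*``: larger particles a = 10 nm at TMP = 5 kPa and
  ubar0 = 1.11e-2 m/s (same PeR ~ 78 as the small-particle case).
* ``CM-1..4, FMM-1..4, FMS-1..4``: per-geometry parameter families that
  share the universality duplet (beta0/PeR, gamma0/PeR) while varying R,
  membrane thickness (same Darcy permeability kappa = 1.36e-16 m^2), feed
  concentration and inlet velocity — the master-curve families.
* ``G1-*, G2-*``: cross-geometry families sharing one duplet across CM,
  FMM and FMS.

TMP is the natural sweep variable (PeR is proportional to it at fixed
membrane), so scenarios carry a default TMP and :func:`collapse_table`
re-targets it per requested PeR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .dispersion import DispersionModel
from .errors import ConfigError
from .geometry import ChannelGeometry
from .indicators import compute_indicators, peclet_transversal
from .outer import OperatingConditions
from .solver import Numerics, SolutionState, solve

__all__ = [
    "RunConfig",
    "load_config",
    "builtin_scenario",
    "scenario_names",
    "run_and_report",
    "sweep_tmp",
    "collapse_table",
]

# reference system constants
A_REF = 3.13e-9
LP_REF = 6.7e-10
KAPPA_REF = 1.36e-16
UBAR0_REF = 3.40e-2
U0_REF = {"CM": 6.80e-2, "FMM": 5.09e-2, "FMS": 5.09e-2}
TMP_REF = 16.0e3
PHI_B_REF = 1.0e-3
R_REF = 0.5e-3
L_REF = 0.5


@dataclass(frozen=True)
class RunConfig:
    """One complete, validated run specification."""

    model: DispersionModel
    geom: ChannelGeometry
    ops: OperatingConditions
    numerics: Numerics = field(default_factory=Numerics)
    name: str | None = None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "dispersion": {"a": self.model.a, "T": self.model.T,
                           "eta_s": self.model.eta_s, "phi_b": self.model.phi_b},
            "geometry": {"kind": self.geom.kind, "R": self.geom.R, "L": self.geom.L,
                         "W": self.geom.W, "h": self.geom.h,
                         "kappa": self.geom.kappa, "Lp": self.geom.Lp},
            "operating": {"phi_b": self.ops.phi_b, "u0": self.ops.u0,
                          "ubar0": self.ops.ubar0, "PL": self.ops.PL,
                          "TMP_lin": self.ops.TMP_lin, "Pperm": self.ops.Pperm},
            "numerics": {"n_z": self.numerics.n_z, "tol": self.numerics.tol,
                         "max_iter": self.numerics.max_iter},
        }
        return d

    def with_tmp(self, tmp: float) -> "RunConfig":
        return replace(self, ops=replace(self.ops, TMP_lin=tmp, Pperm=None))

    def with_ubar0(self, ubar0: float) -> "RunConfig":
        return replace(self, ops=replace(self.ops, ubar0=ubar0, u0=None))


_ALLOWED = {
    "dispersion": {"a", "T", "eta_s", "phi_b"},
    "geometry": {"kind", "R", "L", "W", "h", "kappa", "Lp"},
    "operating": {"phi_b", "u0", "ubar0", "PL", "TMP_lin", "Pperm"},
    "numerics": {"n_z", "tol", "max_iter", "omega", "ratio_clip"},
}


def _block(data: dict, key: str, required: bool = True) -> dict:
    blk = data.get(key)
    if blk is None:
        if required:
            raise ConfigError(f"missing configuration block {key!r}")
        return {}
    if not isinstance(blk, dict):
        raise ConfigError(f"configuration block {key!r} must be a mapping")
    unknown = set(blk) - _ALLOWED[key]
    if unknown:
        raise ConfigError(f"unknown field(s) in block {key!r}: {sorted(unknown)}")
    return blk


def config_from_dict(data: dict, name: str | None = None) -> RunConfig:
    """Build a validated RunConfig from nested plain mappings (SI units)."""
    disp = _block(data, "dispersion")
    geo = _block(data, "geometry")
    op = _block(data, "operating")
    num = _block(data, "numerics", required=False)
    if "a" not in disp:
        raise ConfigError("dispersion block needs the particle radius 'a' (m)")
    if "kind" not in geo or "R" not in geo or "L" not in geo:
        raise ConfigError("geometry block needs 'kind', 'R' and 'L'")
    phi_b = op.get("phi_b", disp.get("phi_b"))
    if phi_b is None:
        raise ConfigError("feed volume fraction 'phi_b' missing")
    try:
        model = DispersionModel(a=float(disp["a"]), phi_b=float(phi_b),
                                T=float(disp.get("T", 293.15)),
                                eta_s=float(disp.get("eta_s", 1.0e-3)))
        geom = ChannelGeometry(
            kind=str(geo["kind"]), R=float(geo["R"]), L=float(geo["L"]),
            W=float(geo.get("W", 1.0)),
            h=None if geo.get("h") is None else float(geo["h"]),
            kappa=None if geo.get("kappa") is None else float(geo["kappa"]),
            Lp=None if geo.get("Lp") is None else float(geo["Lp"]),
        )
        ops = OperatingConditions(
            phi_b=float(phi_b),
            u0=None if op.get("u0") is None else float(op["u0"]),
            ubar0=None if op.get("ubar0") is None else float(op["ubar0"]),
            PL=float(op.get("PL", 101325.0)),
            TMP_lin=None if op.get("TMP_lin") is None else float(op["TMP_lin"]),
            Pperm=None if op.get("Pperm") is None else float(op["Pperm"]),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
    numerics = Numerics(
        n_z=int(num.get("n_z", 129)), tol=float(num.get("tol", 1e-6)),
        max_iter=int(num.get("max_iter", 500)),
        omega=float(num.get("omega", 0.5)),
        ratio_clip=float(num.get("ratio_clip", 3.0)),
    )
    return RunConfig(model=model, geom=geom, ops=ops, numerics=numerics,
                     name=name or data.get("name"))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"configuration file {path} does not contain a mapping")
    return config_from_dict(data)


# --------------------------------------------------------------------------------------
# builtin scenarios
# --------------------------------------------------------------------------------------

def _ref(kind: str, *, a=A_REF, phi_b=PHI_B_REF, tmp=TMP_REF, u0=None, ubar0=None,
         R=R_REF, L=L_REF, Lp=LP_REF, h_over_R=None, name="") -> RunConfig:
    if h_over_R is not None:
        geom = ChannelGeometry(kind=kind, R=R, L=L, h=h_over_R * R, kappa=KAPPA_REF)
    else:
        geom = ChannelGeometry(kind=kind, R=R, L=L, Lp=Lp)
    if u0 is None and ubar0 is None:
        u0 = U0_REF[kind]
    model = DispersionModel(a=a, phi_b=phi_b)
    ops = OperatingConditions(phi_b=phi_b, u0=u0, ubar0=ubar0, TMP_lin=tmp)
    return RunConfig(model=model, geom=geom, ops=ops, name=name)


def _table3_row(kind, R_mm, h_over_R, lp_ratio, phib_1e3, ubar_ratio, name):
    kwargs = dict(R=R_mm * 1e-3, phi_b=phib_1e3 * 1e-3,
                  ubar0=ubar_ratio * UBAR0_REF, u0=None, name=name)
    if h_over_R is None:
        kwargs["Lp"] = lp_ratio * LP_REF
    else:
        kwargs["h_over_R"] = h_over_R
    return _ref(kind, **kwargs)


def _build_registry() -> dict:
    reg: dict[str, RunConfig] = {}
    for kind in ("CM", "FMM", "FMS"):
        reg[f"ref-{kind}"] = _ref(kind, name=f"ref-{kind}")
        reg[f"fig6a-{kind}"] = _ref(kind, name=f"fig6a-{kind}")
        reg[f"fig6b-{kind}"] = _ref(kind, a=10e-9, tmp=5.0e3, u0=None,
                                    ubar0=1.11e-2, name=f"fig6b-{kind}")
    # FMM operated at the CM inlet wall shear rate (same u0, same R)
    reg["fig6a-FMM2"] = _ref("FMM", u0=U0_REF["CM"], name="fig6a-FMM2")
    cm_u0_6b = 1.11e-2 / 0.5   # CM centerline velocity of the fig6b family
    reg["fig6b-FMM2"] = _ref("FMM", a=10e-9, tmp=5.0e3, u0=cm_u0_6b,
                             name="fig6b-FMM2")

    # master-curve families: (R_mm, h/R, Lp/Lp_REF, phi_b/1e-3, ubar0/ubar0_REF)
    table3 = {
        "CM-1": ("CM", 0.5, None, 1.00, 1.00, 1.00),
        "CM-2": ("CM", 0.5, 0.5, None, 1.00, 1.00),
        "CM-3": ("CM", 0.5, 1.0, None, 1.69, 1.00),
        "CM-4": ("CM", 0.25, 0.5, None, 1.00, 4.00),
        "FMM-1": ("FMM", 0.5, None, 1.00, 1.00, 1.00),
        "FMM-2": ("FMM", 0.5, 0.5, None, 1.24, 1.00),
        "FMM-3": ("FMM", 0.5, 1.0, None, 2.44, 1.00),
        "FMM-4": ("FMM", 0.25, 0.5, None, 1.23, 4.00),
        "FMS-1": ("FMS", 0.5, None, 1.00, 1.00, 1.00),
        "FMS-2": ("FMS", 0.5, 0.5, None, 1.24, 1.00),
        "FMS-3": ("FMS", 0.5, 1.0, None, 2.44, 1.00),
        "FMS-4": ("FMS", 0.25, 0.5, None, 1.23, 4.00),
    }
    for name, (kind, r_mm, hr, lpr, phib, ubr) in table3.items():
        reg[name] = _table3_row(kind, r_mm, hr, lpr, phib, ubr, name)

    # cross-geometry families sharing one duplet
    g_fams = {
        "G1": {"CM": (1.00, 1.00), "FMM": (0.375, 0.50), "FMS": (0.186, 0.25)},
        "G2": {"CM": (2.00, 1.00), "FMM": (0.750, 0.50), "FMS": (0.375, 0.25)},
    }
    for fam, rows in g_fams.items():
        for kind, (phib, ubr) in rows.items():
            name = f"{fam}-{kind}"
            reg[name] = _ref(kind, phi_b=phib * 1e-3, ubar0=ubr * UBAR0_REF,
                             u0=None, name=name)
    return reg


_REGISTRY = _build_registry()


def scenario_names() -> list[str]:
    return sorted(_REGISTRY)


def builtin_scenario(name: str) -> RunConfig:
    """Return the named builtin benchmark scenario."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigError(
            f"unknown scenario {name!r}; known: {', '.join(scenario_names())}"
        ) from None


# --------------------------------------------------------------------------------------
# drivers
# --------------------------------------------------------------------------------------

def run_and_report(config: RunConfig, outdir=None, plot: bool = False):
    """Solve one operating point; optionally write the results bundle.

    Writes (when ``outdir`` is given): ``profiles.csv`` with the axial
    profiles, ``indicators.json`` with the global indicators and
    ``metadata.json`` echoing the inputs plus the residual history.
    Returns ``(state, report)``.
    """
    state = solve(config.geom, config.model, config.ops, config.numerics)
    report = compute_indicators(state)
    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        state.to_frame().to_csv(out / "profiles.csv", index=False)
        (out / "indicators.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
        meta = config.to_dict()
        meta["iterations"] = state.iterations
        meta["converged"] = state.converged
        meta["residual_history"] = state.residual_history
        (out / "metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n")
        if plot:
            _plot_bundle(state, out)
    return state, report


def _plot_bundle(state: SolutionState, out):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2), constrained_layout=True)
    axes[0].plot(state.z, state.phi_w)
    axes[0].set(xlabel="z (m)", ylabel=r"$\phi_w$")
    axes[1].plot(state.z, state.pressure.vw)
    axes[1].set(xlabel="z (m)", ylabel=r"$v_w$ (m/s)")
    axes[2].plot(state.z, state.pressure.u0_z)
    axes[2].set(xlabel="z (m)", ylabel=r"$u_0$ (m/s)")
    fig.savefig(out / "profiles.png", dpi=150)
    plt.close(fig)


def sweep_tmp(config: RunConfig, tmp_values) -> pd.DataFrame:
    """Solve the scenario over a set of linearized-TMP values (Pa).

    Returns one tidy row per operating point with the global indicators.
    """
    rows = []
    for tmp in np.asarray(tmp_values, dtype=float):
        cfg = config.with_tmp(float(tmp))
        state = solve(cfg.geom, cfg.model, cfg.ops, cfg.numerics)
        rep = compute_indicators(state)
        rows.append({
            "scenario": config.name, "TMP_Pa": tmp, "PeR": rep.PeR,
            "beta": rep.beta, "beta0": rep.beta0, "alpha": rep.alpha,
            "vw_mean_m_s": rep.vw_mean, "Pi_mean_Pa": rep.Pi_mean,
            "phi_w_outlet": rep.phi_w_outlet,
        })
    return pd.DataFrame(rows)


def collapse_table(names, pe_values) -> pd.DataFrame:
    """Master-curve data: beta at prescribed PeR values for several scenarios.

    PeR is retargeted by adjusting the TMP of each scenario
    (TMP = PeR*D0/(R*Lp), everything else fixed), so scenarios sharing the
    duplet (beta0/PeR, gamma0/PeR) should trace out one beta(PeR) curve.
    """
    rows = []
    for name in names:
        cfg = builtin_scenario(name) if isinstance(name, str) else name
        base = peclet_transversal(cfg.geom, cfg.model, cfg.ops)
        for pe in np.asarray(pe_values, dtype=float):
            tmp = float(cfg.ops.TMP_lin) * pe / base
            run = cfg.with_tmp(tmp)
            state = solve(run.geom, run.model, run.ops, run.numerics)
            rep = compute_indicators(state)
            rows.append({
                "scenario": cfg.name, "PeR_target": pe, "PeR": rep.PeR,
                "TMP_Pa": tmp, "beta": rep.beta, "beta0": rep.beta0,
                "beta0_over_PeR": rep.beta0_over_PeR,
                "gamma0_over_PeR": rep.gamma0_over_PeR,
            })
    return pd.DataFrame(rows)
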