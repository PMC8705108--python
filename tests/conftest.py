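"""Shared fixtures: reference parameter sets and cached solver runs.

The reference membrane (R = 0.5 mm, L = 0.5 m, Lp = 6.7e-10 m/(Pa s)) with
an aqueous hard-sphere feed is used throughout; full solves are cached per
session because many tests interrogate the same converged states.
"""

import numpy as np
import pytest

import crossflow as cf


@pytest.fixture(scope="session")
def ref_model():
    return cf.DispersionModel(a=3.13e-9, phi_b=1e-3)


@pytest.fixture(scope="session")
def ref_geom_cm():
    return cf.ChannelGeometry(kind="CM", R=0.5e-3, L=0.5, Lp=6.7e-10)


@pytest.fixture(scope="session")
def ref_ops_cm():
    return cf.OperatingConditions(phi_b=1e-3, u0=6.80e-2, TMP_lin=16e3)


@pytest.fixture(scope="session")
def solved():
    """Factory returning (and caching) the converged state of a builtin scenario."""
    cache: dict[str, cf.SolutionState] = {}

    def _solve(name: str) -> cf.SolutionState:
        if name not in cache:
            cfg = cf.builtin_scenario(name)
            cache[name] = cf.solve(cfg.geom, cfg.model, cfg.ops, cfg.numerics)
        return cache[name]

    return _solve


@pytest.fixture(scope="session")
def phi_grid():
    return np.linspace(0.0, 0.45, 100)
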