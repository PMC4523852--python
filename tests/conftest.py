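"""Shared fixtures: parameter presets and precomputed solver bundles."""

from __future__ import annotations

import numpy as np
import pytest

import qmebench as qb
from qmebench.experiments import make_propagator
from qmebench.nonmarkov import choi_propagate, measure_from_extended


@pytest.fixture(scope="session")
def grid800():
    return np.arange(0.0, 801.0, 1.0)


@pytest.fixture(scope="session")
def exciton_excited():
    rho = np.zeros((2, 2), dtype=complex)
    rho[0, 0] = 1.0
    return rho


def _cell(omega0, lam, gamma, T, grid, rho0, heom_tol):
    """TC2/TL2/HEOM trajectories on a shared bath expansion."""
    model = qb.DimerModel(omega0=omega0, J=100.0, lam=lam, gamma=gamma, T=T)
    cfg = qb.converge_heom(model, heom_tol)
    corr = qb.correlation_expansion(model, cfg.K)
    heom = qb.propagate_heom(qb.build_hierarchy(model, corr, cfg), rho0, grid)
    tc2 = qb.propagate_tc2(qb.build_tc2_system(model, corr), rho0, grid)
    tl2 = qb.propagate_tl2(model, corr, rho0, grid)
    return {"model": model, "config": cfg, "corr": corr,
            "heom": heom, "tc2": tc2, "tl2": tl2}


@pytest.fixture(scope="session")
def weak_cell(grid800, exciton_excited):
    """λ = 5 cm⁻¹, T = 250 K: the weak-coupling coincidence regime."""
    return _cell(70.0, 5.0, 50.0, 250.0, grid800, exciton_excited, 1e-4)


@pytest.fixture(scope="session")
def strong_cell(grid800, exciton_excited):
    """λ = 100 cm⁻¹, T = 300 K: the intermediate/strong-coupling regime."""
    return _cell(70.0, 100.0, 50.0, 300.0, grid800, exciton_excited, 1e-3)


def _measure(solver, model, grid, heom_tol=1e-3, epsilon=1e-6):
    cfg = qb.converge_heom(model, heom_tol) if solver == "heom" else None
    K = cfg.K if cfg is not None else 10
    prop = make_propagator(solver, model, K=K, heom_config=cfg)
    return measure_from_extended(choi_propagate(prop, grid), epsilon)


@pytest.fixture(scope="session")
def slow_bath_measures(grid800):
    """γ = 20 cm⁻¹ study: RHP measure for all three solvers at T = 200 K."""
    model = qb.DimerModel(omega0=40.0, J=100.0, lam=5.0, gamma=20.0, T=200.0)
    return {s: _measure(s, model, grid800) for s in ("tc2", "tl2", "heom")}


@pytest.fixture(scope="session")
def tc2_measure_grid(grid800):
    """TC2 non-Markovianity over the (λ, T) family at ω0 = 70 cm⁻¹."""
    out = {}
    for lam in (5.0, 20.0, 50.0, 100.0):
        for T in (200.0, 250.0, 300.0):
            model = qb.DimerModel(omega0=70.0, J=100.0, lam=lam, gamma=50.0, T=T)
            out[(lam, T)] = _measure("tc2", model, grid800).N
    return out
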