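"""Steady-state solution of the reduced hepatic network.

Internal metabolite concentrations are solved so that every balanced species
has zero net production.  The solver works in log-concentration space (which
enforces positivity), using a damped Newton/Powell hybrid root find with a
stiff pseudo-transient (ODE) fallback when the algebraic solve fails or lands
outside tolerance.  Warm starts along protocol grids make repeated solves
cheap.  The procedure is fully deterministic.

Convergence contract: ``max_i |dC_i/dt| / max(C_i, 1) < 1e-8``; non-converged
solves are reported with their residual, never silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .hormones import gamma_at_glucose
from .model import ModelDefinition
from .ratelaws import evaluate_rate

__all__ = ["PlasmaState", "SteadyStateResult", "solve_steady_state", "CONVERGENCE_TOL"]

CONVERGENCE_TOL = 1e-8


@dataclass(frozen=True)
class PlasmaState:
    """Clamped plasma nutrient concentrations (mM)."""

    glucose: float = 6.0
    fructose: float = 0.0
    galactose: float = 0.0
    glycerol: float = 0.2
    ffa: float = 0.4
    ammonia: float = 0.05
    ethanol: float = 0.0
    lactate: float = 1.0
    glutamine: float = 0.5
    glutamate: float = 0.05

    def __post_init__(self):
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"plasma {f.name} must be non-negative")

    def replace(self, **kwargs) -> "PlasmaState":
        vals = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        vals.update(kwargs)
        return PlasmaState(**vals)


@dataclass
class SteadyStateResult:
    """Fluxes (µmol·h⁻¹·g⁻¹), solved internal concentrations, diagnostics."""

    fluxes: dict[str, float]
    internal_concentrations: dict[str, float]
    converged: bool
    residual: float
    gamma: float = field(default=np.nan)

    def mass_balance(self, model: ModelDefinition) -> dict[str, float]:
        """Net production of every internal metabolite at the solution."""
        out = {}
        for met in model.internal_ids:
            out[met] = sum(
                r.stoichiometry.get(met, 0.0) * self.fluxes[r.id] for r in model.reactions.values()
            )
        return out


def _concentration_map(model: ModelDefinition, plasma: PlasmaState) -> dict[str, float]:
    conc: dict[str, float] = {}
    plasma_vals = {f.name: getattr(plasma, f.name) for f in dc_fields(plasma)}
    for met in model.metabolites.values():
        if met.role == "plasma":
            conc[met.id] = plasma_vals.get(met.id, met.default)
        elif met.role == "store":
            conc[met.id] = float(met.level)
    return conc


def _flux_vector(model, rxns, conc, vmax, gamma) -> np.ndarray:
    return np.array([evaluate_rate(r, conc, vmax[r.id], gamma) for r in rxns])


def solve_steady_state(
    model: ModelDefinition,
    plasma: PlasmaState,
    vmax_set: Mapping[str, float] | None = None,
    gamma: float | None = None,
    x0: Mapping[str, float] | None = None,
    t_max: float = 1e4,
) -> SteadyStateResult:
    """Solve the network to steady state at a clamped plasma composition.

    Parameters
    ----------
    model
        Validated :class:`ModelDefinition`.
    plasma
        Clamped plasma nutrient state.
    vmax_set
        reaction id -> maximal activity; defaults to the model's reference
        values.  May be a plain mapping or anything with ``.vmax`` mapping
        (e.g. an individualized :class:`~hepaflux.individualize.VmaxSet`).
    gamma
        Shared phosphorylated enzyme fraction.  When ``None`` it is derived
        from plasma glucose through the hormone transfer functions (glucose
        clamped to the transfer validity range for out-of-range scans).
    x0
        Optional warm-start internal concentrations (metabolite id -> mM).
    t_max
        Pseudo-transient integration horizon for the fallback path.
    """
    if vmax_set is None:
        vmax = model.reference_vmax()
    elif hasattr(vmax_set, "vmax"):
        vmax = dict(vmax_set.vmax)
    else:
        vmax = dict(vmax_set)
    missing = set(model.reactions) - set(vmax)
    if missing:
        raise ValueError(f"vmax_set missing reactions: {sorted(missing)}")

    if gamma is None:
        g = min(max(plasma.glucose, 2.0), 14.0)
        gamma = gamma_at_glucose(g)

    internal = model.internal_ids
    rxns = list(model.reactions.values())
    stoich = np.zeros((len(internal), len(rxns)))
    for j, r in enumerate(rxns):
        for i, met in enumerate(internal):
            stoich[i, j] = r.stoichiometry.get(met, 0.0)

    base_conc = _concentration_map(model, plasma)

    def residuals_from_logc(x: np.ndarray) -> np.ndarray:
        conc = dict(base_conc)
        c = np.exp(np.clip(x, -46.0, 46.0))
        conc.update(zip(internal, c))
        return stoich @ _flux_vector(model, rxns, conc, vmax, gamma)

    if x0 is not None:
        guess = np.array([max(float(x0[m]), 1e-9) for m in internal])
    else:
        guess = np.array([max(model.metabolites[m].default, 1e-9) for m in internal])
    lx0 = np.log(guess)

    def scaled_residual(x: np.ndarray) -> float:
        r = residuals_from_logc(x)
        c = np.exp(np.clip(x, -46.0, 46.0))
        return float(np.max(np.abs(r) / np.maximum(c, 1.0))) if len(r) else 0.0

    sol_x = lx0
    try:
        res = root(residuals_from_logc, lx0, method="hybr", tol=1e-12)
        if scaled_residual(res.x) <= scaled_residual(sol_x):
            sol_x = res.x
    except Exception:  # root can fail on pathological Jacobians; fallback below
        pass

    if scaled_residual(sol_x) >= CONVERGENCE_TOL:
        # Pseudo-transient continuation: integrate d(log C)/dt = f(C)/C.
        def rhs(_t, x):
            c = np.exp(np.clip(x, -46.0, 46.0))
            return residuals_from_logc(x) / c

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ivp = solve_ivp(rhs, (0.0, t_max), lx0, method="LSODA", rtol=1e-9, atol=1e-10)
        if ivp.success:
            try:
                res = root(residuals_from_logc, ivp.y[:, -1], method="hybr", tol=1e-12)
                cand = res.x
            except Exception:
                cand = ivp.y[:, -1]
            if scaled_residual(cand) < scaled_residual(sol_x):
                sol_x = cand
            elif scaled_residual(ivp.y[:, -1]) < scaled_residual(sol_x):
                sol_x = ivp.y[:, -1]

    resid = scaled_residual(sol_x)
    converged = resid < CONVERGENCE_TOL
    c = np.exp(np.clip(sol_x, -46.0, 46.0))
    conc = dict(base_conc)
    conc.update(zip(internal, c))
    flux = _flux_vector(model, rxns, conc, vmax, gamma)
    result = SteadyStateResult(
        fluxes={r.id: float(v) for r, v in zip(rxns, flux)},
        internal_concentrations={m: float(v) for m, v in zip(internal, c)},
        converged=converged,
        residual=resid,
        gamma=float(gamma),
    )
    if not converged:
        warnings.warn(
            f"steady state did not converge (residual {resid:.3e}) at glucose "
            f"{plasma.glucose} mM",
            RuntimeWarning,
            stacklevel=2,
        )
    return result
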