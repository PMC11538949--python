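"""Simulation protocols: capacity scans, glucose sweep, function panels.

The protocols mirror how perfused-liver capacities are probed experimentally:

* **substrate scans** titrate one plasma substrate over a grid while the rest
  of the plasma composition sits at a mid-physiological background (glucose
  6 mM, hormone coupling active) and read the relevant uptake/production
  flux at steady state; the maximal capacity is the flux at the top of the
  grid (saturation).
* the **glucose sweep** varies plasma glucose from the severely fasted
  (3 mM) to the well-fed (12 mM) state; at each level the hormone/NEFA
  transfer functions and the phosphorylation state set the regulatory
  context.  Net glucose exchange is signed so that production
  (gluconeogenesis) is negative and consumption (glycolysis) positive; the
  **neutral point** is the interpolated zero crossing.
* the **capacity panel** aggregates 14 maximal capacities plus fed/fasted
  physiological readouts per animal, and feeds group statistics, clustering
  and the enzyme-signature regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .individualize import VmaxSet
from .kinetics.hormones import gamma_at_glucose, hormone_transfer
from .kinetics.model import ModelDefinition
from .kinetics.solver import PlasmaState, solve_steady_state
from .proteomics import AbundanceMatrix
from .stats import clustergram, differential_test, two_group_test

__all__ = [
    "DEFAULT_GRIDS",
    "CAPACITY_FUNCTIONS",
    "CapacityCurve",
    "FunctionProfile",
    "substrate_scan",
    "glucose_sweep",
    "neutral_point",
    "capacity_panel",
    "profiles_frame",
    "group_compare_functions",
    "cluster_functions",
    "signature_regression",
]

#: Titration grids (mM) for the capacity scans and the glucose sweep.
DEFAULT_GRIDS: dict[str, np.ndarray] = {
    "glucose": np.round(np.arange(3.0, 12.0001, 0.05), 10),
    "fructose": np.round(np.arange(0.0, 10.0001, 0.25), 10),
    "galactose": np.round(np.arange(0.0, 10.0001, 0.25), 10),
    "glycerol": np.round(np.arange(0.0, 10.0001, 0.25), 10),
    "ffa": np.round(np.arange(0.0, 1.6001, 0.05), 10),
    "ammonia": np.round(np.arange(0.0, 5.0001, 0.1), 10),
    "ethanol": np.round(np.arange(0.0, 20.0001, 0.5), 10),
}

#: Which model flux a titration reads out.
_SCAN_FLUX = {
    "fructose": "fructose_uptake",
    "galactose": "galactose_uptake",
    "glycerol": "glycerol_uptake",
    "ffa": "fatty_acid_uptake",
    "ammonia": "ammonia_transport",
    "ethanol": "ethanol_uptake",
}

#: The 14 maximal capacities of the default panel.
CAPACITY_FUNCTIONS = (
    "fructose_uptake",
    "galactose_uptake",
    "glycerol_uptake",
    "glucose_production",
    "glucose_uptake",
    "glycogen_storage",
    "ffa_uptake",
    "tag_synthesis",
    "fatty_acid_synthesis",
    "vldl_export",
    "bhb_production",
    "urea_production",
    "ammonia_uptake",
    "ethanol_uptake",
)

#: Physiological readouts reported at the fed (12 mM) and fasted (3 mM) states.
PHYSIOLOGICAL_READOUTS = (
    "glucose_exchange",
    "glycogen_storage",
    "glycerol_uptake",
    "ffa_uptake",
    "tag_synthesis",
    "vldl_export",
    "urea_production",
    "glutamine_exchange",
    "glutamate_exchange",
    "tag_content",
)

SCAN_BACKGROUND_GLUCOSE = 6.0


@dataclass
class CapacityCurve:
    """Steady-state flux along one substrate titration."""

    substrate: str
    grid: np.ndarray
    flux: np.ndarray  # headline flux (masked NaN where the solver failed)
    fluxes: pd.DataFrame  # grid × all reaction fluxes
    converged: np.ndarray
    max_capacity: float

    @property
    def flagged(self) -> bool:
        return not bool(self.converged.all())


@dataclass
class FunctionProfile:
    """Per-animal metabolic function vector: capacities + fed/fasted readouts."""

    sample_id: str
    group: str | None
    capacities: dict[str, float]
    fed: dict[str, float] = field(default_factory=dict)
    fasted: dict[str, float] = field(default_factory=dict)
    flagged: bool = False


def _vmax_mapping(vmax_set) -> Mapping[str, float] | None:
    if vmax_set is None:
        return None
    return vmax_set.vmax if isinstance(vmax_set, VmaxSet) else vmax_set


def substrate_scan(
    model: ModelDefinition,
    vmax_set=None,
    substrate: str = "ffa",
    grid: Sequence[float] | None = None,
    background: PlasmaState | None = None,
) -> CapacityCurve:
    """Titrate one plasma substrate and record steady-state fluxes.

    The background plasma state sits at glucose 6 mM with the NEFA level set
    by the transfer function (unless the titrated substrate is FFA itself)
    and the phosphorylation state coupled to the background glucose.
    Non-converged grid points are masked and flag the curve.
    """
    if substrate not in _SCAN_FLUX:
        raise ValueError(f"unknown scan substrate {substrate!r}; choose from {sorted(_SCAN_FLUX)}")
    grid = np.asarray(DEFAULT_GRIDS[substrate] if grid is None else grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    if background is None:
        background = PlasmaState(
            glucose=SCAN_BACKGROUND_GLUCOSE,
            ffa=hormone_transfer(SCAN_BACKGROUND_GLUCOSE).nefa,
        )
    gamma = gamma_at_glucose(min(max(background.glucose, 2.0), 14.0))
    vmax = _vmax_mapping(vmax_set)

    rows, conv = [], []
    x0 = None
    for value in grid:
        plasma = background.replace(**{substrate: float(value)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = solve_steady_state(model, plasma, vmax_set=vmax, gamma=gamma, x0=x0)
        if res.converged:
            x0 = res.internal_concentrations
        rows.append(res.fluxes)
        conv.append(res.converged)
    fluxes = pd.DataFrame(rows, index=pd.Index(grid, name=substrate))
    conv = np.array(conv)
    headline = fluxes[_SCAN_FLUX[substrate]].to_numpy().copy()
    headline[~conv] = np.nan
    if not conv.all():
        warnings.warn(
            f"{substrate} scan: {int((~conv).sum())} grid points did not converge",
            RuntimeWarning,
            stacklevel=2,
        )
    return CapacityCurve(
        substrate=substrate,
        grid=grid,
        flux=headline,
        fluxes=fluxes,
        converged=conv,
        max_capacity=float(headline[-1]),
    )


def glucose_sweep(
    model: ModelDefinition,
    vmax_set=None,
    grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Steady-state function readouts across the fasted-to-fed glucose range.

    At each plasma glucose level the hormone transfer functions set NEFA and
    the phosphorylation state.  Returns one row per glucose level with the
    physiological readouts, the regulatory state and all reaction fluxes.
    """
    grid = np.asarray(DEFAULT_GRIDS["glucose"] if grid is None else grid, dtype=float)
    if grid.min() < 3.0 - 1e-9 or grid.max() > 12.0 + 1e-9:
        raise ValueError("glucose sweep grid must lie within [3, 12] mM")
    vmax = _vmax_mapping(vmax_set)
    rows = []
    x0 = None
    for g in grid:
        h = hormone_transfer(float(g))
        plasma = PlasmaState(glucose=float(g), ffa=h.nefa)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = solve_steady_state(model, plasma, vmax_set=vmax, x0=x0)
        if res.converged:
            x0 = res.internal_concentrations
        f = res.fluxes
        rows.append(
            {
                "glucose": g,
                "nefa": h.nefa,
                "gamma": res.gamma,
                "converged": res.converged,
                "glucose_exchange": f["glucose_transport"],
                "glycogen_storage": f["glycogen_synthase"] - f["glycogen_phosphorylase"],
                "glycerol_uptake": f["glycerol_uptake"],
                "ffa_uptake": f["fatty_acid_uptake"],
                "tag_synthesis": f["tag_synthesis"],
                "vldl_export": f["vldl_export"],
                "urea_production": f["urea_cycle"],
                "glutamine_exchange": f["glutaminase"],
                "glutamate_exchange": f["glutamate_transport"],
                "tag_content": f["tag_synthesis"] - f["lipolysis"],
                "bhb_production": f["ketogenesis"],
                "fatty_acid_synthesis": f["fatty_acid_synthesis"],
            }
        )
    return pd.DataFrame(rows)


def neutral_point(sweep: pd.DataFrame) -> float:
    """Glucose level where net hepatic glucose exchange crosses zero.

    Linear interpolation of the first production→consumption sign change in
    the sweep.  Returns NaN (with a warning) if the sweep never crosses zero.
    """
    g = sweep["glucose"].to_numpy()
    f = sweep["glucose_exchange"].to_numpy()
    for i in range(1, len(g)):
        if f[i - 1] < 0 <= f[i]:
            return float(g[i - 1] - f[i - 1] * (g[i] - g[i - 1]) / (f[i] - f[i - 1]))
    warnings.warn("no production-to-consumption switch in sweep", stacklevel=2)
    return float("nan")


def _single_profile(
    model: ModelDefinition,
    vmax_set,
    grids: Mapping[str, Sequence[float]],
    sample_id: str,
    group: str | None,
) -> FunctionProfile:
    sweep = glucose_sweep(model, vmax_set, grid=grids["glucose"])
    fasted = sweep.iloc[0]
    fed = sweep.iloc[-1]
    scans = {
        s: substrate_scan(model, vmax_set, s, grid=grids[s])
        for s in ("fructose", "galactose", "glycerol", "ffa", "ammonia", "ethanol")
    }
    flagged = (not bool(sweep["converged"].all())) or any(c.flagged for c in scans.values())

    capacities = {
        "fructose_uptake": scans["fructose"].max_capacity,
        "galactose_uptake": scans["galactose"].max_capacity,
        "glycerol_uptake": scans["glycerol"].max_capacity,
        "glucose_production": float(max(0.0, -fasted["glucose_exchange"])),
        "glucose_uptake": float(fed["glucose_exchange"]),
        "glycogen_storage": float(fed["glycogen_storage"]),
        "ffa_uptake": scans["ffa"].max_capacity,
        "tag_synthesis": float(scans["ffa"].fluxes["tag_synthesis"].iloc[-1]),
        "fatty_acid_synthesis": float(fed["fatty_acid_synthesis"]),
        "vldl_export": float(scans["ffa"].fluxes["vldl_export"].iloc[-1]),
        "bhb_production": float(fasted["bhb_production"]),
        "urea_production": float(scans["ammonia"].fluxes["urea_cycle"].iloc[-1]),
        "ammonia_uptake": scans["ammonia"].max_capacity,
        "ethanol_uptake": scans["ethanol"].max_capacity,
    }
    fed_readouts = {k: float(fed[k]) for k in PHYSIOLOGICAL_READOUTS}
    fasted_readouts = {k: float(fasted[k]) for k in PHYSIOLOGICAL_READOUTS}
    return FunctionProfile(
        sample_id=sample_id,
        group=group,
        capacities=capacities,
        fed=fed_readouts,
        fasted=fasted_readouts,
        flagged=flagged,
    )


def capacity_panel(
    model: ModelDefinition,
    vmax_sets: Sequence[VmaxSet] | VmaxSet,
    groups: Mapping[str, str] | None = None,
    grids: Mapping[str, Sequence[float]] | None = None,
) -> list[FunctionProfile]:
    """The full function panel (14 maximal capacities + fed/fasted readouts)
    for each animal's individualized model.  Deterministic."""
    if isinstance(vmax_sets, VmaxSet):
        vmax_sets = [vmax_sets]
    if not vmax_sets:
        raise ValueError("need at least one VmaxSet")
    use_grids = dict(DEFAULT_GRIDS)
    if grids:
        use_grids.update({k: np.asarray(v, dtype=float) for k, v in grids.items()})
    out = []
    for vs in vmax_sets:
        group = groups.get(vs.sample_id) if groups else None
        out.append(_single_profile(model, vs, use_grids, vs.sample_id, group))
    return out


def profiles_frame(
    profiles: Sequence[FunctionProfile], which: str = "capacities"
) -> pd.DataFrame:
    """Samples × functions matrix from a list of profiles.

    ``which`` selects ``capacities``, ``fed`` or ``fasted``.
    """
    if which not in ("capacities", "fed", "fasted"):
        raise ValueError("which must be one of capacities/fed/fasted")
    rows = {p.sample_id: getattr(p, which) for p in profiles}
    df = pd.DataFrame(rows).T
    df.index.name = "sample_id"
    return df


def group_compare_functions(
    profiles: Sequence[FunctionProfile], which: str = "capacities"
) -> pd.DataFrame:
    """Per-function two-group comparison (normality-gated t / rank-sum test).

    Returns mean per group, mean difference (case - control), the p-value,
    the test used, and the 0.05 / 0.01 significance tiers.
    """
    df = profiles_frame(profiles, which)
    groups = pd.Series({p.sample_id: p.group for p in profiles})
    if groups.isna().any():
        raise ValueError("profiles must carry group labels for comparison")
    ctrl = df.loc[groups == "control"]
    case = df.loc[groups == "case"]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for fn in df.columns:
        x, y = ctrl[fn].to_numpy(), case[fn].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, test = two_group_test(x, y)
        rows.append(
            {
                "function_id": fn,
                "mean_control": x.mean(),
                "mean_case": y.mean(),
                "mean_difference": y.mean() - x.mean(),
                "p": p,
                "test": test,
                "significant_0.05": p < 0.05,
                "significant_0.01": p < 0.01,
            }
        )
    return pd.DataFrame(rows).set_index("function_id")


def cluster_functions(profiles: Sequence[FunctionProfile], which: str = "capacities"):
    """Clustergram of the function panel: z-score per function, cluster
    functions (rows) and samples (columns)."""
    df = profiles_frame(profiles, which)
    if df.shape[1] < 2 or df.shape[0] < 4:
        raise ValueError("need >= 2 functions and >= 4 samples")
    return clustergram(df.T)  # rows = functions, columns = samples


def signature_regression(
    matrix: AbundanceMatrix,
    profiles: Sequence[FunctionProfile],
    function_id: str,
    which: str = "capacities",
    differential: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Protein signature of one metabolic function by per-protein OLS.

    Each protein's abundance across all samples (both groups pooled) is
    regressed against the per-sample value of the chosen function; the slope
    t-test p-value and R² are reported together with a cross-flag marking
    proteins that are differentially abundant between the groups.
    """
    df = profiles_frame(profiles, which)
    if function_id not in df.columns:
        raise KeyError(f"unknown function {function_id!r}")
    samples = [s for s in matrix.sample_ids if s in df.index]
    if len(samples) != len(matrix.sample_ids) or len(samples) != len(df):
        raise ValueError("samples of matrix and profiles are not aligned")
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for regression")

    y = df.loc[samples, function_id].to_numpy(dtype=float)
    x = matrix.intensities[samples].to_numpy(dtype=float)  # proteins × samples
    n = len(samples)
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean()
    sxx = ((x - xm) ** 2).sum(axis=1)
    syy = ((y - ym) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        r2 = np.where((sxx > 0) & (syy > 0), sxy**2 / (sxx * syy), 0.0)
        se = np.sqrt(np.maximum(syy / sxx - slope**2, 0.0) / (n - 2))
        t = np.where(se > 0, slope / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    # a perfect fit (zero residual, nonzero slope) is maximally significant
    p = np.where((se == 0) & (np.abs(slope) > 0), 0.0, p)
    p = np.where(np.isfinite(slope), p, 1.0)

    if differential is None:
        differential = differential_test(matrix)
    da = differential["significant"].reindex(matrix.intensities.index).fillna(False)
    return pd.DataFrame(
        {
            "slope": np.where(np.isfinite(slope), slope, np.nan),
            "p": p,
            "r2": np.where(np.isfinite(r2), r2, 0.0),
            "significant": p < alpha,
            "differentially_abundant": da.to_numpy(dtype=bool),
        },
        index=matrix.intensities.index,
    )
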