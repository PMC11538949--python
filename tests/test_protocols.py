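"""Capacity scans, glucose sweep, panel and group-level analyses.

Non-acceptance protocol tests run on coarse grids for speed; the default
(fine) grids are exercised by the calibration/acceptance tests.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from hepaflux.individualize import VmaxSet
from hepaflux.protocols import (
    CAPACITY_FUNCTIONS,
    capacity_panel,
    cluster_functions,
    glucose_sweep,
    group_compare_functions,
    neutral_point,
    profiles_frame,
    signature_regression,
    substrate_scan,
    FunctionProfile,
)
from hepaflux.proteomics import AbundanceMatrix
from conftest import COARSE_GRIDS


def _quiet_scan(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return substrate_scan(*args, **kwargs)


# --- neutral point -------------------------------------------------------

def test_neutral_point_linear_interpolation():
    sweep = pd.DataFrame({"glucose": np.arange(3.0, 12.1, 0.5)})
    sweep["glucose_exchange"] = sweep["glucose"] - 8.0
    assert neutral_point(sweep) == pytest.approx(8.0, abs=1e-12)


def test_neutral_point_no_crossing_flagged():
    sweep = pd.DataFrame({"glucose": [3.0, 6.0], "glucose_exchange": [1.0, 2.0]})
    with pytest.warns(UserWarning, match="no production-to-consumption"):
        assert np.isnan(neutral_point(sweep))


# --- scans ----------------------------------------------------------------

def test_zero_transporter_gives_flat_zero_curve(model):
    vmax = model.reference_vmax()
    vmax["fatty_acid_uptake"] = 0.0
    curve = _quiet_scan(model, vmax, "ffa", grid=COARSE_GRIDS["ffa"])
    assert np.allclose(curve.flux, 0.0, atol=1e-9)
    assert curve.max_capacity == pytest.approx(0.0, abs=1e-9)


def test_scan_curves_monotone_on_reference(model):
    for sub in ("fructose", "galactose", "glycerol", "ffa", "ammonia", "ethanol"):
        curve = _quiet_scan(model, None, sub, grid=COARSE_GRIDS[sub])
        assert not curve.flagged
        assert np.all(np.diff(curve.flux) >= -1e-6), sub


def test_halving_vmax_halves_capacity(model):
    full = _quiet_scan(model, None, "ffa", grid=COARSE_GRIDS["ffa"])
    half = _quiet_scan(
        model, {r: 0.5 * v for r, v in model.reference_vmax().items()}, "ffa",
        grid=COARSE_GRIDS["ffa"],
    )
    assert half.max_capacity == pytest.approx(0.5 * full.max_capacity, rel=1e-6)


def test_invalid_scan_arguments(model):
    with pytest.raises(ValueError, match="unknown scan substrate"):
        substrate_scan(model, None, "caffeine")
    with pytest.raises(ValueError, match="strictly increasing"):
        substrate_scan(model, None, "ffa", grid=[1.0, 0.5])


# --- glucose sweep --------------------------------------------------------

def test_sweep_signs_and_nefa_background(reference_sweep):
    """Fasted end produces glucose (negative exchange), fed end consumes;
    the NEFA background follows the transfer-function anchors."""
    s = reference_sweep
    assert s["glucose_exchange"].iloc[0] < 0
    assert s["glucose_exchange"].iloc[-1] > 0
    assert s["nefa"].iloc[0] == pytest.approx(1.0, abs=1e-9)
    assert s["nefa"].iloc[-1] == pytest.approx(0.2, abs=1e-9)
    assert s["converged"].all()


def test_fasted_fed_contrasts(reference_sweep):
    s = reference_sweep
    fasted, fed = s.iloc[0], s.iloc[-1]
    assert fasted["ffa_uptake"] > fed["ffa_uptake"]
    assert fasted["bhb_production"] > 10 * fed["bhb_production"]
    assert fed["glycogen_storage"] > fasted["glycogen_storage"]


def test_sweep_grid_bounds(model):
    with pytest.raises(ValueError, match="within"):
        glucose_sweep(model, grid=[2.0, 5.0])


# --- panel ----------------------------------------------------------------

def test_panel_has_14_capacities(cohort_profiles):
    assert len(CAPACITY_FUNCTIONS) == 14
    for p in cohort_profiles:
        assert set(p.capacities) == set(CAPACITY_FUNCTIONS)
        assert len(p.capacities) == 14
        assert p.fed and p.fasted


def test_identical_vmax_sets_identical_profiles(model):
    ref = model.reference_vmax()
    sets = [VmaxSet("a", dict(ref)), VmaxSet("b", dict(ref))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profiles = capacity_panel(model, sets, grids=COARSE_GRIDS)
    assert profiles[0].capacities == profiles[1].capacities
    assert profiles[0].fed == profiles[1].fed


def test_panel_deterministic(model):
    vs = VmaxSet("x", model.reference_vmax())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p1 = capacity_panel(model, vs, grids=COARSE_GRIDS)[0]
        p2 = capacity_panel(model, vs, grids=COARSE_GRIDS)[0]
    assert p1.capacities == p2.capacities and p1.fasted == p2.fasted


def test_cohort_direction_of_pregnancy_profile(cohort_profiles):
    """The case group's mean capacities fall for the FFA/urea axis."""
    df = profiles_frame(cohort_profiles, "capacities")
    groups = pd.Series({p.sample_id: p.group for p in cohort_profiles})
    ctrl = df.loc[groups == "control"].mean()
    case = df.loc[groups == "case"].mean()
    for fn in ("ffa_uptake", "urea_production", "bhb_production", "ammonia_uptake"):
        assert case[fn] < ctrl[fn], fn


# --- group statistics -----------------------------------------------------

def test_group_compare_functions_contract(cohort_profiles):
    res = group_compare_functions(cohort_profiles, "capacities")
    assert set(res.index) == set(CAPACITY_FUNCTIONS)
    assert res["p"].between(0, 1).all()
    assert (res["significant_0.01"] <= res["significant_0.05"]).all()
    assert res.loc["ffa_uptake", "mean_difference"] < 0
    assert res.loc["urea_production", "significant_0.05"]


def test_group_compare_null_cohort(model):
    """Identical-reference cohorts with tiny jitter: no function should be
    overwhelmingly significant."""
    rng = np.random.default_rng(0)
    ref = model.reference_vmax()
    sets, groups = [], {}
    for i in range(8):
        v = {k: x * float(np.exp(rng.normal(0, 0.02))) for k, x in ref.items()}
        sid = f"s{i}"
        sets.append(VmaxSet(sid, v))
        groups[sid] = "control" if i < 4 else "case"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profiles = capacity_panel(model, sets, groups=groups, grids=COARSE_GRIDS)
    res = group_compare_functions(profiles)
    assert res["significant_0.01"].sum() <= 2


# --- clustering -----------------------------------------------------------

def test_cluster_functions_standardization_and_split(cohort_profiles):
    res = cluster_functions(cohort_profiles, "capacities")
    z = res.standardized.to_numpy()
    assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(z.std(axis=1), 1, atol=1e-12)
    groups = pd.Series({p.sample_id: p.group for p in cohort_profiles})
    split = res.col_top_split
    # majority agreement between the top split and the true groups
    tab = pd.crosstab(split, groups.reindex(split.index))
    agreement = max(
        tab.loc[c].get("case", 0) + tab.drop(c).get("control", pd.Series(0)).sum()
        for c in tab.index
    )
    assert agreement >= 11  # of 15 samples


def test_cluster_membership_invariant_to_profile_order(cohort_profiles):
    res1 = cluster_functions(cohort_profiles, "capacities")
    res2 = cluster_functions(list(reversed(cohort_profiles)), "capacities")
    s1 = res1.col_top_split
    s2 = res2.col_top_split.reindex(s1.index)
    # same partition up to label swap
    same = (s1 == s2).all() or (s1 != s2).all()
    assert same


def test_cluster_functions_requires_enough_samples(cohort_profiles):
    with pytest.raises(ValueError):
        cluster_functions(cohort_profiles[:3])


# --- signature regression -------------------------------------------------

def _toy_profiles(matrix, capacity_values):
    return [
        FunctionProfile(sample_id=s, group=g, capacities={"cap": float(v)})
        for s, g, v in zip(matrix.sample_ids, matrix.groups, capacity_values)
    ]


def test_signature_regression_exact_linear_protein():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        rng.uniform(1e5, 1e7, size=(10, 6)),
        index=[f"p{i}" for i in range(10)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = pd.Series(["control"] * 3 + ["case"] * 3, index=df.columns)
    m = AbundanceMatrix(df, groups)
    cap = 2.0 + 3e-6 * df.loc["p4"]  # exact linear function of protein p4
    res = signature_regression(m, _toy_profiles(m, cap), "cap")
    assert res.loc["p4", "r2"] == pytest.approx(1.0, abs=1e-9)
    assert res.loc["p4", "slope"] == pytest.approx(3e-6, rel=1e-9)
    assert res.loc["p4", "significant"]
    assert res["r2"].idxmax() == "p4"


def test_signature_regression_matches_closed_form():
    """Slope, p and R² agree with the simple-regression formulas on a
    six-point hand example."""
    from scipy import stats as sps

    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    y = np.array([2.0, 4.1, 5.9, 8.2, 9.8, 12.3])
    df = pd.DataFrame([x * 1e6], index=["p0"], columns=[f"s{i}" for i in range(6)])
    df.loc["p1"] = [5e6, 4e6, 6e6, 5.5e6, 4.5e6, 5e6]
    m = AbundanceMatrix(df, pd.Series(["control"] * 3 + ["case"] * 3, index=df.columns))
    res = signature_regression(m, _toy_profiles(m, y), "cap")
    ref = sps.linregress(x * 1e6, y)
    assert res.loc["p0", "slope"] == pytest.approx(ref.slope, rel=1e-9)
    assert res.loc["p0", "p"] == pytest.approx(ref.pvalue, rel=1e-6)
    assert res.loc["p0", "r2"] == pytest.approx(ref.rvalue**2, rel=1e-9)


def test_signature_regression_null_rate():
    """Permuted capacities: ~5% of proteins significant by chance."""
    rng = np.random.default_rng(2)
    df = pd.DataFrame(
        rng.lognormal(14, 1, size=(800, 12)),
        index=[f"p{i}" for i in range(800)],
        columns=[f"s{i}" for i in range(12)],
    )
    m = AbundanceMatrix(df, pd.Series(["control"] * 6 + ["case"] * 6, index=df.columns))
    cap = rng.normal(10, 1, size=12)
    res = signature_regression(m, _toy_profiles(m, cap), "cap")
    assert 0.01 < res["significant"].mean() < 0.10


def test_signature_regression_requires_alignment():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.uniform(1, 2, (4, 4)), index=list("abcd"),
                      columns=[f"s{i}" for i in range(4)])
    m = AbundanceMatrix(df, pd.Series(["control", "control", "case", "case"], index=df.columns))
    profiles = _toy_profiles(m, [1, 2, 3, 4])[:2]
    with pytest.raises(ValueError, match="aligned"):
        signature_regression(m, profiles, "cap")
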