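"""Biophysical imaging markers and their association with metabolic function.

Handles three per-sample scalar markers: shear wave speed ``c`` (m/s,
stiffness), penetration rate ``a`` (m/s, inverse viscosity) — both from
magnetic resonance elastography — and the apparent diffusion coefficient
``ADC`` (mm²/s) from diffusion-weighted imaging.  The ADC is obtained by
mono-exponential fitting (linear regression of -ln S against b over the
seven standard b-values).  Associations with metabolic functions use simple
OLS over all samples pooled, with significance (p < 0.05) and tendency
(0.05 <= p < 0.1) tiers.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .protocols import FunctionProfile, profiles_frame
from .stats import bh_adjust, two_group_test
from .synthetic import B_VALUES

__all__ = [
    "PROPERTIES",
    "fit_adc",
    "biophysics_records",
    "compare_groups_biophysics",
    "property_function_regression",
]

#: Recognized biophysical property columns.
PROPERTIES = ("c", "a", "adc")

SIGNIFICANCE_P = 0.05
TENDENCY_P = 0.10


def fit_adc(signals: pd.DataFrame) -> float:
    """Apparent diffusion coefficient (mm²/s) from a per-b-value signal table.

    Mono-exponential model ``S(b) = S0 * exp(-b * ADC)`` fitted by least
    squares on the log scale: the ADC is minus the slope of ``ln S`` vs
    ``b``.  Scale-invariant in S0 and exact on noiseless input.
    """
    if not {"b", "signal"} <= set(signals.columns):
        raise ValueError("signal table needs 'b' and 'signal' columns")
    b = signals["b"].to_numpy(dtype=float)
    s = signals["signal"].to_numpy(dtype=float)
    if len(np.unique(b)) < 2:
        raise ValueError("need at least 2 distinct b-values")
    if np.any(s <= 0):
        raise ValueError("non-positive signal; log-linear ADC fit undefined")
    slope, _ = np.polyfit(b, np.log(s), 1)
    return float(-slope)


def biophysics_records(
    sample_ids: Sequence[str],
    c: Sequence[float],
    a: Sequence[float],
    adc: Sequence[float],
) -> pd.DataFrame:
    """Assemble a per-sample biophysics table (columns: sample_id, c, a, adc)."""
    df = pd.DataFrame(
        {"sample_id": list(sample_ids), "c": c, "a": a, "adc": adc}
    ).set_index("sample_id")
    if (df <= 0).any().any():
        raise ValueError("biophysical properties must be positive")
    return df


def compare_groups_biophysics(
    records: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Group means ± SD and normality-gated two-sided test per property."""
    groups = pd.Series(dict(groups)).reindex(records.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    rows = []
    for prop in [p for p in PROPERTIES if p in records.columns]:
        x = records.loc[groups == "control", prop].to_numpy(dtype=float)
        y = records.loc[groups == "case", prop].to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need >= 2 samples per group")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, test = two_group_test(x, y)
        rows.append(
            {
                "property_id": prop,
                "mean_control": x.mean(),
                "sd_control": x.std(ddof=1),
                "mean_case": y.mean(),
                "sd_case": y.std(ddof=1),
                "p": p,
                "test": test,
            }
        )
    return pd.DataFrame(rows).set_index("property_id")


def _tier(p: float) -> str:
    if p < SIGNIFICANCE_P:
        return "significant"
    if p < TENDENCY_P:
        return "tendency"
    return "ns"


def property_function_regression(
    records: pd.DataFrame,
    profiles: Sequence[FunctionProfile] | pd.DataFrame,
    property_id: str,
    function_set: Iterable[str] | None = None,
    which: str = "capacities",
    bh: bool = False,
) -> pd.DataFrame:
    """OLS of each metabolic function on one biophysical property.

    All samples are pooled (control and case on one regression line).  The
    slope t-test p-value, R² and the significance/tendency tier are reported
    per function; an optional BH adjustment across the function set is off by
    default (raw p-values with 0.05/0.1 tiers are the primary report).
    """
    if property_id not in records.columns:
        raise KeyError(f"unknown property {property_id!r}")
    funcs = (
        profiles
        if isinstance(profiles, pd.DataFrame)
        else profiles_frame(profiles, which)
    )
    common = [s for s in records.index if s in funcs.index]
    if len(common) != len(records) or len(common) != len(funcs):
        raise ValueError("samples of records and profiles are not aligned")
    if len(common) < 3:
        raise ValueError("need at least 3 samples")
    x = records.loc[common, property_id].to_numpy(dtype=float)
    if function_set is not None:
        funcs = funcs[[f for f in function_set]]
    rows = []
    for fn in funcs.columns:
        y = funcs.loc[common, fn].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(
                {
                    "property_id": property_id,
                    "function_id": fn,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "p": 1.0,
                    "r2": 0.0,
                }
            )
            continue
        fit = sps.linregress(x, y)
        rows.append(
            {
                "property_id": property_id,
                "function_id": fn,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "p": float(fit.pvalue),
                "r2": float(fit.rvalue**2),
            }
        )
    df = pd.DataFrame(rows).set_index("function_id")
    if bh:
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df["tier"] = [_tier(p) for p in df["p_adj"]]
    else:
        df["tier"] = [_tier(p) for p in df["p"]]
    return df
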