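"""Shared fixtures: synthetic cohorts and (expensive) simulation products."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from hepaflux.individualize import cohort_models
from hepaflux.kinetics import default_model
from hepaflux.proteomics import AbundanceMatrix, reference_profile
from hepaflux.protocols import capacity_panel, glucose_sweep
from hepaflux.synthetic import (
    default_enzyme_map,
    generate_proteome,
    planted_effects,
    pregnancy_profile_fixture,
    profile_effects,
)

#: Coarse protocol grids for fast non-acceptance tests.
COARSE_GRIDS = {
    "glucose": np.round(np.arange(3.0, 12.001, 0.25), 10),
    "fructose": np.round(np.arange(0.0, 10.001, 1.0), 10),
    "galactose": np.round(np.arange(0.0, 10.001, 1.0), 10),
    "glycerol": np.round(np.arange(0.0, 10.001, 1.0), 10),
    "ffa": np.round(np.arange(0.0, 1.6001, 0.2), 10),
    "ammonia": np.round(np.arange(0.0, 5.001, 0.5), 10),
    "ethanol": np.round(np.arange(0.0, 20.001, 2.5), 10),
}


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def enzyme_map():
    return default_enzyme_map()


@pytest.fixture(scope="session")
def reference_sweep(model):
    """Glucose sweep of the shipped reference model at the default grid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return glucose_sweep(model)


def make_cohort_matrix(seed: int = 11, cv: float = 0.2, n_background: int = 60) -> AbundanceMatrix:
    """7 control + 8 case proteome embedding the pregnancy profile on the
    mapped enzymes plus random background proteins."""
    emap = default_enzyme_map()
    mapped = sorted({p for prots in emap.mapping.values() for p in prots})
    prof_eff = profile_effects(pregnancy_profile_fixture(), emap)
    rng = np.random.default_rng(seed)
    baseline = 10.0 ** rng.uniform(5.0, 9.0, size=len(mapped) + n_background)
    ids = mapped + [f"BG{i:04d}" for i in range(n_background)]
    fold = np.ones(len(ids))
    eff = {e.protein_id: 2.0**e.log2_effect for e in prof_eff}
    for i, p in enumerate(ids):
        fold[i] = eff.get(p, 1.0)
    n_control, n_case = 7, 8
    n = n_control + n_case
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    noise = (
        np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(len(ids), n)))
        if cv > 0
        else np.ones((len(ids), n))
    )
    mean = np.column_stack(
        [
            np.repeat(baseline[:, None], n_control, axis=1),
            (baseline * fold)[:, None] * np.ones((len(ids), n_case)),
        ]
    )
    samples = [f"ctrl_{i+1}" for i in range(n_control)] + [f"case_{i+1}" for i in range(n_case)]
    groups = pd.Series(["control"] * n_control + ["case"] * n_case, index=samples, dtype=object)
    return AbundanceMatrix(pd.DataFrame(mean * noise, index=ids, columns=samples), groups)


@pytest.fixture(scope="session")
def cohort_matrix():
    return make_cohort_matrix()


@pytest.fixture(scope="session")
def cohort_vmax_sets(cohort_matrix, model, enzyme_map):
    return cohort_models(cohort_matrix, model, enzyme_map)


@pytest.fixture(scope="session")
def cohort_profiles(model, cohort_vmax_sets, cohort_matrix):
    """Function panel for the 15-animal synthetic cohort (coarse grids)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return capacity_panel(
            model,
            cohort_vmax_sets,
            groups=cohort_matrix.groups.to_dict(),
            grids=COARSE_GRIDS,
        )


@pytest.fixture(scope="session")
def small_matrix():
    """A 60-protein 4 vs 4 proteome with a handful of planted effects."""
    ids = [f"P{i+1:05d}" for i in range(60)]
    eff = planted_effects(ids, 8, seed=5, min_log2=1.0, max_log2=2.0)
    return generate_proteome(4, 4, 60, effects=eff, cv=0.15, seed=5)
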