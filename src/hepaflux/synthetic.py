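"""Synthetic two-group proteomes, biophysical markers and DWI signals.

Every downstream stage of the pipeline can be exercised without any external
download: this module generates label-free proteome matrices with planted
differential effects (known ground truth), a fixed "pregnancy profile" of
enzyme changes for directional simulations, biophysical markers linearly
coupled to chosen metabolic capacities, and mono-exponential DWI signal decays
over the standard seven b-values.

All generators are deterministic for a fixed seed (``numpy.random.default_rng``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .proteomics import AbundanceMatrix, EnzymeMap

__all__ = [
    "EffectSpec",
    "PregnancyProfile",
    "B_VALUES",
    "generate_proteome",
    "planted_effects",
    "pregnancy_profile_fixture",
    "profile_effects",
    "generate_biophysics",
    "generate_dwi_signals",
    "default_enzyme_map",
    "write_truth_sidecar",
]

#: DWI diffusion-weighting factors (s/mm²).
B_VALUES = (50.0, 175.0, 300.0, 425.0, 550.0, 675.0, 800.0)

#: Log-uniform baseline intensity range: six decades of LFQ dynamic range.
BASELINE_DECADES = (4.0, 10.0)


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect on one protein (case vs control, log2 scale)."""

    protein_id: str
    log2_effect: float
    significant_flag: bool = True

    def __post_init__(self):
        if not np.isfinite(self.log2_effect):
            raise ValueError(f"non-finite log2 effect for {self.protein_id}")


@dataclass(frozen=True)
class PregnancyProfile:
    """Multiplicative enzyme/reaction abundance changes of late pregnancy.

    Keys are either model reaction ids (applied to every mapped protein) or
    individual protein ids (overriding the reaction-level factor).  Unlisted
    entries default to 1.0.
    """

    scale_factors: Mapping[str, float]

    _ALIASES = {
        "CPT1": "Cpt1a",
        "CPT2": "Cpt2",
        "CPS1": "Cps1",
        "OTC": "Otc",
        "ASL": "Asl",
        "NAGS": "Nags",
        "CGI-58": "Abhd5",
        "CGI58": "Abhd5",
        "perilipin-3": "Plin3",
    }

    def __post_init__(self):
        for key, f in self.scale_factors.items():
            if not f > 0:
                raise ValueError(f"scale factor for {key} must be > 0")

    def factor(self, key: str) -> float:
        key = self._ALIASES.get(key, key)
        return float(self.scale_factors.get(key, 1.0))


def pregnancy_profile_fixture() -> PregnancyProfile:
    """The fixed qualitative enzyme profile of the late-pregnant rat liver.

    Fatty-acid uptake transport is reduced by 20 %; the regulatory urea-cycle
    enzymes (CPS1, ornithine transporter, OTC, ASL, NAGS), the short/long
    chain acyl-CoA dehydrogenases, perilipin-3 and the glycolytic lump are
    downregulated (default factor 0.6 where no magnitude is established);
    the lipase co-activator CGI-58 (ABHD5) is upregulated; CPT1/CPT2 are
    unchanged.
    """
    factors: dict[str, float] = {
        # reaction-level
        "fatty_acid_uptake": 0.8,
        "glycolysis_lower": 0.6,
        # urea cycle regulatory enzymes (protein-level)
        "Cps1": 0.6,
        "Slc25a15": 0.6,  # ornithine transporter
        "Otc": 0.6,
        "Asl": 0.6,
        "Nags": 0.6,
        # lipid droplet regulation
        "Plin3": 0.6,
        "Abhd5": 1.5,
        # mitochondrial fatty acid oxidation
        "Cpt1a": 1.0,
        "Cpt2": 1.0,
        "Acads": 0.6,
        "Acadl": 0.6,
    }
    return PregnancyProfile(factors)


def default_enzyme_map() -> EnzymeMap:
    """Shipped reaction -> protein map for the ``hepatocore`` model."""
    import io

    ref = resources.files("hepaflux.data").joinpath("hepatocore_enzymes.tsv")
    df = pd.read_csv(io.StringIO(ref.read_text()), sep="\t")
    mapping: dict[str, list[str]] = {}
    for rid, sub in df.groupby("reaction_id", sort=False):
        mapping[str(rid)] = list(sub["protein_id"].astype(str))
    return EnzymeMap(mapping)


def profile_effects(profile: PregnancyProfile, enzyme_map: EnzymeMap) -> list[EffectSpec]:
    """Translate a reaction/protein profile into per-protein planted effects.

    Protein-level factors override the factor of the reaction a protein is
    mapped to; proteins mapped to several reactions take the strongest
    deviation from 1.
    """
    per_protein: dict[str, float] = {}
    for rid, prots in enzyme_map.mapping.items():
        f_rxn = profile.factor(rid)
        for p in prots:
            f = profile.factor(p) if p in profile.scale_factors else f_rxn
            cur = per_protein.get(p, 1.0)
            if abs(np.log2(f)) > abs(np.log2(cur)):
                per_protein[p] = f
    return [
        EffectSpec(p, float(np.log2(f)), significant_flag=(f != 1.0))
        for p, f in sorted(per_protein.items())
        if f != 1.0
    ]


def planted_effects(
    protein_ids: Sequence[str],
    n_effects: int,
    seed: int,
    min_log2: float = 0.5,
    max_log2: float = 2.0,
    frac_down: float = 0.5,
) -> list[EffectSpec]:
    """Sample a set of planted effects over a protein universe.

    Magnitudes are drawn uniformly in ``[min_log2, max_log2]`` on the log2
    scale with a configurable fraction of downregulated proteins.
    """
    if n_effects > len(protein_ids):
        raise ValueError("more effects than proteins")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(protein_ids), size=n_effects, replace=False)
    mags = rng.uniform(min_log2, max_log2, size=n_effects)
    down = rng.random(n_effects) < frac_down
    signs = np.where(down, -1.0, 1.0)
    return [
        EffectSpec(protein_ids[i], float(s * m)) for i, s, m in zip(chosen, signs, mags)
    ]


def generate_proteome(
    n_control: int,
    n_case: int,
    n_proteins: int,
    effects: Iterable[EffectSpec] = (),
    cv: float = 0.2,
    seed: int = 0,
    censor_threshold: float | None = None,
) -> AbundanceMatrix:
    """Generate a two-group log-normal LFQ intensity matrix.

    Per-protein baselines are log-uniform over six decades.  Case-group means
    are multiplied by ``2**log2_effect`` for each planted effect.  The
    multiplicative noise has unit mean and coefficient of variation ``cv``
    (``cv = 0`` produces exact noiseless ratios).

    Parameters
    ----------
    censor_threshold
        Optional left-censoring: intensities below this value are set to 0
        (missing), emulating the detection limit of label-free proteomics.
        Default off.
    """
    if n_control < 2 or n_case < 2:
        raise ValueError("need at least 2 samples per group")
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    if not cv >= 0:
        raise ValueError("cv must be >= 0")
    effects = list(effects)
    ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
    known = set(ids)
    seen: set[str] = set()
    for e in effects:
        if e.protein_id in seen:
            raise ValueError(f"duplicate protein in effects: {e.protein_id}")
        seen.add(e.protein_id)
        if e.protein_id not in known:
            raise ValueError(f"effect references unknown protein {e.protein_id}")

    rng = np.random.default_rng(seed)
    lo, hi = BASELINE_DECADES
    baseline = 10.0 ** rng.uniform(lo, hi, size=n_proteins)
    fold = np.ones(n_proteins)
    idx = {p: i for i, p in enumerate(ids)}
    for e in effects:
        fold[idx[e.protein_id]] = 2.0**e.log2_effect

    n = n_control + n_case
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(n_proteins, n)))
    else:
        noise = np.ones((n_proteins, n))
    mean = np.column_stack(
        [np.repeat(baseline[:, None], n_control, axis=1), (baseline * fold)[:, None] * np.ones((n_proteins, n_case))]
    )
    inten = mean * noise
    if censor_threshold is not None:
        inten = np.where(inten < censor_threshold, 0.0, inten)

    samples = [f"ctrl_{i + 1}" for i in range(n_control)] + [f"case_{i + 1}" for i in range(n_case)]
    groups = pd.Series(
        ["control"] * n_control + ["case"] * n_case, index=samples, dtype=object
    )
    df = pd.DataFrame(inten, index=pd.Index(ids, name="Protein IDs"), columns=samples)
    return AbundanceMatrix(df, groups)


def generate_biophysics(
    capacity: Sequence[float],
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int = 0,
) -> np.ndarray:
    """Biophysical property values linearly coupled to a metabolic capacity.

    ``property = intercept + slope * capacity + N(0, noise_sd)``; deterministic
    for a fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    cap = np.asarray(capacity, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=cap.shape) if noise_sd > 0 else 0.0
    return intercept + slope * cap + noise


def generate_dwi_signals(
    adc: float, s0: float, noise_sd: float, seed: int = 0
) -> pd.DataFrame:
    """Mono-exponential DWI signal decay at the seven standard b-values.

    ``S(b) = s0 * exp(-b * adc) + N(0, noise_sd)``, with b in s/mm² and adc
    in mm²/s.
    """
    if adc < 0:
        raise ValueError("adc must be >= 0")
    if not s0 > 0:
        raise ValueError("s0 must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    b = np.array(B_VALUES)
    rng = np.random.default_rng(seed)
    signal = s0 * np.exp(-b * adc)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=b.shape)
    return pd.DataFrame({"b": b, "signal": signal})


def write_truth_sidecar(
    path: str | Path,
    effects: Iterable[EffectSpec],
    seed: int,
    extra: Mapping | None = None,
) -> None:
    """Ground-truth JSON sidecar: planted effects and the generator seed."""
    payload = {
        "seed": int(seed),
        "effects": [
            {
                "protein_id": e.protein_id,
                "log2_effect": e.log2_effect,
                "significant_flag": bool(e.significant_flag),
            }
            for e in effects
        ],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
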