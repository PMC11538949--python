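"""Per-animal model instantiation by abundance scaling of maximal activities.

For each reaction the maximal activity of animal *a* is the reference value
scaled by the ratio of measured enzyme abundance to the control-mean
reference abundance::

    vmax_a = vmax_ref * E_a / E_ref

Isozymes/subunits mapped to one lumped reaction are aggregated by summation
*before* the ratio, so the mean of the individualized activities over control
animals recovers the reference activity exactly.  Reactions with no mapped
protein, a zero reference, or zero measured abundance fall back to the
reference activity (provenance ``reference_fallback``), never to a spurious
zero-capacity liver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics.model import ModelDefinition
from .proteomics import AbundanceMatrix, EnzymeMap, reaction_abundance, reference_profile

__all__ = ["VmaxSet", "scale_vmax", "build_individual_model", "cohort_models"]

logger = logging.getLogger(__name__)


@dataclass
class VmaxSet:
    """Per-reaction maximal activities (µmol·h⁻¹·g⁻¹) for one animal."""

    sample_id: str
    vmax: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for rid, v in self.vmax.items():
            if v < 0:
                raise ValueError(f"negative vmax for {rid}")

    @property
    def n_fallback(self) -> int:
        return sum(1 for p in self.provenance.values() if p == "reference_fallback")

    def scaled_by(self, factors: Mapping[str, float]) -> "VmaxSet":
        """New VmaxSet with reaction-level multiplicative factors applied."""
        vmax = {rid: v * factors.get(rid, 1.0) for rid, v in self.vmax.items()}
        return VmaxSet(self.sample_id, vmax, dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vmax": pd.Series(self.vmax),
                "provenance": pd.Series(self.provenance).reindex(self.vmax.keys()),
            }
        ).rename_axis("reaction_id")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def scale_vmax(vmax_ref: float, e_a: float, e_ref: float) -> float:
    """Scale a reference maximal activity by the abundance ratio E_a / E_ref.

    Raises ``ValueError`` for a non-positive reference abundance; the caller
    treats that as the fallback signal and keeps the reference activity.
    """
    if not vmax_ref > 0:
        raise ValueError("vmax_ref must be positive")
    if e_a < 0:
        raise ValueError("abundance must be non-negative")
    if not e_ref > 0:
        raise ValueError("reference abundance must be positive (fallback signal)")
    return vmax_ref * e_a / e_ref


def build_individual_model(
    model: ModelDefinition,
    matrix: AbundanceMatrix,
    enzyme_map: EnzymeMap,
    reference: pd.Series | None = None,
    sample_id: str | None = None,
) -> VmaxSet:
    """Individualized VmaxSet for one animal.

    Per reaction, the sample abundance and the reference abundance are the
    sums of the mapped proteins' intensities (sample values vs control-mean
    values); the reference activity is scaled by their ratio.  Unmapped
    reactions, zero references and zero sample abundances keep the reference
    activity with provenance ``reference_fallback``.
    """
    if sample_id not in matrix.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    if reference is None:
        reference = reference_profile(matrix)
    enzyme_map.validate_against(model)

    vmax: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for rid, rxn in model.reactions.items():
        per_sample = reaction_abundance(matrix, enzyme_map, rid)
        prots = [p for p in enzyme_map[rid] if p in reference.index]
        e_ref = float(reference.loc[prots].sum()) if prots else 0.0
        e_a = float(per_sample.loc[sample_id]) if not per_sample.isna().all() else np.nan
        if not np.isfinite(e_a) or e_ref <= 0 or e_a <= 0:
            vmax[rid] = rxn.vmax_ref
            provenance[rid] = "reference_fallback"
        else:
            vmax[rid] = scale_vmax(rxn.vmax_ref, e_a, e_ref)
            provenance[rid] = "scaled"
    n_fb = sum(1 for p in provenance.values() if p == "reference_fallback")
    if n_fb:
        logger.info("sample %s: %d reactions fell back to reference vmax", sample_id, n_fb)
    return VmaxSet(sample_id=sample_id, vmax=vmax, provenance=provenance)


def cohort_models(
    matrix: AbundanceMatrix,
    model: ModelDefinition,
    enzyme_map: EnzymeMap,
    reference: pd.Series | None = None,
) -> list[VmaxSet]:
    """One individualized VmaxSet per sample, in the matrix's sample order."""
    if reference is None:
        reference = reference_profile(matrix)
    return [
        build_individual_model(model, matrix, enzyme_map, reference, s)
        for s in matrix.sample_ids
    ]
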