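"""Reading and validating label-free proteome tables.

The on-disk format mirrors a MaxQuant ``proteinGroups`` export reduced to the
columns this pipeline needs: ``Protein IDs``, ``Gene names`` and one
``LFQ intensity <sample>`` column per sample.  Group membership (control vs
case) is supplied separately, either programmatically or via a YAML/CSV
mapping file.

The control reference profile (per-protein mean LFQ intensity over control
livers) and the per-reaction abundance aggregation defined here are the
inputs to the vmax individualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AbundanceMatrix",
    "EnzymeMap",
    "read_abundance_table",
    "read_group_assignment",
    "reference_profile",
    "reaction_abundance",
]

GROUPS = ("control", "case")
INTENSITY_PREFIX = "LFQ intensity "


@dataclass
class AbundanceMatrix:
    """Proteins × samples LFQ intensity matrix with group labels.

    ``intensities`` is a DataFrame indexed by protein id with one column per
    sample; ``groups`` maps each sample id to ``"control"`` or ``"case"``.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    gene_names: pd.Series | None = None

    def __post_init__(self):
        self.groups = pd.Series(self.groups, dtype=object).reindex(self.intensities.columns)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without group assignment: {missing}")
        unknown = set(self.groups.unique()) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}; expected {GROUPS}")
        if self.intensities.index.duplicated().any():
            dups = self.intensities.index[self.intensities.index.duplicated()].unique()
            raise ValueError(f"duplicate protein IDs: {list(dups)[:5]}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities")
        for g in GROUPS:
            if (self.groups == g).sum() < 2:
                raise ValueError(f"insufficient group size: need >= 2 '{g}' samples")
        all_zero = (self.intensities == 0).all(axis=1)
        if all_zero.any():
            warnings.warn(
                f"{int(all_zero.sum())} proteins have all-zero intensity", stacklevel=2
            )

    # -- selectors ------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_matrix(self, group: str) -> pd.DataFrame:
        return self.intensities[self.samples_in(group)]

    # -- i/o -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame({"Protein IDs": self.intensities.index})
        out["Gene names"] = (
            self.gene_names.reindex(self.intensities.index).fillna("").to_numpy()
            if self.gene_names is not None
            else ""
        )
        for s in self.sample_ids:
            out[f"{INTENSITY_PREFIX}{s}"] = self.intensities[s].to_numpy()
        out.to_csv(path, sep="\t", index=False)

    def median_normalized(self) -> "AbundanceMatrix":
        """Optional per-sample median normalization (default pipeline: off)."""
        med = self.intensities.replace(0, np.nan).median(axis=0)
        scale = med.mean() / med
        return AbundanceMatrix(self.intensities * scale, self.groups.copy(), self.gene_names)


def read_group_assignment(path: str | Path) -> dict[str, str]:
    """Sample -> group mapping from YAML (``sample: group``) or two-column CSV."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        payload = yaml.safe_load(path.read_text())
        return {str(k): str(v) for k, v in payload.items()}
    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_abundance_table(
    path: str | Path,
    group_assignment: Mapping[str, str] | str | Path,
    intensity_column_prefix: str = INTENSITY_PREFIX,
    median_normalize: bool = False,
) -> AbundanceMatrix:
    """Read a proteinGroups-style TSV into a validated :class:`AbundanceMatrix`.

    Parameters
    ----------
    path
        Tab-separated file with ``Protein IDs`` and per-sample intensity
        columns named ``<prefix><sample id>``.
    group_assignment
        sample id -> ``control``/``case``, or a path to a YAML/CSV mapping.
    """
    if not isinstance(group_assignment, Mapping):
        group_assignment = read_group_assignment(group_assignment)
    df = pd.read_csv(path, sep="\t")
    if "Protein IDs" not in df.columns:
        raise ValueError("malformed header: missing 'Protein IDs' column")
    sample_cols = [c for c in df.columns if c.startswith(intensity_column_prefix)]
    if not sample_cols:
        raise ValueError(f"malformed header: no '{intensity_column_prefix}*' columns")
    samples = [c[len(intensity_column_prefix):] for c in sample_cols]
    unknown = set(group_assignment) - set(samples)
    if unknown:
        raise ValueError(f"unknown samples in group assignment: {sorted(unknown)}")
    inten = df[sample_cols].copy()
    inten.columns = samples
    inten.index = df["Protein IDs"].astype(str)
    inten = inten[[s for s in samples if s in group_assignment]]
    genes = (
        df.set_index(df["Protein IDs"].astype(str))["Gene names"].astype(str)
        if "Gene names" in df.columns
        else None
    )
    mat = AbundanceMatrix(inten.astype(float), pd.Series(group_assignment), genes)
    return mat.median_normalized() if median_normalize else mat


@dataclass
class EnzymeMap:
    """reaction id -> protein ids (isozymes/subunits) catalyzing the lump."""

    mapping: dict[str, list[str]] = field(default_factory=dict)

    def __getitem__(self, reaction_id: str) -> list[str]:
        return self.mapping[reaction_id]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.mapping

    def reactions(self) -> list[str]:
        return list(self.mapping)

    def validate_against(self, model) -> None:
        """Every model reaction must appear (possibly with an empty list)."""
        missing = set(model.reactions) - set(self.mapping)
        if missing:
            raise ValueError(f"enzyme map missing model reactions: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnzymeMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"reaction_id", "protein_id"} <= set(df.columns):
            raise ValueError("enzyme map TSV needs 'reaction_id' and 'protein_id' columns")
        mapping: dict[str, list[str]] = {}
        for rid, sub in df.groupby("reaction_id", sort=False):
            prots = [p for p in sub["protein_id"].astype(str) if p and p != "nan"]
            mapping[str(rid)] = prots
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"reaction_id": rid, "protein_id": pid}
            for rid, prots in self.mapping.items()
            for pid in (prots or [""])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def reference_profile(matrix: AbundanceMatrix) -> pd.Series:
    """Per-protein arithmetic mean intensity over control samples only."""
    controls = matrix.samples_in("control")
    if len(controls) < 2:
        raise ValueError("need >= 2 control samples for a reference profile")
    return matrix.intensities[controls].mean(axis=1)


def reaction_abundance(
    matrix: AbundanceMatrix, enzyme_map: EnzymeMap, reaction_id: str
) -> pd.Series:
    """Per-sample total intensity of the proteins mapped to one reaction.

    Isozymes/subunits are aggregated by summation (the maximal activity of a
    lumped reaction scales with total catalytic protein).  An unmapped
    reaction returns an all-NaN series flagged by the caller.
    """
    if reaction_id not in enzyme_map:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    prots = [p for p in enzyme_map[reaction_id] if p in matrix.intensities.index]
    if not prots:
        return pd.Series(np.nan, index=matrix.sample_ids, name=reaction_id)
    return matrix.intensities.loc[prots].sum(axis=0).rename(reaction_id)
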