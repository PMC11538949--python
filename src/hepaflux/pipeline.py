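"""End-to-end orchestration: proteome → statistics → individualized models →
function panels → structure–function correlation.

A single :class:`PipelineConfig` (usually loaded from YAML) drives the run;
every stage writes tidy TSV/JSON reports into the output directory and the
run log records seeds, package versions, fallback counts and solver flags.
Stage failures abort with a stage-tagged error message.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biophysics import compare_groups_biophysics, fit_adc, property_function_regression
from .individualize import cohort_models
from .kinetics.model import default_model, load_model_definition
from .protocols import (
    DEFAULT_GRIDS,
    capacity_panel,
    cluster_functions,
    glucose_sweep,
    group_compare_functions,
    neutral_point,
    profiles_frame,
)
from .proteomics import EnzymeMap, read_abundance_table, read_group_assignment
from .stats import clustergram, differential_test, log2_intensities, pca_scores, summarize_differential
from .synthetic import (
    default_enzyme_map,
    generate_biophysics,
    generate_proteome,
    planted_effects,
    pregnancy_profile_fixture,
    profile_effects,
    write_truth_sidecar,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_synthetic_inputs"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, thresholds and grids for one pipeline run."""

    abundance: str | Path
    groups: str | Path | Mapping[str, str]
    output: str | Path
    enzyme_map: str | Path | None = None
    model: str | Path | None = None
    biophysics: str | Path | None = None
    dwi: str | Path | None = None
    seed: int = 0
    p_threshold: float = 0.05
    p_strict: float = 0.01
    tendency: float = 0.10
    lfc_threshold: float = 1.0
    grids: dict = field(default_factory=dict)
    run_structure_function: bool = True

    def __post_init__(self):
        for name, v in (
            ("p_threshold", self.p_threshold),
            ("p_strict", self.p_strict),
            ("tendency", self.tendency),
        ):
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        paths = payload.get("paths", {})
        thr = payload.get("thresholds", {})
        return cls(
            abundance=paths["abundance"],
            groups=paths["groups"],
            output=paths.get("output", "hepaflux_out"),
            enzyme_map=paths.get("enzyme_map"),
            model=paths.get("model"),
            biophysics=paths.get("biophysics"),
            dwi=paths.get("dwi"),
            seed=int(payload.get("seed", 0)),
            p_threshold=float(thr.get("p", 0.05)),
            p_strict=float(thr.get("p_strict", 0.01)),
            tendency=float(thr.get("tendency", 0.10)),
            lfc_threshold=float(thr.get("log2fc", 1.0)),
            grids=payload.get("grids", {}),
            run_structure_function=bool(payload.get("run_structure_function", True)),
        )


def _expand_grids(grids: Mapping) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for key, spec in grids.items():
        if key not in DEFAULT_GRIDS:
            raise PipelineError("config", f"unknown grid {key!r}")
        if isinstance(spec, Mapping):
            out[key] = np.round(
                np.arange(spec["start"], spec["stop"] + 1e-9, spec["step"]), 10
            )
        else:
            out[key] = np.asarray(spec, dtype=float)
    return out


def write_synthetic_inputs(
    outdir: str | Path,
    seed: int = 0,
    n_control: int = 7,
    n_case: int = 8,
    n_proteins: int = 400,
    n_random_effects: int = 40,
    cv: float = 0.2,
) -> dict[str, Path]:
    """Generate a complete synthetic input bundle for a pipeline run.

    The proteome embeds the shipped enzyme map's proteins (case samples carry
    the pregnancy profile) plus random background proteins with planted
    effects; biophysical markers are linearly coupled to the planted FFA
    signal with noise; the ground truth goes to a JSON sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    emap = default_enzyme_map()
    mapped = sorted({p for prots in emap.mapping.values() for p in prots})
    profile = pregnancy_profile_fixture()
    prof_eff = profile_effects(profile, emap)

    n_background = max(n_proteins - len(mapped), 0)
    bg_ids = [f"P{i + 1:05d}" for i in range(n_background)]
    bg_eff = planted_effects(bg_ids, min(n_random_effects, n_background), seed=seed + 1)

    matrix = generate_proteome(
        n_control, n_case, n_background, effects=bg_eff, cv=cv, seed=seed
    )
    rng = np.random.default_rng(seed + 2)
    baseline = 10.0 ** rng.uniform(5.5, 8.5, size=len(mapped))
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    noise = (
        np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(len(mapped), n_control + n_case)))
        if cv > 0
        else np.ones((len(mapped), n_control + n_case))
    )
    fold = np.array([2.0 ** next((e.log2_effect for e in prof_eff if e.protein_id == p), 0.0) for p in mapped])
    mean = np.column_stack(
        [
            np.repeat(baseline[:, None], n_control, axis=1),
            (baseline * fold)[:, None] * np.ones((len(mapped), n_case)),
        ]
    )
    mapped_df = pd.DataFrame(mean * noise, index=mapped, columns=matrix.sample_ids)
    inten = pd.concat([mapped_df, matrix.intensities])
    from .proteomics import AbundanceMatrix

    full = AbundanceMatrix(inten, matrix.groups)

    paths: dict[str, Path] = {}
    paths["abundance"] = outdir / "proteome.tsv"
    full.to_tsv(paths["abundance"])
    paths["groups"] = outdir / "groups.yaml"
    paths["groups"].write_text(yaml.safe_dump(full.groups.to_dict()))
    paths["enzyme_map"] = outdir / "enzyme_map.tsv"
    emap.to_tsv(paths["enzyme_map"])

    # biophysical markers: penetration rate coupled to the planted FFA change
    is_case = (full.groups == "case").to_numpy()
    drive = np.where(is_case, 0.8, 1.0)  # FFA-uptake transporter factor
    a = generate_biophysics(drive, slope=-4.0, intercept=5.5, noise_sd=0.25, seed=seed + 3)
    c = generate_biophysics(drive, slope=0.0, intercept=1.8, noise_sd=0.15, seed=seed + 4)
    adc_true = np.where(is_case, 0.48e-3, 0.42e-3)
    adc = adc_true + np.random.default_rng(seed + 5).normal(0, 0.02e-3, size=adc_true.shape)
    bio = pd.DataFrame(
        {"sample_id": full.sample_ids, "c": c, "a": a, "adc": adc}
    )
    paths["biophysics"] = outdir / "biophysics.csv"
    bio.to_csv(paths["biophysics"], index=False)

    from .synthetic import generate_dwi_signals

    dwi_rows = []
    for i, (sid, adc_i) in enumerate(zip(full.sample_ids, adc_true)):
        tab = generate_dwi_signals(adc_i, s0=1.0, noise_sd=0.005, seed=seed + 100 + i)
        tab.insert(0, "sample_id", sid)
        dwi_rows.append(tab)
    paths["dwi"] = outdir / "dwi_signals.csv"
    pd.concat(dwi_rows).to_csv(paths["dwi"], index=False)

    paths["truth"] = outdir / "truth.json"
    write_truth_sidecar(paths["truth"], list(prof_eff) + list(bg_eff), seed)
    return paths


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and return the mapping of report names to paths."""
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log_lines = [f"hepaflux {__version__}", f"seed {config.seed}"]

    # -- proteomics_io ---------------------------------------------------
    try:
        groups = (
            dict(config.groups)
            if isinstance(config.groups, Mapping)
            else read_group_assignment(config.groups)
        )
        matrix = read_abundance_table(config.abundance, groups)
        emap = (
            EnzymeMap.from_tsv(config.enzyme_map)
            if config.enzyme_map
            else default_enzyme_map()
        )
    except Exception as exc:
        raise PipelineError("proteomics_io", str(exc)) from exc
    log_lines.append(
        f"abundance: {len(matrix.protein_ids)} proteins x {len(matrix.sample_ids)} samples"
    )

    # -- abundance_stats -------------------------------------------------
    try:
        diff = differential_test(
            matrix, alpha=config.p_threshold, lfc_threshold=config.lfc_threshold
        )
        written["differential"] = outdir / "differential_abundance.tsv"
        diff.to_csv(written["differential"], sep="\t")
        summary = summarize_differential(diff)
        scores, evr = pca_scores(matrix, n_components=2)
        written["pca"] = outdir / "pca_scores.tsv"
        scores.assign(group=matrix.groups).to_csv(written["pca"], sep="\t")
        cg = clustergram(log2_intensities(matrix))
        written["clustergram"] = outdir / "protein_clustergram_columns.tsv"
        pd.DataFrame(
            {"cluster": cg.col_top_split, "group": matrix.groups}
        ).to_csv(written["clustergram"], sep="\t")
    except Exception as exc:
        raise PipelineError("abundance_stats", str(exc)) from exc
    summary["pca_explained_variance"] = [float(v) for v in evr]

    # -- individualization ------------------------------------------------
    try:
        model = (
            load_model_definition(config.model) if config.model else default_model()
        )
        vmax_sets = cohort_models(matrix, model, emap)
        tidy = pd.concat(
            [vs.to_frame().assign(sample_id=vs.sample_id) for vs in vmax_sets]
        )
        written["vmax_sets"] = outdir / "vmax_sets.tsv"
        tidy.to_csv(written["vmax_sets"], sep="\t")
        n_fb = {vs.sample_id: vs.n_fallback for vs in vmax_sets}
        log_lines.append(f"vmax fallback counts: {n_fb}")
    except Exception as exc:
        raise PipelineError("individualization", str(exc)) from exc

    # -- capacity_protocols -----------------------------------------------
    try:
        grids = _expand_grids(config.grids)
        sweep_ref = glucose_sweep(model, grid=grids.get("glucose"))
        written["reference_sweep"] = outdir / "reference_glucose_sweep.tsv"
        sweep_ref.to_csv(written["reference_sweep"], sep="\t", index=False)
        summary["reference_neutral_point_mM"] = float(neutral_point(sweep_ref))

        profiles = capacity_panel(
            model, vmax_sets, groups=matrix.groups.to_dict(), grids=grids or None
        )
        panel = profiles_frame(profiles, "capacities")
        fed = profiles_frame(profiles, "fed").add_prefix("fed_")
        fasted = profiles_frame(profiles, "fasted").add_prefix("fasted_")
        full_panel = pd.concat([panel, fed, fasted], axis=1)
        full_panel.insert(0, "group", matrix.groups.reindex(full_panel.index))
        written["function_panel"] = outdir / "function_panel.tsv"
        full_panel.to_csv(written["function_panel"], sep="\t")

        stats_caps = group_compare_functions(profiles, "capacities")
        written["function_group_stats"] = outdir / "function_group_stats.tsv"
        stats_caps.to_csv(written["function_group_stats"], sep="\t")

        fc = cluster_functions(profiles, "capacities")
        written["function_cluster"] = outdir / "function_cluster_columns.tsv"
        pd.DataFrame(
            {"cluster": fc.col_top_split, "group": matrix.groups.reindex(fc.col_top_split.index)}
        ).to_csv(written["function_cluster"], sep="\t")
        flagged = [p.sample_id for p in profiles if p.flagged]
        if flagged:
            log_lines.append(f"panel solver flags: {flagged}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("capacity_protocols", str(exc)) from exc

    # -- structure_function ------------------------------------------------
    if config.run_structure_function and (config.biophysics or config.dwi):
        try:
            if config.biophysics and not Path(config.biophysics).exists():
                raise FileNotFoundError(f"biophysics table not found: {config.biophysics}")
            records = None
            if config.biophysics:
                records = pd.read_csv(config.biophysics).set_index("sample_id")
            if config.dwi:
                if not Path(config.dwi).exists():
                    raise FileNotFoundError(f"DWI table not found: {config.dwi}")
                dwi = pd.read_csv(config.dwi)
                adc_fit = (
                    dwi.groupby("sample_id", sort=False)
                    .apply(lambda g: fit_adc(g), include_groups=False)
                    .rename("adc_fit")
                )
                written["adc"] = outdir / "adc_fits.tsv"
                adc_fit.to_csv(written["adc"], sep="\t")
                if records is not None:
                    records = records.join(adc_fit)
            if records is not None:
                comp = compare_groups_biophysics(
                    records[[c for c in records.columns if c in ("c", "a", "adc")]],
                    matrix.groups.to_dict(),
                )
                written["biophysics_groups"] = outdir / "biophysics_group_stats.tsv"
                comp.to_csv(written["biophysics_groups"], sep="\t")
                regs = []
                for prop in ("c", "a", "adc"):
                    if prop in records.columns:
                        regs.append(
                            property_function_regression(
                                records[[prop]], profiles, prop
                            ).reset_index()
                        )
                sf = pd.concat(regs, ignore_index=True)
                written["structure_function"] = outdir / "structure_function_regression.tsv"
                sf.to_csv(written["structure_function"], sep="\t", index=False)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("structure_function", str(exc)) from exc
    elif config.run_structure_function and config.biophysics is None and config.dwi is None:
        log_lines.append("structure_function: skipped (no biophysics inputs)")

    written["summary"] = outdir / "summary.json"
    written["summary"].write_text(json.dumps(summary, indent=2, default=float))
    written["log"] = outdir / "run.log"
    written["log"].write_text("\n".join(log_lines) + "\n")
    return written
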