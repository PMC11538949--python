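"""Differential abundance and multivariate statistics for proteome matrices.

Pipeline stage behind the volcano plot, the protein clustergram, the PCA and
the pathway enrichment analysis: per-protein Welch tests on log2 intensities
with Benjamini–Hochberg control, classification into up / down /
sub-threshold / not-significant, sample-space PCA, per-row standardized
hierarchical clustering, and a gene-set-permutation enrichment score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .proteomics import AbundanceMatrix

__all__ = [
    "differential_test",
    "summarize_differential",
    "percent_differential",
    "bh_adjust",
    "normality_gate",
    "two_group_test",
    "pca_scores",
    "clustergram",
    "ClustergramResult",
    "EnrichmentResult",
    "enrichment_score",
    "enrichment_table",
    "read_gmt",
]


def log2_intensities(matrix: AbundanceMatrix) -> pd.DataFrame:
    """log2-transformed intensities; zeros replaced by half the smallest
    positive value in the matrix (variance-stabilizing floor)."""
    x = matrix.intensities.to_numpy(dtype=float).copy()
    pos = x[x > 0]
    floor = 0.5 * pos.min() if pos.size else 1.0
    x[x <= 0] = floor
    return pd.DataFrame(np.log2(x), index=matrix.intensities.index, columns=matrix.intensities.columns)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def differential_test(
    matrix: AbundanceMatrix,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Per-protein two-group differential abundance (case vs control).

    Welch's two-sided t-test on log2 intensities, BH adjustment over all
    proteins, and volcano classes: ``up`` (log2fc > threshold and
    significant), ``down`` (log2fc < -threshold and significant),
    ``sub-threshold`` (significant but small fold change), else ``ns``.
    Fold changes are log2 of the ratio of raw group means.

    Returns a DataFrame indexed by protein id with columns ``log2fc``,
    ``p_raw``, ``p_adj``, ``significant``, ``class``.
    """
    ctrl = matrix.group_matrix("control").to_numpy(dtype=float)
    case = matrix.group_matrix("case").to_numpy(dtype=float)
    logs = log2_intensities(matrix)
    lc = logs[matrix.samples_in("control")].to_numpy()
    lk = logs[matrix.samples_in("case")].to_numpy()

    mean_c = ctrl.mean(axis=1)
    mean_k = case.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_k / mean_c)

    degenerate = (lc.var(axis=1) == 0) & (lk.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(lk, lc, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} proteins with zero variance in both groups; p set to 1",
            stacklevel=2,
        )
        p[degenerate] = 1.0
    p = np.where(np.isfinite(p), p, 1.0)
    p_adj = bh_adjust(p)

    p_class = p_adj if use_adjusted else p
    significant = p_class < alpha
    klass = np.where(
        significant & (log2fc > lfc_threshold),
        "up",
        np.where(
            significant & (log2fc < -lfc_threshold),
            "down",
            np.where(significant, "sub-threshold", "ns"),
        ),
    )
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_raw": p,
            "p_adj": p_adj,
            "significant": significant,
            "class": klass,
        },
        index=matrix.intensities.index,
    )


def summarize_differential(results: pd.DataFrame) -> dict:
    """Bookkeeping over a differential table: counts and percentages."""
    n_total = len(results)
    n_up = int((results["class"] == "up").sum())
    n_down = int((results["class"] == "down").sum())
    n_sig = int(results["significant"].sum())
    return {
        "n_total": n_total,
        "n_up": n_up,
        "n_down": n_down,
        "n_significant": n_sig,
        "percent_updown": percent_differential(n_up + n_down, n_total),
        "percent_significant": percent_differential(n_sig, n_total),
    }


def percent_differential(n_regulated: int, n_total: int) -> float:
    """Share of regulated proteins, in percent, rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_regulated / n_total, 1)


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> str:
    """One-sample Kolmogorov–Smirnov check against a fitted normal.

    Returns ``"normal"`` or ``"non-normal"``; used by the group comparisons to
    choose between Welch's t-test and the rank-sum test.  The statistic is
    computed against a normal with the sample's own mean and SD, making the
    gate invariant to affine rescaling.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant sample in normality gate", stacklevel=2)
        return "non-normal"
    _, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return "normal" if p >= alpha else "non-normal"


def two_group_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, str]:
    """Normality-gated two-sided comparison of two independent samples.

    Welch's t-test when both samples pass the KS normality gate, otherwise
    the Wilcoxon rank-sum (Mann–Whitney) test.  Returns ``(p, test_name)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        warnings.warn("zero variance in both groups", stacklevel=2)
        return 1.0, "degenerate"
    if normality_gate(x) == "normal" and normality_gate(y) == "normal":
        return float(sps.ttest_ind(x, y, equal_var=False).pvalue), "welch"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue), "ranksum"


def pca_scores(
    matrix: AbundanceMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples in centered log2 intensity space.

    Returns the per-sample scores (samples × components) and the explained
    variance fractions (descending, summing to ≤ 1).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x = log2_intensities(matrix).to_numpy().T  # samples × proteins
    limit = min(x.shape[0] - 1, x.shape[1])
    if n_components > limit:
        raise ValueError(f"n_components must be <= {limit}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x - x.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


@dataclass
class ClustergramResult:
    """Row-standardized matrix with row/column dendrograms."""

    standardized: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    col_top_split: pd.Series  # column -> cluster {1, 2} at the top split

    def dropped_rows(self) -> list:
        return list(getattr(self, "_dropped", []))


def clustergram(data: pd.DataFrame) -> ClustergramResult:
    """Hierarchical clustering of a features × samples matrix.

    Each row is z-scored (mean 0, SD 1) before agglomerative clustering of
    rows and columns with Euclidean distance and average linkage.  Constant
    rows are dropped with a warning.  The top split of the column dendrogram
    (two-cluster cut) is returned for group-separation checks.
    """
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = list(data.index[~keep])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant rows", stacklevel=2)
    x = x[keep]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant rows")
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    zdf = pd.DataFrame(z, index=data.index[keep], columns=data.columns)

    row_link = hierarchy.linkage(z, method="average", metric="euclidean")
    col_link = hierarchy.linkage(z.T, method="average", metric="euclidean")
    row_order = [zdf.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [zdf.columns[i] for i in hierarchy.leaves_list(col_link)]
    split = hierarchy.fcluster(col_link, t=2, criterion="maxclust")
    result = ClustergramResult(
        standardized=zdf,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=row_order,
        col_order=col_order,
        col_top_split=pd.Series(split, index=zdf.columns),
    )
    result._dropped = dropped
    return result


@dataclass(frozen=True)
class EnrichmentResult:
    """Weighted running-sum enrichment of one gene set in a ranked list."""

    pathway_id: str
    es: float
    p_perm: float
    n_hits: int
    fdr: float = np.nan


def _running_sum_es(stats_sorted: np.ndarray, hit: np.ndarray, weight: float = 1.0) -> float:
    n = stats_sorted.size
    n_hits = int(hit.sum())
    n_miss = n - n_hits
    w = np.abs(stats_sorted) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    p_hit = np.cumsum(hit_w) / denom if denom > 0 else np.cumsum(hit) / max(n_hits, 1)
    p_miss = np.cumsum(~hit) / n_miss if n_miss > 0 else np.zeros(n)
    running = p_hit - p_miss
    es = float(running[np.argmax(np.abs(running))])
    return min(1.0, max(-1.0, es))  # guard cumsum roundoff at the bounds


def enrichment_score(
    ranked_stats: Sequence[tuple[str, float]],
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    pathway_id: str = "gene_set",
) -> EnrichmentResult:
    """Weighted Kolmogorov–Smirnov running-sum enrichment score.

    The list is ranked by the statistic (descending, stable ties); hits
    increment the running sum proportionally to ``|stat|**weight``, misses
    decrement it uniformly; the ES is the maximum signed deviation, in
    [-1, 1].  The null distribution is built by drawing random gene sets of
    equal size from the ranked universe (gene-set permutation), and
    ``p = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    ids = [i for i, _ in ranked_stats]
    stat = np.array([s for _, s in ranked_stats], dtype=float)
    order = np.argsort(-stat, kind="stable")
    ids_sorted = [ids[i] for i in order]
    stat_sorted = stat[order]
    genes = set(gene_set)
    hit = np.array([i in genes for i in ids_sorted])
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")

    es = _running_sum_es(stat_sorted, hit, weight)
    rng = np.random.default_rng(seed)
    n = len(ids_sorted)
    count = 0
    for _ in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=n_hits, replace=False)] = True
        if abs(_running_sum_es(stat_sorted, perm_hit, weight)) >= abs(es):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return EnrichmentResult(pathway_id=pathway_id, es=es, p_perm=p, n_hits=n_hits)


def enrichment_table(
    ranked_stats: Sequence[tuple[str, float]],
    gene_sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of several pathways with BH FDR across pathways.

    A pathway is called significantly regulated when both its permutation p
    and its BH FDR are at or below ``alpha``.
    """
    rows = []
    for k, (pid, genes) in enumerate(gene_sets.items()):
        r = enrichment_score(
            ranked_stats, genes, n_perm=n_perm, seed=seed + k, pathway_id=pid
        )
        rows.append({"pathway_id": pid, "es": r.es, "p_perm": r.p_perm, "n_hits": r.n_hits})
    df = pd.DataFrame(rows).set_index("pathway_id")
    df["fdr"] = bh_adjust(df["p_perm"].to_numpy())
    df["significant"] = (df["p_perm"] <= alpha) & (df["fdr"] <= alpha)
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: name, description, then member ids, tab-separated."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]}")
        sets[parts[0]] = set(parts[2:])
    return sets
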