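"""Differential statistics against independent oracles: Welch formula,
brute-force BH step-up, exhaustive running-sum enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hepaflux.proteomics import AbundanceMatrix
from hepaflux.stats import (
    bh_adjust,
    clustergram,
    differential_test,
    enrichment_score,
    enrichment_table,
    normality_gate,
    pca_scores,
    percent_differential,
    read_gmt,
    summarize_differential,
)
from hepaflux.synthetic import EffectSpec, generate_proteome


# --- independent oracles -------------------------------------------------

def bh_oracle(p):
    """Literal step-up definition: sort, scale by n/rank, enforce monotone
    from the largest rank down, cap at one."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running_min = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adj[i] = min(running_min, 1.0)
    return adj


def welch_oracle(x, y):
    """Textbook Welch statistic with Welch-Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


def es_oracle(ids, stat, genes, weight=1.0):
    """Exhaustive running-sum maximum, scanning every prefix explicitly."""
    order = sorted(range(len(ids)), key=lambda i: -stat[i])
    hits = [ids[i] in genes for i in order]
    w = [abs(stat[i]) ** weight for i in order]
    denom = sum(wi for wi, h in zip(w, hits) if h)
    n_miss = len(ids) - sum(hits)
    best, running = 0.0, 0.0
    for wi, h in zip(w, hits):
        running += (wi / denom) if h else (-1.0 / n_miss if n_miss else 0.0)
        if abs(running) > abs(best):
            best = running
    return best


# --- bh_adjust -----------------------------------------------------------

def test_bh_hand_examples():
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(300):
        p = rng.random(rng.integers(1, 40))
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


# --- differential_test ---------------------------------------------------

def _matrix_from_log2(ctrl_cols, case_cols):
    df = pd.DataFrame({**ctrl_cols, **case_cols}).astype(float)
    df = 2.0**df
    groups = pd.Series(
        ["control"] * len(ctrl_cols) + ["case"] * len(case_cols), index=df.columns
    )
    return AbundanceMatrix(df, groups)


def test_welch_textbook_example():
    """log2 groups (1,2,3) vs (2,3,4): |t| = 1.2247, p ~ 0.288."""
    m = _matrix_from_log2(
        {"c1": [1.0], "c2": [2.0], "c3": [3.0]}, {"k1": [2.0], "k2": [3.0], "k3": [4.0]}
    )
    res = differential_test(m)
    t_ref, p_ref = welch_oracle([2, 3, 4], [1, 2, 3])
    assert abs(t_ref) == pytest.approx(1.2247, abs=1e-4)
    assert res["p_raw"].iloc[0] == pytest.approx(p_ref, rel=1e-9)
    assert res["p_raw"].iloc[0] == pytest.approx(0.2879, abs=2e-4)


def test_noiseless_doubling_gives_unit_log2fc():
    m = generate_proteome(3, 3, 4, effects=[EffectSpec("P00002", 1.0)], cv=0.0, seed=0)
    with pytest.warns(UserWarning, match="zero variance"):
        res = differential_test(m)
    assert res.loc["P00002", "log2fc"] == pytest.approx(1.0, abs=1e-12)
    assert (res["p_raw"] == 1.0).all()  # degenerate-variance path


def test_null_type_i_error_near_nominal():
    """Under the null ~5% of raw p-values fall below 0.05."""
    fracs = []
    for seed in range(3):
        m = generate_proteome(7, 8, 2000, effects=(), cv=0.2, seed=seed)
        res = differential_test(m)
        fracs.append((res["p_raw"] < 0.05).mean())
    assert 0.035 < np.mean(fracs) < 0.065


def test_classes_partition_and_match_thresholds():
    m = generate_proteome(5, 5, 300, effects=[EffectSpec("P00010", 2.0), EffectSpec("P00020", -2.0)], cv=0.1, seed=1)
    res = differential_test(m)
    assert set(res["class"]) <= {"up", "down", "sub-threshold", "ns"}
    assert res.loc["P00010", "class"] == "up"
    assert res.loc["P00020", "class"] == "down"
    up = res[res["class"] == "up"]
    assert ((up["log2fc"] > 1.0) & (up["p_adj"] < 0.05)).all()
    counts = res["class"].value_counts()
    assert counts.sum() == len(res)


def test_percent_differential_arithmetic():
    assert percent_differential(30, 400) == 7.5
    with pytest.raises(ValueError):
        percent_differential(1, 0)


# --- normality gate -------------------------------------------------------

def test_normality_gate_on_gaussian_samples():
    rng = np.random.default_rng(1)
    calls = [normality_gate(rng.normal(size=200)) for _ in range(100)]
    frac_normal = np.mean([c == "normal" for c in calls])
    assert frac_normal >= 0.85  # ~0.95 expected at alpha = 0.05


def test_normality_gate_flags_heavy_outliers():
    rng = np.random.default_rng(2)
    flagged = 0
    for _ in range(20):
        x = np.concatenate([np.ones(50) + rng.normal(0, 1e-3, 50), [1000.0]])
        flagged += normality_gate(x) == "non-normal"
    assert flagged == 20


def test_normality_gate_affine_invariant():
    rng = np.random.default_rng(3)
    x = rng.normal(size=80)
    assert normality_gate(x) == normality_gate(5.0 + 3.0 * x)
    with pytest.warns(UserWarning, match="constant"):
        assert normality_gate(np.ones(10)) == "non-normal"


# --- PCA ------------------------------------------------------------------

def test_pca_line_explains_everything():
    """Samples on a line in protein space: PC1 captures 100% variance."""
    t = np.array([0.0, 1.0, 2.0, 3.0])
    direction = np.array([1.0, -2.0, 0.5, 3.0, 1.0])
    df = pd.DataFrame(2.0 ** (5 + np.outer(t, direction)).T,
                      index=[f"p{i}" for i in range(5)],
                      columns=["c1", "c2", "k1", "k2"])
    m = AbundanceMatrix(df, pd.Series(["control", "control", "case", "case"], index=df.columns))
    scores, evr = pca_scores(m, n_components=2)
    assert evr[0] == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9


def test_pca_invariant_to_sample_order(small_matrix):
    scores1, _ = pca_scores(small_matrix, 2)
    perm = list(np.random.default_rng(0).permutation(small_matrix.sample_ids))
    m2 = AbundanceMatrix(small_matrix.intensities[perm], small_matrix.groups[perm])
    scores2, _ = pca_scores(m2, 2)
    for pc in ("PC1", "PC2"):
        a = scores1[pc].reindex(perm).to_numpy()
        b = scores2[pc].to_numpy()
        assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)


def test_pca_separates_planted_groups(small_matrix):
    from sklearn.metrics import silhouette_score

    scores, _ = pca_scores(small_matrix, 2)
    labels = (small_matrix.groups == "case").astype(int).to_numpy()
    assert silhouette_score(scores.to_numpy(), labels) > 0


def test_pca_rejects_too_many_components(small_matrix):
    with pytest.raises(ValueError):
        pca_scores(small_matrix, 9)  # only 8 samples
    with pytest.raises(ValueError):
        pca_scores(small_matrix, 0)


# --- clustergram ----------------------------------------------------------

def _two_block_frame():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 0.3, size=(12, 4))
    b = rng.normal(3, 0.3, size=(12, 4))
    x = np.hstack([a, b]) + rng.normal(0, 0.05, size=(12, 8))
    return pd.DataFrame(x, index=[f"f{i}" for i in range(12)],
                        columns=[f"g1_{i}" for i in range(4)] + [f"g2_{i}" for i in range(4)])


def test_clustergram_standardization_contract():
    res = clustergram(_two_block_frame())
    z = res.standardized.to_numpy()
    assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(z.std(axis=1), 1, atol=1e-12)


def test_clustergram_top_split_recovers_blocks():
    res = clustergram(_two_block_frame())
    split = res.col_top_split
    g1 = set(split[[c for c in split.index if c.startswith("g1")]])
    g2 = set(split[[c for c in split.index if c.startswith("g2")]])
    assert len(g1) == 1 and len(g2) == 1 and g1 != g2


def test_clustergram_invariant_to_row_scaling():
    df = _two_block_frame()
    res1 = clustergram(df)
    scaled = df * np.array([10.0**i for i in range(len(df))])[:, None]
    res2 = clustergram(scaled)
    assert np.allclose(res1.standardized.to_numpy(), res2.standardized.to_numpy())
    assert res1.col_order == res2.col_order


def test_clustergram_drops_constant_rows():
    df = _two_block_frame()
    df.loc["const"] = 5.0
    with pytest.warns(UserWarning, match="constant"):
        res = clustergram(df)
    assert "const" not in res.standardized.index


# --- enrichment -----------------------------------------------------------

def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    stat = rng.normal(size=n)
    return [(f"g{i}", float(s)) for i, s in enumerate(stat)]


def test_es_full_set_is_one():
    ranked = _ranked(12)
    res = enrichment_score(ranked, {i for i, _ in ranked}, n_perm=100, seed=0)
    assert res.es == pytest.approx(1.0)


def test_es_sign_convention():
    ranked = [(f"g{i}", float(10 - i)) for i in range(10)]
    top = enrichment_score(ranked, {"g0", "g1", "g2"}, n_perm=100, seed=0)
    bottom = enrichment_score(ranked, {"g7", "g8", "g9"}, n_perm=100, seed=0)
    assert top.es > 0 > bottom.es


def test_es_matches_exhaustive_oracle():
    rng = np.random.default_rng(5)
    for trial in range(150):
        n = int(rng.integers(5, 30))
        ranked = _ranked(n, seed=trial)
        ids = [i for i, _ in ranked]
        stat = [s for _, s in ranked]
        k = int(rng.integers(1, n))
        genes = set(rng.choice(ids, size=k, replace=False))
        res = enrichment_score(ranked, genes, n_perm=100, seed=trial)
        assert res.es == pytest.approx(es_oracle(ids, stat, genes), abs=1e-12)
        assert -1.0 <= res.es <= 1.0


def test_es_permutation_p_reproducible_and_bounded():
    ranked = _ranked(40, seed=9)
    genes = {"g0", "g3", "g11", "g25"}
    r1 = enrichment_score(ranked, genes, n_perm=200, seed=7)
    r2 = enrichment_score(ranked, genes, n_perm=200, seed=7)
    assert r1.p_perm == r2.p_perm
    assert 0 < r1.p_perm <= 1
    with pytest.raises(ValueError):
        enrichment_score(ranked, {"absent"}, n_perm=100, seed=0)
    with pytest.raises(ValueError):
        enrichment_score(ranked, genes, n_perm=10, seed=0)


def test_enrichment_table_and_gmt(tmp_path):
    ranked = [(f"g{i}", float(20 - i)) for i in range(20)]
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("top\tdesc\tg0\tg1\tg2\tg3\nbottom\tdesc\tg16\tg17\tg18\tg19\n")
    sets = read_gmt(gmt)
    df = enrichment_table(ranked, sets, n_perm=200, seed=1)
    assert df.loc["top", "es"] > 0 > df.loc["bottom", "es"]
    assert {"es", "p_perm", "fdr", "significant"} <= set(df.columns)


def test_summarize_differential_counts(small_matrix):
    res = differential_test(small_matrix)
    s = summarize_differential(res)
    assert s["n_total"] == 60
    assert s["n_up"] + s["n_down"] <= s["n_significant"] + len(res)
    assert s["percent_updown"] == percent_differential(s["n_up"] + s["n_down"], 60)
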