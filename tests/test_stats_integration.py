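import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmrnull.stats_integration import (compare_groups, dmr_feature_pca,
                                       dunn_posthoc, enrichment_battery,
                                       expression_summary, fisher_association,
                                       marker_detection,
                                       methylation_expression_profile,
                                       spearman)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def test_mann_whitney_extreme_separation():
    """{1,2,3} vs {101,102,103}: U = 0, p equals the exact enumeration
    minimum 2/C(6,3) = 0.1."""
    res = compare_groups([1, 2, 3, 101, 102, 103], ["a"] * 3 + ["b"] * 3)
    assert res["test"] == "mann-whitney"
    assert res["statistic"] in (0.0, 9.0)  # U for one side; 9 = n1*n2 - 0
    assert res["p"] == pytest.approx(2 / 20)


def test_identical_groups_center_p():
    res = compare_groups([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    assert res["p"] > 0.9


def test_kruskal_matches_hand_rank_formula():
    groups = {"a": [1.0, 3.0], "b": [2.0, 5.0], "c": [4.0, 6.0]}
    values = sum(groups.values(), [])
    labels = sum([[k] * 2 for k in groups], [])
    res = compare_groups(values, labels, test="kruskal-wallis")
    ranks = stats.rankdata(values)
    n = len(values)
    by = {k: ranks[np.array(labels) == k] for k in groups}
    h = 12 / (n * (n + 1)) * sum(len(r) * r.mean() ** 2 for r in by.values()) \
        - 3 * (n + 1)
    assert res["statistic"] == pytest.approx(h)


def test_dunn_posthoc_bonferroni():
    rng = np.random.default_rng(0)
    values = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                             rng.normal(5, 1, 20)])
    labels = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
    res = compare_groups(values, labels, posthoc=True)
    ph = res["posthoc"]
    assert len(ph) == 3
    assert np.allclose(ph["p_adj"], np.minimum(ph["p"] * 3, 1.0))
    sig = ph[(ph["group2"] == "c") | (ph["group1"] == "c")]
    assert (sig["p_adj"] < 0.05).all()
    ab = ph[(ph["group1"] == "a") & (ph["group2"] == "b")]
    assert ab["p_adj"].iloc[0] > 0.05


def test_compare_groups_errors():
    with pytest.raises(ValueError):
        compare_groups([1, 2], ["a", "a"])
    with pytest.raises(ValueError):
        compare_groups([1, 2, 3], ["a", "b", "c"], test="mann-whitney")


# ---------------------------------------------------------------------------
# Fisher association
# ---------------------------------------------------------------------------

def test_fisher_balanced_table():
    bg = set(range(40))
    a = set(range(20))
    b = set(range(10, 30))
    res = fisher_association(a, b, bg)
    assert res["table"] == [[10, 10], [10, 10]]
    assert res["odds_ratio"] == 1.0 and res["p"] == 1.0


def test_fisher_matches_hypergeometric_tail_enumeration():
    # table [[20,5],[5,20]] via constructed sets
    bg = set(range(50))
    a = set(range(25))
    b = set(range(20)) | set(range(25, 30))
    res = fisher_association(a, b, bg)
    assert res["table"] == [[20, 5], [5, 20]]
    assert res["odds_ratio"] == pytest.approx((20 * 20) / (5 * 5))
    # brute-force two-sided exact p: sum of hypergeometric probabilities
    # of all tables (row/col margins fixed) no more likely than observed
    probs = [stats.hypergeom.pmf(k, 50, 25, 25) for k in range(26)]
    p_obs = stats.hypergeom.pmf(20, 50, 25, 25)
    p_exact = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
    assert res["p"] == pytest.approx(p_exact, rel=1e-9)


def test_fisher_zero_cell():
    bg = set(range(20))
    a = set(range(10))
    res = fisher_association(a, a, bg)
    assert np.isinf(res["odds_ratio"]) and 0 < res["p"] <= 1


def test_fisher_empty_background():
    with pytest.raises(ValueError):
        fisher_association({1}, {2}, set())


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_monotone_and_ties():
    rho, p = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
    assert rho == pytest.approx(1.0)
    rho2, _ = spearman([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
    assert rho2 == pytest.approx(-1.0)
    # ties handled with midranks: match the explicit rank-Pearson formula
    x = [1, 2, 2, 3, 4, 5, 5, 6, 7, 8, 9, 10]
    y = [2, 1, 4, 4, 3, 7, 6, 5, 9, 8, 11, 10]
    rho3, _ = spearman(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    assert rho3 == pytest.approx(np.corrcoef(rx, ry)[0, 1])


def test_spearman_exact_p_small_n():
    """Exact permutation p for n=4 equals full enumeration."""
    x = [1.0, 2.0, 3.0, 4.0]
    y = [1.0, 3.0, 2.0, 4.0]
    rho, p = spearman(x, y)
    rhos = []
    for perm in itertools.permutations([1, 3, 2, 4]):
        rhos.append(np.corrcoef([1, 2, 3, 4], perm)[0, 1])
    expected = np.mean([abs(r) >= abs(rho) - 1e-12 for r in rhos])
    assert p == pytest.approx(expected)


# ---------------------------------------------------------------------------
# methylation x expression
# ---------------------------------------------------------------------------

def test_expression_summary_zero_mean_is_na():
    tpm = pd.DataFrame({"gene_id": ["g1", "g2"],
                        "a": [1.0, 0.0], "b": [2.0, 0.0],
                        "c": [3.0, 4.0], "d": [5.0, 4.0]})
    out = expression_summary(tpm, ["a", "b"], ["c", "d"])
    assert np.isnan(out.loc[1, "log2fc"])
    assert out.loc[0, "log2fc"] == pytest.approx(np.log2(4.0 / 1.5))
    assert out.loc[0, "baseline"] == pytest.approx(11 / 4)


def _profile_fixture(sign):
    n = 12
    meth = np.linspace(0.2, 0.9, n)
    dmrs = pd.DataFrame({"all.mean": meth, "log2fc": sign * meth})
    classes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                            "dmr_index": range(n),
                            "location_class": ["5p_type2"] * n})
    expr = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                         "baseline": np.exp(sign * meth),
                         "log2fc": sign * meth})
    return dmrs, classes, expr


def test_methylation_expression_monotone_classes():
    dmrs, classes, expr = _profile_fixture(-1.0)
    out = methylation_expression_profile(dmrs, classes, expr)
    row = out[out["location_class"] == "5p_type2"].iloc[0]
    assert row["rho_baseline"] == pytest.approx(-1.0)   # anti-monotone
    assert row["rho_log2fc"] == pytest.approx(1.0)
    assert row["sign_concordance"] == pytest.approx(1.0)


def test_methylation_expression_small_class_is_na():
    dmrs, classes, expr = _profile_fixture(1.0)
    out = methylation_expression_profile(dmrs.iloc[:2], classes.iloc[:2],
                                         expr.iloc[:2])
    row = out.iloc[0]
    assert np.isnan(row["rho_baseline"]) and np.isnan(row["rho_log2fc"])


def test_multi_dmr_genes_are_averaged():
    dmrs = pd.DataFrame({"all.mean": [0.2, 0.8], "log2fc": [0.1, 0.3]})
    classes = pd.DataFrame({"gene_id": ["g", "g"], "dmr_index": [0, 1],
                            "location_class": ["body_only"] * 2})
    expr = pd.DataFrame({"gene_id": ["g"], "baseline": [5.0], "log2fc": [0.5]})
    out = methylation_expression_profile(dmrs, classes, expr, min_genes=1)
    assert out.iloc[0]["n_genes"] == 1  # one gene after averaging its 2 DMRs


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _block_matrix():
    rows = []
    for _ in range(10):
        rows.append([1, 1, 1, 0, 0, 0])
    for _ in range(10):
        rows.append([0, 0, 0, 1, 1, 1])
    m = pd.DataFrame(rows, columns=["gene_body", "exon", "intron",
                                    "te", "cne", "upstream"])
    # small perturbations so rows are not literally identical
    m.iloc[0, 5] = 1
    m.iloc[19, 0] = 1
    return m


def test_pca_separates_blocks():
    res = dmr_feature_pca(_block_matrix())
    pc1 = res.scores["PC1"].to_numpy()
    assert (pc1[:10] > 0).all() != (pc1[10:] > 0).all()  # opposite signs
    assert res.explained[0] > 0.5
    sig = res.feature_correlations
    assert (sig[sig["significant"]]["p_bonf"] < 0.05).all()


def test_pca_row_permutation_leaves_eigenvalues():
    m = _block_matrix()
    r1 = dmr_feature_pca(m)
    r2 = dmr_feature_pca(m.sample(frac=1.0, random_state=1))
    assert np.allclose(np.sort(np.abs(r1.explained)),
                       np.sort(np.abs(r2.explained)), atol=1e-10)


def test_pca_matches_power_iteration_oracle():
    rng = np.random.default_rng(2)
    m = pd.DataFrame(rng.integers(0, 2, size=(10, 6)),
                     columns=list("abcdef")).astype(float)
    m = m.loc[m.var(axis=1) > 0]
    res = dmr_feature_pca(m, n_pcs=1)
    corr = np.corrcoef(m.to_numpy())
    centered = corr - corr.mean(axis=0)
    scaled = centered / centered.std(axis=0, ddof=1)
    cov = scaled @ scaled.T
    v = np.ones(len(cov))
    for _ in range(5000):
        v = cov @ v
        v /= np.linalg.norm(v)
    lead = res.scores["PC1"].to_numpy()
    lead = lead / np.linalg.norm(lead)
    assert abs(abs(v @ lead) - 1.0) < 1e-6


def test_pca_constant_matrix_errors():
    m = pd.DataFrame(np.ones((5, 4)))
    with pytest.raises(ValueError):
        dmr_feature_pca(m)


# ---------------------------------------------------------------------------
# markers and enrichment
# ---------------------------------------------------------------------------

def test_marker_rule():
    fpkm = pd.DataFrame({"neuron": [10.0, 4.0, 10.0],
                         "glia": [1.0, 0.0, 3.0],
                         "endo": [1.0, 0.0, 3.0]},
                        index=["g1", "g2", "g3"])
    markers = marker_detection(fpkm)
    assert "g1" in markers["neuron"]       # 10 > 5 and 10 > 5*1
    assert "g2" not in markers["neuron"]   # fails > 5 FPKM
    assert "g3" not in markers["neuron"]   # 10 < 5*3
    with pytest.raises(ValueError):
        marker_detection(fpkm[["neuron"]])


def test_marker_lists_mutually_exclusive_on_separated_profiles():
    rng = np.random.default_rng(1)
    n, k = 60, 4
    fpkm = pd.DataFrame(rng.uniform(0, 0.5, size=(n, k)),
                        columns=[f"ct{i}" for i in range(k)],
                        index=[f"g{i}" for i in range(n)])
    for i in range(n):
        fpkm.iloc[i, i % k] = 50.0
    markers = marker_detection(fpkm)
    all_lists = [set(v) for v in markers.values()]
    for a, b in itertools.combinations(all_lists, 2):
        assert not (a & b)


def test_enrichment_battery_bh_stepup_and_bonferroni():
    bg = set(range(100))
    dmr_genes = set(range(20))
    sets = {f"s{i}": set(rng_set) for i, rng_set in enumerate(
        [range(0, 10), range(5, 30), range(50, 70), range(10, 90)])}
    bh = enrichment_battery(sets, dmr_genes, bg, correction="BH")
    raw = bh["p"].to_numpy()
    m = len(raw)
    order = np.argsort(raw)
    stepped = np.empty(m)
    prev = 1.0
    for rank, idx in list(enumerate(order))[::-1]:
        prev = min(prev, raw[idx] * m / (rank + 1))
        stepped[idx] = prev
    assert np.allclose(bh["p_adj"], stepped)
    bonf = enrichment_battery(sets, dmr_genes, bg, correction="bonferroni")
    assert np.allclose(bonf["p_adj"], np.minimum(raw * m, 1.0))
    assert (bonf["p_adj"].to_numpy() >= bh["p_adj"].to_numpy() - 1e-12).all()
    with pytest.raises(ValueError, match="disjoint"):
        enrichment_battery({"bad": {999}}, dmr_genes, bg)
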