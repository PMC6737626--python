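"""Statistical layer: group tests, categorical association, methylation vs
expression by DMR location, the DMR-feature PCA, and cell-type marker rules.

Non-parametric tests follow the analysis conventions of the study:
Mann-Whitney U for two groups, Kruskal-Wallis with Dunn's post-hoc
(Bonferroni) for more, Fisher's exact test for categorical association,
Spearman correlation for differently scaled variables (exact permutation
p for n <= 9), and Bonferroni or Benjamini-Hochberg correction batteries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compare_groups",
    "dunn_posthoc",
    "fisher_association",
    "spearman",
    "expression_summary",
    "gene_dmr_classes",
    "methylation_expression_profile",
    "dmr_feature_pca",
    "PCAResult",
    "marker_detection",
    "enrichment_battery",
]


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare_groups(values: Sequence[float], grouping: Sequence,
                   test: str = "auto", posthoc: bool = False,
                   correction: str = "bonferroni") -> dict:
    """Mann-Whitney U (two groups) or Kruskal-Wallis (more) on values.

    Returns a dict with ``test``, ``statistic``, ``p`` and, when requested
    for >2 groups, a Dunn pairwise table under ``posthoc``.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    labels = pd.unique(grouping)
    groups = [values[grouping == g] for g in labels]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >=2 nonempty groups")
    if test == "auto":
        test = "mann-whitney" if len(groups) == 2 else "kruskal-wallis"
    if test == "mann-whitney":
        if len(groups) != 2:
            raise ValueError("mann-whitney requires exactly two groups")
        stat, p = stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided")
        out = {"test": "mann-whitney", "statistic": float(stat), "p": float(p)}
    elif test == "kruskal-wallis":
        stat, p = stats.kruskal(*groups)
        out = {"test": "kruskal-wallis", "statistic": float(stat), "p": float(p)}
        if posthoc:
            out["posthoc"] = dunn_posthoc(values, grouping, correction=correction)
    else:
        raise ValueError(f"unknown test {test!r}")
    return out


def dunn_posthoc(values: Sequence[float], grouping: Sequence,
                 correction: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise rank test with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)), with
    T the standard tie term; two-sided normal p, optionally Bonferroni
    multiplied by the number of pairs.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    labels = list(pd.unique(grouping))
    ranks = stats.rankdata(values)
    n_total = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    pairs = list(itertools.combinations(labels, 2))
    for a, b in pairs:
        ra = ranks[grouping == a]
        rb = ranks[grouping == b]
        z = (ra.mean() - rb.mean()) / math.sqrt(
            var_base * (1.0 / len(ra) + 1.0 / len(rb)))
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p": p})
    df = pd.DataFrame(rows)
    if correction == "bonferroni":
        df["p_adj"] = np.minimum(df["p"] * len(pairs), 1.0)
    elif correction in ("BH", "bh", "fdr_bh"):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df


# ---------------------------------------------------------------------------
# categorical association
# ---------------------------------------------------------------------------

def fisher_association(in_set_a: set, in_set_b: set, background: set,
                       or_kind: str = "sample") -> dict:
    """Two-sided Fisher's exact test for membership association.

    Builds the 2x2 table over ``background`` and reports either the sample
    (cross-product) odds ratio or the conditional MLE.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    a = set(in_set_a) & background
    b = set(in_set_b) & background
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(background) - n11 - n10 - n01
    table = [[n11, n10], [n01, n00]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if or_kind == "sample":
        if n10 * n01 == 0:
            odds = math.inf if n11 * n00 > 0 else (0.0 if n11 == 0 or n00 == 0 else 1.0)
        else:
            odds = (n11 * n00) / (n10 * n01)
    elif or_kind == "conditional":
        odds = float(stats.contingency.odds_ratio(table).statistic)
    else:
        raise ValueError(f"unknown or_kind {or_kind!r}")
    return {"odds_ratio": float(odds), "p": float(p), "table": table,
            "or_kind": or_kind}


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _exact_spearman_p(rho: float, ranks_x: np.ndarray,
                      ranks_y: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman's rho (small n)."""
    n = len(ranks_x)
    perms = np.array(list(itertools.permutations(range(n))))
    ry = ranks_y[perms]
    rx = ranks_x - ranks_x.mean()
    ryc = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx ** 2).sum() * (ryc ** 2).sum(axis=1))
    rhos = (ryc @ rx) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho with exact permutation p for n <= 9, t otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    rho, p_t = stats.spearmanr(x, y)
    if len(x) <= 9:
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        return float(rho), _exact_spearman_p(float(rho), rx, ry)
    return float(rho), float(p_t)


# ---------------------------------------------------------------------------
# methylation x expression
# ---------------------------------------------------------------------------

def expression_summary(tpm: pd.DataFrame, group1: Sequence[str],
                       group2: Sequence[str]) -> pd.DataFrame:
    """Gene-level baseline (mean TPM over all samples) and log2(group2/group1).

    A zero group mean gives log2fc = NA (excluded from correlations).
    """
    samples = list(group1) + list(group2)
    baseline = tpm[samples].mean(axis=1)
    m1 = tpm[list(group1)].mean(axis=1)
    m2 = tpm[list(group2)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where((m1 > 0) & (m2 > 0), np.log2(m2 / m1), np.nan)
    return pd.DataFrame({"gene_id": tpm["gene_id"], "baseline": baseline,
                         "log2fc": log2fc})


LOCATION_CLASSES = ["body_only", "5p_type1", "5p_type2", "3p_type1", "3p_type2"]


def gene_dmr_classes(dmrs: pd.DataFrame, features) -> pd.DataFrame:
    """Long (gene_id, dmr_index, location_class) table.

    Classes: regulatory type-1/2 hits by side, and body-only for DMRs that
    overlap a gene body without touching its first/last 1 kb.
    """
    from .annotation import classify_regulatory_hits

    hits = classify_regulatory_hits(dmrs, features)
    rows = []
    for _, h in hits[hits["hit_type"].isin([1, 2])].iterrows():
        rows.append((h["gene_id"], h["dmr_index"],
                     f"{h['side']}_type{h['hit_type']}"))
    typed = {(g, i) for g, i, _ in rows}
    genes = features.genes
    for i, d in dmrs.reset_index(drop=True).iterrows():
        g_scaf = genes[genes["scaffold"] == d["scaffold"]]
        for _, g in g_scaf.iterrows():
            body = max(d["start"], g.start) < min(d["end"], g.end)
            if body and (g.gene_id, i) not in typed:
                rows.append((g.gene_id, i, "body_only"))
    return pd.DataFrame(rows, columns=["gene_id", "dmr_index", "location_class"])


def methylation_expression_profile(dmrs: pd.DataFrame, classes: pd.DataFrame,
                                   expression: pd.DataFrame,
                                   min_genes: int = 3) -> pd.DataFrame:
    """Spearman correlations of methylation vs expression per location class.

    For each class: rho(baseline TPM, DMR all.mean) and rho(expression
    log2fc, methylation log2fc), with DMR values averaged per gene when a
    gene carries more than one DMR; plus the per-class fraction of genes
    whose methylation and expression fold-differences share a sign.
    Classes with fewer than ``min_genes`` genes report NA.
    """
    d = dmrs.reset_index(drop=True)
    merged = classes.merge(
        d[["all.mean", "log2fc"]].rename(
            columns={"all.mean": "meth_mean", "log2fc": "meth_log2fc"}),
        left_on="dmr_index", right_index=True)
    per_gene = (merged.groupby(["location_class", "gene_id"])
                      [["meth_mean", "meth_log2fc"]].mean().reset_index())
    per_gene = per_gene.merge(expression, on="gene_id", how="inner")
    rows = []
    for cls, grp in per_gene.groupby("location_class"):
        rec = {"location_class": cls, "n_genes": len(grp)}
        base = grp.dropna(subset=["baseline", "meth_mean"])
        if len(base) >= min_genes and base["baseline"].nunique() > 1:
            rec["rho_baseline"], rec["p_baseline"] = spearman(
                base["baseline"], base["meth_mean"])
        else:
            rec["rho_baseline"] = rec["p_baseline"] = np.nan
        fc = grp.dropna(subset=["log2fc", "meth_log2fc"])
        if len(fc) >= min_genes and fc["log2fc"].nunique() > 1:
            rec["rho_log2fc"], rec["p_log2fc"] = spearman(
                fc["log2fc"], fc["meth_log2fc"])
        else:
            rec["rho_log2fc"] = rec["p_log2fc"] = np.nan
        rec["sign_concordance"] = float(
            np.mean(np.sign(fc["log2fc"]) == np.sign(fc["meth_log2fc"]))
        ) if len(fc) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DMR-feature PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame           # DMR x PC scores
    explained: np.ndarray          # variance fraction per PC
    feature_correlations: pd.DataFrame  # PC x feature r, p, p_bonf, significant


def dmr_feature_pca(matrix: pd.DataFrame, n_pcs: int = 5,
                    alpha: float = 0.05) -> PCAResult:
    """PCA of the DMR x DMR correlation matrix from a binary feature matrix.

    The binary overlap matrix (DMRs x feature classes) is turned into a
    DMR x DMR Pearson correlation matrix; that matrix is centered and
    scaled column-wise (prcomp-style) and decomposed by SVD.  Each of the
    first ``n_pcs`` PC score vectors is then correlated against each
    feature column, Bonferroni-corrected over n_pcs x n_features tests.
    Rows with no variance (all-zero or all-one feature vectors) are
    dropped before correlating.
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("feature matrix must be binary")
    row_var = X.var(axis=1)
    keep = row_var > 0
    if keep.sum() < 2:
        raise ValueError("matrix is (near-)constant: no row variation to correlate")
    Xk = X[keep]
    corr = np.corrcoef(Xk)
    centered = corr - corr.mean(axis=0)
    sd = centered.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    scaled = centered / sd
    u, s, _ = np.linalg.svd(scaled, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    scores = u[:, :n_pcs] * s[:n_pcs]
    explained = (s ** 2) / (s ** 2).sum()
    score_df = pd.DataFrame(scores, index=matrix.index[keep],
                            columns=[f"PC{i + 1}" for i in range(n_pcs)])
    rows = []
    n_tests = n_pcs * matrix.shape[1]
    for pc in score_df.columns:
        for feat in matrix.columns:
            fv = Xk[:, matrix.columns.get_loc(feat)]
            if np.ptp(fv) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(score_df[pc], fv)
            p_b = min(p * n_tests, 1.0) if np.isfinite(p) else np.nan
            rows.append({"pc": pc, "feature": feat, "r": r, "p": p,
                         "p_bonf": p_b,
                         "significant": bool(np.isfinite(p_b) and p_b < alpha)})
    return PCAResult(scores=score_df, explained=explained[:n_pcs],
                     feature_correlations=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cell-type markers and enrichment batteries
# ---------------------------------------------------------------------------

def marker_detection(fpkm_by_celltype: pd.DataFrame,
                     min_fpkm: float = 5.0,
                     fold: float = 5.0) -> dict[str, list]:
    """Cell-type markers: FPKM > 5 in the type and > 5x the mean of others."""
    if fpkm_by_celltype.shape[1] < 2:
        raise ValueError("need >=2 cell types")
    markers: dict[str, list] = {}
    cols = list(fpkm_by_celltype.columns)
    vals = fpkm_by_celltype.to_numpy(dtype=float)
    for j, ct in enumerate(cols):
        own = vals[:, j]
        others = np.delete(vals, j, axis=1).mean(axis=1)
        mask = (own > min_fpkm) & (own > fold * others)
        markers[ct] = list(fpkm_by_celltype.index[mask])
    return markers


def enrichment_battery(gene_sets: Mapping[str, set], dmr_genes: set,
                       background: set,
                       correction: str = "BH") -> pd.DataFrame:
    """Fisher enrichment of DMR genes in each gene set, with multiple-test
    correction across the battery (Bonferroni or Benjamini-Hochberg)."""
    background = set(background)
    dmr_genes = set(dmr_genes) & background
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes)
        if not genes & background:
            raise ValueError(f"gene set {name!r} disjoint from background")
        res = fisher_association(dmr_genes, genes, background)
        rows.append({"set": name, "n_set": len(genes & background),
                     "n_hit": res["table"][0][0],
                     "odds_ratio": res["odds_ratio"], "p": res["p"]})
    df = pd.DataFrame(rows)
    if correction.lower() in ("bh", "fdr_bh"):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    elif correction.lower() == "bonferroni":
        df["p_adj"] = np.minimum(df["p"] * len(df), 1.0)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df
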