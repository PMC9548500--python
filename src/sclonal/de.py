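"""Wilcoxon rank-sum differential expression and gene-set over-representation.

Per-gene two-sided Wilcoxon rank-sum tests between two cell groups on the
log-normalized scale, Bonferroni family-wise correction over the genes
actually tested, and fold changes on linear normalized means with a
pseudocount. Over-representation of a thresholded DE gene list in GMT gene
sets uses the upper-tail hypergeometric with Benjamini–Hochberg q-values.
"""

from __future__ import annotations

import warnings
from math import comb
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import _linear_from_norm

__all__ = [
    "wilcoxon_de",
    "wilcoxon_exact_p",
    "bonferroni_adjust",
    "read_gmt",
    "ora_enrichment",
    "select_de_genes",
]


def wilcoxon_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Wilcoxon rank-sum p over all group assignments (handles ties).

    Computes the exact permutation distribution of the group-A rank sum over
    every assignment of the pooled values into groups of the observed sizes
    (midranks for ties; counted by dynamic programming rather than literal
    enumeration), and doubles the smaller tail, capped at 1.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    # doubled midranks are integers, so the rank-sum distribution is a lattice
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(int)
    n1 = len(x)
    w_obs2 = int(ranks2[:n1].sum())

    max_sum = int(ranks2.sum())
    # dp[j, s] = number of size-j subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        dp[1 : n1 + 1, r:] += dp[0:n1, : max_sum + 1 - r]
    dist = dp[n1]
    total = comb(len(pooled), n1)
    n_le = dist[: w_obs2 + 1].sum()
    n_ge = dist[w_obs2:].sum()
    return float(min(1.0, 2.0 * min(n_le, n_ge) / total))


def bonferroni_adjust(p, m: int) -> np.ndarray:
    """Family-wise correction: each p -> min(1, p * m)."""
    p = np.asarray(p, dtype=float)
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def wilcoxon_de(
    norm: ad.AnnData,
    group_a,
    group_b,
    min_pct: float = 0.1,
    min_abs_log2fc_prefilter: float = 0.25,
    pseudocount: float = 1.0,
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Per-gene differential expression between two disjoint cell groups.

    Means are taken on the linear normalized scale (expm1 of the log values);
    log2FC = log2((mean_A + pseudocount) / (mean_B + pseudocount)). Genes are
    tested only when max(pct_A, pct_B) >= min_pct and |log2FC| >= the
    prefilter; p-values are exact by enumeration when both groups are of size
    <= ``exact_max_n``, else the tie- and continuity-corrected normal
    approximation. Bonferroni m = number of genes actually tested.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")

    lin = _linear_from_norm(norm)
    ia = norm.obs_names.get_indexer(group_a)
    ib = norm.obs_names.get_indexer(group_b)
    if (ia < 0).any() or (ib < 0).any():
        raise ValueError("group contains cells absent from the matrix")

    A, B = lin[ia], lin[ib]
    mean_a = np.asarray(A.mean(axis=0)).ravel()
    mean_b = np.asarray(B.mean(axis=0)).ravel()
    pct_a = np.asarray((A > 0).mean(axis=0)).ravel()
    pct_b = np.asarray((B > 0).mean(axis=0)).ravel()
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    tested = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(log2fc) >= min_abs_log2fc_prefilter)
    m = int(tested.sum())
    if m == 0:
        warnings.warn("all genes removed by the DE prefilters; empty table")

    pvals = np.full(norm.n_vars, np.nan)
    if m > 0:
        Xa = np.asarray(norm.X[ia][:, tested].todense() if sp.issparse(norm.X) else norm.X[np.ix_(ia, np.where(tested)[0])])
        Xb = np.asarray(norm.X[ib][:, tested].todense() if sp.issparse(norm.X) else norm.X[np.ix_(ib, np.where(tested)[0])])
        if len(group_a) <= exact_max_n and len(group_b) <= exact_max_n:
            pvals[tested] = [wilcoxon_exact_p(Xa[:, j], Xb[:, j]) for j in range(m)]
        else:
            res = stats.mannwhitneyu(Xa, Xb, alternative="two-sided", method="asymptotic", axis=0)
            pvals[tested] = res.pvalue

    padj = np.full(norm.n_vars, np.nan)
    if m > 0:
        padj[tested] = bonferroni_adjust(pvals[tested], m)
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "p_value": pvals,
            "p_adj": padj,
            "pct_A": pct_a,
            "pct_B": pct_b,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "tested": tested,
        },
        index=norm.var_names.copy(),
    )
    table.loc[~tested, ["p_value", "p_adj"]] = np.nan
    return table


def select_de_genes(table: pd.DataFrame, fc_threshold: float = 1.8, padj_threshold: float = 0.05) -> list[str]:
    """Genes with |fold change| > fc_threshold (linear scale) and p_adj < padj_threshold."""
    sel = (np.abs(table["log2FC"]) > np.log2(fc_threshold)) & (table["p_adj"] < padj_threshold)
    return list(table.index[sel.fillna(False)])


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: name <tab> description <tab> gene ... per line.

    Duplicate genes within a line are deduplicated; duplicate set names or
    lines with fewer than three fields are errors naming the line.
    """
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
        genes = {g for g in fields[2:] if g}
        if not genes:
            raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
        sets[name] = genes
    return sets


def ora_enrichment(
    de_genes,
    universe,
    gene_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``de_genes`` in each gene set.

    For a set S: K = |S ∩ universe| successes in a population of M = |universe|,
    n = |de_genes| draws, k = |S ∩ de_genes| observed; p = P(X >= k) upper
    tail; q = Benjamini–Hochberg over sets with K > 0. DE genes outside the
    universe are dropped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    de = set(de_genes)
    outside = de - universe
    if outside:
        warnings.warn(f"{len(outside)} DE genes outside the universe dropped")
        de &= universe

    M, n = len(universe), len(de)
    rows = []
    for name, genes in gene_sets.items():
        K = len(genes & universe)
        if K == 0:
            continue
        overlap = sorted(genes & de)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append((name, k, K, n, M, p, ",".join(overlap)))
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "M", "p", "genes"]).set_index("set")
    if len(table) > 0:
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["q"] = []
    return table.sort_values("p")
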