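"""Cell and gene quality control for UMI count matrices.

Normalization is per-cell scaling to 10,000 counts followed by log(x + 1);
cell filters are the conventional metric set — detected-gene bounds, UMI
floor, mitochondrial fraction cap, housekeeping-expression floor — plus a
simulated-doublet nearest-neighbour score; genes detected in too few kept
cells are removed afterwards. Boundary semantics are literal: genes >= min
and <= max, UMI >= min, mito < max, housekeeping mean > min, doublet score
< threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = ["QCThresholds", "lognormalize", "cell_qc_metrics", "doublet_scores", "apply_qc"]

FAILURE_REASONS = ["n_genes_low", "n_genes_high", "n_umi_low", "mito_high", "hk_low", "doublet"]


@dataclass(frozen=True)
class QCThresholds:
    """Cell and gene filter thresholds. ``min_hk`` / ``doublet_threshold`` may
    be None to disable the corresponding filter (e.g. when no housekeeping
    genes are annotated or doublet scores were not computed)."""

    min_genes: int = 300
    max_genes: int = 3000
    min_umi: int = 500
    max_mito: float = 0.2
    min_hk: float | None = 0.8
    min_cells_per_gene: int = 10
    doublet_threshold: float | None = 0.5

    def __post_init__(self):
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes > max_genes")
        for name, v in asdict(self).items():
            if v is not None and not np.isfinite(v):
                raise ValueError(f"threshold {name} must be finite")


def _raw_matrix(adata: ad.AnnData) -> sp.csr_matrix:
    X = adata.layers.get("counts", adata.X)
    return sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()


def lognormalize(adata: ad.AnnData, scale: float = 10_000.0, log_base: str = "natural") -> ad.AnnData:
    """Return a copy with X = log(count / cell_total * scale + 1).

    Natural log by default; ``log_base="two"`` divides by log(2). Zero counts
    map to exactly 0 and the sparsity pattern is preserved. Raw counts are
    kept in ``layers["counts"]``.
    """
    if log_base not in ("natural", "two"):
        raise ValueError("log_base must be 'natural' or 'two'")
    X = _raw_matrix(adata)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        raise ValueError(f"cells with zero total counts: {list(adata.obs_names[zero])[:10]}")
    norm = X.astype(np.float64).copy()
    norm = sp.csr_matrix(norm.multiply(scale / totals[:, None]))
    norm.data = np.log1p(norm.data)
    if log_base == "two":
        norm.data /= np.log(2.0)
    out = adata.copy()
    out.layers["counts"] = X
    out.X = norm
    out.uns["normalization"] = {"scale": scale, "log_base": log_base}
    return out


def _linear_from_norm(norm: ad.AnnData) -> sp.csr_matrix:
    """Undo the log: back to counts-per-scale units (expm1 on the stored base)."""
    base = norm.uns.get("normalization", {}).get("log_base", "natural")
    X = sp.csr_matrix(norm.X, dtype=np.float64).copy()
    if base == "two":
        X.data = np.exp2(X.data) - 1.0
    else:
        X.data = np.expm1(X.data)
    return X


def cell_qc_metrics(adata: ad.AnnData, annotation: pd.DataFrame, norm: ad.AnnData | None = None) -> pd.DataFrame:
    """Per-cell QC table: n_genes, n_umi, mito_ratio, hk_mean, doublet_score, pass.

    ``hk_mean`` is the mean *normalized* expression over housekeeping genes
    (the normalization precedes the housekeeping criterion); ``norm`` is
    computed on the fly when not supplied. doublet_score is NaN until filled
    by :func:`doublet_scores`; ``pass`` is filled by :func:`apply_qc`.
    """
    missing = adata.var_names.difference(annotation.index)
    if len(missing) > 0:
        raise ValueError(f"annotation does not cover genes: {list(missing)[:10]}")
    X = _raw_matrix(adata)
    cat = annotation.loc[adata.var_names, "category"].to_numpy()
    mito_mask = (annotation.loc[adata.var_names, "chromosome"] == "MT").to_numpy() | (cat == "mitochondrial")
    hk_mask = cat == "housekeeping"

    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        mito_ratio = np.where(n_umi > 0, np.asarray(X[:, mito_mask].sum(axis=1)).ravel() / n_umi, 0.0)
    if hk_mask.any():
        if norm is None:
            norm = lognormalize(adata)
        hk_mean = np.asarray(sp.csr_matrix(norm.X)[:, hk_mask].mean(axis=1)).ravel()
    else:
        hk_mean = np.full(adata.n_obs, np.nan)

    return pd.DataFrame(
        {
            "n_genes": n_genes,
            "n_umi": n_umi.astype(np.int64),
            "mito_ratio": mito_ratio,
            "hk_mean": hk_mean,
            "doublet_score": np.nan,
            "pass": pd.array([pd.NA] * adata.n_obs, dtype="boolean"),
        },
        index=adata.obs_names.copy(),
    )


def _lognorm_dense(X: sp.csr_matrix, scale: float = 10_000.0) -> np.ndarray:
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    out = sp.csr_matrix(X.multiply(scale / totals[:, None]))
    out.data = np.log1p(out.data)
    return out


def doublet_scores(
    adata: ad.AnnData,
    n_sim_ratio: float = 2.0,
    n_hvg: int = 1000,
    n_pcs: int = 20,
    k: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Simulated-doublet nearest-neighbour doublet score per cell, in [0, 1].

    round(n_sim_ratio * n) artificial doublets are synthesized by summing the
    raw counts of uniformly sampled observed cell pairs; observed + simulated
    cells are normalized jointly, restricted to the ``n_hvg`` most variable
    genes, and embedded in ``n_pcs`` principal components fitted on observed
    cells. The raw score f — the fraction of a cell's k nearest neighbours
    that are simulated — is rescaled by the simulation prior
    rho = n_sim / (n_sim + n) to f / (f + (1 - f) * rho / (1 - rho)),
    so 0.5 means "as doublet-like as a simulated doublet".
    """
    n = adata.n_obs
    if n < 50:
        raise ValueError("doublet scoring needs at least 50 cells")
    if k == 0:
        k = int(round(0.5 * np.sqrt(n)))
    if n <= k:
        raise ValueError(f"need more than k={k} cells")
    rng = np.random.default_rng(seed)
    X = _raw_matrix(adata)

    n_sim = int(round(n_sim_ratio * n))
    pairs = rng.integers(0, n, size=(n_sim, 2))
    sim = X[pairs[:, 0]] + X[pairs[:, 1]]

    joint = _lognorm_dense(sp.vstack([X, sim]).tocsr())
    obs_norm = joint[:n]
    # HVG by variance of the normalized expression, computed on observed cells
    mean = np.asarray(obs_norm.mean(axis=0)).ravel()
    sq = np.asarray(obs_norm.multiply(obs_norm).mean(axis=0)).ravel()
    var = sq - mean**2
    hvg = np.argsort(var)[::-1][: min(n_hvg, joint.shape[1])]
    joint_hvg = np.asarray(joint[:, hvg].todense())

    n_pcs = min(n_pcs, len(hvg), n - 1)
    pca = PCA(n_components=n_pcs, random_state=int(seed) % (2**32))
    pca.fit(joint_hvg[:n])
    emb = pca.transform(joint_hvg)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neigh = idx[:, 1:]  # drop self (an observed cell is always its own nearest point)
    f = (neigh >= n).mean(axis=1)

    rho = n_sim / (n_sim + n)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = f / (f + (1.0 - f) * rho / (1.0 - rho))
    return np.nan_to_num(score, nan=0.0)


def apply_qc(
    adata: ad.AnnData,
    qc: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[ad.AnnData, dict]:
    """Filter cells by the five predicates, then genes by detection in kept cells.

    A cell is kept iff n_genes in [min_genes, max_genes], n_umi >= min_umi,
    mito_ratio < max_mito, hk_mean > min_hk and doublet_score <
    doublet_threshold. Requesting the housekeeping or doublet filter (a
    non-None threshold) when the metric was never computed is an explicit
    error. Genes detected in fewer than ``min_cells_per_gene`` kept cells are
    then dropped. Returns the filtered AnnData and a report counting failures
    per reason (a cell may fail several).
    """
    missing = adata.obs_names.difference(qc.index)
    if len(missing) > 0:
        raise ValueError(f"QC table does not cover cells: {list(missing)[:10]}")
    q = qc.loc[adata.obs_names]

    fails = pd.DataFrame(index=q.index)
    fails["n_genes_low"] = q["n_genes"] < thresholds.min_genes
    fails["n_genes_high"] = q["n_genes"] > thresholds.max_genes
    fails["n_umi_low"] = q["n_umi"] < thresholds.min_umi
    fails["mito_high"] = q["mito_ratio"] >= thresholds.max_mito
    if thresholds.min_hk is not None:
        hk = q["hk_mean"]
        if hk.isna().all():
            raise ValueError(
                "housekeeping filter requested (min_hk set) but no housekeeping "
                "metric was computed; annotate housekeeping genes or set min_hk=None"
            )
        fails["hk_low"] = hk <= thresholds.min_hk
    else:
        fails["hk_low"] = False
    if thresholds.doublet_threshold is not None:
        ds = q["doublet_score"]
        if ds.isna().all():
            raise ValueError(
                "doublet filter requested (doublet_threshold set) but no doublet "
                "scores were computed; run doublet_scores or set doublet_threshold=None"
            )
        fails["doublet"] = ds >= thresholds.doublet_threshold
    else:
        fails["doublet"] = False

    keep_cells = ~fails.any(axis=1)
    kept = adata[keep_cells.to_numpy()].copy()

    Xk = _raw_matrix(kept)
    cells_per_gene = np.asarray((Xk > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= thresholds.min_cells_per_gene
    kept = kept[:, keep_genes].copy()

    report = {
        "n_cells_in": int(adata.n_obs),
        "n_cells_kept": int(kept.n_obs),
        "n_genes_in": int(adata.n_vars),
        "n_genes_kept": int(kept.n_vars),
        "cell_failures": {reason: int(fails[reason].sum()) for reason in FAILURE_REASONS},
        "genes_dropped_low_detection": int((~keep_genes).sum()),
        "thresholds": asdict(thresholds),
    }
    return kept, report
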