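"""Expression-inferred copy-number alteration profiles.

Malignant cells carry chromosome-scale gains and losses that shift the
expression of whole gene neighbourhoods up or down relative to copy-neutral
cells. With immune cells (T and B cells) as the "normal" reference, the
per-cell CNA signal is recovered by a deterministic chain:

1. drop genes whose mean normalized expression over all cells is below a
   cutoff (lowly expressed genes carry no dosage signal);
2. center each gene on its reference-cell mean;
3. clip residuals symmetrically (individual outlier genes must not dominate
   a window);
4. order genes genomically and smooth each cell's residual vector with a
   pyramidal moving window within each chromosome — windows never cross
   chromosome boundaries, since CNAs are intra-chromosomal events;
5. subtract each cell's median across genes (removes per-cell offsets from
   global expression differences);
6. re-center each gene on the post-smoothing reference mean, so reference
   cells average exactly zero everywhere.

The result is a genes x cells matrix of smoothed residuals ("CNA level",
0 = copy-neutral); tumor mean profiles over it are the vectors whose Pearson
correlation the clonality test uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CNAParams", "CNAMatrix", "TumorProfileSet", "infer_cna_matrix", "mean_cna_profiles", "pyramidal_weights"]


@dataclass(frozen=True)
class CNAParams:
    """Parameters of the smoothing chain.

    min_mean_expr: gene-inclusion cutoff on mean normalized expression.
    clip: symmetric cap on reference-centered residuals.
    window: odd number of genes per smoothing window.
    weights: "pyramidal" (1, 2, ..., ceil(w/2), ..., 2, 1) or "uniform".
    exclude_chromosomes: chromosome labels left out of the profile (the
        mitochondrial pseudo-chromosome by default; CNA profiles are
        autosomal).
    """

    min_mean_expr: float = 0.1
    clip: float = 3.0
    window: int = 101
    weights: str = "pyramidal"
    exclude_chromosomes: tuple[str, ...] = ("MT",)

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.clip <= 0:
            raise ValueError("clip must be positive")
        if self.weights not in ("pyramidal", "uniform"):
            raise ValueError("weights must be 'pyramidal' or 'uniform'")


@dataclass
class CNAMatrix:
    """Smoothed CNA residuals: DataFrame genes (genomic order) x cells."""

    values: pd.DataFrame
    gene_info: pd.DataFrame  # chromosome, start per retained gene, genomic order
    reference_cells: tuple[str, ...]
    params: CNAParams

    def to_frame(self) -> pd.DataFrame:
        out = self.gene_info.join(self.values)
        return out


@dataclass
class TumorProfileSet:
    """Mean CNA vector per group over a common gene index."""

    profiles: pd.DataFrame  # genes x groups
    group_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.profiles.columns)


def pyramidal_weights(window: int) -> np.ndarray:
    """1, 2, ..., ceil(window/2), ..., 2, 1 — the triangular window."""
    half = (window + 1) // 2
    return np.concatenate([np.arange(1, half + 1), np.arange(half - 1, 0, -1)]).astype(float)


def _chromosome_sort_key(labels: pd.Series) -> pd.Series:
    """Numeric labels in numeric order, then the rest lexicographically."""
    def key(c: str):
        try:
            return (0, int(c), "")
        except ValueError:
            return (1, 0, c)

    return labels.map(key)


def _smoothing_matrix(n_genes: int, window: int, weights: str) -> sp.csr_matrix:
    """Banded row-stochastic smoother; rows truncated and renormalized at edges."""
    w = pyramidal_weights(window) if weights == "pyramidal" else np.ones(window)
    half = window // 2
    offsets = range(-half, half + 1)
    diags = [np.full(n_genes - abs(off), w[half + off]) for off in offsets if abs(off) < n_genes]
    offs = [off for off in offsets if abs(off) < n_genes]
    S = sp.diags(diags, offs, shape=(n_genes, n_genes), format="csr")
    row_sums = np.asarray(S.sum(axis=1)).ravel()
    return sp.diags(1.0 / row_sums) @ S


def infer_cna_matrix(
    norm: ad.AnnData,
    annotation: pd.DataFrame,
    reference_cells,
    query_cells,
    params: CNAParams = CNAParams(),
) -> CNAMatrix:
    """Run the six-step smoothing chain; returns residuals for all cells.

    ``norm`` is the log-normalized expression (cells x genes). Reference and
    query sets must be disjoint; reference rows are retained in the output as
    the copy-neutral control.
    """
    reference_cells = list(reference_cells)
    query_cells = list(query_cells)
    if len(reference_cells) < 2:
        raise ValueError("need at least 2 reference cells")
    overlap = set(reference_cells) & set(query_cells)
    if overlap:
        raise ValueError(f"reference and query cells overlap: {sorted(overlap)[:5]}")
    cells = reference_cells + query_cells
    missing = set(cells) - set(norm.obs_names)
    if missing:
        raise ValueError(f"cells not in matrix: {sorted(missing)[:5]}")
    missing_genes = norm.var_names.difference(annotation.index)
    if len(missing_genes) > 0:
        raise ValueError(f"annotation does not cover genes: {list(missing_genes)[:5]}")

    sub = norm[cells]
    X = sub.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)

    # (1) gene inclusion on mean normalized expression over ALL cells
    ann = annotation.loc[norm.var_names]
    keep = (X.mean(axis=0) >= params.min_mean_expr) & ~ann["chromosome"].isin(params.exclude_chromosomes).to_numpy()
    X = X[:, keep]
    ann = ann.loc[keep]

    # (2) reference centering, (3) clipping
    n_ref = len(reference_cells)
    ref_mean = X[:n_ref].mean(axis=0)
    R = np.clip(X - ref_mean, -params.clip, params.clip)

    # (4) genomic ordering and within-chromosome smoothing
    order = (
        ann[["chromosome", "start"]]
        .assign(_ck=_chromosome_sort_key(ann["chromosome"]), _gid=ann.index)
        .sort_values(["_ck", "start", "_gid"], kind="mergesort")
    )
    gene_order = order.index
    R = R[:, ann.index.get_indexer(gene_order)]

    smoothed = np.empty_like(R)
    pos = 0
    for chrom in order["chromosome"].unique():
        g = int((order["chromosome"] == chrom).sum())
        if g < 1:
            warnings.warn(f"chromosome {chrom} has no genes after filtering; skipped")
            continue
        S = _smoothing_matrix(g, params.window, params.weights)
        smoothed[:, pos : pos + g] = R[:, pos : pos + g] @ S.T
        pos += g

    # (5) per-cell median correction, (6) reference re-centering
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    smoothed -= smoothed[:n_ref].mean(axis=0)

    values = pd.DataFrame(smoothed.T, index=gene_order, columns=cells)
    gene_info = order[["chromosome", "start"]].copy()
    return CNAMatrix(values=values, gene_info=gene_info, reference_cells=tuple(reference_cells), params=params)


def mean_cna_profiles(cna: CNAMatrix, groups: pd.Series | dict) -> TumorProfileSet:
    """Arithmetic mean CNA vector per group label.

    ``groups`` maps cell -> group label; the caller restricts it to malignant
    cells (reference cells should not enter tumor profiles).
    """
    groups = pd.Series(groups)
    missing = groups.index.difference(cna.values.columns)
    if len(missing) > 0:
        raise ValueError(f"grouped cells absent from CNA matrix: {sorted(missing)[:5]}")
    profiles = {}
    sizes = {}
    for label in pd.unique(groups):
        members = groups.index[groups == label]
        if len(members) == 0:
            raise ValueError(f"group {label!r} is empty")
        profiles[str(label)] = cna.values[members].mean(axis=1)
        sizes[str(label)] = int(len(members))
    return TumorProfileSet(profiles=pd.DataFrame(profiles), group_sizes=sizes)
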