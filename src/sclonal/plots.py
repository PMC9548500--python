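"""Optional figures: CNA heatmap, clonality null histogram, volcano plot."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cna import CNAMatrix  # noqa: E402
from .clonality import ClonalityResult  # noqa: E402


def cna_heatmap(cna: CNAMatrix, path: str, groups=None, vlim: float = 0.5):
    """Cells x genes heatmap in genomic order with per-chromosome panel breaks."""
    vals = cna.values.T.to_numpy()
    if groups is not None:
        order = np.argsort([groups.get(c, "") for c in cna.values.columns], kind="stable")
        vals = vals[order]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.imshow(vals, aspect="auto", cmap="RdBu_r", vmin=-vlim, vmax=vlim, interpolation="nearest")
    bounds = np.cumsum(cna.gene_info["chromosome"].value_counts(sort=False).to_numpy())[:-1]
    for b in bounds:
        ax.axvline(b - 0.5, color="k", lw=0.4)
    ax.set_xlabel("genes (genomic order)")
    ax.set_ylabel("cells")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def null_histogram(result: ClonalityResult, path: str):
    """Histogram of unrelated-pair correlations with tested pairs marked."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.null_sample, bins=20, color="0.7", edgecolor="k")
    for _, row in result.pvalues.iterrows():
        ax.axvline(row["r"], color="crimson", lw=1.2)
        ax.text(row["r"], ax.get_ylim()[1] * 0.95, f"r={row['r']:.2f}\np={row['p']:.3g}",
                rotation=90, va="top", fontsize=7)
    ax.set_xlabel("Pearson r (unrelated tumor pairs)")
    ax.set_ylabel("pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def volcano(de_table, path: str, fc_threshold: float = 1.5, padj_threshold: float = 0.05):
    """log2FC vs -log10 adjusted p with the usual threshold guides."""
    t = de_table[de_table["tested"]]
    fig, ax = plt.subplots(figsize=(5, 4))
    y = -np.log10(np.clip(t["p_adj"].to_numpy(), 1e-300, None))
    ax.scatter(t["log2FC"], y, s=6, c="0.4", alpha=0.6, linewidths=0)
    ax.axhline(-np.log10(padj_threshold), color="red", lw=0.8)
    for s in (-1, 1):
        ax.axvline(s * np.log2(fc_threshold), color="red", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
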