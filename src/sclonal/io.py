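"""Readers and writers for the on-disk formats used throughout the package.

Count matrices travel as Matrix Market triplets with ``barcodes.tsv`` /
``features.tsv`` sidecars (the 10x convention: features rows are
``gene_id  gene_symbol  feature_type``). Gene annotation, cell metadata,
QC reports and result tables are plain TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end", "category"]


def write_10x_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as matrix.mtx + barcodes.tsv + features.tsv (genes x cells on disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    # 10x stores genes as rows
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(X.T), field="integer")
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    feats = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "gene_symbol": adata.var.get("gene_symbol", pd.Series(adata.var_names, index=adata.var_names)),
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)


def read_10x_mtx(indir: str | Path) -> ad.AnnData:
    """Read a matrix.mtx/barcodes.tsv/features.tsv triple into AnnData (cells x genes)."""
    indir = Path(indir)
    mat = scipy.io.mmread(str(indir / "matrix.mtx"))
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    adata = ad.AnnData(
        X=sp.csr_matrix(mat.T),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(
            {"gene_symbol": feats[1].values if feats.shape[1] > 1 else feats[0].values},
            index=pd.Index(feats[0].astype(str), name="gene_id"),
        ),
    )
    return adata


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (gene_id, chromosome, start, end[, category])."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in ("gene_id", "chromosome", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path} missing columns: {missing}")
    if "category" not in df.columns:
        df["category"] = "ordinary"
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in annotation: {dups[:5]}")
    return df.set_index("gene_id", drop=False)


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Cell metadata TSV with at least columns barcode, sample_id; class column optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "barcode" not in df.columns:
        raise ValueError(f"cell metadata {path} must have a 'barcode' column")
    return df.set_index("barcode", drop=False)


def read_housekeeping_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def file_checksum(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
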