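import anndata as ad
import numpy as np
import pandas as pd
import pytest

import sclonal as sc


def adata_from_dense(X, barcodes=None, genes=None, **obs_cols):
    """AnnData (cells x genes) from a dense array, for hand-built toys."""
    X = np.asarray(X)
    n, g = X.shape
    barcodes = barcodes or [f"cell{i + 1}" for i in range(n)]
    genes = genes or [f"gene{j + 1}" for j in range(g)]
    obs = pd.DataFrame({k: v for k, v in obs_cols.items()}, index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    return ad.AnnData(X=X.astype(np.float64), obs=obs, var=var)


def flat_annotation(genes, chromosome="1", category="ordinary"):
    """Annotation placing the listed genes consecutively on one chromosome."""
    return pd.DataFrame(
        {
            "gene_id": genes,
            "chromosome": chromosome,
            "start": np.arange(1, len(genes) + 1) * 1000,
            "end": np.arange(1, len(genes) + 1) * 1000 + 100,
            "category": category,
        }
    ).set_index("gene_id", drop=False)


@pytest.fixture(scope="session")
def two_clone_dataset():
    """Two samples sharing a clone, one with a private clone; immune reference."""
    ann = sc.make_genome(6, 100, n_mito=8, n_housekeeping=30, seed=5)
    clones = [
        sc.CloneSpec("shared", (("1", 1, 6_000_000, 2.0), ("3", 1, 5_000_000, 0.5))),
        sc.CloneSpec("private", (("5", 1, 7_000_000, 1.8),)),
    ]
    plans = [
        sc.CellPlan("S1", {"malignant": 150, "T_cell": 60, "B_cell": 40}, {"malignant": "shared"}),
        sc.CellPlan("S2", {"malignant": 150, "T_cell": 60, "B_cell": 40}, {"malignant": "shared"}),
        sc.CellPlan("S3", {"malignant": 150, "T_cell": 60, "B_cell": 40}, {"malignant": "private"}),
    ]
    return sc.simulate_tumor_counts(ann, clones, plans, seed=11)
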