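"""Synthetic multi-tumor scRNA-seq data with known ground truth.

The generator emulates the structure the downstream stages are built for:
several tumors (samples) each carrying malignant cells of one or more clones
with segmental copy-number alterations, immune reference cells without CNAs,
heterotypic doublets, mitochondrial and housekeeping gene categories, and
read-level records for a single RNA-editing site. Every cell carries truth
labels (class, clone, doublet status) so recovery can be scored exactly.

Count model: per-gene baseline means are drawn once from a gamma across genes
and shared by all samples; a cell of clone *k* has expected expression
``baseline(g) x copy_multiplier(k, g) x library_size`` and observed counts are
negative binomial (gamma-Poisson) with a single global dispersion. CNAs act
multiplicatively on expected expression; doublets are sums of the raw counts
of two independently simulated parent cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .editing import SiteSpec

__all__ = [
    "CloneSpec",
    "CellPlan",
    "SimulatedDataset",
    "SimulatedReads",
    "make_genome",
    "simulate_tumor_counts",
    "simulate_editing_reads",
]


@dataclass(frozen=True)
class CloneSpec:
    """A tumor clone as a set of copy-number segments.

    segments: (chromosome, start_bp, end_bp, copy_multiplier); 1.0 is
    copy-neutral, 2.0 a one-copy gain of a diploid locus, 0.5 a one-copy loss.
    Segments within a chromosome must not overlap.
    """

    clone_id: str
    segments: tuple[tuple[str, int, int, float], ...] = ()

    def __post_init__(self):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, mult in self.segments:
            if mult <= 0:
                raise ValueError(f"clone {self.clone_id}: copy_multiplier must be > 0, got {mult}")
            if end < start:
                raise ValueError(f"clone {self.clone_id}: segment end < start on {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in itertools.pairwise(ivs):
                if s2 <= e1:
                    raise ValueError(f"clone {self.clone_id}: overlapping segments on chromosome {chrom}")


@dataclass(frozen=True)
class CellPlan:
    """Cell counts per class for one sample, plus library-size and doublet settings.

    ``clone_of`` maps malignant class names to clone ids; classes absent from
    it (e.g. T_cell, B_cell) are copy-neutral reference classes.
    """

    sample_id: str
    classes: dict[str, int] = field(default_factory=dict)
    clone_of: dict[str, str] = field(default_factory=dict)
    doublet_fraction: float = 0.0
    library_size_log_mean: float = float(np.log(2000.0))
    library_size_log_sd: float = 0.35

    def __post_init__(self):
        if any(n < 0 for n in self.classes.values()):
            raise ValueError(f"plan {self.sample_id}: negative cell counts")
        if not 0.0 <= self.doublet_fraction < 1.0:
            raise ValueError(f"plan {self.sample_id}: doublet_fraction must be in [0, 1)")
        unknown = set(self.clone_of) - set(self.classes)
        if unknown:
            raise ValueError(f"plan {self.sample_id}: clone_of references unknown classes {sorted(unknown)}")


@dataclass
class SimulatedDataset:
    """Counts plus the truth labels and specs that generated them."""

    counts: ad.AnnData  # cells x genes; obs: sample_id, cell_class, clone_id, is_doublet, doublet_parents
    annotation: pd.DataFrame
    clone_specs: tuple[CloneSpec, ...]

    @property
    def truth(self) -> pd.DataFrame:
        return self.counts.obs[["sample_id", "cell_class", "clone_id", "is_doublet", "doublet_parents"]]


@dataclass
class SimulatedReads:
    """Read-level records for an editing site plus per-cell truth bookkeeping."""

    reads: pd.DataFrame  # read_id, umi, cell_barcode, sample_id, base, base_quality
    per_cell: pd.DataFrame  # barcode-indexed: sample_id, cell_class, n_umis, n_alt_umis, in_edited_class


def make_genome(
    n_chromosomes: int,
    genes_per_chromosome: int,
    n_mito: int = 0,
    n_housekeeping: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a gene annotation table with evenly spaced genes.

    Autosomes are labelled "1".."n_chromosomes" with ``genes_per_chromosome``
    genes each; ``n_mito`` genes go on chromosome "MT". ``n_housekeeping``
    autosomal genes (chosen with the seed) are flagged ``housekeeping`` and
    later receive inflated baselines from :func:`simulate_tumor_counts`.
    """
    if n_chromosomes <= 0 or genes_per_chromosome <= 0:
        raise ValueError("n_chromosomes and genes_per_chromosome must be positive")
    if n_mito < 0 or n_housekeeping < 0:
        raise ValueError("n_mito and n_housekeeping must be non-negative")
    n_auto = n_chromosomes * genes_per_chromosome
    if n_housekeeping > n_auto:
        raise ValueError("more housekeeping genes requested than autosomal genes")

    rows = []
    spacing = 100_000
    for c in range(1, n_chromosomes + 1):
        for i in range(genes_per_chromosome):
            start = (i + 1) * spacing
            rows.append((f"G{c}_{i + 1:04d}", str(c), start, start + 1000, "ordinary"))
    for i in range(n_mito):
        start = (i + 1) * 1000
        rows.append((f"MT_{i + 1:02d}", "MT", start, start + 500, "mitochondrial"))
    ann = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "category"])

    rng = np.random.default_rng(seed)
    auto_idx = ann.index[ann["chromosome"] != "MT"]
    hk = rng.choice(auto_idx, size=n_housekeeping, replace=False)
    ann.loc[np.sort(hk), "category"] = "housekeeping"
    return ann.set_index("gene_id", drop=False)


def _clone_multipliers(annotation: pd.DataFrame, clone: CloneSpec) -> np.ndarray:
    mult = np.ones(len(annotation))
    chrom = annotation["chromosome"].to_numpy()
    start = annotation["start"].to_numpy()
    known = set(chrom)
    for seg in clone.segments:
        seg_chrom, seg_start, seg_end, m = seg
        if seg_chrom not in known:
            raise ValueError(
                f"clone {clone.clone_id}: segment {seg_chrom}:{seg_start}-{seg_end} "
                f"references unknown chromosome {seg_chrom!r}"
            )
        mask = (chrom == seg_chrom) & (start >= seg_start) & (start <= seg_end)
        mult[mask] = m
    return mult


def simulate_tumor_counts(
    annotation: pd.DataFrame,
    clone_specs: list[CloneSpec] | tuple[CloneSpec, ...],
    plans: list[CellPlan] | tuple[CellPlan, ...],
    baseline_mean_shape: float = 0.5,
    dispersion: float = 2.0,
    seed: int = 0,
    mito_fraction: float = 0.05,
    housekeeping_scale: float = 30.0,
) -> SimulatedDataset:
    """Simulate UMI counts for every plan over a shared gene baseline.

    ``dispersion`` is the negative-binomial shape (variance mu + mu^2/dispersion);
    ``mito_fraction`` the expected share of each cell's counts on MT genes;
    ``housekeeping_scale`` the baseline inflation of housekeeping genes
    relative to the mean gene, calibrated so typical singlets clear the
    housekeeping QC threshold.
    """
    if baseline_mean_shape <= 0 or dispersion <= 0:
        raise ValueError("baseline_mean_shape and dispersion must be positive")
    clones = {c.clone_id: c for c in clone_specs}
    for plan in plans:
        missing = set(plan.clone_of.values()) - set(clones)
        if missing:
            raise ValueError(f"plan {plan.sample_id} references unknown clones {sorted(missing)}")

    rng = np.random.default_rng(seed)
    n_genes = len(annotation)
    baseline = rng.gamma(baseline_mean_shape, 1.0, size=n_genes) + 1e-3
    cat = annotation["category"].to_numpy()
    hk = cat == "housekeeping"
    if hk.any():
        baseline[hk] = housekeeping_scale * baseline.mean() * rng.uniform(0.8, 1.2, size=hk.sum())
    mito = (annotation["chromosome"] == "MT").to_numpy()
    if mito.any() and mito_fraction > 0:
        target = mito_fraction / (1.0 - mito_fraction) * baseline[~mito].sum()
        baseline[mito] *= target / baseline[mito].sum()

    mult_cache = {cid: _clone_multipliers(annotation, c) for cid, c in clones.items()}

    def draw_cells(plan: CellPlan, cls: str, n: int) -> np.ndarray:
        clone_id = plan.clone_of.get(cls)
        w = baseline * (mult_cache[clone_id] if clone_id else 1.0)
        p = w / w.sum()
        lib = rng.lognormal(plan.library_size_log_mean, plan.library_size_log_sd, size=n)
        mu = lib[:, None] * p[None, :]
        lam = rng.gamma(dispersion, mu / dispersion)
        return rng.poisson(lam)

    blocks, obs_rows, barcodes = [], [], []
    for plan in plans:
        class_names = sorted(plan.classes)
        counter = itertools.count(1)
        for cls in class_names:
            n = plan.classes[cls]
            if n == 0:
                continue
            blocks.append(draw_cells(plan, cls, n))
            for _ in range(n):
                barcodes.append(f"{plan.sample_id}-{next(counter):05d}")
                obs_rows.append((plan.sample_id, cls, plan.clone_of.get(cls, ""), False, ""))
        n_singlets = sum(plan.classes.values())
        n_doublets = int(round(plan.doublet_fraction * n_singlets))
        for _ in range(n_doublets):
            if len(class_names) >= 2:
                a, b = rng.choice(len(class_names), size=2, replace=False)
            else:
                a = b = 0
            ca, cb = class_names[a], class_names[b]
            pair = draw_cells(plan, ca, 1) + draw_cells(plan, cb, 1)
            blocks.append(pair)
            barcodes.append(f"{plan.sample_id}-{next(counter):05d}")
            obs_rows.append((plan.sample_id, "doublet", "", True, f"{ca}+{cb}"))

    X = sp.csr_matrix(np.vstack(blocks).astype(np.int64))
    obs = pd.DataFrame(
        obs_rows,
        columns=["sample_id", "cell_class", "clone_id", "is_doublet", "doublet_parents"],
        index=pd.Index(barcodes, name="barcode"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=annotation.copy())
    adata.uns["simulation"] = {
        "seed": seed,
        "baseline_mean_shape": baseline_mean_shape,
        "dispersion": dispersion,
        "mito_fraction": mito_fraction,
        "housekeeping_scale": housekeeping_scale,
    }
    return SimulatedDataset(counts=adata, annotation=annotation, clone_specs=tuple(clone_specs))


def simulate_editing_reads(
    truth: pd.DataFrame,
    site: SiteSpec,
    edited_classes: set[tuple[str, str]],
    edit_rate: float,
    coverage_mean: float,
    error_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedReads:
    """Simulate reads at a single editing site for every cell in ``truth``.

    Each cell receives Poisson(coverage_mean) UMIs with one read each; reads
    from cells in an edited (sample, class) stratum carry the alternate base
    with probability ``edit_rate``, all others with probability ``error_rate``
    (sequencing error). Base qualities are drawn in the Phred 30-40 range.
    """
    if not 0.0 <= edit_rate <= 1.0 or not 0.0 <= error_rate <= 1.0:
        raise ValueError("edit_rate and error_rate must be probabilities")
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    cols = ["read_id", "umi", "cell_barcode", "sample_id", "base", "base_quality"]
    if len(truth) == 0:
        empty = pd.DataFrame(columns=cols)
        per_cell = pd.DataFrame(columns=["sample_id", "cell_class", "n_umis", "n_alt_umis", "in_edited_class"])
        return SimulatedReads(reads=empty, per_cell=per_cell)

    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for bc, rec in truth.iterrows():
        stratum = (rec["sample_id"], rec["cell_class"])
        rate = edit_rate if stratum in edited_classes else error_rate
        n = int(rng.poisson(coverage_mean))
        alt = rng.random(n) < rate
        quals = rng.integers(30, 41, size=n)
        for j in range(n):
            rows.append(
                (
                    f"{bc}_r{j + 1}",
                    f"{bc}_u{j + 1}",
                    bc,
                    rec["sample_id"],
                    site.alt_base if alt[j] else site.ref_base,
                    int(quals[j]),
                )
            )
        truth_rows.append((rec["sample_id"], rec["cell_class"], n, int(alt.sum()), stratum in edited_classes))

    reads = pd.DataFrame(rows, columns=cols)
    per_cell = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "cell_class", "n_umis", "n_alt_umis", "in_edited_class"],
        index=truth.index.copy(),
    )
    return SimulatedReads(reads=reads, per_cell=per_cell)
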