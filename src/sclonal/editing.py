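"""Per-cell detection of a single-base RNA-editing site from read-level records.

APOBEC3A-mediated C>U editing (C→T in cDNA) at a known transcript position,
e.g. DDOST 558C>U, is called per cell: reads are quality-filtered, collapsed
to UMI consensus by majority base, and a cell is *edited* when enough UMIs
carry the alternate base. Cells with no surviving UMI are *unobserved* —
never counted as unedited — so sparse coverage does not deflate the edited
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

VALID_BASES = {"A", "C", "G", "T"}
READ_COLUMNS = ["read_id", "umi", "cell_barcode", "sample_id", "base", "base_quality"]


@dataclass(frozen=True)
class SiteSpec:
    """A single editing site: reference base, alternate (edited) base, locus label."""

    site_id: str
    ref_base: str
    alt_base: str
    coordinate: str = ""

    def __post_init__(self):
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ValueError(f"ref/alt bases must be one of {sorted(VALID_BASES)}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")


def call_site_editing(
    reads: pd.DataFrame,
    site: SiteSpec,
    min_base_quality: int = 20,
    min_alt_umis: int = 1,
) -> pd.DataFrame:
    """Call edited / unedited / unobserved per cell from site-level reads.

    Reads below ``min_base_quality`` or with base N are discarded; each UMI's
    base is the majority base of its surviving reads (ties discard the UMI);
    a cell is *edited* with >= ``min_alt_umis`` alternate-base UMIs, *unedited*
    with surviving UMIs but fewer alternate ones, *unobserved* with none.

    Returns a barcode-indexed table: sample_id, n_reads, n_umis, n_alt_umis, call.
    """
    if len(reads) == 0:
        return pd.DataFrame(columns=["sample_id", "n_reads", "n_umis", "n_alt_umis", "call"])
    bad = ~reads["base"].isin(VALID_BASES | {"N"})
    if bad.any():
        offender = reads.loc[bad, "read_id"].iloc[0]
        raise ValueError(f"read {offender!r} has invalid base {reads.loc[bad, 'base'].iloc[0]!r}")

    per_cell = reads.groupby("cell_barcode", sort=True).agg(
        sample_id=("sample_id", "first"), n_reads=("read_id", "size")
    )

    kept = reads[(reads["base_quality"] >= min_base_quality) & (reads["base"] != "N")]
    if len(kept) > 0:
        votes = kept.groupby(["cell_barcode", "umi", "base"], sort=False).size().reset_index(name="n")
        top_n = votes.groupby(["cell_barcode", "umi"], sort=False)["n"].transform("max")
        winners = votes[votes["n"] == top_n]
        # a UMI whose top count is shared by >1 base has no consensus
        consensus = winners[~winners.duplicated(subset=["cell_barcode", "umi"], keep=False)]
        n_umis = consensus.groupby("cell_barcode").size()
        n_alt = consensus[consensus["base"] == site.alt_base].groupby("cell_barcode").size()
    else:
        n_umis = pd.Series(dtype=int)
        n_alt = pd.Series(dtype=int)

    out = per_cell.copy()
    out["n_umis"] = n_umis.reindex(out.index).fillna(0).astype(int)
    out["n_alt_umis"] = n_alt.reindex(out.index).fillna(0).astype(int)
    out["call"] = np.where(
        out["n_umis"] == 0, "unobserved", np.where(out["n_alt_umis"] >= min_alt_umis, "edited", "unedited")
    )
    out.index.name = "cell_barcode"
    return out


def summarize_editing(
    calls: pd.DataFrame,
    cell_metadata: pd.DataFrame,
    class_collapse: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Edited-cell fractions per (sample, cell class).

    ``cell_metadata`` is barcode-indexed with sample_id and cell_class columns
    covering every cell of the experiment; cells absent from ``calls`` count
    as unobserved. ``class_collapse`` optionally maps classes to coarser
    labels (e.g. epithelial vs non-epithelial: {"epithelial": "Epi", ...}).

    Fractions use covered cells as denominator; strata with zero covered
    cells get NaN.
    """
    missing = calls.index.difference(cell_metadata.index)
    if len(missing) > 0:
        raise ValueError(f"cells without metadata: {sorted(missing)[:10]}")
    meta = cell_metadata[["sample_id", "cell_class"]].copy()
    if class_collapse is not None:
        meta["cell_class"] = meta["cell_class"].map(lambda c: class_collapse.get(c, c))
    meta["call"] = calls["call"].reindex(meta.index).fillna("unobserved")

    rows = []
    for (sample, cls), grp in meta.groupby(["sample_id", "cell_class"], sort=True):
        n_total = len(grp)
        n_cov = int((grp["call"] != "unobserved").sum())
        n_edit = int((grp["call"] == "edited").sum())
        frac = n_edit / n_cov if n_cov > 0 else np.nan
        rows.append((sample, cls, n_total, n_cov, n_edit, frac))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "cell_class", "n_cells_total", "n_cells_covered", "n_cells_edited", "edited_fraction"],
    )


def reads_from_alignments(
    path: str,
    chromosome: str,
    position: int,
    barcode_tag: str = "CB",
    umi_tag: str = "UB",
) -> pd.DataFrame:
    """Extract a site-level read table from a SAM/BAM file at a 1-based position.

    Each alignment overlapping the position contributes one row with the base
    it carries there and its quality; alignments lacking the barcode or UMI
    tag, or with a deletion/refskip at the position, are dropped. The file's
    read group / sample is taken from the RG SM field when present, else "".
    """
    import pysam

    target = position - 1  # pysam is 0-based
    rows = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        sample_by_rg = {rg.get("ID"): rg.get("SM", "") for rg in fh.header.to_dict().get("RG", [])}
        for aln in fh:
            if aln.is_unmapped or aln.reference_name != chromosome:
                continue
            if not (aln.has_tag(barcode_tag) and aln.has_tag(umi_tag)):
                continue
            qpos = None
            for q, r in aln.get_aligned_pairs(matches_only=True):
                if r == target:
                    qpos = q
                    break
            if qpos is None:
                continue
            sample = ""
            if aln.has_tag("RG"):
                sample = sample_by_rg.get(aln.get_tag("RG"), "")
            rows.append(
                (
                    aln.query_name,
                    aln.get_tag(umi_tag),
                    aln.get_tag(barcode_tag),
                    sample,
                    aln.query_sequence[qpos].upper(),
                    int(aln.query_qualities[qpos]) if aln.query_qualities is not None else 0,
                )
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)
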