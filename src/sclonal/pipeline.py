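"""End-to-end orchestration of the analysis stages from one configuration.

Stage order: simulate (optional) -> qc -> cna -> clonality -> de -> ora ->
editing. Each stage is run only when its config section is present, writes
its tables under the output directory, and contributes an entry (parameters,
output checksums, counts) to a machine-readable run report. Validation
errors are collected and reported all at once before any compute.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .cna import CNAParams, infer_cna_matrix, mean_cna_profiles
from .clonality import test_clonality
from .de import ora_enrichment, read_gmt, select_de_genes, wilcoxon_de
from .editing import SiteSpec, call_site_editing, summarize_editing
from .qc import QCThresholds, apply_qc, cell_qc_metrics, doublet_scores, lognormalize
from .synthetic import CellPlan, CloneSpec, simulate_editing_reads, simulate_tumor_counts, make_genome

STAGES = ["simulate", "qc", "cna", "clonality", "de", "ora", "editing"]


class ConfigError(ValueError):
    """Raised with every validation problem at once."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(["config file must contain a mapping"])
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Schema check; returns the full list of problems (empty when valid)."""
    problems = []
    if "outdir" not in cfg:
        problems.append("outdir: required")
    if not isinstance(cfg.get("seed", 0), int):
        problems.append("seed: must be an integer")
    if "simulate" not in cfg and "inputs" not in cfg:
        problems.append("either 'simulate' or 'inputs' must be given")
    inputs = cfg.get("inputs", {})
    for key in ("matrix_dir", "annotation", "metadata"):
        if "inputs" in cfg:
            if key not in inputs:
                problems.append(f"inputs.{key}: required")
            elif not Path(inputs[key]).exists():
                problems.append(f"inputs.{key}: path does not exist: {inputs[key]}")
    if "cna" in cfg and not cfg["cna"].get("reference_classes"):
        problems.append("cna.reference_classes: required (e.g. [T_cell, B_cell])")
    if "clonality" in cfg:
        if "cna" not in cfg:
            problems.append("clonality requires the cna stage")
        if not cfg["clonality"].get("tested_pairs"):
            problems.append("clonality.tested_pairs: required")
    if "de" in cfg:
        for key in ("group_a_samples", "group_b_samples"):
            if not cfg["de"].get(key):
                problems.append(f"de.{key}: required")
    if "ora" in cfg:
        if "de" not in cfg:
            problems.append("ora requires the de stage")
        gmt = cfg["ora"].get("gmt")
        if not gmt:
            problems.append("ora.gmt: required when the ora stage is enabled")
        elif not Path(gmt).exists():
            problems.append(f"ora.gmt: path does not exist: {gmt}")
    if "editing" in cfg:
        ed = cfg["editing"]
        if "site" not in ed:
            problems.append("editing.site: required (site_id, ref_base, alt_base)")
        if "reads" not in ed and "simulate" not in ed:
            problems.append("editing: either a 'reads' path or a 'simulate' block is required")
        if "reads" in ed and not Path(ed["reads"]).exists():
            problems.append(f"editing.reads: path does not exist: {ed['reads']}")
    return problems


def _log(report: dict, stage: str, status: str, t0: float, **info) -> None:
    entry = {"stage": stage, "status": status, "seconds": round(time.time() - t0, 3), **info}
    report["stages"].append(entry)
    print(f"[{time.strftime('%H:%M:%S')}] {stage}: {status} " + json.dumps(info, default=str)[:400])


def _checksums(paths: list[Path]) -> dict[str, str]:
    return {p.name: sio.file_checksum(p) for p in paths if p.exists()}


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages in order; returns the run report.

    The report is also written to <outdir>/run_report.json. A failure in any
    stage raises after logging the stage name.
    """
    problems = validate_config(cfg)
    if problems:
        raise ConfigError(problems)

    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    report: dict = {"seed": seed, "stages": []}

    # --- simulate or load ---------------------------------------------------
    t0 = time.time()
    if "simulate" in cfg:
        sim_cfg = cfg["simulate"]
        annotation = make_genome(
            n_chromosomes=sim_cfg.get("n_chromosomes", 10),
            genes_per_chromosome=sim_cfg.get("genes_per_chromosome", 100),
            n_mito=sim_cfg.get("n_mito", 10),
            n_housekeeping=sim_cfg.get("n_housekeeping", 50),
            seed=seed,
        )
        clones = [
            CloneSpec(c["clone_id"], tuple(tuple(s) for s in c.get("segments", [])))
            for c in sim_cfg.get("clones", [])
        ]
        plans = [
            CellPlan(
                sample_id=s["sample_id"],
                classes=dict(s.get("classes", {})),
                clone_of=dict(s.get("clone_of", {})),
                doublet_fraction=float(s.get("doublet_fraction", 0.0)),
                library_size_log_mean=float(s.get("library_size_log_mean", np.log(2000.0))),
                library_size_log_sd=float(s.get("library_size_log_sd", 0.35)),
            )
            for s in sim_cfg.get("samples", [])
        ]
        dataset = simulate_tumor_counts(
            annotation,
            clones,
            plans,
            baseline_mean_shape=float(sim_cfg.get("baseline_mean_shape", 0.5)),
            dispersion=float(sim_cfg.get("dispersion", 2.0)),
            seed=seed,
            mito_fraction=float(sim_cfg.get("mito_fraction", 0.05)),
        )
        adata = dataset.counts
        simdir = outdir / "simulated"
        sio.write_10x_mtx(adata, simdir)
        sio.write_annotation(annotation, simdir / "annotation.tsv")
        truth = dataset.truth.copy()
        truth.insert(0, "barcode", truth.index)
        sio.write_tsv(truth, simdir / "truth.tsv")
        outputs = [simdir / f for f in ("matrix.mtx", "barcodes.tsv", "features.tsv", "annotation.tsv", "truth.tsv")]
        _log(report, "simulate", "ok", t0, n_cells=int(adata.n_obs), n_genes=int(adata.n_vars),
             checksums=_checksums(outputs))
    else:
        inputs = cfg["inputs"]
        adata = sio.read_10x_mtx(inputs["matrix_dir"])
        annotation = sio.read_annotation(inputs["annotation"])
        meta = sio.read_cell_metadata(inputs["metadata"])
        adata.obs = adata.obs.join(meta.drop(columns=["barcode"], errors="ignore"))
        if "cell_class" not in adata.obs or "sample_id" not in adata.obs:
            raise ValueError("stage load: metadata must provide sample_id and cell_class per barcode")
        if "housekeeping_list" in cfg:
            hk = set(sio.read_housekeeping_list(cfg["housekeeping_list"]))
            annotation.loc[annotation.index.isin(hk), "category"] = "housekeeping"
        _log(report, "load", "ok", t0, n_cells=int(adata.n_obs), n_genes=int(adata.n_vars))

    # --- qc ------------------------------------------------------------------
    if "qc" in cfg:
        t0 = time.time()
        qc_cfg = dict(cfg["qc"])
        skip_doublets = qc_cfg.pop("skip_doublets", False)
        if skip_doublets:
            qc_cfg["doublet_threshold"] = None
        thresholds = QCThresholds(**{k: v for k, v in qc_cfg.items() if k in QCThresholds.__dataclass_fields__})
        norm = lognormalize(adata)
        qc_table = cell_qc_metrics(adata, annotation, norm)
        if not skip_doublets:
            qc_table["doublet_score"] = doublet_scores(adata, seed=seed)
        adata, qc_report = apply_qc(adata, qc_table, thresholds)
        qc_out = qc_table.copy()
        qc_out.insert(0, "barcode", qc_out.index)
        sio.write_tsv(qc_out.drop(columns=["pass"]), outdir / "qc_metrics.tsv")
        keptdir = outdir / "filtered"
        sio.write_10x_mtx(adata, keptdir)
        _log(report, "qc", "ok", t0, **{k: v for k, v in qc_report.items() if k != "thresholds"},
             checksums=_checksums([outdir / "qc_metrics.tsv", keptdir / "matrix.mtx", keptdir / "barcodes.tsv"]))

    # --- cna ------------------------------------------------------------------
    profiles = None
    if "cna" in cfg:
        t0 = time.time()
        cna_cfg = dict(cfg["cna"])
        ref_classes = set(cna_cfg.pop("reference_classes"))
        malignant = cna_cfg.pop("malignant_classes", None)
        group_by = cna_cfg.pop("group_by", "sample_id")
        params = CNAParams(**{k: v for k, v in cna_cfg.items() if k in CNAParams.__dataclass_fields__})
        norm = lognormalize(adata)
        classes = adata.obs["cell_class"]
        ref_cells = adata.obs_names[classes.isin(ref_classes)]
        if malignant is not None:
            query_mask = classes.isin(set(malignant))
        else:
            query_mask = ~classes.isin(ref_classes | {"doublet"})
        query_cells = adata.obs_names[query_mask]
        cna = infer_cna_matrix(norm, annotation, ref_cells, query_cells, params)
        groups = adata.obs.loc[query_cells, group_by]
        profiles = mean_cna_profiles(cna, groups)
        prof_out = profiles.profiles.copy()
        prof_out.insert(0, "gene_id", prof_out.index)
        sio.write_tsv(prof_out, outdir / "cna_profiles.tsv")
        sio.write_tsv(cna.to_frame().reset_index(), outdir / "cna_matrix.tsv")
        _log(report, "cna", "ok", t0, n_reference=len(ref_cells), n_query=len(query_cells),
             n_genes=int(cna.values.shape[0]), params=asdict(params),
             checksums=_checksums([outdir / "cna_profiles.tsv", outdir / "cna_matrix.tsv"]))

    # --- clonality -------------------------------------------------------------
    if "clonality" in cfg:
        t0 = time.time()
        cl_cfg = cfg["clonality"]
        result = test_clonality(
            profiles,
            tested_pairs=[tuple(p) for p in cl_cfg["tested_pairs"]],
            related_pairs=[tuple(p) for p in cl_cfg.get("related_pairs", [])],
            method=cl_cfg.get("method", "gaussian"),
            fisher_z=bool(cl_cfg.get("fisher_z", True)),
        )
        sio.write_tsv(result.r_matrix.reset_index(), outdir / "clonality_r_matrix.tsv")
        sio.write_tsv(pd.DataFrame({"null_r": result.null_sample}), outdir / "clonality_null.tsv")
        sio.write_tsv(result.pvalues, outdir / "clonality_pvalues.tsv")
        _log(report, "clonality", "ok", t0, n_null=len(result.null_sample),
             pvalues=result.pvalues[["label_a", "label_b", "r", "p"]].to_dict("records"),
             checksums=_checksums([outdir / f for f in
                                   ("clonality_r_matrix.tsv", "clonality_null.tsv", "clonality_pvalues.tsv")]))

    # --- de ---------------------------------------------------------------------
    de_table = None
    if "de" in cfg:
        t0 = time.time()
        de_cfg = cfg["de"]
        obs = adata.obs
        mask = obs["cell_class"].isin(set(de_cfg["classes"])) if de_cfg.get("classes") else ~obs["cell_class"].eq("doublet")
        ga = adata.obs_names[mask & obs["sample_id"].isin(set(de_cfg["group_a_samples"]))]
        gb = adata.obs_names[mask & obs["sample_id"].isin(set(de_cfg["group_b_samples"]))]
        norm = lognormalize(adata)
        de_table = wilcoxon_de(
            norm,
            ga,
            gb,
            min_pct=float(de_cfg.get("min_pct", 0.1)),
            min_abs_log2fc_prefilter=float(de_cfg.get("min_abs_log2fc_prefilter", 0.25)),
            pseudocount=float(de_cfg.get("pseudocount", 1.0)),
        )
        out = de_table.copy()
        out.insert(0, "gene_id", out.index)
        sio.write_tsv(out, outdir / "de_table.tsv")
        _log(report, "de", "ok", t0, n_a=len(ga), n_b=len(gb), n_tested=int(de_table["tested"].sum()),
             checksums=_checksums([outdir / "de_table.tsv"]))

    # --- ora ---------------------------------------------------------------------
    if "ora" in cfg:
        t0 = time.time()
        ora_cfg = cfg["ora"]
        sets = read_gmt(ora_cfg["gmt"])
        de_genes = select_de_genes(
            de_table,
            fc_threshold=float(ora_cfg.get("fc_threshold", 1.8)),
            padj_threshold=float(ora_cfg.get("padj_threshold", 0.05)),
        )
        universe = list(de_table.index[de_table["tested"]])
        enrich = ora_enrichment(de_genes, universe, sets)
        sio.write_tsv(enrich.reset_index(), outdir / "ora_table.tsv")
        _log(report, "ora", "ok", t0, n_de=len(de_genes), n_universe=len(universe), n_sets=len(enrich),
             checksums=_checksums([outdir / "ora_table.tsv"]))

    # --- editing -------------------------------------------------------------------
    if "editing" in cfg:
        t0 = time.time()
        ed_cfg = cfg["editing"]
        site = SiteSpec(**ed_cfg["site"])
        if "reads" in ed_cfg:
            reads = pd.read_csv(ed_cfg["reads"], sep="\t")
        else:
            sim_ed = ed_cfg["simulate"]
            truth = adata.obs[["sample_id", "cell_class"]]
            reads = simulate_editing_reads(
                truth,
                site,
                edited_classes={tuple(p) for p in sim_ed.get("edited_classes", [])},
                edit_rate=float(sim_ed.get("edit_rate", 0.5)),
                coverage_mean=float(sim_ed.get("coverage_mean", 5.0)),
                error_rate=float(sim_ed.get("error_rate", 0.001)),
                seed=seed,
            ).reads
            sio.write_tsv(reads, outdir / "editing_reads.tsv")
        calls = call_site_editing(
            reads,
            site,
            min_base_quality=int(ed_cfg.get("min_base_quality", 20)),
            min_alt_umis=int(ed_cfg.get("min_alt_umis", 1)),
        )
        meta = adata.obs[["sample_id", "cell_class"]]
        collapse = ed_cfg.get("class_collapse")
        summary = summarize_editing(calls, meta, class_collapse=collapse)
        sio.write_tsv(calls.reset_index(), outdir / "editing_calls.tsv")
        sio.write_tsv(summary, outdir / "editing_summary.tsv")
        _log(report, "editing", "ok", t0, n_cells_called=len(calls),
             checksums=_checksums([outdir / "editing_calls.tsv", outdir / "editing_summary.tsv"]))

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
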