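"""End-to-end orchestration: simulate/load -> preprocess -> QC -> DE panel ->
principal-curve pseudotime -> enrichment scan -> biomarker hazard groups.

Every stage writes its artifact to the output directory before the next
stage runs, so a run can be inspected or resumed at any point; a fixed seed
gives byte-identical outputs. Stage-level logging records input/output
sample and gene counts in machine-readable form.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import biomarker, diffexp, genesets, preprocess, qc, synthgen, trajectory

log = logging.getLogger("dcistraj")


@dataclass
class PipelineConfig:
    """Full pipeline configuration.

    Either ``counts_path``/``meta_path`` point at existing TSVs, or
    ``simulate`` holds a synthetic-cohort configuration (the default).
    """

    outdir: str = "dcistraj_out"
    seed: int = 0
    counts_path: str | None = None
    meta_path: str | None = None
    libstats_path: str | None = None
    simulate: synthgen.CohortConfig = field(default_factory=synthgen.CohortConfig)
    min_gene_frac: float = 0.05
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    panel_alpha: float = 1e-5
    panel_use_adjusted: bool = True
    boundaries: trajectory.SegmentBoundaries = field(default_factory=trajectory.SegmentBoundaries)
    scan: genesets.ScanConfig = field(default_factory=genesets.ScanConfig)
    scan_block_patients: bool = False
    receptor_thresholds: biomarker.ReceptorThresholds = field(default_factory=biomarker.ReceptorThresholds)
    marker_panel: biomarker.MarkerPanel = field(default_factory=biomarker.MarkerPanel)
    run_scan: bool = True
    run_ssgsea: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in [
            ("simulate", synthgen.CohortConfig),
            ("qc_thresholds", qc.QCThresholds),
            ("boundaries", trajectory.SegmentBoundaries),
            ("scan", genesets.ScanConfig),
            ("receptor_thresholds", biomarker.ReceptorThresholds),
            ("marker_panel", biomarker.MarkerPanel),
        ]:
            if key in d and isinstance(d[key], dict):
                sub_d = d[key]
                for tup_field in ("lesions_range", "sections_probs", "emt_peaks", "emt_widths", "libsize_range", "progressors"):
                    if tup_field in sub_d and isinstance(sub_d[tup_field], list):
                        sub_d[tup_field] = tuple(sub_d[tup_field])
                d[key] = sub(**sub_d)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _stage(name: str, **counts) -> None:
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def cooccurring_patients(meta: pd.DataFrame) -> list:
    """Patients with usable samples from both DCIS and IDC."""
    has = meta.groupby("patient")["tissue"].agg(lambda t: {"DCIS", "IDC"} <= set(t))
    return sorted(has.index[has])


def run_full_pipeline(config: PipelineConfig, truth: synthgen.Truth | None = None) -> dict:
    """Run every stage and return a summary dict (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)

    # ---- stage: input -------------------------------------------------------
    if config.counts_path:
        counts = preprocess.read_counts(config.counts_path)
        meta = pd.read_csv(config.meta_path, sep="\t", index_col=0)
        stats = (
            pd.read_csv(config.libstats_path, sep="\t", index_col=0)
            if config.libstats_path
            else None
        )
    else:
        sim_cfg = dataclasses.replace(config.simulate, seed=rng_seed)
        counts, meta, truth = synthgen.simulate_cohort(sim_cfg)
        stats = synthgen.simulate_libstats(meta, seed=rng_seed + 101, frac_fail=0.02)
        preprocess.write_counts(counts, out / "counts.tsv")
        meta.to_csv(out / "meta.tsv", sep="\t")
        stats.to_csv(out / "libstats.tsv", sep="\t")
        truth.t.to_frame().join(truth.injected_bad).to_csv(out / "truth_samples.tsv", sep="\t")
        truth.program_membership.rename("program").to_frame().to_csv(out / "truth_genes.tsv", sep="\t")
    _stage("input", genes=counts.shape[0], samples=counts.shape[1])

    # ---- stage: preprocess --------------------------------------------------
    filtered = preprocess.filter_genes(counts, config.min_gene_frac)
    factors = preprocess.tmm_factors(filtered)
    expr = preprocess.log_cpm(filtered, factors)
    expr.round(4).to_csv(out / "log_cpm.tsv", sep="\t")
    _stage("preprocess", genes_kept=filtered.shape[0], samples=filtered.shape[1])

    # ---- stage: qc ----------------------------------------------------------
    report = qc.run_qc(expr, meta, stats=stats, thresholds=config.qc_thresholds)
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t")
    retained = report.retained
    expr_q = expr[retained]
    counts_q = filtered[retained]
    meta_q = meta.loc[retained]
    _stage("qc", **report.counts)

    # ---- stage: differential expression / panel -----------------------------
    co_pats = cooccurring_patients(meta_q)
    co_mask = meta_q["patient"].isin(co_pats) & meta_q["tissue"].isin(["DCIS", "IDC"])
    co_ids = list(meta_q.index[co_mask])
    de = diffexp.fit_de(
        counts_q[co_ids],
        meta_q.loc[co_ids, "tissue"],
        patient=meta_q.loc[co_ids, "patient"],
        group_order=("DCIS", "IDC"),
    )
    de.table.to_csv(out / "de_dcis_vs_idc.tsv", sep="\t")
    panel = diffexp.select_panel(de, config.panel_alpha, config.panel_use_adjusted)
    pd.Series(panel, name="gene_id").to_csv(out / "panel.tsv", sep="\t", index=False)
    _stage("de_panel", contrast_samples=len(co_ids), contrast_patients=len(co_pats), panel_genes=len(panel))

    # ---- stage: pseudotime --------------------------------------------------
    _, coords = trajectory.pca_embed_panel(expr_q, panel, fit_samples=co_ids)
    curve = trajectory.fit_principal_curve(coords[["pc1", "pc2"]])
    order = trajectory.order_samples(curve, meta_q["tissue"])
    segments = trajectory.segment_positions(order, config.boundaries)
    pcp = coords.join(order, how="right").join(segments)
    pcp.to_csv(out / "pcp_order.tsv", sep="\t")
    diff, welch_p = trajectory.compare_group_positions(
        order.loc[meta_q.index[meta_q["tissue"] == "DCIS"], "pcp_position"],
        meta_q["patient_status"],
        "Pure",
        "NotPure",
    )
    _stage("pseudotime", samples=len(order), converged=curve.converged)

    # ---- stage: gene sets ---------------------------------------------------
    sets = None
    ssgsea = None
    scan = None
    if truth is not None:
        membership = truth.program_membership
        sets = {
            f"{prog.upper()}_PROGRAM": set(membership.index[membership == prog])
            for prog in ("basal", "emt", "proliferation")
        }
        sets = {k: v & set(expr_q.index) for k, v in sets.items()}
        genesets.write_gmt(sets, out / "programs.gmt")
    if sets and config.run_ssgsea:
        ssgsea = genesets.ssgsea_scores(expr_q, sets, alpha=config.scan.ssgsea_alpha)
        ssgsea.round(5).to_csv(out / "ssgsea.tsv", sep="\t")
        _stage("ssgsea", sets=ssgsea.shape[0], samples=ssgsea.shape[1])
    if sets and config.run_scan and len(order) >= config.scan.window:

        def de_engine(window_ids, rest_ids):
            ids = list(window_ids) + list(rest_ids)
            labels = pd.Series(
                ["window"] * len(window_ids) + ["rest"] * len(rest_ids), index=ids
            )
            res = diffexp.fit_de(
                counts_q[ids],
                labels,
                patient=meta_q.loc[ids, "patient"] if config.scan_block_patients else None,
                group_order=("rest", "window"),
            )
            return res.table

        scan = genesets.window_enrichment_scan(order, sets, de_engine, config.scan)
        scan.to_csv(out / "scan.tsv", sep="\t", index=False)
        _stage("scan", windows=scan["window_start_rank"].nunique())

    # ---- stage: biomarkers --------------------------------------------------
    receptor = biomarker.receptor_status_call(expr_q, config.receptor_thresholds)
    receptor.to_csv(out / "receptor_status.tsv", sep="\t")
    hazard = biomarker.hazard_assignments(expr_q, meta_q, config.marker_panel)
    hazard.to_csv(out / "hazard_groups.tsv", sep="\t")
    status = meta_q.groupby("patient")["patient_status"].first()
    fold_lower = biomarker.enrichment_fold(
        hazard["group"], status.reindex(hazard.index), biomarker.HazardGroup.LOWER.value, "Pure", "NotPure"
    )
    fold_higher = biomarker.enrichment_fold(
        hazard["group"], status.reindex(hazard.index), biomarker.HazardGroup.HIGHER.value, "NotPure", "Pure"
    )
    _stage("hazard", patients=len(hazard))

    summary = {
        "seed": rng_seed,
        "counts": report.counts,
        "conservation_ok": report.check_conservation(),
        "panel_size": int(len(panel)),
        "consensus_correlation": de.consensus_correlation,
        "curve_converged": bool(curve.converged),
        "welch_mean_diff_pure_vs_notpure": float(diff),
        "welch_p": float(welch_p),
        "lower_hazard_fold": fold_lower,
        "higher_hazard_fold": fold_higher,
        "n_windows": int(scan["window_start_rank"].nunique()) if scan is not None else 0,
    }
    if truth is not None:
        rho = spearmanr(
            order["pcp_position"], truth.t.reindex(order.index)
        ).statistic
        summary["pcp_truth_spearman_abs"] = float(abs(rho))
        panel_programs = truth.program_membership.reindex(panel)
        summary["panel_precision_basal_emt"] = float(
            panel_programs.isin(["basal", "emt"]).mean()
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary
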