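"""End-to-end orchestration: matrices in, report tables out.

Runs the full analysis in the order data model -> dynamicity -> stage
clustering (transcript, protein, joint) -> transcript-protein integration
-> optional cross-species comparison -> differential/enrichment
statistics, writing one TSV per result table plus a manifest echoing every
parameter and seed, so a run is reproducible from the manifest alone.

Inputs are either user-supplied files (matrix + sample-sheet TSVs) or the
built-in synthetic generator (the default), whose ground truth also powers
the stage-program term map used to exercise the enrichment path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

import devodyn
from devodyn import (
    AlignmentSpec, ImputationSpec, SimConfig, Scale,
    assign_stage, bh_adjust, cluster_overlap_test, cross_correlate,
    detection_and_core, differential_timepoints, fisher_enrichment,
    genewise_correlation, gini_table, group_clusters_kmeans,
    impute_shifted_beta, log_transform, maternal_enrichment, read_matrix,
    read_sample_sheet, refine_clusters, replicate_correlation,
    simulate_paired, simulate_two_species, timepoint_means,
    timepointwise_correlation, tp_index, train_som, variability_filter,
    write_matrix, zscore_profiles,
)
from devodyn.integration import cpm_expressed, detected_in_min_replicates
from devodyn.synthetic_data import FLYLIKE_TIMEPOINTS

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """All thresholds, grids and seeds of a full run.

    Defaults follow the analysis conventions: Gini split at 0.1, top-90%
    IQR variability for clustering inputs, 75th-percentile cluster
    refinement, correlation alpha 0.05, fold change 2, FDR 0.05, 4x4
    per-layer SOM grids and a 5x4 joint grid, k = 4 index groups.
    """

    # inputs (None -> simulate)
    tx_path: Optional[str] = None
    prot_path: Optional[str] = None
    sheet_path: Optional[str] = None
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    # thresholds
    gini_threshold: float = 0.1
    prot_top_percent: float = 90.0
    tx_top_percent: float = 90.0
    cross_top_percent: float = 70.0
    refine_percentile: float = 75.0
    alpha: float = 0.05
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    stage_margin: float = 1.0
    min_cpm: float = 10.0
    min_cpm_samples: int = 3
    detect_min_reps: int = 4

    # grids & grouping
    prot_grid: tuple[int, int] = (4, 4)
    tx_grid: tuple[int, int] = (4, 4)
    joint_grid: tuple[int, int] = (5, 4)
    som_iterations: int = 1000
    kmeans_k: int = 4

    # cross-species
    run_cross_species: bool = True
    n_orthologs: int = 1000
    frac_conserved: float = 0.7

    # differential
    diff_tp_a: str = "Ewhite"
    diff_tp_b: str = "Ebrown"

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gini_threshold <= 1:
            raise ValueError("gini_threshold must lie in [0, 1]")
        for name in ("prot_top_percent", "tx_top_percent", "cross_top_percent"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must lie in (0, 100]")
        if not 0 < self.refine_percentile < 100:
            raise ValueError("refine_percentile must lie in (0, 100)")
        if not 0 < self.alpha < 1 or not 0 < self.fdr_threshold < 1:
            raise ValueError("alpha and fdr_threshold must lie in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.kmeans_k < 1:
            raise ValueError("kmeans_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**{k: tuple(v) if k.endswith("_grid") else v for k, v in raw.items()})
        if sim_raw:
            if "timepoints" in sim_raw:
                sim_raw["timepoints"] = [tuple(t) for t in sim_raw["timepoints"]]
            cfg.sim = SimConfig(**sim_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["timepoints"] = [list(t) for t in d["sim"]["timepoints"]]
        d["sim"]["coupling_rho"] = (float(self.sim.coupling_rho)
                                    if np.ndim(self.sim.coupling_rho) == 0
                                    else list(map(float, self.sim.coupling_rho)))
        for k in ("prot_grid", "tx_grid", "joint_grid"):
            d[k] = list(d[k])
        return d


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis; returns a summary dict and writes tables.

    Every stage writes its tables under ``out_dir``; a ``manifest.json``
    echoes the complete configuration (the manifest alone reproduces the
    run). Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # ---- omics_io ---------------------------------------------------------
    stage = "omics_io"
    try:
        truth = orthologs = xsp_truth = data_b = None
        if config.simulate:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            if config.run_cross_species:
                sim_b = dataclasses.replace(
                    sim, n_genes=max(config.n_orthologs, sim.n_genes // 2),
                    timepoints=FLYLIKE_TIMEPOINTS, species="B",
                    gene_prefix="h", seed=config.seed + 101)
                (tx, prot, sheet, truth), data_b, orthologs, xsp_truth = \
                    simulate_two_species(sim, sim_b, config.n_orthologs,
                                         config.frac_conserved)
            else:
                tx, prot, sheet, truth = simulate_paired(sim)
            write_matrix(tx, out / "tx_cpm.tsv")
            write_matrix(prot, out / "prot_log2.tsv")
            sheet.table.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
            _write(truth, out / "truth.tsv")
        else:
            if not (config.tx_path and config.prot_path and config.sheet_path):
                raise ValueError("tx_path, prot_path and sheet_path required")
            tx = read_matrix(config.tx_path, Scale.cpm)
            prot = read_matrix(config.prot_path, Scale.lfq_log2)
            sheet = read_sample_sheet(config.sheet_path)

        prot_imp = impute_shifted_beta(prot, ImputationSpec(seed=config.seed + 1))
        prot_means = timepoint_means(prot_imp, sheet)
        prot_means_raw = timepoint_means(prot, sheet)  # non-imputed, NaN holes
        tx_means = timepoint_means(tx, sheet)
        rep_corr = replicate_correlation(prot)
        _write(rep_corr, out / "replicate_correlation.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, "io_error", str(exc)) from exc

    # ---- dynamicity -------------------------------------------------------
    stage = "dynamicity"
    try:
        # Gini needs nonnegative inputs; log2 LFQ intensities are positive
        gini = gini_table(prot_means, threshold=config.gini_threshold)
        _write(gini, out / "gini.tsv")
        detect = detection_and_core(prot, sheet)
        _write(detect.detected.astype(int), out / "stage_detection.tsv")
        venn = {"+".join(sorted(k)): v for k, v in detect.venn_counts().items()}
        (out / "venn_counts.json").write_text(json.dumps(venn, sort_keys=True, indent=1))
        summary["n_core"] = int(detect.core.sum())
        summary["n_dynamic"] = int((gini["class"] == "dynamic").sum())
        summary["n_stable"] = int((gini["class"] == "stable").sum())
    except Exception as exc:
        raise PipelineError(stage, "compute_error", str(exc)) from exc

    # ---- stage_clustering -------------------------------------------------
    stage = "stage_clustering"
    try:
        stage_of = sheet.stage_of()
        prot_keep = variability_filter(prot_means, config.prot_top_percent)
        prot_keep = prot_keep.intersection(
            detected_in_min_replicates(prot, sheet, config.detect_min_reps))
        tx_keep = variability_filter(tx_means, config.tx_top_percent)
        tx_keep = tx_keep.intersection(
            cpm_expressed(tx, config.min_cpm, config.min_cpm_samples))

        models = {}
        for name, means, keep, grid in (
                ("prot", prot_means, prot_keep, config.prot_grid),
                ("tx", tx_means, tx_keep, config.tx_grid)):
            z = zscore_profiles(means.subset(features=keep))
            model = train_som(z, grid_shape=grid, iterations=config.som_iterations,
                              seed=config.seed + (2 if name == "prot" else 3))
            model = refine_clusters(model, config.refine_percentile)
            model = assign_stage(model, stage_of, config.stage_margin)
            models[name] = model
            table = pd.DataFrame({
                "cluster": model.assignment,
                "distance": model.distance,
                "kept": model.assignment.map(model.kept),
                "stage": model.assignment.map(model.stage_label.fillna("none")),
            })
            _write(table, out / f"clusters_{name}.tsv")
        summary["prot_kept_clusters"] = int(models["prot"].kept.sum())
        summary["tx_kept_clusters"] = int(models["tx"].kept.sum())
    except Exception as exc:
        raise PipelineError(stage, "compute_error", str(exc)) from exc

    # ---- integration ------------------------------------------------------
    stage = "integration"
    try:
        tx_log_means = pd.DataFrame(np.log2(tx_means.observed() + 1.0))
        tp_corr = timepointwise_correlation(tx_log_means, prot_means.observed())
        _write(tp_corr, out / "timepoint_correlation.tsv")

        gw_genes = (cpm_expressed(tx, config.min_cpm, config.min_cpm_samples)
                    .intersection(detected_in_min_replicates(prot, sheet,
                                                             config.detect_min_reps))
                    .intersection(variability_filter(prot_means, config.prot_top_percent)))
        gw = genewise_correlation(tx_log_means, prot_means.observed(),
                                  genes=gw_genes, alpha=config.alpha)
        _write(gw, out / "genewise_correlation.tsv")
        summary["frac_positive"] = float((gw["class"] == "positive").mean())
        summary["frac_negative"] = float((gw["class"] == "negative").mean())

        tx_z = zscore_profiles(pd.DataFrame(np.log2(tx_means.observed() + 1.0)))
        prot_z = zscore_profiles(prot_means)
        joint_genes = tx_z.feature_ids.intersection(prot_z.feature_ids) \
                                      .intersection(gw_genes)
        joint = pd.concat([tx_z.values.loc[joint_genes],
                           prot_z.values.loc[joint_genes]], axis=1)
        joint.columns = ([f"tx_{c}" for c in tx_z.values.columns]
                         + [f"prot_{c}" for c in prot_z.values.columns])
        joint_model = train_som(joint, grid_shape=config.joint_grid,
                                iterations=config.som_iterations,
                                seed=config.seed + 4)
        joint_model = refine_clusters(joint_model, config.refine_percentile)
        index = tp_index(joint_model, tx_z.values.loc[joint_genes],
                         prot_z.values.loc[joint_genes], stage_of)
        groups = group_clusters_kmeans(index, k=min(config.kmeans_k, len(index)),
                                       seed=config.seed + 5)
        _write(index.assign(group=groups), out / "tp_index.tsv")

        overlap = cluster_overlap_test(models["tx"], models["prot"])
        _write(overlap, out / "cluster_overlap.tsv", index=False)
    except Exception as exc:
        raise PipelineError(stage, "compute_error", str(exc)) from exc

    # ---- cross_species ----------------------------------------------------
    if config.run_cross_species and orthologs is not None:
        stage = "cross_species"
        try:
            tx_b, prot_b, sheet_b, _ = data_b
            prot_b_imp = impute_shifted_beta(prot_b, ImputationSpec(seed=config.seed + 6))
            means_b = timepoint_means(prot_b_imp, sheet_b)
            records, tp_mat, per_stage = cross_correlate(
                prot_means, sheet, means_b, sheet_b, orthologs,
                top_percent=config.cross_top_percent, alpha=config.alpha)
            _write(records, out / "xspecies_records.tsv", index=False)
            _write(tp_mat, out / "xspecies_timepoint_matrix.tsv")
            for st, rec in per_stage.items():
                _write(rec, out / f"xspecies_{st}.tsv", index=False)
            summary["xspecies_median_R"] = float(records["R"].median())
        except Exception as exc:
            raise PipelineError(stage, "compute_error", str(exc)) from exc

    # ---- stats_enrichment -------------------------------------------------
    stage = "stats_enrichment"
    try:
        diff = differential_timepoints(tx, sheet, config.diff_tp_a, config.diff_tp_b,
                                       alpha=config.fdr_threshold,
                                       fc_threshold=config.fc_threshold)
        _write(diff, out / "differential_egg.tsv")
        summary["n_up_first_egg"] = int((diff["direction"] == "up_a").sum())

        if truth is not None:
            up_a = set(diff.index[diff["direction"] == "up_a"])
            maternal_ref = set(truth.index[truth["maternal"]])
            mat = maternal_enrichment(up_a, maternal_ref, set(diff.index))
            mat.to_json(out / "maternal_enrichment.json")
            summary["maternal_p"] = float(mat["p"])

            # stage-program term map from ground truth exercises enrichment
            term_map = {f"program_{s}": set(truth.index[truth["label"] == s])
                        for s in sorted(set(truth["label"]) - {"stable"})}
            background = set(models["prot"].assignment.index)
            stage_feats = models["prot"].feature_stage()
            rows = []
            for st in sorted(set(stage_feats.dropna()) - {"none"}):
                genes = set(stage_feats.index[stage_feats == st])
                enr = fisher_enrichment(genes, term_map, background)
                enr = enr.assign(cluster_stage=st)
                rows.append(enr)
            if rows:
                _write(pd.concat(rows), out / "stage_enrichment.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, "compute_error", str(exc)) from exc

    manifest = {"package_version": devodyn.__version__,
                "config": config.to_dict(), "summary": summary}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return summary
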