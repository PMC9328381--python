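"""End-to-end orchestration: simulate -> preprocess -> features -> classify ->
network -> enrich, with seeded determinism and a checksummed run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import to_tree

from . import __version__
from .classify import CVResult, ModelSpec, nested_cv, nonresponder_detection_curve
from .data import (
    ConfigError,
    ExpressionMatrix,
    SampleTable,
    align_paired_design,
    read_expression_matrix,
    read_sample_table,
    write_expression_matrix,
    write_sample_table,
)
from .enrichment import hypergeometric_enrichment, prior_coexpression_fraction, read_evidence_pairs, read_gmt
from .features import delta_expression, encode_clinical, expression_features
from .network import (
    build_network,
    consensus_modules,
    detect_group_specific_modules,
    module_overlap_test,
)
from .preprocess import run_qc
from .simulate import SimulationConfig, ModuleSpec, simulate_cohort

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed by stage-name hashing."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class PipelineConfig:
    """Validated parameters for a full run; see module docstrings for units."""

    out_dir: Path = Path("run")
    seed: int = 0
    # either a simulation config or paths to the three input tables
    simulation: SimulationConfig | None = None
    expr_pre_path: Path | None = None
    expr_wk4_path: Path | None = None
    samples_path: Path | None = None
    # preprocessing
    expression_floor: float = 5.0
    blacklist: list[str] = field(default_factory=list)
    z_cutoff: float = 4.0
    # features / classification
    contrast: str = "expr_ratio"
    family: str = "l2_logistic"
    k_outer: int = 10
    k_inner: int = 5
    # network
    network_timepoint: str = "pretreatment"
    beta_grid: list[float] | None = None
    r2_target: float = 0.85
    min_module_size: int = 30
    cut_height: float = 0.99
    hub_fraction: float = 0.20
    grey_fraction_threshold: float = 0.5
    # enrichment
    gmt_path: Path | None = None
    evidence_path: Path | None = None
    min_term_size: int = 10
    max_term_size: int = 2000

    def validate(self) -> None:
        if self.simulation is None and not (self.expr_pre_path and self.expr_wk4_path and self.samples_path):
            raise ConfigError("either a simulation block or the three input paths are required")
        if self.simulation is not None:
            self.simulation.validate()
        if self.k_outer < 2 or self.k_inner < 2:
            raise ConfigError("k_outer and k_inner must both be >= 2")
        if not 0 < self.hub_fraction <= 1:
            raise ConfigError("hub_fraction must lie in (0, 1]")
        if self.network_timepoint not in ("pretreatment", "week4"):
            raise ConfigError("network_timepoint must be pretreatment or week4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            modules = sim.pop("module_spec", None)
            if modules is not None:
                sim["module_spec"] = [
                    ModuleSpec(int(m["size"]), float(m["correlation"]), m.get("restriction", "both"))
                    for m in modules
                ]
            sim = SimulationConfig(**sim)
        for key in ("out_dir", "expr_pre_path", "expr_wk4_path", "samples_path", "gmt_path", "evidence_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        cfg = cls(simulation=sim, **raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def linkage_to_newick(tree: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    root = to_tree(tree)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(root, root.dist) + ";"


def cv_result_to_dict(result: CVResult) -> dict:
    d = {
        "family": result.family,
        "seed": result.seed,
        "k_outer": result.k_outer,
        "k_inner": result.k_inner,
        "summary": result.summary,
        "fold_metrics": result.fold_metrics.assign(
            chosen_params=result.fold_metrics["chosen_params"].map(json.dumps)
        ).to_dict(orient="records"),
    }
    if result.coefficient_summary is not None:
        top = result.coefficient_summary.head(50)
        d["top_coefficients"] = {i: {"mean": float(r["mean"]), "sd": float(r["sd"])}
                                 for i, r in top.iterrows()}
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the manifest dictionary.

    Outputs land under ``config.out_dir``; partial outputs are retained on
    stage failure.  The manifest records the package version, global seed,
    a hash of the configuration, and a sha256 checksum of every artifact.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        artifacts[name] = _sha256(path)

    # --- simulate or load -------------------------------------------------
    if config.simulation is not None:
        logger.info("stage=simulate n_genes=%d n_patients=%d seed=%d",
                    config.simulation.n_genes,
                    config.simulation.n_good + config.simulation.n_nonresponder,
                    stage_seed(config.seed, "simulate"))
        sim = SimulationConfig(**{**config.simulation.__dict__,
                                  "seed": stage_seed(config.seed, "simulate")})
        cohort = simulate_cohort(sim)
        expr_pre, expr_wk4, samples = cohort.expr_pre, cohort.expr_wk4, cohort.samples
        write_expression_matrix(expr_pre, out / "expr_pre.tsv")
        write_expression_matrix(expr_wk4, out / "expr_wk4.tsv")
        write_sample_table(samples, out / "samples.tsv")
        truth = {
            "module_labels": cohort.ground_truth.module_labels.to_dict(),
            "module_restrictions": cohort.ground_truth.module_restrictions,
            "signal_genes": cohort.ground_truth.signal_genes,
            "unexpressed_genes": cohort.ground_truth.unexpressed_genes,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth))
        for name in ("expr_pre.tsv", "expr_wk4.tsv", "samples.tsv", "ground_truth.json"):
            emit(name, out / name)
    else:
        expr_pre = read_expression_matrix(config.expr_pre_path, "log2")
        expr_wk4 = read_expression_matrix(config.expr_wk4_path, "log2")
        samples = read_sample_table(config.samples_path)

    # --- preprocess (jointly across timepoints, then split back) ----------
    combined = ExpressionMatrix(pd.concat([expr_pre.frame, expr_wk4.frame], axis=1),
                                expr_pre.scale_tag)
    normalized, qc = run_qc(combined, floor=config.expression_floor,
                            blacklist=set(config.blacklist), z_cutoff=config.z_cutoff)
    logger.info("stage=preprocess probes_in=%d probes_out=%d outliers=%d",
                qc.n_probes_in, qc.n_probes_out, len(qc.outlier_samples))
    (out / "qc_report.json").write_text(json.dumps(qc.to_dict(), default=str))
    emit("qc_report.json", out / "qc_report.json")
    expr_pre = ExpressionMatrix(normalized.frame[expr_pre.sample_ids], "normalized_log2")
    expr_wk4 = ExpressionMatrix(normalized.frame[expr_wk4.sample_ids], "normalized_log2")

    # --- features ----------------------------------------------------------
    pairing = align_paired_design(expr_pre, expr_wk4, samples)
    if config.contrast == "expr_ratio":
        feats = expression_features(delta_expression(expr_pre, expr_wk4, pairing))
    elif config.contrast in ("expr_pre", "expr_wk4"):
        feats = expression_features(expr_pre if config.contrast == "expr_pre" else expr_wk4,
                                    pairing, config.contrast)
    else:
        feats = encode_clinical(samples, config.contrast)
    feats.frame.to_csv(out / "features.tsv", sep="\t")
    emit("features.tsv", out / "features.tsv")
    logger.info("stage=features contrast=%s n_features=%d n_patients=%d",
                config.contrast, *feats.frame.shape)

    # --- classify ----------------------------------------------------------
    pathways = None
    if config.gmt_path is not None:
        pathways = {t: s for t, s in read_gmt(config.gmt_path).terms.items()}
    spec = ModelSpec(config.family, pathways=pathways if config.family == "pathway_supported" else None)
    labels = samples.response_by_patient().loc[feats.patient_ids]
    cv = nested_cv(feats, labels, spec, config.k_outer, config.k_inner,
                   seed=stage_seed(config.seed, "classify"))
    (out / "cv_result.json").write_text(json.dumps(cv_result_to_dict(cv)))
    cv.fold_metrics.assign(chosen_params=cv.fold_metrics["chosen_params"].map(json.dumps)) \
        .to_csv(out / "cv_folds.tsv", sep="\t", index=False)
    curve = nonresponder_detection_curve(cv.scores, cv.labels)
    curve.to_csv(out / "detection_curve.tsv", sep="\t", index=False)
    for name in ("cv_result.json", "cv_folds.tsv", "detection_curve.tsv"):
        emit(name, out / name)
    logger.info("stage=classify family=%s auc=%.3f+/-%.3f bacc=%.3f+/-%.3f",
                config.family, cv.summary["roc_auc_mean"], cv.summary["roc_auc_sem"],
                cv.summary["balanced_accuracy_mean"], cv.summary["balanced_accuracy_sem"])

    # --- network (group vs consensus at one timepoint) ---------------------
    tp_matrix = expr_pre if config.network_timepoint == "pretreatment" else expr_wk4
    by_group: dict[str, ExpressionMatrix] = {}
    for group in ("good", "nonresponder"):
        sample_ids = samples.frame.loc[
            (samples.frame["response"] == group)
            & (samples.frame["timepoint"] == config.network_timepoint), "sample_id"]
        cols = [s for s in sample_ids if s in tp_matrix.frame.columns]
        by_group[group] = ExpressionMatrix(tp_matrix.frame[cols], tp_matrix.scale_tag)
    cons_assign, group_assigns = consensus_modules(
        by_group, config.beta_grid, config.r2_target,
        config.min_module_size, config.cut_height)
    specific = detect_group_specific_modules(group_assigns["nonresponder"], cons_assign,
                                             config.grey_fraction_threshold)
    overlap_p = module_overlap_test(group_assigns["nonresponder"], cons_assign)
    non_net = build_network(by_group["nonresponder"], config.beta_grid, config.r2_target,
                            config.min_module_size, config.cut_height, config.hub_fraction)
    modules_table = pd.DataFrame({
        "gene": non_net.assignment.gene_ids,
        "module": non_net.assignment.labels.values,
        "connectivity": non_net.connectivity.values,
    })
    all_hubs = {g for hubs in non_net.hubs.values() for g in hubs}
    modules_table["is_hub"] = modules_table["gene"].isin(all_hubs)
    modules_table.to_csv(out / "modules.tsv", sep="\t", index=False)
    non_net.fit.table.to_csv(out / "scale_free_fit.tsv", sep="\t", index=False)
    overlap_p.to_csv(out / "module_overlap_p.tsv", sep="\t")
    specific.to_csv(out / "group_specific_modules.tsv", sep="\t", index=False)
    (out / "dendrogram.nwk").write_text(
        linkage_to_newick(non_net.dendrogram, non_net.assignment.gene_ids))
    for name in ("modules.tsv", "scale_free_fit.tsv", "module_overlap_p.tsv",
                 "group_specific_modules.tsv", "dendrogram.nwk"):
        emit(name, out / name)
    logger.info("stage=network beta=%g modules=%d group_specific=%d",
                non_net.fit.chosen_beta, len(non_net.assignment.modules()), len(specific))

    # --- enrichment ---------------------------------------------------------
    if config.gmt_path is not None:
        collection = read_gmt(config.gmt_path, universe=set(tp_matrix.probe_ids))
        query = set().union(*(set(non_net.hubs.get(m, [])) for m in specific["module"])) \
            if len(specific) else all_hubs
        if query:
            table = hypergeometric_enrichment(query, collection,
                                              config.min_term_size, config.max_term_size)
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            emit("enrichment.tsv", out / "enrichment.tsv")
            logger.info("stage=enrich terms=%d top_p=%.3g", len(table), table["p_value"].iloc[0])
    if config.evidence_path is not None:
        evidence = read_evidence_pairs(config.evidence_path)
        per_module, overall = prior_coexpression_fraction(non_net.hubs, evidence)
        (out / "coexpression_evidence.json").write_text(json.dumps(
            {"per_module": per_module, "overall": overall}))
        emit("coexpression_evidence.json", out / "coexpression_evidence.json")

    # --- manifest -----------------------------------------------------------
    cfg_text = repr(sorted((k, str(v)) for k, v in config.__dict__.items()))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
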