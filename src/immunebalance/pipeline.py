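"""End-to-end orchestration of the immune-balance analysis.

``run_pipeline`` chains the stages — scoring, group statistics and delta
networks, SOM metaclustering, clinical clustering, prediction validation —
over one cohort and writes every artifact into an output directory. Each
tabular artifact starts with a comment line embedding the config hash and
seed so any result file is traceable to the run that produced it; wall-clock
timestamps are isolated to the manifest so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import io as ibio
from . import scores as sc
from . import som as somod
from . import stats as st
from . import validation as val
from .cohort import (
    CONTROL,
    PATIENT,
    ClinicalDomainSet,
    CohortDataset,
    CohortError,
    PanelDefinition,
)
from .simulate import SimulationConfig, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    # data source: either file paths or a synthetic simulation config
    subset_csv: str | None = None
    labels_csv: str | None = None
    clinical_csv: str | None = None
    simulation: SimulationConfig | None = None

    panel: PanelDefinition = field(default_factory=PanelDefinition)
    domains_preset: str = "four-domain"

    correlation_method: str = "spearman"
    delta_threshold: float = 0.4
    tsne_perplexity: float = 5.0
    som_grid: tuple[int, int] = (4, 4)
    som_epochs: int = 200
    n_metaclusters: int = 8
    n_boot_composition: int = 1000
    clinical_k: int = 3
    importance_permutations: int = 100
    validation_bootstrap: int = 500
    cv_repeats: int = 5

    seed: int = 0
    outdir: str = "immunebalance_out"

    def domains(self) -> ClinicalDomainSet:
        return ClinicalDomainSet.preset(self.domains_preset)

    def to_dict(self) -> dict:
        d = {
            "subset_csv": self.subset_csv,
            "labels_csv": self.labels_csv,
            "clinical_csv": self.clinical_csv,
            "synthetic": self.simulation is not None,
            "panel": self.panel.to_dict(),
            "domains_preset": self.domains_preset,
            "correlation_method": self.correlation_method,
            "delta_threshold": self.delta_threshold,
            "tsne_perplexity": self.tsne_perplexity,
            "som_grid": list(self.som_grid),
            "som_epochs": self.som_epochs,
            "n_metaclusters": self.n_metaclusters,
            "n_boot_composition": self.n_boot_composition,
            "clinical_k": self.clinical_k,
            "importance_permutations": self.importance_permutations,
            "validation_bootstrap": self.validation_bootstrap,
            "cv_repeats": self.cv_repeats,
            "seed": self.seed,
        }
        if self.simulation is not None:
            d["simulation_seed"] = self.simulation.seed
            d["n_patients"] = self.simulation.n_patients
            d["n_controls"] = self.simulation.n_controls
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(cfg: PipelineConfig) -> str:
    return f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, **kwargs) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_stamp(cfg))
        df.to_csv(fh, **kwargs)


def load_cohort(cfg: PipelineConfig) -> CohortDataset:
    if cfg.simulation is not None:
        return generate_cohort(cfg.simulation)
    if cfg.subset_csv is None or cfg.labels_csv is None:
        raise CohortError("config needs either a simulation block or cohort CSV paths")
    return ibio.read_cohort(cfg.subset_csv, cfg.labels_csv, cfg.clinical_csv)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_scores(cohort: CohortDataset, cfg: PipelineConfig, outdir: Path) -> sc.ScoreTable:
    table = sc.compute_score_table(cohort, cfg.panel, cfg.domains())
    _write_csv(table.table, outdir / "scores.csv", cfg, index_label="sample_id")
    ibio.write_json(
        {**table.metadata(), "config_hash": cfg.config_hash(), "seed": cfg.seed},
        outdir / "scores_meta.json",
    )
    n_scored = int(table["cds"].notna().sum())
    log.info("scores: %d samples, %d with complete clinical rows", len(table.table), n_scored)
    return table


def stage_networks(cohort: CohortDataset, cfg: PipelineConfig, outdir: Path) -> st.DeltaNetwork:
    tests = st.compare_subsets(cohort)
    _write_csv(st.subset_tests_frame(tests), outdir / "subset_tests.csv", cfg, index=False)
    mat_p = st.correlation_matrix(cohort.group_matrix(PATIENT), cfg.correlation_method)
    mat_c = st.correlation_matrix(cohort.group_matrix(CONTROL), cfg.correlation_method)
    _write_csv(mat_p, outdir / "correlation_patients.csv", cfg)
    _write_csv(mat_c, outdir / "correlation_controls.csv", cfg)
    network = st.delta_network(mat_p, mat_c, threshold=cfg.delta_threshold)
    ibio.write_delta_network(
        network, outdir / "delta_network.tsv", outdir / "delta_network.graphml"
    )
    if len(cohort.sample_ids) >= 3 * cfg.tsne_perplexity:
        coords = st.embed_2d(cohort.subset_matrix, cfg.tsne_perplexity, seed=cfg.seed)
        coords["group"] = cohort.group_labels
        _write_csv(coords, outdir / "tsne_embedding.csv", cfg, index_label="sample_id")
    else:
        log.info("t-SNE skipped: fewer than 3x perplexity samples")
    log.info("delta network: %d nodes, %d edges at |dr| >= %.2f",
             len(network.nodes), len(network.edges), cfg.delta_threshold)
    return network


def stage_metaclusters(
    cohort: CohortDataset, score_table: sc.ScoreTable, cfg: PipelineConfig, outdir: Path
) -> somod.MetaclusterAssignment:
    som = somod.train_som(
        cohort.subset_matrix, grid=cfg.som_grid, epochs=cfg.som_epochs, seed=cfg.seed + 1
    )
    k = min(cfg.n_metaclusters, som.n_nodes)
    node_map = somod.metacluster(som, k=k)
    assignment = somod.assign_and_compose(cohort, som, node_map)

    coords = somod._grid_coordinates(*som.grid)
    codebook = pd.DataFrame(som.codebook, columns=som.feature_names)
    codebook.insert(0, "grid_row", coords[:, 0].astype(int))
    codebook.insert(1, "grid_col", coords[:, 1].astype(int))
    codebook.insert(2, "metacluster", [f"MC{m}" for m in node_map])
    _write_csv(codebook, outdir / "som_codebook.csv", cfg, index_label="node")

    assign_df = pd.DataFrame(
        {
            "node": assignment.sample_nodes,
            "metacluster": assignment.sample_metaclusters,
            "group": cohort.group_labels,
        }
    )
    _write_csv(assign_df, outdir / "metacluster_assignment.csv", cfg, index_label="sample_id")
    _write_csv(assignment.composition, outdir / "metacluster_composition.csv", cfg,
               index_label="metacluster")
    diffs = somod.composition_differences(
        assignment, cohort.group_labels, n_boot=cfg.n_boot_composition, seed=cfg.seed + 2
    )
    _write_csv(diffs, outdir / "composition_differences.csv", cfg, index_label="metacluster")
    volcano = somod.metacluster_marker_differences(cohort, assignment)
    _write_csv(volcano, outdir / "metacluster_volcano.csv", cfg, index=False)
    weights = somod.metacluster_ids_weights(assignment, score_table["ids"])
    _write_csv(weights.to_frame(), outdir / "metacluster_ids_weights.csv", cfg,
               index_label="metacluster")
    return assignment


def stage_clinical(
    cohort: CohortDataset, score_table: sc.ScoreTable, cfg: PipelineConfig, outdir: Path
) -> clin.ClinicalClusterResult | None:
    if cohort.clinical_matrix is None:
        log.info("clinical stage skipped: no clinical table")
        return None
    domains = cfg.domains()
    cols = [d for d in domains.domains if d in cohort.clinical_matrix.columns]
    if len(cols) < len(domains.domains):
        log.info("clinical stage skipped: clinical table lacks configured domains")
        return None
    binary = cohort.clinical_matrix[cols].loc[
        cohort.clinical_matrix.index.intersection(cohort.patient_ids)
    ]
    if len(binary) <= cfg.clinical_k:
        log.info("clinical stage skipped: too few patients to cluster")
        return None
    result = clin.cluster_clinical(
        binary,
        cds=score_table["cds"],
        k=cfg.clinical_k,
        n_perm=cfg.importance_permutations,
        seed=cfg.seed + 3,
    )
    out = pd.DataFrame({"cluster": result.labels})
    if result.tiers is not None:
        out["tier"] = result.tiers
    out = out.join(result.coordinates)
    _write_csv(out, outdir / "clinical_clusters.csv", cfg, index_label="sample_id")
    ibio.write_json(
        {
            "medoids": list(result.medoids),
            "importance": result.importance.to_dict(),
            "excluded_rows": list(result.excluded),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
        },
        outdir / "clinical_clusters_meta.json",
    )
    log.info("clinical clustering: %d patients in, %d excluded for missing data",
             len(binary), len(result.excluded))
    return result


def stage_validation(
    cohort: CohortDataset,
    score_table: sc.ScoreTable,
    clinical_result: clin.ClinicalClusterResult | None,
    cfg: PipelineConfig,
    outdir: Path,
) -> dict:
    t = score_table.table
    y = (t["group"] == PATIENT).astype(int).to_numpy()
    roc = val.roc_auc(t["ids"].to_numpy(), y)
    _write_csv(roc.to_frame(), outdir / "ids_roc.csv", cfg, index=False)

    report: dict = {
        "ids_auc": roc.auc,
        "ids_auc_ci": [roc.ci_low, roc.ci_high],
        "youden_threshold": roc.youden_threshold,
        "youden_sensitivity": roc.youden_sensitivity,
        "youden_specificity": roc.youden_specificity,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }

    # IDS vs clinical z-score coupling (patients with complete clinical rows)
    mask = t["clinical_z"].notna()
    if mask.sum() >= 3 and t.loc[mask, "ids"].std() > 0:
        from scipy.stats import pearsonr

        r, p = pearsonr(t.loc[mask, "ids"], t.loc[mask, "clinical_z"])
        report["ids_clinical_pearson_r"] = float(r)
        report["ids_clinical_pearson_p"] = float(p)

    features = t[["pro_mean", "anti_mean", "ids", "delta_ids"]]
    X = features.to_numpy(dtype=float)

    boot = val.bootstrap_optimism(
        val.logistic_spec, X, y, metric="auc", B=cfg.validation_bootstrap, seed=cfg.seed + 4
    )
    report["composite_patient_vs_control"] = boot.to_dict()
    cv = val.repeated_cv(
        val.logistic_spec, X, y, k=10, repeats=cfg.cv_repeats, metric="auc", seed=cfg.seed + 5
    )
    report["repeated_cv_auc"] = {"mean": cv["mean"], "sd": cv["sd"], "k": cv["k"]}

    if clinical_result is not None and clinical_result.tiers is not None:
        ids_cl = clinical_result.tiers.index
        Xc = features.loc[ids_cl]
        tiers = clinical_result.tiers
        counts = tiers.value_counts()
        if len(counts) >= 2 and counts.min() >= 2:
            model = val.fit_composite_model(Xc, tiers, kind="ovr_logistic", seed=cfg.seed + 6)
            probs = model.predict_proba(Xc)
            per_class = {}
            nb_frames = []
            for ci, cls in enumerate(model.classes_):
                y_bin = (tiers == cls).astype(int).to_numpy()
                if y_bin.sum() in (0, len(y_bin)):
                    continue
                per_class[str(cls)] = val.auc_score(probs[:, ci], y_bin)
                nb = val.decision_curve(
                    np.clip(probs[:, ci], 1e-6, 1 - 1e-6), y_bin,
                    thresholds=np.arange(0.05, 0.95, 0.05),
                )
                frame = nb.to_frame()
                frame.insert(0, "class", str(cls))
                nb_frames.append(frame)
            report["severity_ovr_auc"] = per_class
            if nb_frames:
                _write_csv(pd.concat(nb_frames, ignore_index=True),
                           outdir / "decision_curves.csv", cfg, index=False)
            imp = val.permutation_importance(model, Xc, tiers, n_perm=20, seed=cfg.seed + 7)
            report["severity_feature_importance"] = imp.to_dict()

            # calibration of the largest-class one-vs-rest probabilities
            top = str(counts.index[0])
            ti = list(map(str, model.classes_)).index(top)
            cal = val.calibration(
                np.clip(probs[:, ti], 1e-6, 1 - 1e-6),
                (tiers == top).astype(int).to_numpy(),
                n_bins=min(10, len(tiers)),
            )
            report["calibration"] = {
                "class": top,
                "intercept": cal.intercept,
                "slope": cal.slope,
                "flagged": cal.flagged,
            }
            _write_csv(cal.bins, outdir / "calibration_bins.csv", cfg, index=False)

    ibio.write_json(report, outdir / "validation_report.json")
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the validation report.

    Artifacts written: scores.csv(+meta), subset_tests.csv, correlation
    matrices, delta_network.tsv/.graphml, SOM codebook/assignment/
    composition/volcano/weights, clinical_clusters.csv(+meta),
    ids_roc.csv, decision_curves.csv, calibration_bins.csv,
    validation_report.json, summary.txt and manifest.json.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(cfg)
    if cfg.simulation is not None:
        ibio.write_cohort(cohort, outdir / "cohort")

    def _run(stage_name, fn, *args):
        try:
            return fn(*args)
        except CohortError as exc:
            raise CohortError(f"stage {stage_name!r}: {exc}") from exc

    score_table = _run("scores", stage_scores, cohort, cfg, outdir)
    network = _run("networks", stage_networks, cohort, cfg, outdir)
    _run("metaclusters", stage_metaclusters, cohort, score_table, cfg, outdir)
    clinical_result = _run("clinical", stage_clinical, cohort, score_table, cfg, outdir)
    report = _run("validation", stage_validation, cohort, score_table,
                  clinical_result, cfg, outdir)

    summary = [
        f"immunebalance pipeline (config {cfg.config_hash()}, seed {cfg.seed})",
        f"cohort: {len(cohort.patient_ids)} patients, {len(cohort.control_ids)} controls, "
        f"{len(cohort.subset_names)} subsets",
        f"IDS AUC (patients vs controls): {report['ids_auc']:.3f} "
        f"[{report['ids_auc_ci'][0]:.3f}, {report['ids_auc_ci'][1]:.3f}]",
        f"delta network: {len(network.edges)} edges at |dr| >= {cfg.delta_threshold}",
    ]
    if "ids_clinical_pearson_r" in report:
        summary.append(
            f"IDS vs clinical z: r = {report['ids_clinical_pearson_r']:.3f} "
            f"(p = {report['ids_clinical_pearson_p']:.2e})"
        )
    if clinical_result is None:
        summary.append("clinical stages skipped (no usable clinical table)")
    (outdir / "summary.txt").write_text("\n".join(summary) + "\n", encoding="utf-8")

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    ibio.write_json(manifest, outdir / "manifest.json")
    return report
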