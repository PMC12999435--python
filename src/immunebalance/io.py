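"""Readers and writers for cohort tables and configuration files.

Interchange formats are plain UTF-8 CSV with a header row and ``sample_id``
as the first column ("." decimal separator), plus YAML/JSON for panels and
pipeline configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CONTROL,
    PATIENT,
    ClinicalDomainSet,
    CohortDataset,
    CohortError,
    PanelDefinition,
)


def write_cohort(cohort: CohortDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort as subsets.csv, labels.csv and (optionally) clinical.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subsets": outdir / "subsets.csv",
        "labels": outdir / "labels.csv",
    }
    cohort.subset_matrix.to_csv(paths["subsets"], index_label="sample_id")
    labels = pd.DataFrame({"group": cohort.group_labels})
    if cohort.genetic_labels is not None:
        labels["genetic_label"] = cohort.genetic_labels
    if cohort.latent_severity is not None:
        labels["latent_severity"] = cohort.latent_severity
    labels.to_csv(paths["labels"], index_label="sample_id")
    if cohort.clinical_matrix is not None:
        paths["clinical"] = outdir / "clinical.csv"
        cohort.clinical_matrix.to_csv(paths["clinical"], index_label="sample_id")
    return paths


def read_cohort(
    subset_csv: str | Path,
    labels_csv: str | Path,
    clinical_csv: str | Path | None = None,
) -> CohortDataset:
    """Load and validate a cohort from CSV tables.

    Frequencies outside [0, 100] are rejected with the offending row and
    column named; clinical rows may cover only a subset of samples
    (typically patients) and missing entries are tolerated as NaN.
    """
    subsets = pd.read_csv(subset_csv, index_col=0)
    if subsets.index.has_duplicates:
        dupes = subsets.index[subsets.index.duplicated()].tolist()
        raise CohortError(f"duplicate sample ids: {dupes}")
    for col in subsets.columns:
        vals = pd.to_numeric(subsets[col], errors="coerce")
        if vals.isna().any():
            bad = subsets.index[vals.isna()][0]
            raise CohortError(f"unparseable numeric at row {bad!r}, column {col!r}")
        out = vals[(vals < 0) | (vals > 100)]
        if len(out):
            raise CohortError(
                f"frequency outside [0, 100] at row {out.index[0]!r}, column {col!r}: "
                f"{out.iloc[0]}"
            )
        subsets[col] = vals

    labels_df = pd.read_csv(labels_csv, index_col=0)
    if "group" not in labels_df.columns:
        raise CohortError("labels CSV needs a 'group' column")
    groups = labels_df["group"].astype(str)
    bad = set(groups.unique()) - {PATIENT, CONTROL}
    if bad:
        raise CohortError(f"labels must be patient/control, got {sorted(bad)}")

    clinical = None
    if clinical_csv is not None:
        clinical = pd.read_csv(clinical_csv, index_col=0)
    genetic = (
        labels_df["genetic_label"] if "genetic_label" in labels_df.columns else None
    )
    severity = (
        labels_df["latent_severity"].dropna()
        if "latent_severity" in labels_df.columns
        else None
    )
    return CohortDataset(
        subset_matrix=subsets,
        group_labels=groups,
        clinical_matrix=clinical,
        genetic_labels=genetic,
        latent_severity=severity,
    )


def load_panel(path: str | Path) -> PanelDefinition:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
    return PanelDefinition.from_dict(data)


def save_panel(panel: PanelDefinition, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(panel.to_dict(), fh)
        else:
            json.dump(panel.to_dict(), fh, indent=2)


def load_domains(spec: str | Path | list) -> ClinicalDomainSet:
    if isinstance(spec, str) and spec in ("four-domain", "six-domain"):
        return ClinicalDomainSet.preset(spec)
    if isinstance(spec, (list, tuple)):
        return ClinicalDomainSet(domains=tuple(spec))
    with open(spec, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return ClinicalDomainSet(domains=tuple(data["domains"]))


def write_delta_network(network, tsv_path: str | Path, graphml_path: str | Path | None = None):
    """Export a delta network as an edge-list TSV and optionally GraphML."""
    import networkx as nx

    cols = ["node_a", "node_b", "r_patient", "r_control", "delta_r", "stronger_in"]
    network.edges[cols].to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(network.to_graph(), graphml_path)


def _to_native(obj):
    if isinstance(obj, dict):
        return {str(k): _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_to_native(v) for v in obj.tolist()]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json(data: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_to_native(data), fh, indent=2, allow_nan=True)
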