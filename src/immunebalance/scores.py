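"""Immune and clinical dysregulation scores.

The immune dysregulation score (IDS) of a sample is

    IDS = log( GM(inflammatory subsets) / GM(regulatory subsets) )

where GM is the geometric mean of percent-of-parent frequencies (a small
pseudocount guards zeros). Positive IDS means the inflammatory compartment
dominates the regulatory one. dIDS re-centers IDS on the control-group mean.
Pro_mean / Anti_mean are arithmetic means of control-standardized
frequencies of the inflammatory / regulatory panel subsets.

The clinical dysregulation score (CDS) counts binary-coded clinical
manifestation domains present in a patient; clinical_z is its z-score over
the scored patients.

``select_balance`` is a greedy compositional balance search in the spirit of
forward selection over log-contrasts: it looks for the two disjoint subset
groups whose log-ratio of geometric means best discriminates a binary
outcome under cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import ClinicalDomainSet, CohortDataset, CohortError, PanelDefinition
from .validation import auc_score


def geometric_mean(values, pseudocount: float = 0.0) -> float:
    """Geometric mean of positive percents, with pseudocount added to zeros."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise CohortError("geometric mean of empty input")
    if (arr < 0).any():
        raise CohortError("geometric mean requires non-negative values")
    arr = arr + pseudocount
    if (arr <= 0).any():
        raise CohortError("values must be strictly positive after pseudocount")
    return float(np.exp(np.mean(np.log(arr))))


def compute_ids(sample_frequencies: pd.Series, panel: PanelDefinition) -> float:
    """IDS of a single sample: log-ratio of panel geometric means."""
    missing = [s for s in panel.all_subsets if s not in sample_frequencies.index]
    if missing:
        raise CohortError(f"sample lacks panel subsets: {missing}")
    vals = sample_frequencies[list(panel.all_subsets)].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise CohortError("non-finite subset frequency")
    # pseudocount engages only when a zero is present, so strictly positive
    # inputs give the exact log-ratio (antisymmetry/equivariance hold exactly)
    pro = sample_frequencies[list(panel.inflammatory_subsets)].to_numpy(dtype=float)
    anti = sample_frequencies[list(panel.regulatory_subsets)].to_numpy(dtype=float)
    gm_pro = geometric_mean(pro, panel.pseudocount if (pro == 0).any() else 0.0)
    gm_anti = geometric_mean(anti, panel.pseudocount if (anti == 0).any() else 0.0)
    return float(np.log(gm_pro / gm_anti) / np.log(panel.log_base))


def compute_cds(clinical_row: pd.Series, domains: ClinicalDomainSet) -> int | None:
    """Count of present clinical domains; None if any domain is missing."""
    missing_cols = [d for d in domains.domains if d not in clinical_row.index]
    if missing_cols:
        raise CohortError(f"clinical row lacks domains: {missing_cols}")
    vals = clinical_row[list(domains.domains)].astype(float)
    if vals.isna().any():
        return None
    bad = vals[~vals.isin([0.0, 1.0])]
    if len(bad):
        raise CohortError(f"non-binary clinical value(s): {bad.to_dict()}")
    return int(vals.sum())


@dataclass
class ScoreTable:
    """Per-sample score table plus the control reference used to build it."""

    table: pd.DataFrame  # columns: ids, delta_ids, pro_mean, anti_mean, cds, clinical_z
    panel: PanelDefinition
    domains: ClinicalDomainSet
    control_ids_mean: float
    control_stats: pd.DataFrame  # per-subset control mean/sd used for standardization

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]

    def metadata(self) -> dict:
        return {
            "panel": self.panel.to_dict(),
            "domains": list(self.domains.domains),
            "control_ids_mean": self.control_ids_mean,
            "control_stats": self.control_stats.to_dict(),
        }


def compute_score_table(
    cohort: CohortDataset,
    panel: PanelDefinition | None = None,
    domains: ClinicalDomainSet | None = None,
) -> ScoreTable:
    """Compute IDS, dIDS, Pro_mean, Anti_mean, CDS and clinical_z per sample.

    dIDS is IDS minus the control-group mean IDS, so controls average to
    zero by construction. Pro_mean/Anti_mean standardize each panel subset
    against the control mean and SD before averaging; a zero control SD in
    any panel subset makes those features undefined and is an error.
    CDS and clinical_z are computed only for samples with a complete
    clinical row; incomplete rows are excluded (and visible as NaN).
    """
    panel = panel or PanelDefinition()
    domains = domains or ClinicalDomainSet()
    controls = cohort.control_ids
    if len(controls) == 0:
        raise CohortError("score table needs at least one control sample")

    ids = cohort.subset_matrix.apply(lambda row: compute_ids(row, panel), axis=1)
    control_ids_mean = float(ids.loc[controls].mean())
    delta_ids = ids - control_ids_mean

    ctrl = cohort.subset_matrix.loc[controls, list(panel.all_subsets)]
    ctrl_mean = ctrl.mean()
    ctrl_sd = ctrl.std(ddof=1) if len(controls) > 1 else ctrl.std(ddof=0)
    degenerate = ctrl_sd[ctrl_sd == 0]
    if len(degenerate):
        raise CohortError(
            f"zero control SD for panel subset(s) {list(degenerate.index)}; "
            "Pro_mean/Anti_mean undefined"
        )
    z = (cohort.subset_matrix[list(panel.all_subsets)] - ctrl_mean) / ctrl_sd
    pro_mean = z[list(panel.inflammatory_subsets)].mean(axis=1)
    anti_mean = z[list(panel.regulatory_subsets)].mean(axis=1)

    cds = pd.Series(np.nan, index=cohort.sample_ids, dtype=float)
    if cohort.clinical_matrix is not None:
        for sid in cohort.clinical_matrix.index:
            val = compute_cds(cohort.clinical_matrix.loc[sid], domains)
            if val is not None:
                cds.loc[sid] = val

    clinical_z = pd.Series(np.nan, index=cohort.sample_ids, dtype=float)
    scored_patients = cds.loc[cohort.patient_ids].dropna()
    if len(scored_patients) >= 2 and scored_patients.nunique() > 1:
        clinical_z.loc[scored_patients.index] = (
            scored_patients - scored_patients.mean()
        ) / scored_patients.std(ddof=1)

    table = pd.DataFrame(
        {
            "group": cohort.group_labels,
            "ids": ids,
            "delta_ids": delta_ids,
            "pro_mean": pro_mean,
            "anti_mean": anti_mean,
            "cds": cds,
            "clinical_z": clinical_z,
        }
    )
    control_stats = pd.DataFrame({"mean": ctrl_mean, "sd": ctrl_sd})
    return ScoreTable(
        table=table,
        panel=panel,
        domains=domains,
        control_ids_mean=control_ids_mean,
        control_stats=control_stats,
    )


def ratio_vs_controls(
    cohort: CohortDataset,
    inflammatory_subset: str,
    regulatory_subset: str,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Per-sample inflammatory/regulatory ratio normalized to the control mean.

    The raw ratio (with pseudocount in numerator and denominator) is divided
    by its control-group mean, so the normalized ratio averages exactly 1
    over controls.
    """
    for s in (inflammatory_subset, regulatory_subset):
        if s not in cohort.subset_matrix.columns:
            raise CohortError(f"unknown subset {s!r}")
    if len(cohort.control_ids) == 0:
        raise CohortError("ratio normalization needs controls")
    num = cohort.subset_matrix[inflammatory_subset] + pseudocount
    den = cohort.subset_matrix[regulatory_subset] + pseudocount
    raw = num / den
    return raw / raw.loc[cohort.control_ids].mean()


# ---------------------------------------------------------------------------
# Greedy compositional balance search
# ---------------------------------------------------------------------------


@dataclass
class BalanceSolution:
    """Result of the greedy balance search."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    criterion: float  # outer-CV AUC of the selected balance
    trace: list[dict] = field(default_factory=list)

    def score(self, features: pd.DataFrame, pseudocount: float = 0.01) -> pd.Series:
        return _balance_score(features, self.numerator, self.denominator, pseudocount)


def _balance_score(features, numerator, denominator, pseudocount) -> pd.Series:
    logs = np.log(features + pseudocount)
    return logs[list(numerator)].mean(axis=1) - logs[list(denominator)].mean(axis=1)


def _cv_auc(score: np.ndarray, y: np.ndarray, folds) -> float:
    """Mean held-out AUC of a fixed (parameter-free) score over given folds."""
    aucs = [auc_score(score[test], y[test]) for _, test in folds]
    return float(np.mean(aucs))


def _greedy_search(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    max_vars: int,
    folds,
    pseudocount: float,
    tol: float,
) -> tuple[tuple[str, ...], tuple[str, ...], list[dict]]:
    logs = np.log(X + pseudocount)
    idx = range(len(names))

    def score_of(num: tuple, den: tuple) -> np.ndarray:
        return logs[:, list(num)].mean(axis=1) - logs[:, list(den)].mean(axis=1)

    best_pair, best_auc = None, -np.inf
    for i in idx:
        for j in idx:
            if i == j:
                continue
            a = _cv_auc(score_of((i,), (j,)), y, folds)
            if a > best_auc:
                best_auc, best_pair = a, ((i,), (j,))
    num, den = best_pair
    trace = [{"numerator": [names[i] for i in num],
              "denominator": [names[j] for j in den], "cv_auc": best_auc}]

    while len(num) + len(den) < max_vars:
        cand_best, cand = -np.inf, None
        used = set(num) | set(den)
        for i in idx:
            if i in used:
                continue
            a_num = _cv_auc(score_of(num + (i,), den), y, folds)
            a_den = _cv_auc(score_of(num, den + (i,)), y, folds)
            if a_num > cand_best:
                cand_best, cand = a_num, (num + (i,), den)
            if a_den > cand_best:
                cand_best, cand = a_den, (num, den + (i,))
        if cand is None or cand_best <= best_auc + tol:
            break
        num, den = cand
        best_auc = cand_best
        trace.append({"numerator": [names[i] for i in num],
                      "denominator": [names[j] for j in den], "cv_auc": best_auc})
    return num, den, trace


def select_balance(
    features: pd.DataFrame,
    outcome: pd.Series,
    max_vars: int = 6,
    cv_folds: int = 5,
    seed: int = 0,
    pseudocount: float = 0.01,
    tolerance: float = 1e-4,
) -> BalanceSolution:
    """Greedy forward search for a discriminative compositional balance.

    Starts from the best single numerator/denominator pair by cross-validated
    AUC of the log-contrast score, then adds one variable (to either side)
    per step while the CV-AUC improves, up to ``max_vars`` variables.

    The reported ``criterion`` is an honest outer-CV estimate: the greedy
    selection is repeated inside each training fold and the balance selected
    there is scored on the held-out fold, so a search over pure noise stays
    near AUC 0.5. The returned numerator/denominator come from the
    full-data search.
    """
    if features.shape[1] < 3:
        raise CohortError("balance search needs at least 3 candidate features")
    if max_vars < 2:
        raise CohortError("max_vars must be at least 2")
    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise CohortError("outcome must contain both classes")
    X = features.to_numpy(dtype=float)
    names = list(features.columns)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    inner_folds = list(skf.split(X, y))
    num, den, trace = _greedy_search(X, y, names, max_vars, inner_folds, pseudocount, tolerance)

    outer = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + 1)
    outer_aucs = []
    for train, test in outer.split(X, y):
        tr_folds = list(
            StratifiedKFold(n_splits=min(cv_folds, 3), shuffle=True, random_state=seed + 2)
            .split(X[train], y[train])
        )
        n_tr, d_tr, _ = _greedy_search(
            X[train], y[train], names, max_vars, tr_folds, pseudocount, tolerance
        )
        logs = np.log(X[test] + pseudocount)
        s = logs[:, list(n_tr)].mean(axis=1) - logs[:, list(d_tr)].mean(axis=1)
        outer_aucs.append(auc_score(s, y[test]))

    return BalanceSolution(
        numerator=tuple(names[i] for i in num),
        denominator=tuple(names[j] for j in den),
        criterion=float(np.mean(outer_aucs)),
        trace=trace,
    )
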