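"""Self-organizing-map metaclustering of sample immunophenotypes.

A small Kohonen map is trained on standardized sample-level subset-frequency
vectors; codebook nodes are then merged by average-linkage hierarchical
clustering into k metaclusters (the FlowSOM two-stage recipe, applied at
sample rather than event level). Samples inherit the metacluster of their
best-matching node. Downstream: group composition with bootstrap CIs,
per-metacluster marker differences, and metacluster-to-IDS weights.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu, pearsonr

from .cohort import CONTROL, PATIENT, CohortDataset, CohortError
from .stats import bh_fdr

log = logging.getLogger(__name__)


@dataclass
class SOMModel:
    grid: tuple[int, int]
    codebook: np.ndarray  # nodes x features
    feature_names: list[str]
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    bmu_counts: np.ndarray  # training-sample occupancy per node
    epochs: int
    learning_rate: float
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    def standardize(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.feature_names:
            raise CohortError("feature set does not match SOM training features")
        X = features.to_numpy(dtype=float)
        return (X - self.standardize_mean) / self.standardize_sd

    def best_matching_units(self, features: pd.DataFrame) -> np.ndarray:
        X = self.standardize(features)
        d2 = ((X[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def _grid_coordinates(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def train_som(
    features: pd.DataFrame,
    grid: tuple[int, int] = (4, 4),
    epochs: int = 200,
    learning_rate: float = 0.5,
    seed: int = 0,
) -> SOMModel:
    """Train an online Kohonen map on z-scored features.

    Each epoch presents every sample in a seeded shuffled order; the
    best-matching unit and its Gaussian grid neighborhood move toward the
    sample with a linearly decaying learning rate, while the neighborhood
    radius decays from half the grid diagonal to 1.
    """
    rows, cols = grid
    if rows < 2 or cols < 2:
        raise CohortError("grid must be at least 2x2")
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise CohortError("non-finite feature values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd

    n_nodes = rows * cols
    if len(Xs) < n_nodes:
        log.warning("fewer samples (%d) than SOM nodes (%d)", len(Xs), n_nodes)

    rng = np.random.default_rng(seed)
    codebook = rng.standard_normal((n_nodes, Xs.shape[1]))
    coords = _grid_coordinates(rows, cols)
    radius0 = float(np.hypot(rows - 1, cols - 1)) / 2.0

    total_steps = max(epochs * len(Xs), 1)
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(len(Xs)):
            frac = step / total_steps
            lr = learning_rate * (1.0 - frac)
            radius = max(radius0 * (1.0 - frac), 1.0)
            x = Xs[i]
            bmu = int(((codebook - x) ** 2).sum(axis=1).argmin())
            d2 = ((coords - coords[bmu]) ** 2).sum(axis=1)
            h = np.exp(-d2 / (2.0 * radius**2))
            codebook += (lr * h)[:, None] * (x - codebook)
            step += 1

    d2 = ((Xs[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    bmus = d2.argmin(axis=1)
    counts = np.bincount(bmus, minlength=n_nodes)
    return SOMModel(
        grid=grid,
        codebook=codebook,
        feature_names=list(features.columns),
        standardize_mean=mean,
        standardize_sd=sd,
        bmu_counts=counts,
        epochs=epochs,
        learning_rate=learning_rate,
        seed=seed,
    )


def metacluster(som: SOMModel, k: int = 8) -> np.ndarray:
    """Merge codebook nodes into k metaclusters (average-linkage Euclidean).

    Labels are renumbered 1..k by descending training-sample occupancy, so
    MC1 is always the most populated metacluster.
    """
    if not 1 <= k <= som.n_nodes:
        raise CohortError(f"k must lie in [1, {som.n_nodes}]")
    if k == som.n_nodes:
        raw = np.arange(1, k + 1)
    else:
        Z = linkage(som.codebook, method="average", metric="euclidean")
        raw = fcluster(Z, t=k, criterion="maxclust")
    # occupancy-ordered renumbering; ties broken by raw label for determinism
    occupancy = {
        lab: som.bmu_counts[raw == lab].sum() for lab in np.unique(raw)
    }
    order = sorted(occupancy, key=lambda lab: (-occupancy[lab], lab))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return np.array([remap[lab] for lab in raw])


@dataclass
class MetaclusterAssignment:
    node_map: np.ndarray  # node -> metacluster (1-based)
    sample_nodes: pd.Series  # sample -> best-matching unit
    sample_metaclusters: pd.Series  # sample -> metacluster label "MC<j>"
    composition: pd.DataFrame  # metacluster x group sample fractions

    @property
    def k(self) -> int:
        return int(self.node_map.max())


def assign_and_compose(
    cohort: CohortDataset, som: SOMModel, node_map: np.ndarray
) -> MetaclusterAssignment:
    """Map samples to metaclusters and compute per-group composition."""
    feats = cohort.subset_matrix[som.feature_names] if set(som.feature_names) <= set(
        cohort.subset_matrix.columns
    ) else None
    if feats is None:
        raise CohortError("cohort lacks SOM training features")
    bmus = som.best_matching_units(feats)
    mcs = node_map[bmus]
    sample_nodes = pd.Series(bmus, index=cohort.sample_ids, name="node")
    labels = pd.Series([f"MC{m}" for m in mcs], index=cohort.sample_ids, name="metacluster")

    k = int(node_map.max())
    mc_index = [f"MC{i}" for i in range(1, k + 1)]
    comp = {}
    for group in (PATIENT, CONTROL):
        ids = cohort.patient_ids if group == PATIENT else cohort.control_ids
        counts = labels.loc[ids].value_counts().reindex(mc_index, fill_value=0)
        comp[group] = counts / max(len(ids), 1)
    composition = pd.DataFrame(comp)
    return MetaclusterAssignment(
        node_map=node_map,
        sample_nodes=sample_nodes,
        sample_metaclusters=labels,
        composition=composition,
    )


def composition_differences(
    assignment: MetaclusterAssignment,
    group_labels: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient-minus-control composition differences with bootstrap 95% CIs.

    Differences are in percentage points and sum to zero across
    metaclusters. CIs are percentile intervals from resampling samples
    within each group.
    """
    if n_boot < 200:
        raise CohortError("n_boot must be >= 200")
    labels = assignment.sample_metaclusters
    pat_ids = group_labels.index[group_labels == PATIENT]
    ctl_ids = group_labels.index[group_labels == CONTROL]
    if len(pat_ids) == 0 or len(ctl_ids) == 0:
        raise CohortError("both groups must be non-empty")
    mc_index = assignment.composition.index

    def frac(ids) -> np.ndarray:
        counts = labels.loc[ids].value_counts().reindex(mc_index, fill_value=0)
        return counts.to_numpy() / len(ids)

    point = (frac(pat_ids) - frac(ctl_ids)) * 100.0
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(mc_index)))
    pat_arr, ctl_arr = np.asarray(pat_ids), np.asarray(ctl_ids)
    for b in range(n_boot):
        bp = pat_arr[rng.integers(0, len(pat_arr), len(pat_arr))]
        bc = ctl_arr[rng.integers(0, len(ctl_arr), len(ctl_arr))]
        boots[b] = (frac(bp) - frac(bc)) * 100.0
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "proportion_patient": assignment.composition[PATIENT].to_numpy(),
            "proportion_control": assignment.composition[CONTROL].to_numpy(),
            "difference_pp": point,
            "ci_low": np.minimum(lo, point),
            "ci_high": np.maximum(hi, point),
        },
        index=mc_index,
    )


def metacluster_marker_differences(
    cohort: CohortDataset, assignment: MetaclusterAssignment
) -> pd.DataFrame:
    """Patient-vs-control marker differences within each metacluster.

    Per feature: difference of group mean z-scores (standardized over the
    full cohort) plus a Mann-Whitney p and a BH q adjusted within the
    metacluster. Metaclusters with fewer than 2 samples in either group are
    flagged untested rather than silently zeroed.
    """
    X = cohort.subset_matrix
    sd = X.std(ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean()) / sd
    rows = []
    for mc in assignment.composition.index:
        ids = assignment.sample_metaclusters.index[assignment.sample_metaclusters == mc]
        pat = [i for i in ids if cohort.group_labels[i] == PATIENT]
        ctl = [i for i in ids if cohort.group_labels[i] == CONTROL]
        if len(pat) < 2 or len(ctl) < 2:
            for feat in X.columns:
                rows.append({"metacluster": mc, "feature": feat, "delta_z": np.nan,
                             "p_value": np.nan, "q_value": np.nan, "tested": False})
            continue
        ps, dzs = [], []
        for feat in X.columns:
            a, b = Z.loc[pat, feat], Z.loc[ctl, feat]
            dzs.append(float(a.mean() - b.mean()))
            if np.ptp(np.concatenate([a, b])) == 0:
                ps.append(1.0)
            else:
                ps.append(float(mannwhitneyu(a, b, alternative="two-sided",
                                             method="asymptotic")[1]))
        qs = bh_fdr(ps)
        for feat, dz, p, q in zip(X.columns, dzs, ps, qs):
            rows.append({"metacluster": mc, "feature": feat, "delta_z": dz,
                         "p_value": p, "q_value": float(q), "tested": True})
    return pd.DataFrame(rows)


def metacluster_ids_weights(
    assignment: MetaclusterAssignment, ids_values: pd.Series
) -> pd.Series:
    """Pearson correlation between metacluster membership and per-sample IDS.

    Metaclusters containing all samples or none have an undefined weight and
    come back NaN; everything else lies in [-1, 1].
    """
    labels = assignment.sample_metaclusters
    missing = set(labels.index) - set(ids_values.index)
    if missing:
        raise CohortError(f"IDS missing for samples: {sorted(missing)[:5]}")
    ids_aligned = ids_values.loc[labels.index].to_numpy(dtype=float)
    out = {}
    for mc in assignment.composition.index:
        member = (labels == mc).to_numpy(dtype=float)
        if member.std() == 0 or ids_aligned.std() == 0:
            out[mc] = np.nan
        else:
            out[mc] = float(pearsonr(member, ids_aligned)[0])
    return pd.Series(out, name="ids_weight")
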