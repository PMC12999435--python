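"""Clinical phenotype clustering: Jaccard distance, classical MDS, PAM.

Patients are clustered on binary clinical manifestation profiles with
partitioning around medoids on the Jaccard distance, embedded for display by
classical (metric) multidimensional scaling, and mapped to mild / moderate /
severe tiers by mean clinical dysregulation score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .cohort import CohortError

TIERS = ("mild", "moderate", "severe")


def jaccard_distance_matrix(binary_matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Pairwise Jaccard distances between binary rows.

    d(a, b) = 1 - |a AND b| / |a OR b|; two all-zero rows are at distance 0
    by convention (patients with no recorded findings are identical under
    this feature set). Rows with any missing value are excluded and
    reported back as the second return value.
    """
    vals = binary_matrix.to_numpy(dtype=float)
    complete = ~np.isnan(vals).any(axis=1)
    excluded = list(binary_matrix.index[~complete])
    kept = binary_matrix.loc[complete]
    v = kept.to_numpy(dtype=float)
    if not np.isin(v, (0.0, 1.0)).all():
        raise CohortError("clinical matrix must be binary 0/1")
    if len(kept) == 0:
        raise CohortError("no complete clinical rows")
    # scipy's boolean jaccard: disagreements / union; all-zero pair -> 0
    d = squareform(pdist(v.astype(bool), metric="jaccard"))
    return pd.DataFrame(d, index=kept.index, columns=kept.index), excluded


def classical_mds(distance_matrix: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS by double-centering eigendecomposition.

    Negative eigenvalues (non-Euclidean distances such as Jaccard) are
    truncated to zero.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise CohortError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    lam[lam < 1e-12 * max(lam.max(), 1e-300)] = 0.0  # numerical-noise axes collapse
    coords = eigvec[:, order] * np.sqrt(lam)
    index = (
        distance_matrix.index
        if isinstance(distance_matrix, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    return pd.DataFrame(coords, index=index, columns=[f"mds{i + 1}" for i in range(dims)])


@dataclass
class PAMResult:
    medoids: list[int]  # positional indices into the distance matrix
    labels: np.ndarray  # cluster id per sample, 0..k-1 in medoid order
    cost: float


def _assign(D: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]
    labels = sub.argmin(axis=1)
    return labels, float(sub.min(axis=1).sum())


def pam_cluster(distance_matrix, k: int, seed: int = 0) -> PAMResult:
    """Partitioning around medoids on a precomputed distance matrix.

    When the medoid-set space is small enough (which covers any realistic
    clinical cohort) the globally optimal medoid set is found by exhaustive
    enumeration; otherwise greedy BUILD followed by best-improvement SWAP
    runs to convergence. Fully deterministic: all ties resolve to the lowest
    index / lexicographically smallest medoid set (the seed is accepted for
    interface symmetry but the algorithm needs no randomness).
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if not 2 <= k <= n:
        raise CohortError(f"k must lie in [2, {n}]")

    from math import comb
    if comb(n, k) <= 50_000:
        from itertools import combinations

        best_set, best_cost = None, np.inf
        for medoid_set in combinations(range(n), k):
            cost = float(D[:, medoid_set].min(axis=1).sum())
            if cost < best_cost - 1e-12:
                best_cost, best_set = cost, medoid_set
        medoids = list(best_set)
        labels, cost = _assign(D, medoids)
        return PAMResult(medoids=medoids, labels=labels, cost=cost)

    # BUILD: start from the point minimizing total distance, then greedily
    # add the medoid giving the largest cost reduction; lowest index on ties.
    medoids = [int(D.sum(axis=1).argmin())]
    while len(medoids) < k:
        best_j, best_cost = None, np.inf
        current = D[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            cost = float(np.minimum(current, D[:, j]).sum())
            if cost < best_cost - 1e-12:
                best_cost, best_j = cost, j
        medoids.append(best_j)

    labels, cost = _assign(D, medoids)
    improved = True
    while improved:
        improved = False
        best_swap, best_cost = None, cost
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                _, c = _assign(D, trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is not None:
            mi, h = best_swap
            medoids[mi] = h
            labels, cost = _assign(D, medoids)
            improved = True

    order = np.argsort(medoids, kind="stable")
    medoids_sorted = [medoids[i] for i in order]
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[lab] for lab in labels])
    return PAMResult(medoids=medoids_sorted, labels=labels, cost=cost)


def cluster_feature_importance(
    binary_matrix: pd.DataFrame,
    labels: np.ndarray,
    n_perm: int = 100,
    k: int | None = None,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance of each binary feature for the partition.

    For each feature, the column is permuted across samples and the
    clustering (PAM on Jaccard) recomputed; importance is the mean of
    1 - ARI(original, permuted-partition), clipped at 0. Load-bearing
    features scramble the partition when permuted; irrelevant ones leave it
    intact.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise CohortError("need at least 2 clusters")
    if n_perm < 50:
        raise CohortError("n_perm must be >= 50")
    k = k or len(np.unique(labels))
    rng = np.random.default_rng(seed)
    out = {}
    for feat in binary_matrix.columns:
        scores = []
        for _ in range(n_perm):
            perm = binary_matrix.copy()
            perm[feat] = rng.permutation(perm[feat].to_numpy())
            dist, _ = jaccard_distance_matrix(perm)
            new_labels = pam_cluster(dist, k=k, seed=seed).labels
            scores.append(1.0 - adjusted_rand_score(labels, new_labels))
        out[feat] = float(np.clip(np.mean(scores), 0.0, None))
    return pd.Series(out).sort_values(ascending=False)


def map_severity(labels: np.ndarray, cds_per_sample: pd.Series | np.ndarray) -> dict[int, str]:
    """Map exactly 3 clusters to mild / moderate / severe by mean CDS.

    Lowest mean CDS is mild, highest is severe; ties break by cluster size
    (larger = more severe).
    """
    labels = np.asarray(labels)
    cds = np.asarray(cds_per_sample, dtype=float)
    clusters = np.unique(labels)
    if len(clusters) != 3:
        raise CohortError("severity tiering is defined for exactly 3 clusters")
    stats = []
    for c in clusters:
        mask = labels == c
        stats.append((float(np.nanmean(cds[mask])), int(mask.sum()), int(c)))
    ordered = sorted(stats, key=lambda t: (t[0], t[1], -t[2]))
    return {c: tier for (_, _, c), tier in zip(ordered, TIERS)}


@dataclass
class ClinicalClusterResult:
    distance: pd.DataFrame
    coordinates: pd.DataFrame
    medoids: list
    labels: pd.Series
    tiers: pd.Series | None
    importance: pd.Series
    excluded: list


def cluster_clinical(
    binary_matrix: pd.DataFrame,
    cds: pd.Series | None = None,
    k: int = 3,
    n_perm: int = 100,
    seed: int = 0,
) -> ClinicalClusterResult:
    """End-to-end clinical clustering: Jaccard -> MDS -> PAM -> tiers."""
    dist, excluded = jaccard_distance_matrix(binary_matrix)
    coords = classical_mds(dist, dims=2)
    pam = pam_cluster(dist, k=k, seed=seed)
    labels = pd.Series(pam.labels, index=dist.index, name="cluster")
    tiers = None
    if k == 3 and cds is not None:
        tier_map = map_severity(pam.labels, cds.loc[dist.index].to_numpy())
        tiers = labels.map(tier_map).rename("tier")
    importance = cluster_feature_importance(
        binary_matrix.loc[dist.index], pam.labels, n_perm=n_perm, k=k, seed=seed
    )
    return ClinicalClusterResult(
        distance=dist,
        coordinates=coords,
        medoids=[dist.index[m] for m in pam.medoids],
        labels=labels,
        tiers=tiers,
        importance=importance,
        excluded=excluded,
    )
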