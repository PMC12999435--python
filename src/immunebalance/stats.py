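"""Group comparisons, FDR control, correlation matrices and delta networks.

Patients and controls get separate subset-subset correlation matrices; the
delta network collects the pairs whose correlation changes between groups
beyond a threshold — the "rewiring" view of immune dysregulation, in which
associations present in healthy donors weaken, disappear or reverse in
patients while inflammatory populations gain coordinated structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

from .cohort import CONTROL, PATIENT, CohortDataset, CohortError


@dataclass
class SubsetTestResult:
    subset: str
    statistic: float | None
    p_value: float | None
    q_value: float | None
    direction: int | None  # sign of patient median minus control median
    median_patient: float | None
    median_control: float | None
    flagged: str | None = None


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise CohortError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_subsets(cohort: CohortDataset) -> list[SubsetTestResult]:
    """Two-sided Mann-Whitney patient-vs-control test per subset, BH-adjusted.

    The exact null distribution is used when both groups have <= 8 samples
    and no cross-group ties; otherwise the tie-corrected normal
    approximation. Subsets constant across all samples have no defined
    statistic: they are flagged and excluded from the FDR family.
    """
    pat = cohort.group_matrix(PATIENT)
    ctl = cohort.group_matrix(CONTROL)
    if len(pat) < 2 or len(ctl) < 2:
        raise CohortError("need >=2 samples per group")

    results: list[SubsetTestResult] = []
    tested: list[int] = []
    for subset in cohort.subset_names:
        x = pat[subset].to_numpy(dtype=float)
        y = ctl[subset].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x, y])) == 0:
            results.append(
                SubsetTestResult(subset, None, None, None, None, float(np.median(x)),
                                 float(np.median(y)), flagged="constant across samples")
            )
            continue
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
        stat, p = mannwhitneyu(x, y, alternative="two-sided", method=method)
        med_x, med_y = float(np.median(x)), float(np.median(y))
        results.append(
            SubsetTestResult(subset, float(stat), float(p), None,
                             int(np.sign(med_x - med_y)), med_x, med_y)
        )
        tested.append(len(results) - 1)

    if tested:
        qs = bh_fdr([results[i].p_value for i in tested])
        for i, q in zip(tested, qs):
            results[i].q_value = float(q)
    return results


def subset_tests_frame(results: list[SubsetTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subset": r.subset,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
                "median_patient": r.median_patient,
                "median_control": r.median_control,
                "flagged": r.flagged,
            }
            for r in results
        ]
    )


def correlation_matrix(subset_matrix: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Pairwise subset correlations with pairwise-complete missing handling.

    Constant columns have undefined correlations; those entries stay NaN and
    never enter a network.
    """
    if method not in ("spearman", "pearson"):
        raise CohortError(f"method must be spearman or pearson, got {method!r}")
    if len(subset_matrix) < 3:
        raise CohortError("need at least 3 samples for a correlation matrix")
    corr = subset_matrix.corr(method=method, min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    # a constant column correlates with nothing, including itself
    const = subset_matrix.std(ddof=0) == 0
    for c in const[const].index:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


@dataclass
class DeltaNetwork:
    """Signed, thresholded patient-minus-control correlation-change network."""

    nodes: list[str]
    edges: pd.DataFrame  # node_a, node_b, r_patient, r_control, delta_r, sign, stronger_in
    threshold: float

    @property
    def degrees(self) -> pd.Series:
        deg = pd.Series(0, index=self.nodes, dtype=int)
        for _, row in self.edges.iterrows():
            deg[row["node_a"]] += 1
            deg[row["node_b"]] += 1
        return deg

    @property
    def hubs(self) -> pd.Series:
        return self.degrees.sort_values(ascending=False, kind="stable")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(
                row["node_a"], row["node_b"],
                r_patient=row["r_patient"], r_control=row["r_control"],
                delta_r=row["delta_r"], stronger_in=row["stronger_in"],
            )
        return g


def delta_network(
    mat_patient: pd.DataFrame,
    mat_control: pd.DataFrame,
    threshold: float = 0.4,
) -> DeltaNetwork:
    """Edges where |r_patient - r_control| >= threshold.

    ``sign`` is the sign of the dominant association (the group correlation
    with larger magnitude) and ``stronger_in`` the group carrying it. When
    the two magnitudes are within 0.1 of each other — e.g. a full sign
    reversal — the edge is reported from the control reference: the healthy
    association (its sign, stronger_in=control) that was lost or reversed in
    patients. Undefined correlations (NaN in either group) never form edges.
    """
    if list(mat_patient.columns) != list(mat_control.columns) or list(
        mat_patient.index
    ) != list(mat_control.index):
        raise CohortError("correlation matrices must share node set and ordering")
    nodes = list(mat_patient.columns)
    rows = []
    for i, a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            b = nodes[j]
            rp, rc = mat_patient.iloc[i, j], mat_control.iloc[i, j]
            if np.isnan(rp) or np.isnan(rc):
                continue
            d = rp - rc
            if abs(d) >= threshold:
                if abs(rp) - abs(rc) > 0.1:
                    sign_assoc, stronger = int(np.sign(rp)), PATIENT
                else:
                    sign_assoc, stronger = int(np.sign(rc)), CONTROL
                rows.append(
                    {
                        "node_a": a,
                        "node_b": b,
                        "r_patient": float(rp),
                        "r_control": float(rc),
                        "delta_r": float(d),
                        "sign": sign_assoc,
                        "stronger_in": stronger,
                    }
                )
    edges = pd.DataFrame(
        rows,
        columns=["node_a", "node_b", "r_patient", "r_control", "delta_r", "sign", "stronger_in"],
    )
    return DeltaNetwork(nodes=nodes, edges=edges, threshold=threshold)


def embed_2d(
    feature_matrix: pd.DataFrame,
    perplexity: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic 2D t-SNE embedding of standardized sample features.

    This is a visualization contract (neighborhood preservation), not a
    bespoke embedding: the backend is scikit-learn's t-SNE with PCA
    initialization, fixed by the seed.
    """
    X = feature_matrix.to_numpy(dtype=float)
    if len(X) < 3 * perplexity:
        raise CohortError(
            f"need at least {int(np.ceil(3 * perplexity))} samples for perplexity {perplexity}"
        )
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    if np.allclose(Xs, Xs[0]):  # fully degenerate input: coincident embedding
        coords = np.zeros((len(Xs), 2))
    else:
        # exact method: cohorts are small and the result is reproducible
        coords = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            init="pca",
            method="exact",
        ).fit_transform(Xs)
    return pd.DataFrame(coords, index=feature_matrix.index, columns=["tsne1", "tsne2"])
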