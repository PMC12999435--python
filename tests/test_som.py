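"""SOM metaclustering: training, node merging, composition, marker tables."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from immunebalance import (
    CohortDataset,
    CohortError,
    SOMModel,
    assign_and_compose,
    composition_differences,
    metacluster,
    metacluster_ids_weights,
    metacluster_marker_differences,
    train_som,
)


def make_som_from_codebook(codebook, grid, counts=None):
    n, p = codebook.shape
    return SOMModel(
        grid=grid,
        codebook=np.asarray(codebook, dtype=float),
        feature_names=[f"f{i}" for i in range(p)],
        standardize_mean=np.zeros(p),
        standardize_sd=np.ones(p),
        bmu_counts=np.asarray(counts if counts is not None else np.ones(n, dtype=int)),
        epochs=0,
        learning_rate=0.0,
        seed=0,
    )


def two_blob_cohort(n_a=30, n_b=30, p=4, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_a, p)), rng.normal(sep, 1, (n_b, p))])
    X = np.clip(np.abs(X) + 1.0, 0.5, 99.0)  # keep within percent bounds
    idx = pd.Index([f"p{i}" for i in range(n_a)] + [f"c{i}" for i in range(n_b)],
                   name="sample_id")
    return CohortDataset(
        subset_matrix=pd.DataFrame(X, index=idx, columns=[f"f{i}" for i in range(p)]),
        group_labels=pd.Series(["patient"] * n_a + ["control"] * n_b, index=idx),
    )


class TestTrainSOM:
    def test_zero_learning_rate_keeps_init(self, three_blob_features):
        X, _ = three_blob_features
        som = train_som(X, grid=(3, 3), epochs=1, learning_rate=0.0, seed=5)
        expected_init = np.random.default_rng(5).standard_normal((9, X.shape[1]))
        np.testing.assert_array_equal(som.codebook, expected_init)

    def test_blobs_use_multiple_units(self, three_blob_features):
        X, _ = three_blob_features
        som = train_som(X, grid=(4, 4), epochs=30, seed=0)
        assert len(np.unique(som.best_matching_units(X))) >= 3

    def test_determinism(self, three_blob_features):
        X, _ = three_blob_features
        a = train_som(X, grid=(4, 4), epochs=10, seed=1)
        b = train_som(X, grid=(4, 4), epochs=10, seed=1)
        np.testing.assert_array_equal(a.codebook, b.codebook)

    def test_quantization_error_decreases_with_training(self, three_blob_features):
        X, _ = three_blob_features
        def qe(som):
            Xs = som.standardize(X)
            d2 = ((Xs[:, None, :] - som.codebook[None]) ** 2).sum(axis=2)
            return float(np.sqrt(d2.min(axis=1)).mean())

        untrained = train_som(X, grid=(4, 4), epochs=1, learning_rate=0.0, seed=2)
        trained = train_som(X, grid=(4, 4), epochs=50, seed=2)
        assert qe(trained) < qe(untrained)

    def test_bad_inputs(self, three_blob_features):
        X, _ = three_blob_features
        with pytest.raises(CohortError):
            train_som(X, grid=(1, 4))
        bad = X.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(CohortError):
            train_som(bad)


class TestMetacluster:
    def test_k_equals_node_count(self):
        som = make_som_from_codebook(np.random.default_rng(0).normal(size=(6, 3)), (2, 3))
        assert len(np.unique(metacluster(som, k=6))) == 6

    def test_k_one(self):
        som = make_som_from_codebook(np.random.default_rng(0).normal(size=(6, 3)), (2, 3))
        assert (metacluster(som, k=1) == 1).all()

    def test_two_tight_groups_recovered(self):
        rng = np.random.default_rng(1)
        codebook = np.vstack([rng.normal(0, 0.1, (4, 3)), rng.normal(10, 0.1, (4, 3))])
        som = make_som_from_codebook(codebook, (2, 4))
        labels = metacluster(som, k=2)
        assert adjusted_rand_score([0] * 4 + [1] * 4, labels) == 1.0

    def test_occupancy_renumbering(self):
        rng = np.random.default_rng(2)
        codebook = np.vstack([rng.normal(0, 0.1, (4, 3)), rng.normal(10, 0.1, (4, 3))])
        # second node group holds nearly all training samples -> must be MC1
        som = make_som_from_codebook(codebook, (2, 4), counts=[1, 1, 1, 1, 50, 50, 50, 50])
        labels = metacluster(som, k=2)
        assert (labels[4:] == 1).all() and (labels[:4] == 2).all()

    def test_k_out_of_range(self):
        som = make_som_from_codebook(np.zeros((4, 2)), (2, 2))
        with pytest.raises(CohortError):
            metacluster(som, k=5)


class TestAssignCompose:
    def test_cohort_equal_to_codebook(self):
        codebook = np.arange(12.0).reshape(4, 3) + 1.0
        som = make_som_from_codebook(codebook, (2, 2))
        idx = pd.Index(list("abcd"), name="sample_id")
        cohort = CohortDataset(
            subset_matrix=pd.DataFrame(codebook, index=idx, columns=som.feature_names),
            group_labels=pd.Series(["patient", "patient", "control", "control"], index=idx),
        )
        assignment = assign_and_compose(cohort, som, np.array([1, 2, 3, 4]))
        np.testing.assert_array_equal(assignment.sample_nodes.to_numpy(), [0, 1, 2, 3])

    def test_group_confined_to_blob(self):
        cohort = two_blob_cohort()
        som = train_som(cohort.subset_matrix, grid=(2, 2), epochs=30, seed=0)
        node_map = metacluster(som, k=2)
        assignment = assign_and_compose(cohort, som, node_map)
        comp = assignment.composition
        # each group occupies exactly one metacluster
        assert set(comp["patient"]) == {0.0, 1.0}
        assert set(comp["control"]) == {0.0, 1.0}

    def test_compositions_sum_to_one(self, default_cohort):
        som = train_som(default_cohort.subset_matrix, grid=(4, 4), epochs=20, seed=0)
        assignment = assign_and_compose(default_cohort, som, metacluster(som, k=8))
        sums = assignment.composition.sum()
        assert sums["patient"] == pytest.approx(1.0, abs=1e-9)
        assert sums["control"] == pytest.approx(1.0, abs=1e-9)

    def test_feature_mismatch_rejected(self, default_cohort):
        som = train_som(default_cohort.subset_matrix, grid=(2, 2), epochs=5, seed=0)
        cohort2 = two_blob_cohort()
        with pytest.raises(CohortError):
            assign_and_compose(cohort2, som, metacluster(som, k=2))


class TestCompositionDifferences:
    def _assignment(self, cohort, seed=0):
        som = train_som(cohort.subset_matrix, grid=(2, 2), epochs=30, seed=seed)
        return assign_and_compose(cohort, som, metacluster(som, k=2))

    def test_identical_compositions_cover_zero(self):
        # groups drawn from the same two blobs in equal proportion
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(10, 1, (100, 4))])
        X = np.clip(np.abs(X) + 1.0, 0.5, 99.0)
        order = rng.permutation(200)
        idx = pd.Index([f"s{i}" for i in range(200)], name="sample_id")
        groups = pd.Series(np.where(np.arange(200) % 2 == 0, "patient", "control"), index=idx)
        cohort = CohortDataset(
            subset_matrix=pd.DataFrame(X[order], index=idx,
                                       columns=[f"f{i}" for i in range(4)]),
            group_labels=groups,
        )
        diffs = composition_differences(self._assignment(cohort),
                                        cohort.group_labels, n_boot=400, seed=1)
        assert (diffs["ci_low"] <= 0).all() and (diffs["ci_high"] >= 0).all()

    def test_planted_occupancy_difference_detected(self):
        rng = np.random.default_rng(4)
        # patients 60% blob A, controls 10% blob A
        n = 200
        pat_blob = rng.random(n) < 0.6
        ctl_blob = rng.random(n) < 0.1
        def draw(mask):
            pts = np.where(mask[:, None], rng.normal(0, 1, (n, 4)),
                           rng.normal(10, 1, (n, 4)))
            return np.clip(np.abs(pts) + 1.0, 0.5, 99.0)
        X = np.vstack([draw(pat_blob), draw(ctl_blob)])
        idx = pd.Index([f"s{i}" for i in range(2 * n)], name="sample_id")
        cohort = CohortDataset(
            subset_matrix=pd.DataFrame(X, index=idx, columns=[f"f{i}" for i in range(4)]),
            group_labels=pd.Series(["patient"] * n + ["control"] * n, index=idx),
        )
        diffs = composition_differences(self._assignment(cohort),
                                        cohort.group_labels, n_boot=400, seed=2)
        big = diffs["difference_pp"].abs().idxmax()
        assert not (diffs.loc[big, "ci_low"] <= 0 <= diffs.loc[big, "ci_high"])

    def test_zero_sum_and_ci_contains_point(self, default_cohort):
        som = train_som(default_cohort.subset_matrix, grid=(4, 4), epochs=20, seed=0)
        assignment = assign_and_compose(default_cohort, som, metacluster(som, k=8))
        diffs = composition_differences(assignment, default_cohort.group_labels,
                                        n_boot=300, seed=3)
        assert diffs["difference_pp"].sum() == pytest.approx(0.0, abs=1e-9)
        assert (diffs["ci_low"] <= diffs["difference_pp"]).all()
        assert (diffs["ci_high"] >= diffs["difference_pp"]).all()


class TestMarkerDifferences:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(5)
        X = np.clip(np.abs(rng.normal(5, 1, (40, 3))), 0.5, 99.0)
        X = np.vstack([X, X])  # patients identical to controls
        idx = pd.Index([f"s{i}" for i in range(80)], name="sample_id")
        cohort = CohortDataset(
            subset_matrix=pd.DataFrame(X, index=idx, columns=["a", "b", "c"]),
            group_labels=pd.Series(["patient"] * 40 + ["control"] * 40, index=idx),
        )
        som = train_som(cohort.subset_matrix, grid=(2, 2), epochs=10, seed=0)
        assignment = assign_and_compose(cohort, som, metacluster(som, k=1))
        table = metacluster_marker_differences(cohort, assignment)
        tested = table[table["tested"]]
        np.testing.assert_allclose(tested["delta_z"], 0.0, atol=1e-12)
        np.testing.assert_allclose(tested["p_value"], 1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        pat = np.abs(rng.normal(5, 1, (100, 3)))
        ctl = np.abs(rng.normal(5, 1, (100, 3)))
        pat[:, 0] += 3.0  # shift feature "a" in patients only
        X = np.clip(np.vstack([pat, ctl]), 0.5, 99.0)
        idx = pd.Index([f"s{i}" for i in range(200)], name="sample_id")
        cohort = CohortDataset(
            subset_matrix=pd.DataFrame(X, index=idx, columns=["a", "b", "c"]),
            group_labels=pd.Series(["patient"] * 100 + ["control"] * 100, index=idx),
        )
        som = train_som(cohort.subset_matrix, grid=(2, 2), epochs=10, seed=0)
        assignment = assign_and_compose(cohort, som, metacluster(som, k=1))
        table = metacluster_marker_differences(cohort, assignment)
        tested = table[table["tested"]].set_index("feature")
        assert tested["delta_z"].abs().idxmax() == "a"
        assert tested.loc["a", "q_value"] < 0.1

    def test_undersized_metacluster_flagged(self, default_cohort):
        som = train_som(default_cohort.subset_matrix, grid=(4, 4), epochs=20, seed=0)
        k = 8
        assignment = assign_and_compose(default_cohort, som, metacluster(som, k=k))
        table = metacluster_marker_differences(default_cohort, assignment)
        assert set(table["metacluster"]) == {f"MC{i}" for i in range(1, k + 1)}
        untested = table[~table["tested"]]
        assert untested["delta_z"].isna().all()


class TestIDSWeights:
    def _assignment(self, cohort):
        som = train_som(cohort.subset_matrix, grid=(2, 2), epochs=30, seed=0)
        return assign_and_compose(cohort, som, metacluster(som, k=2))

    def test_constant_ids_undefined(self):
        cohort = two_blob_cohort()
        a = self._assignment(cohort)
        w = metacluster_ids_weights(a, pd.Series(1.0, index=cohort.sample_ids))
        assert w.isna().all()

    def test_top_half_membership_positive_weight(self):
        cohort = two_blob_cohort()
        a = self._assignment(cohort)
        ids_vals = pd.Series(0.0, index=cohort.sample_ids)
        mc1 = a.sample_metaclusters == "MC1"
        ids_vals[mc1] = 2.0  # MC1 members carry the high scores
        w = metacluster_ids_weights(a, ids_vals)
        assert w["MC1"] > 0 and w["MC2"] < 0

    def test_bounds(self, default_cohort):
        from immunebalance import compute_score_table

        a = self._assignment(default_cohort)
        ids_vals = compute_score_table(default_cohort)["ids"]
        w = metacluster_ids_weights(a, ids_vals).dropna()
        assert ((w >= -1) & (w <= 1)).all()


def test_three_blob_pipeline_ari(three_blob_features):
    """SOM + hierarchical merge recovers three well-separated blobs."""
    X, truth = three_blob_features
    som = train_som(X, grid=(4, 4), epochs=30, seed=0)
    labels = metacluster(som, k=3)[som.best_matching_units(X)]
    assert adjusted_rand_score(truth, labels) >= 0.9
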