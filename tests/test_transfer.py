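"""Co-clustering label transfer: distances, trees, cuts, probabilities, calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from pamcross.transfer import (
    UNASSIGNED,
    Dendrogram,
    DistanceMatrix,
    SubtypeCalls,
    SubtypeProbabilities,
    call_subtypes,
    classification_agreement,
    complete_linkage_tree,
    cut_tree_at_k,
    macro_accuracy,
    nearest_centroid_classify,
    pairwise_distances,
    subcluster_label_proportions,
    transfer_subtype_probabilities,
)

from conftest import BASE_PROBS, make_merged
from oracles import brute_force_complete_linkage_partitions


def dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(values))]
    return DistanceMatrix(sample_ids=ids, values=values, metric="test")


def calls_from(mapping):
    s = pd.Series(mapping, name="subtype")
    return SubtypeCalls(labels=s, tie_broken=pd.Series(False, index=s.index))


class TestDistances:
    def test_identical_profiles_distance_zero(self):
        x = np.random.default_rng(0).normal(size=5)
        merged = make_merged(np.column_stack([x, x]) / np.abs(x).max(), ["b", "b"], normalized=True)
        d = pairwise_distances(merged)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_antiproportional_profiles_distance_two(self):
        x = np.array([1.0, -1.0, 0.5, -0.5])
        merged = make_merged(np.column_stack([x, -x]), ["b", "b"], normalized=True)
        d = pairwise_distances(merged)
        assert d.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_correlation_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(42, 6)) * 0.3
        merged = make_merged(X, ["b"] * 6, normalized=True)
        d = pairwise_distances(merged)
        for i in range(6):
            for j in range(6):
                r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                assert d.values[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_sample_is_hard_error(self):
        X = np.ones((4, 2))
        X[:, 0] = [1, 2, 3, 4]
        merged = make_merged(X / 4, ["b", "b"], normalized=True)
        with pytest.raises(ValueError, match="s002"):
            pairwise_distances(merged)


class TestLinkage:
    def test_three_sample_tree_by_hand(self):
        # d(0,1)=1, d(0,2)=5, d(1,2)=4 -> merge {0,1} at 1, then all at 5
        D = np.array([[0, 1, 5], [1, 0, 4], [5, 4, 0]], dtype=float)
        tree = complete_linkage_tree(dm(D))
        assert tree.linkage[0, 2] == pytest.approx(1.0)
        assert tree.linkage[1, 2] == pytest.approx(5.0)
        cut2 = cut_tree_at_k(tree, 2)
        assert cut2["s0"] == cut2["s1"] != cut2["s2"]

    def test_two_samples(self):
        D = np.array([[0, 3.5], [3.5, 0]])
        tree = complete_linkage_tree(dm(D))
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(3.5)

    def test_merge_heights_nondecreasing(self):
        from scipy.spatial.distance import squareform, pdist

        rng = np.random.default_rng(1)
        D = squareform(pdist(rng.normal(size=(12, 5))))
        tree = complete_linkage_tree(dm(D, [f"s{i}" for i in range(12)]))
        assert np.all(np.diff(tree.linkage[:, 2]) >= -1e-12)

    def test_cut_extremes(self):
        D = np.array([[0, 1, 5], [1, 0, 4], [5, 4, 0]], dtype=float)
        tree = complete_linkage_tree(dm(D))
        assert cut_tree_at_k(tree, 1).nunique() == 1
        assert cut_tree_at_k(tree, 3).nunique() == 3
        with pytest.raises(ValueError):
            cut_tree_at_k(tree, 4)
        with pytest.raises(ValueError):
            cut_tree_at_k(tree, 0)

    def test_non_finite_distances_rejected(self):
        D = np.array([[0, np.inf], [np.inf, 0]])
        with pytest.raises(ValueError, match="finite"):
            complete_linkage_tree(dm(D))

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_matches_brute_force_agglomerator(self, n):
        for seed in range(20):
            rng = np.random.default_rng(1000 * n + seed)
            pts = rng.normal(size=(n, 4))
            from scipy.spatial.distance import squareform, pdist

            D = squareform(pdist(pts))
            ids = [f"s{i}" for i in range(n)]
            tree = complete_linkage_tree(dm(D, ids))
            expected = brute_force_complete_linkage_partitions(D)
            for k in range(1, n + 1):
                cut = cut_tree_at_k(tree, k)
                got = {
                    frozenset(np.flatnonzero(cut.to_numpy() == c))
                    for c in np.unique(cut.to_numpy())
                }
                assert got == expected[k], f"n={n} seed={seed} k={k}"


class TestSubclusterProportions:
    def test_qualifying_cluster_proportions(self):
        assignment = pd.Series([0] * 5 + [1], index=[f"r{i}" for i in range(5)] + ["q0"])
        ref = pd.Series(["A", "A", "A", "B", "B"], index=[f"r{i}" for i in range(5)])
        props = subcluster_label_proportions(assignment, ref, min_ref=4)
        assert props[0]["A"] == pytest.approx(0.6)
        assert props[0]["B"] == pytest.approx(0.4)
        assert props[1] is None  # zero reference samples

    def test_exactly_min_ref_disqualified(self):
        # "more than 4" is strict: a cluster with exactly 4 references fails
        assignment = pd.Series([0] * 4, index=[f"r{i}" for i in range(4)])
        ref = pd.Series(["A"] * 4, index=[f"r{i}" for i in range(4)])
        props = subcluster_label_proportions(assignment, ref, min_ref=4)
        assert props[0] is None


class TestTransfer:
    @staticmethod
    def _toy_tree():
        # 6 refs labeled A tightly clustered with q0; 5 refs labeled B with q1
        ids = [f"a{i}" for i in range(6)] + ["q0"] + [f"b{i}" for i in range(5)] + ["q1"]
        pos = np.array([0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06] + [5.0, 5.01, 5.02, 5.03, 5.04, 5.06])
        D = np.abs(pos[:, None] - pos[None, :])
        tree = complete_linkage_tree(dm(D, ids))
        ref = pd.Series(
            ["A"] * 6 + ["B"] * 5, index=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(5)]
        )
        return tree, ref

    def test_unanimous_coclustering(self):
        tree, ref = self._toy_tree()
        probs = transfer_subtype_probabilities(tree, ref, ["q0", "q1"], k_min=2, k_max=2)
        assert probs.probs.loc["q0", "A"] == pytest.approx(1.0)
        assert probs.probs.loc["q1", "B"] == pytest.approx(1.0)

    def test_never_qualifying_is_unassigned(self):
        tree, ref = self._toy_tree()
        # min_ref=10 disqualifies every cluster at every k
        probs = transfer_subtype_probabilities(tree, ref, ["q0"], k_min=2, k_max=5, min_ref=10)
        assert probs.n_contributing_cuts["q0"] == 0
        assert probs.probs.loc["q0"].isna().all()
        calls = call_subtypes(probs)
        assert calls.labels["q0"] == UNASSIGNED

    def test_mean_over_qualifying_cuts_matches_rewalk(self, transfer_run):
        """Averaged vectors equal an independent re-walk of every tree cut."""
        res, _, merged, ref_labels = transfer_run
        model = res.model
        tree = res.tree
        labels = model.labels
        n = tree.n_leaves
        sums = {q: np.zeros(len(labels)) for q in model.query_ids}
        counts = {q: 0 for q in model.query_ids}
        for k in range(model.k_min, min(model.k_max, n) + 1):
            flat = hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel()
            assign = pd.Series(flat, index=tree.leaf_ids)
            for q in model.query_ids:
                members = assign.index[assign == assign[q]]
                refs = [s for s in members if s in ref_labels.index]
                if len(refs) > model.min_ref:
                    vec = np.array(
                        [sum(ref_labels[s] == lab for s in refs) for lab in labels], float
                    ) / len(refs)
                    sums[q] += vec
                    counts[q] += 1
        for q in model.query_ids:
            if counts[q] == 0:
                assert res.probabilities.n_contributing_cuts[q] == 0
            else:
                np.testing.assert_allclose(
                    res.probabilities.probs.loc[q].to_numpy(), sums[q] / counts[q], atol=1e-12
                )
                assert res.probabilities.n_contributing_cuts[q] == counts[q]

    def test_hand_average_of_two_cuts(self):
        probs = SubtypeProbabilities(
            probs=pd.DataFrame({"A": [0.75], "B": [0.25]}, index=["q"]),
            n_contributing_cuts=pd.Series([2], index=["q"]),
        )
        # (A:1) and (A:0.5, B:0.5) average to (A:0.75, B:0.25)
        assert probs.probs.loc["q", "A"] == pytest.approx((1.0 + 0.5) / 2)

    def test_no_reference_labels_is_error(self):
        tree, _ = self._toy_tree()
        with pytest.raises(ValueError):
            transfer_subtype_probabilities(tree, pd.Series(dtype=object), ["q0"])

    def test_min_ref_monotonicity(self, transfer_run):
        res, _, merged, ref_labels = transfer_run
        model = res.model
        n_assigned = []
        for min_ref in (2, 4, 8, 20):
            probs = transfer_subtype_probabilities(
                res.tree, ref_labels, model.query_ids, min_ref=min_ref
            )
            n_assigned.append(int((probs.n_contributing_cuts > 0).sum()))
        assert n_assigned == sorted(n_assigned, reverse=True)

    def test_order_invariance(self, transfer_run):
        from pamcross.expression import MergedMatrix
        from pamcross.transfer import SubtypeTransfer

        res, truth, merged, ref_labels = transfer_run
        rng = np.random.default_rng(99)
        perm = rng.permutation(len(merged.sample_ids))
        cols = [merged.sample_ids[i] for i in perm]
        shuffled = MergedMatrix(
            values=merged.values[cols],
            block_of_sample=merged.block_of_sample.loc[cols],
            normalized=True,
        )
        res2 = SubtypeTransfer(shuffled, ref_labels).fit()
        common = res.probabilities.probs.index
        pd.testing.assert_frame_equal(
            res.probabilities.probs.loc[common],
            res2.probabilities.probs.loc[common],
            atol=1e-9,
        )
        assert (res.calls.labels.loc[common] == res2.calls.labels.loc[common]).all()


class TestCalls:
    def test_argmax_and_tie_rules(self):
        probs = SubtypeProbabilities(
            probs=pd.DataFrame(
                {"A": [0.75, 0.5, np.nan], "B": [0.25, 0.5, np.nan]},
                index=["q1", "q2", "q3"],
            ),
            n_contributing_cuts=pd.Series([3, 2, 0], index=["q1", "q2", "q3"]),
        )
        lex = call_subtypes(probs, "lexicographic")
        assert lex.labels["q1"] == "A" and not lex.tie_broken["q1"]
        assert lex.labels["q2"] == "A" and lex.tie_broken["q2"]
        assert lex.labels["q3"] == UNASSIGNED
        strict = call_subtypes(probs, "unassign")
        assert strict.labels["q2"] == UNASSIGNED


class TestNearestCentroid:
    def test_query_equal_to_centroid(self, centroids):
        ref_vals = pd.concat(
            [centroids.centroids, centroids.centroids], axis=1
        )
        ref_vals.columns = [f"r{i}" for i in range(10)]
        ref_labels = pd.Series(list(centroids.labels) * 2, index=ref_vals.columns)
        query = centroids.centroids.copy()
        query.columns = [f"q_{lab}" for lab in centroids.labels]
        calls = nearest_centroid_classify(ref_vals, ref_labels, query)
        for lab in centroids.labels:
            assert calls.labels[f"q_{lab}"] == lab

    def test_noiseless_cohort_perfect(self, centroids):
        from pamcross.simulate import generate_reference_cohort

        ref = generate_reference_cohort(centroids, 6, noise_sd=0.5, seed=81)
        query = generate_reference_cohort(centroids, 6, noise_sd=0.0, seed=82, platform_id="q")
        calls = nearest_centroid_classify(
            ref.expression.values, ref.true_labels, query.expression.values
        )
        assert (calls.labels == query.true_labels).all()

    def test_noisy_cohort_high_accuracy(self, centroids):
        from pamcross.simulate import generate_reference_cohort

        ref = generate_reference_cohort(centroids, 12, noise_sd=1.0, seed=83)
        query = generate_reference_cohort(centroids, 12, noise_sd=1.0, seed=84, platform_id="q")
        calls = nearest_centroid_classify(
            ref.expression.values, ref.true_labels, query.expression.values
        )
        assert macro_accuracy(calls, query.true_labels) >= 0.9


class TestAgreement:
    def test_identical_and_disjoint(self):
        a = calls_from({"s1": "A", "s2": "B"})
        conc, _ = classification_agreement(a, a)
        assert conc == 1.0
        b = calls_from({"s1": "B", "s2": "A"})
        conc, _ = classification_agreement(a, b)
        assert conc == 0.0

    def test_unassigned_excluded_from_denominator(self):
        a = calls_from({"s1": "A", "s2": "A", "s3": "B", "s4": UNASSIGNED})
        b = calls_from({"s1": "A", "s2": "B", "s3": "B", "s4": "A"})
        conc, conf = classification_agreement(a, b)
        assert conc == pytest.approx(2 / 3)
        assert conf.loc[UNASSIGNED, "A"] == 1

    def test_disjoint_sample_sets_error(self):
        a = calls_from({"s1": "A"})
        b = calls_from({"s2": "A"})
        with pytest.raises(ValueError):
            classification_agreement(a, b)


def test_probability_vectors_valid(transfer_run):
    res, _, _, _ = transfer_run
    assigned = res.probabilities.assigned
    arr = res.probabilities.probs[assigned.to_numpy()].to_numpy()
    assert np.all(arr >= 0)
    np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-9)


def test_parameter_recovery(transfer_run):
    """The standard synthetic run is classified accurately and consistently."""
    res, truth, merged, ref_labels = transfer_run
    assert res.accuracy(truth) >= 0.9
    centroid_calls = nearest_centroid_classify(
        merged.values[list(ref_labels.index)],
        ref_labels,
        merged.values[res.model.query_ids],
    )
    conc, _ = res.concordance_with(centroid_calls)
    assert conc >= 0.85
    assert "assigned" in res.summary()
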