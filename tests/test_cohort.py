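"""Subject clustering and the three model-building regimes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import painpi as pp
from painpi.cohort import assign_subject, kmeans_subjects, pairwise_distance_stats
from painpi.losses import LossSParams
from painpi.train import GDParams


def planted_vectors(rng, k=4, per=6, d=10, sep=8.0):
    centers = rng.normal(scale=sep, size=(k, d))
    rows, labels = [], []
    for c in range(k):
        rows.append(centers[c] + rng.normal(size=(per, d)))
        labels += [c] * per
    X = np.vstack(rows)
    idx = [f"S{i:03d}" for i in range(len(X))]
    return pd.DataFrame(X, index=pd.Index(idx, name="subject_id")), labels


class TestKMeans:
    def test_planted_partition_recovered(self, rng):
        vecs, truth = planted_vectors(rng)
        cm = kmeans_subjects(vecs, k=4, seed=0)
        found = [cm.assignments[s] for s in vecs.index]
        assert adjusted_rand_score(truth, found) == 1.0

    def test_matches_library_kmeans_inertia(self, rng):
        # independent cross-check of the Lloyd loop on the same data
        vecs, _ = planted_vectors(rng, sep=3.0)
        cm = kmeans_subjects(vecs, k=4, seed=0)
        sk = KMeans(n_clusters=4, n_init=10, random_state=0).fit(
            vecs.to_numpy())
        assert cm.inertia == pytest.approx(sk.inertia_, rel=0.01)

    def test_k1_centroid_is_global_mean(self, rng):
        vecs, _ = planted_vectors(rng)
        cm = kmeans_subjects(vecs, k=1, seed=0)
        np.testing.assert_allclose(cm.centroids[0],
                                   vecs.to_numpy().mean(axis=0))

    def test_inertia_trace_non_increasing(self, rng):
        vecs, _ = planted_vectors(rng, sep=1.0)
        cm = kmeans_subjects(vecs, k=3, seed=1, n_restarts=1)
        assert (np.diff(cm.inertia_trace) <= 1e-9).all()

    def test_local_optimality_brute_force(self, rng):
        # at convergence no single-point reassignment lowers inertia
        vecs, _ = planted_vectors(rng, k=3, per=4, d=2, sep=2.0)
        cm = kmeans_subjects(vecs, k=3, seed=2)
        X = vecs.to_numpy()
        labels = np.array([cm.assignments[s] for s in vecs.index])

        def inertia_of(lab):
            total = 0.0
            for c in range(3):
                pts = X[lab == c]
                if len(pts):
                    total += ((pts - pts.mean(axis=0)) ** 2).sum()
            return total

        base = inertia_of(labels)
        for i, c in itertools.product(range(len(X)), range(3)):
            if labels[i] == c:
                continue
            alt = labels.copy()
            alt[i] = c
            assert inertia_of(alt) >= base - 1e-9

    def test_invalid_k(self, rng):
        vecs, _ = planted_vectors(rng)
        with pytest.raises(ValueError):
            kmeans_subjects(vecs, k=0, seed=0)
        with pytest.raises(ValueError):
            kmeans_subjects(vecs, k=len(vecs) + 1, seed=0)


class TestAssignment:
    def test_centroid_assigns_to_itself(self, rng):
        vecs, _ = planted_vectors(rng)
        cm = kmeans_subjects(vecs, k=4, seed=0)
        for c in range(4):
            assert assign_subject(cm.centroids[c], cm) == c

    def test_training_subjects_reassigned_consistently(self, rng):
        vecs, _ = planted_vectors(rng)
        cm = kmeans_subjects(vecs, k=4, seed=0)
        for sid, row in vecs.iterrows():
            assert assign_subject(row.to_numpy(), cm) == cm.assignments[sid]

    def test_midpoint_tie_takes_lower_index(self):
        cm = pp.ClusterModel(k=2, centroids=np.array([[0.0], [2.0]]),
                             assignments={}, inertia=0.0)
        assert assign_subject(np.array([1.0]), cm) == 0

    def test_dimension_mismatch(self, rng):
        vecs, _ = planted_vectors(rng)
        cm = kmeans_subjects(vecs, k=2, seed=0)
        with pytest.raises(ValueError):
            assign_subject(np.zeros(3), cm)


class TestPairwiseDistances:
    def test_pair_count_and_zero_distance(self):
        X = pd.DataFrame(np.zeros((4, 3)),
                         index=pd.Index([f"S{i}" for i in range(4)]))
        stats = pairwise_distance_stats(X, {f"S{i}": 0 for i in range(4)})
        row = stats.iloc[0]
        assert row["n_pairs"] == 6  # 4 choose 2
        assert row["mean"] == 0.0

    def test_translation_invariance(self, rng):
        vecs, truth = planted_vectors(rng, k=2, per=5)
        assign = {s: t for s, t in zip(vecs.index, truth)}
        a = pairwise_distance_stats(vecs, assign)
        b = pairwise_distance_stats(vecs + 11.5, assign)
        pd.testing.assert_frame_equal(a, b)

    def test_singleton_cluster_warns(self, rng):
        vecs, _ = planted_vectors(rng, k=2, per=2)
        assign = {s: (0 if i else 1) for i, s in enumerate(vecs.index)}
        with pytest.warns(UserWarning, match="fewer than 2"):
            stats = pairwise_distance_stats(vecs, assign)
        assert np.isnan(stats.loc[stats.n_subjects == 1, "mean"]).all()


FAST_GD = GDParams(epochs=15, pretrain_epochs=10, seed=0)
FAST_LOSS = LossSParams(alpha=0.15)


class TestRegimes:
    def test_model_counts_match_regime(self, small_cohort):
        gen = pp.build_cohort_models(small_cohort, "generalized",
                                     FAST_LOSS, FAST_GD)
        assert len(gen.models) == 1
        per = pp.build_cohort_models(small_cohort, "personalized",
                                     FAST_LOSS, FAST_GD,
                                     min_rows_personalized=5)
        assert len(per.models) == 12
        hyb = pp.build_cohort_models(small_cohort, "hybrid",
                                     FAST_LOSS, FAST_GD, k=4)
        assert len(hyb.models) == 4
        assert hyb.cluster_model.k == 4

    def test_hybrid_k1_equals_generalized(self, small_cohort):
        gen = pp.build_cohort_models(small_cohort, "generalized",
                                     FAST_LOSS, FAST_GD, seed=3)
        hyb = pp.build_cohort_models(small_cohort, "hybrid",
                                     FAST_LOSS, FAST_GD, k=1, seed=3)
        bg = gen.predict(small_cohort)
        bh = hyb.predict(small_cohort)
        np.testing.assert_allclose(bh.lower, bg.lower)
        np.testing.assert_allclose(bh.upper, bg.upper)

    def test_personalized_skips_small_subjects(self, small_cohort):
        trimmed = pd.concat([
            small_cohort[small_cohort.subject_id != "S001"],
            small_cohort[small_cohort.subject_id == "S001"].head(3),
        ])
        with pytest.warns(UserWarning, match="S001"):
            per = pp.build_cohort_models(trimmed, "personalized",
                                         FAST_LOSS, FAST_GD,
                                         min_rows_personalized=5)
        assert "S001" not in per.models
        assert len(per.models) == 11

    def test_unknown_regime_raises(self, small_cohort):
        with pytest.raises(ValueError):
            pp.build_cohort_models(small_cohort, "federated")
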