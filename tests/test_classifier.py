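"""Triplet network, k-means classifier, likelihoods, and OLO validation."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from bdiflow.classifier import (
    ClusterModel,
    NetworkConfig,
    class_likelihoods,
    fit_clusters,
    fit_fold,
    forward,
    init_params,
    olo_cross_validate,
    predict_class,
    train_embedding,
    triplet_loss,
)

FAST = NetworkConfig(epochs=80, triplets_per_epoch=64, learning_rate=3e-3)


def exhaustive_min_inertia(points, k=3):
    """Brute-force minimum k-means inertia over all assignments of <= 8 points."""
    best = np.inf
    n = len(points)
    for assign in itertools.product(range(k), repeat=n):
        total = 0.0
        for c in range(k):
            members = points[[i for i in range(n) if assign[i] == c]]
            if len(members):
                total += np.sum((members - members.mean(axis=0)) ** 2)
        best = min(best, total)
    return best


class TestTripletLoss:
    def test_boundary_case_is_zero(self):
        a = np.zeros(3)
        n = np.array([math.sqrt(0.5), 0, 0])  # ||a-n||^2 == margin
        assert triplet_loss(a, a, n, margin=0.5) == 0.0

    def test_degenerate_triplet_returns_margin(self):
        a = np.array([1.0, 2.0, 3.0])
        assert triplet_loss(a, a, a, margin=0.7) == pytest.approx(0.7)

    def test_hand_arithmetic(self):
        a, p, n = np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 2.0, 0])
        # max(0, 1 - 4 + 0.5) = 0
        assert triplet_loss(a, p, n, margin=0.5) == 0.0

    def test_unsquared_variant(self):
        a, p, n = np.zeros(2), np.array([3.0, 0]), np.array([0, 1.0])
        assert triplet_loss(a, p, n, 0.5, squared=False) == pytest.approx(2.5)


class TestForward:
    def test_zero_params_map_to_origin(self):
        params = [(np.zeros((20, 20)), np.zeros(20)),
                  (np.zeros((20, 10)), np.zeros(10)),
                  (np.zeros((10, 3)), np.zeros(3))]
        out = forward(np.ones(20), params)
        np.testing.assert_array_equal(out, np.zeros((1, 3)))

    def test_two_neuron_toy_hand_computed(self):
        # tanh hidden layer then linear sum, traced by hand with math.tanh
        params = [(np.eye(2), np.array([0.1, -0.2])), (np.ones((2, 1)), np.array([0.5]))]
        x = np.array([0.5, -0.25])
        expected = math.tanh(0.6) + math.tanh(-0.45) + 0.5
        assert forward(x, params)[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_deterministic(self, rng):
        params = init_params((20, 20, 10, 3), rng)
        x = rng.standard_normal((4, 20))
        np.testing.assert_array_equal(forward(x, params), forward(x, params))

    def test_wrong_input_width_rejected(self, rng):
        params = init_params((20, 20, 10, 3), rng)
        with pytest.raises(ValueError):
            forward(np.ones(7), params)


def separable_features(rng, n_per_class=6, dim=20, sep=5.0, sigma=0.05):
    centers = rng.standard_normal((3, dim)) * sep
    x = np.vstack([centers[c] + sigma * rng.standard_normal((n_per_class, dim))
                   for c in range(3)])
    y = ["0"] * n_per_class + ["1"] * n_per_class + ["23"] * n_per_class
    return x, y


class TestTrainEmbedding:
    def test_separable_classes_reduce_loss_tenfold(self, rng):
        x, y = separable_features(rng)
        cfg = NetworkConfig(epochs=200, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no non-convergence warning allowed
            params, trace = train_embedding(x, y, cfg)
        assert trace[-1] < 0.1 * trace[0]

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((6, 20))
        with pytest.raises(ValueError):
            train_embedding(x, ["1"] * 6, FAST)

    def test_same_seed_identical_parameters(self, rng):
        x, y = separable_features(rng)
        p1, _ = train_embedding(x, y, FAST)
        p2, _ = train_embedding(x, y, FAST)
        for (w1, b1), (w2, b2) in zip(p1, p2):
            np.testing.assert_array_equal(w1, w2)
            np.testing.assert_array_equal(b1, b2)

    def test_parameter_bundle_round_trip(self, rng, tmp_path):
        from bdiflow.classifier import load_params, save_params

        x, y = separable_features(rng)
        params, _ = train_embedding(x, y, FAST)
        save_params(params, FAST, tmp_path / "model.json")
        back, cfg = load_params(tmp_path / "model.json")
        assert cfg == FAST
        np.testing.assert_allclose(forward(x, back), forward(x, params), rtol=1e-12)

    def test_thin_class_warns_but_trains(self, rng):
        x, _ = separable_features(rng, n_per_class=3)
        y = ["0"] * 3 + ["1"] * 3 + ["23"] * 2 + ["0"]
        with pytest.warns(RuntimeWarning, match="< 2 members"):
            train_embedding(x, y[:8] + ["solo"], FAST)


class TestClusters:
    def test_tight_blobs_map_to_their_grades(self):
        z = np.vstack([np.full((4, 3), 0.0), np.full((4, 3), 5.0), np.full((4, 3), -5.0)])
        z = z + 0.01 * np.random.default_rng(1).standard_normal(z.shape)
        y = ["0"] * 4 + ["1"] * 4 + ["23"] * 4
        model = fit_clusters(z, y, seed=0)
        assert sorted(model.cluster_to_class.values()) == ["0", "1", "23"]
        for i, grade in zip((0, 4, 8), ("0", "1", "23")):
            cl = class_likelihoods(z[i], model)
            assert predict_class(cl) == grade

    def test_duplicated_points_same_model(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((6, 3)) * 3
        y = ["0", "0", "1", "1", "23", "23"]
        m1 = fit_clusters(z, y, seed=4)
        m2 = fit_clusters(np.vstack([z, z]), y + y, seed=4)
        np.testing.assert_allclose(
            np.sort(m1.centroids, axis=0), np.sort(m2.centroids, axis=0), atol=1e-8
        )

    def test_mixed_blob_majority_label(self):
        blob = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.05, 0.05, 0]])
        far1 = np.full((2, 3), 8.0)
        far2 = np.full((2, 3), -8.0)
        z = np.vstack([blob, far1, far2])
        y = ["1", "1", "23", "0", "0", "23", "23"]  # blob: 2 of '1' vs 1 of '23'
        model = fit_clusters(z, y, seed=0)
        assert predict_class(class_likelihoods(blob.mean(axis=0), model)) == "1"

    def test_inertia_matches_exhaustive_enumeration(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(7)
        for _ in range(3):
            pts = rng.standard_normal((8, 3))
            km = KMeans(n_clusters=3, n_init=50, random_state=0).fit(pts)
            assert km.inertia_ == pytest.approx(exhaustive_min_inertia(pts), rel=1e-9)


class TestLikelihoods:
    def _model(self, tau=1.0):
        c = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        return ClusterModel(centroids=c, cluster_to_class={0: "0", 1: "1", 2: "23"},
                            temperature=tau)

    def test_at_centroid_with_small_temperature(self):
        cl = class_likelihoods(np.zeros(3), self._model(tau=1e-4))
        assert cl.p[0] > 0.999

    def test_equidistant_is_uniform(self):
        c = np.eye(3)
        model = ClusterModel(centroids=c, cluster_to_class={0: "0", 1: "1", 2: "23"},
                             temperature=1.0)
        cl = class_likelihoods(np.full(3, 1 / 3), model)
        np.testing.assert_allclose(cl.p, 1 / 3, rtol=1e-12)

    def test_softmax_closed_form(self):
        # distances^2 (0, 1, 4) at tau=1 -> softmax(0, -1, -4)
        cl = class_likelihoods(np.zeros(3), self._model(tau=1.0))
        e = np.exp([0.0, -1.0, -4.0])
        np.testing.assert_allclose(cl.p, e / e.sum(), rtol=1e-6)
        assert np.round(cl.p, 4).tolist() == [0.7214, 0.2654, 0.0132]

    def test_normalization_and_prediction_ties(self):
        cl = class_likelihoods(np.zeros(3), self._model())
        assert cl.p.sum() == pytest.approx(1.0, abs=1e-12)
        from bdiflow.classifier import ClassLikelihoods

        assert predict_class(ClassLikelihoods("x", np.full(3, 1 / 3))) == "0"
        assert predict_class(ClassLikelihoods("x", [0.5, 0.3, 0.2])) == "0"
        assert predict_class(ClassLikelihoods("x", [0.1, 0.2, 0.7])) == "23"


class TestOLO:
    def test_one_prediction_per_graded_patient(self, separable_candidates):
        candidates, truths = separable_candidates
        preds = olo_cross_validate(candidates, truths, FAST)
        assert len(preds) == 18
        assert set(preds["patient_id"]) == set(candidates.index)
        np.testing.assert_allclose(
            preds[["p_grade0", "p_grade1", "p_grade23"]].sum(axis=1), 1.0, atol=1e-9
        )

    def test_separable_cohort_classified_accurately(self, separable_candidates):
        candidates, truths = separable_candidates
        preds = olo_cross_validate(candidates, truths, FAST)
        assert (preds["predicted"] == preds["actual"]).mean() >= 0.8

    def test_ungraded_patients_never_trained_or_scored(self, separable_candidates):
        candidates, truths = separable_candidates
        ungraded = pd.DataFrame(
            np.random.default_rng(5).standard_normal((2, 22)),
            columns=candidates.columns, index=["U00", "U01"],
        )
        p1 = olo_cross_validate(candidates, truths, FAST, ungraded=ungraded)
        # poisoning ungraded rows must not change any graded prediction
        p2 = olo_cross_validate(
            candidates, truths, FAST, ungraded=ungraded * 1e6
        )
        g1 = p1[p1["graded"]].reset_index(drop=True)
        g2 = p2[p2["graded"]].reset_index(drop=True)
        pd.testing.assert_frame_equal(g1, g2)
        assert not p1[~p1["graded"]]["actual"].any()

    def test_heldout_row_cannot_leak_into_fold_model(self, separable_candidates):
        candidates, truths = separable_candidates
        held = "P000"
        train = [p for p in candidates.index if p != held]
        poisoned = candidates.copy()
        poisoned.loc[held] = 1e9
        clean_fold = fit_fold(candidates, truths, train, FAST, fold=0)
        poison_fold = fit_fold(poisoned, truths, train, FAST, fold=0)
        assert clean_fold.selected == poison_fold.selected
        for (w1, _), (w2, _) in zip(clean_fold.params, poison_fold.params):
            np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(
            clean_fold.clusters.centroids, poison_fold.clusters.centroids
        )

    def test_too_small_or_single_class_rejected(self, separable_candidates):
        candidates, truths = separable_candidates
        with pytest.raises(ValueError):
            olo_cross_validate(candidates.iloc[:3], truths.iloc[:3], FAST)
        with pytest.raises(ValueError):
            olo_cross_validate(candidates.iloc[:6], truths.iloc[:6], FAST)
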