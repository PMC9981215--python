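"""Diagnosis classifier, 2-D embedding, Pan-Myeloid Axis and stability."""

import numpy as np
import pandas as pd
import pytest

from panmyeloid.cohort import feature_matrix
from panmyeloid.embedding import (
    NetConfig,
    aberration_centroids,
    axis_pipeline,
    bootstrap_stability,
    embed_2d,
    feature_axis_positions,
    hidden_representation,
    order_along_axis,
    pan_myeloid_axis,
    train_classifier,
    _fit_net,
    _continuous_indices,
    _pairwise_taus,
)
from panmyeloid.synthetic import DEFAULT_GENE_CLUSTERS, generate_cohort, scaled_config

FAST_NET = NetConfig(max_iter=60)


@pytest.fixture(scope="module")
def trained(midsize_cohort, schema):
    records, _ = midsize_cohort
    X, _ = feature_matrix(records, schema)
    y = np.array([r.diagnosis for r in records])
    net, per_class, weighted = train_classifier(
        X.to_numpy(), y, schema, folds=5, seed=3, config=FAST_NET
    )
    return X, y, net, per_class, weighted


class TestClassifier:
    def test_architecture_matches_declaration(self, trained):
        _, _, net, _, _ = trained
        assert net.hidden_widths == (100, 65)
        assert len(net.classes_) == 8

    def test_separable_cohort_weighted_auroc(self, trained):
        *_, weighted = trained
        assert weighted >= 0.99

    def test_softmax_rows_sum_to_one(self, trained):
        X, _, net, _, _ = trained
        proba = net.predict_proba(X.to_numpy()[:20])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_permuted_labels_give_chance_auroc(self, midsize_cohort, schema):
        records, _ = midsize_cohort
        X, _ = feature_matrix(records, schema)
        y = np.array([r.diagnosis for r in records])
        rng = np.random.default_rng(0)
        aurocs = []
        for rep in range(3):
            yp = rng.permutation(y)
            _, _, w = train_classifier(
                X.to_numpy(), yp, schema, folds=5, seed=100 + rep, config=FAST_NET
            )
            aurocs.append(w)
        assert 0.45 <= np.mean(aurocs) <= 0.55

    def test_class_smaller_than_folds_rejected(self, schema):
        X = np.zeros((12, schema.size))
        y = ["AML"] * 10 + ["MDS"] * 2
        with pytest.raises(ValueError, match="fewer members"):
            train_classifier(X, y, schema, folds=5)


class TestHiddenRepresentation:
    def test_width_65_and_nonnegative(self, trained):
        X, _, net, _, _ = trained
        H = hidden_representation(net, X.to_numpy()[:30])
        assert H.shape == (30, 65)
        assert np.all(H >= 0)

    def test_deterministic_on_fixed_weights(self, trained):
        X, _, net, _, _ = trained
        a = hidden_representation(net, X.to_numpy()[:10])
        b = hidden_representation(net, X.to_numpy()[:10])
        np.testing.assert_array_equal(a, b)

    def test_feature_length_mismatch_rejected(self, trained):
        _, _, net, _, _ = trained
        with pytest.raises(ValueError):
            hidden_representation(net, np.zeros((3, 10)))


class TestEmbed2D:
    def test_two_columns_and_variance_ordering(self):
        rng = np.random.default_rng(0)
        H = rng.normal(size=(50, 65)) * np.linspace(3, 0.1, 65)
        coords = embed_2d(H)
        assert coords.shape == (50, 2)
        assert coords[:, 0].var() >= coords[:, 1].var()

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        H = rng.normal(size=(40, 10))
        shifted = H + 5.0
        np.testing.assert_allclose(embed_2d(H), embed_2d(shifted), atol=1e-8)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            embed_2d(np.zeros((2, 65)))


class TestAxis:
    def test_orientation_puts_aml_right_of_mds(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        axis = pan_myeloid_axis(coords, ["MDS", "AML", "MDS", "AML"])
        aml = axis[[1, 3]].mean()
        mds = axis[[0, 2]].mean()
        assert aml > mds

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(30, 2))
        dx = np.array(["AML"] * 15 + ["MDS"] * 15)
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        a = pan_myeloid_axis(coords, dx)
        b = pan_myeloid_axis(coords @ R.T, dx)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_collinear_patients_keep_arc_length_order(self):
        t = np.array([0.0, 1.0, 2.0, 5.0])
        coords = np.column_stack([t, 2 * t])
        axis = pan_myeloid_axis(coords, ["MDS", "MDS", "AML", "AML"])
        assert list(np.argsort(axis.to_numpy())) == [0, 1, 2, 3]

    def test_fallback_warning_without_aml(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.warns(UserWarning, match="orientation"):
            pan_myeloid_axis(coords, ["MDS", "MPN", "MDS"])

    def test_lymphoid_only_cohort_rejected(self):
        with pytest.raises(ValueError):
            pan_myeloid_axis(np.zeros((4, 2)), ["ALL", "CLL", "MM", "ALL"])


class TestCentroidsAndOrdering:
    def test_centroid_special_cases(self):
        pos = np.array([0.0, 2.0, 4.0])
        carriers = pd.DataFrame(
            {"single": [1, 0, 0], "pair": [0, 1, 1], "all": [1, 1, 1]}
        )
        cent = aberration_centroids(pos, carriers)
        assert cent["single"] == 0.0
        assert cent["pair"] == 3.0  # midpoint of its two carriers
        assert cent["all"] == 2.0  # cohort centroid

    def test_zero_carrier_aberration_excluded_with_warning(self):
        carriers = pd.DataFrame({"none": [0, 0], "some": [1, 0]})
        with pytest.warns(UserWarning):
            cent = aberration_centroids(np.array([1.0, 2.0]), carriers)
        assert "none" not in cent.index

    def test_order_sorted_with_alphabetical_ties(self):
        order = order_along_axis({"b": 1.0, "a": 1.0, "c": 0.0})
        assert order == ["c", "a", "b"]

    def test_reversing_axis_reverses_order(self):
        pos = {"a": -1.0, "b": 0.5, "c": 2.0}
        fwd = order_along_axis(pos)
        rev = order_along_axis({k: -v for k, v in pos.items()})
        assert rev == fwd[::-1]

    def test_feature_positions_track_where_high_values_sit(self):
        pos = np.array([-2.0, -1.0, 1.0, 2.0])
        feats = pd.DataFrame(
            {"right_loaded": [0.0, 0.0, 1.0, 1.0], "left_loaded": [1.0, 1.0, 0.0, 0.0]}
        )
        fp = feature_axis_positions(pos, feats)
        assert fp["right_loaded"] > 0 > fp["left_loaded"]


class TestPlantedGradient:
    def test_aml_enriched_clusters_lie_right_of_mds_enriched(self, midsize_cohort, schema):
        records, _ = midsize_cohort
        emb = axis_pipeline(records, schema, seed=5, config=FAST_NET)
        gp = emb.gene_positions

        def block_mean(name):
            genes = [g for g in DEFAULT_GENE_CLUSTERS[name] if g in gp.index]
            return float(gp[genes].mean())

        for right in ("R", "MR"):
            for left in ("ML", "L"):
                assert block_mean(right) > block_mean(left)


class TestBootstrapStability:
    def test_resampling_disabled_gives_perfect_tau(self, schema):
        records, _ = generate_cohort(scaled_config(0.15), seed=3, schema=schema)
        report = bootstrap_stability(
            records, schema, B=2, seed=4, config=FAST_NET, resample=False
        )
        # identical cohort and seeds per replicate pair: identical orders
        for taus in report.taus.values():
            finite = taus[np.isfinite(taus)]
            np.testing.assert_allclose(finite, 1.0)

    def test_pair_count_is_b_choose_2(self, schema):
        records, _ = generate_cohort(scaled_config(0.15), seed=5, schema=schema)
        report = bootstrap_stability(records, schema, B=4, seed=6, config=FAST_NET)
        for taus in report.taus.values():
            assert len(taus) == 4 * 3 // 2

    def test_random_permutation_orders_have_null_tau(self):
        rng = np.random.default_rng(0)
        items = [f"g{i}" for i in range(40)]
        maps = [
            dict(zip(items, rng.permutation(len(items)).astype(float)))
            for _ in range(12)
        ]
        taus = _pairwise_taus(maps)
        n = len(items)
        se_tau = np.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
        # pairs share replicates and are correlated; the single-pair SE is
        # a conservative bound for the mean
        assert abs(np.nanmean(taus)) < 3 * se_tau

    def test_b_below_two_rejected(self, schema, small_cohort):
        records, _ = small_cohort
        with pytest.raises(ValueError):
            bootstrap_stability(records, schema, B=1)
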