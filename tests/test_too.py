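"""Tissue-of-origin: sample graph, focal loss, GCNN, explainer, RF baseline."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cfmosaic import autodiff as ad
from cfmosaic import too


def _unit_vectors(angles_deg):
    a = np.deg2rad(angles_deg)
    return pd.DataFrame(
        np.column_stack([np.cos(a), np.sin(a)]),
        index=[f"s{i}" for i in range(len(angles_deg))],
    )


class TestSampleGraph:
    def test_single_node_no_edges(self):
        frame = pd.DataFrame([[1.0, 2.0]], index=["s0"])
        g = too.build_sample_graph(frame, {"s0": "liver"}, top_k=None)
        assert g.A.sum() == 0

    def test_hand_computed_distances_one_edge(self):
        """Unit vectors at 0/29/103 degrees: chord distances ~{0.50, 1.20,
        1.57}; only the first is below delta=0.8.  The threshold rule draws
        exactly one edge; the isolated third node then gets its flagged
        nearest-neighbour fallback edge."""
        frame = _unit_vectors([0, 29, 103])
        g = too.build_sample_graph(frame, None, delta=0.8, top_k=None,
                                   standardize=False)
        assert g.A[0, 1] and g.A[1, 0]
        assert g.isolated_fallback == ["s2"]
        assert g.A[2, 1] and not g.A[2, 0]
        assert g.A.sum() == 4  # the threshold edge plus the fallback edge

    def test_delta_above_diameter_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(12, 6)))
        g = too.build_sample_graph(frame, None, delta=2.01, top_k=None)
        n = len(frame)
        assert g.A.sum() == n * (n - 1)

    def test_adjacency_symmetric_zero_diagonal(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame(rng.normal(size=(20, 10)))
            g = too.build_sample_graph(frame, None, delta=1.2, top_k=None)
            assert (g.A == g.A.T).all()
            assert not g.A.diagonal().any()

    def test_distances_bounded_by_two(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(size=(15, 8)) * 100)
        g = too.build_sample_graph(frame, None, delta=2.01, top_k=None)
        norms = np.linalg.norm(g.X, axis=1)
        assert np.allclose(norms, 1.0)

    def test_isolated_nodes_get_nearest_neighbour(self):
        frame = _unit_vectors([0, 10, 180])  # the 180-degree point is isolated
        g = too.build_sample_graph(frame, None, delta=0.8, top_k=None,
                                   standardize=False)
        assert "s2" in g.isolated_fallback
        assert g.A[2].sum() == 1

    def test_nan_features_rejected(self):
        frame = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="NaN"):
            too.build_sample_graph(frame, None, top_k=None)


class TestFocalLoss:
    def test_confident_correct_prediction_zero_loss(self):
        assert too.focal_loss(np.array([[1.0, 0.0]]), [0]) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_half_probability_closed_form(self):
        val = too.focal_loss(np.array([[0.5, 0.5]]), [0], gamma=2.0)
        assert val == pytest.approx(0.25 * np.log(2), abs=1e-12)

    def test_gamma_zero_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(50, 5))
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        y = rng.integers(0, 5, 50)
        ce = -np.mean(np.log(p[np.arange(50), y]))
        assert too.focal_loss(p, y, gamma=0.0) == pytest.approx(ce, abs=1e-12)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            too.focal_loss(np.array([[0.9, 0.3]]), [0])


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        """Backprop through the attention network agrees with central
        differences on every parameter of the first layer."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        A = np.zeros((6, 6), dtype=bool)
        for i in range(5):
            A[i, i + 1] = A[i + 1, i] = True
        g = too.SampleGraph(
            [f"s{i}" for i in range(6)], X, A, np.array([0, 1, 2, 0, 1, 2]),
            ["a", "b", "c"], [f"f{i}" for i in range(4)],
        )
        cfg = too.GCNNConfig(layers=2, hidden=5, heads=2, classes=3, epochs=1)
        model = too.GCNNModel(4, cfg, rng)
        alpha = np.ones(3)
        labeled = np.arange(6)
        loss = model.loss(ad.Tensor(X), g, labeled, alpha)
        loss.backward()
        eps = 1e-6
        for p in model.params[:3]:
            it = np.nditer(p.data, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                p.data[i] += eps
                lp = model.loss(ad.Tensor(X), g, labeled, alpha).data
                p.data[i] -= 2 * eps
                lm = model.loss(ad.Tensor(X), g, labeled, alpha).data
                p.data[i] += eps
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(float(p.grad[i]), abs=1e-6)


@pytest.fixture(scope="module")
def planted_graph(planted_frame):
    frame, labels, classes = planted_frame
    return too.build_sample_graph(frame, labels, class_names=classes, top_k=None)


@pytest.fixture(scope="module")
def trained_planted(planted_graph):
    cfg = too.GCNNConfig(epochs=120, folds=4, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return too.train_gcnn(planted_graph, cfg)


class TestTrainGCNN:
    def test_designed_separability(self, trained_planted):
        _, report = trained_planted
        assert np.mean(report.fold_accuracies) >= 0.8

    def test_shuffled_labels_at_chance(self, planted_frame):
        frame, labels, classes = planted_frame
        rng = np.random.default_rng(4)
        shuffled = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        g = too.build_sample_graph(frame, shuffled, class_names=classes, top_k=None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, report = too.train_gcnn(
                g, too.GCNNConfig(epochs=60, folds=4, seed=0)
            )
        assert np.mean(report.fold_accuracies) == pytest.approx(0.2, abs=0.1)

    def test_deterministic_under_seed(self, planted_graph):
        cfg = too.GCNNConfig(epochs=30, folds=3, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, r1 = too.train_gcnn(planted_graph, cfg)
            _, r2 = too.train_gcnn(planted_graph, cfg)
        assert r1.fold_accuracies == r2.fold_accuracies

    def test_loss_ignores_unlabeled_nodes(self, planted_frame):
        """Transductive contract: the loss value does not depend on what
        label an unlabeled node would have had."""
        frame, labels, classes = planted_frame
        partial = labels.iloc[:60]
        g = too.build_sample_graph(frame, partial, class_names=classes, top_k=None)
        rng = np.random.default_rng(5)
        model = too.GCNNModel(g.X.shape[1], too.GCNNConfig(epochs=1), rng)
        labeled = np.where(g.y >= 0)[0]
        alpha = np.ones(5)
        base = model.loss(ad.Tensor(g.X), g, labeled, alpha).data
        g2 = too.SampleGraph(g.node_ids, g.X, g.A, g.y.copy(), g.class_names,
                             g.feature_names)
        g2.y[g2.y < 0] = 3  # relabel unlabeled nodes arbitrarily
        hidden = np.where(g.y < 0)[0]
        g2.y[hidden] = 3
        again = model.loss(ad.Tensor(g2.X), g2, labeled, alpha).data
        assert float(base) == pytest.approx(float(again), abs=1e-12)

    def test_message_passing_is_real(self, planted_frame):
        """Removing an unlabeled node changes labeled-node predictions."""
        frame, labels, classes = planted_frame
        partial = labels.iloc[:60]
        g_full = too.build_sample_graph(frame, partial, class_names=classes,
                                        top_k=None)
        # drop the unlabeled tail of the last labeled class: those nodes
        # are graph neighbours of labeled nodes, so predictions must move
        g_small = too.build_sample_graph(
            frame.iloc[:60], partial, class_names=classes, top_k=None
        )
        rng = np.random.default_rng(6)
        model = too.GCNNModel(g_full.X.shape[1], too.GCNNConfig(), rng)
        p_full = model.predict_proba(g_full)[:60]
        p_small = model.predict_proba(g_small)[:60]
        assert not np.allclose(p_full, p_small)


class TestPredict:
    def test_probability_rows_sum_to_one(self, trained_planted, planted_graph):
        model, _ = trained_planted
        probs, labels = too.predict_too(model, planted_graph)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= set(planted_graph.class_names)

    def test_per_class_accuracy_on_designed_data(
        self, trained_planted, planted_graph, planted_frame
    ):
        _, labels_ref, classes = planted_frame
        model, _ = trained_planted
        _, pred = too.predict_too(model, planted_graph)
        accs = [
            (pred[labels_ref == c] == c).mean() for c in classes
        ]
        assert np.median(accs) > 0.6

    def test_agreement_matrix_rows_sum_to_one(self, trained_planted,
                                              planted_graph, planted_frame):
        _, labels_ref, classes = planted_frame
        model, _ = trained_planted
        _, pred = too.predict_too(model, planted_graph)
        mat = too.agreement_matrix(pred, labels_ref, classes)
        assert np.allclose(mat.sum(axis=1), 1.0)

    def test_unknown_node_rejected(self, trained_planted, planted_graph):
        model, _ = trained_planted
        with pytest.raises(KeyError):
            too.predict_too(model, planted_graph, ["nonexistent"])


@pytest.fixture(scope="module")
def report(trained_planted, planted_graph):
    model, _ = trained_planted
    return too.explain_importance(model, planted_graph, steps=80, seed=0)


class TestExplainer:
    def test_scores_in_unit_interval(self, report):
        vals = report.scores.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_planted_groups_recovered(self, report, planted_frame):
        """Top feature group per class matches the planted group >= 4/5."""
        _, _, classes = planted_frame
        top = report.group_summary.idxmax(axis=1)
        hits = sum(top[c] == f"G{k}" for k, c in enumerate(classes))
        assert hits >= 4

    def test_constant_feature_unimportant(self, planted_frame):
        frame, labels, classes = planted_frame
        frame = frame.copy()
        frame["G0:const"] = 5.0
        g = too.build_sample_graph(frame, labels, class_names=classes, top_k=None)
        rng = np.random.default_rng(7)
        model = too.GCNNModel(g.X.shape[1], too.GCNNConfig(epochs=1), rng)
        rep = too.explain_importance(model, g, steps=40, seed=0)
        assert (rep.scores["G0:const"] < rep.threshold).all()


class TestRFBaseline:
    def test_separable_accuracy(self, planted_frame):
        frame, labels, _ = planted_frame
        _, accs = too.rf_too_baseline(frame, labels, seed=0)
        assert np.mean(accs) >= 0.8

    def test_shuffled_labels_at_chance(self, planted_frame):
        frame, labels, _ = planted_frame
        rng = np.random.default_rng(8)
        shuffled = rng.permutation(labels.to_numpy())
        _, accs = too.rf_too_baseline(frame, shuffled, seed=0, cv_folds=4)
        assert np.mean(accs) <= 0.45

    def test_deterministic(self, planted_frame):
        frame, labels, _ = planted_frame
        _, a = too.rf_too_baseline(frame, labels, seed=3, cv_folds=3)
        _, b = too.rf_too_baseline(frame, labels, seed=3, cv_folds=3)
        np.testing.assert_array_equal(a, b)
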