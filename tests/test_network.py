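"""Network invariances, attention normalisation, training smoke tests."""

import numpy as np
import pytest

from graphmhc.data import _make_batch, batch_graphs
from graphmhc.featurize import GraphSample, featurize_pair
from graphmhc.model import GraphMHCClassifier, train_model
from graphmhc.nn import Adam, GraphMHCNetwork, ModelConfig, _BatchConstants


def small_config(**kw):
    base = dict(attention_heads=2, gat_hidden=4, conv_channels=3, dropout=0.0)
    base.update(kw)
    return ModelConfig(**base)


class TestGATLayer:
    def test_attention_normalised_per_destination(self):
        cfg = small_config()
        net = GraphMHCNetwork(cfg, rng=np.random.default_rng(2))
        batch = _make_batch([featurize_pair("GA", "C", label=1)])
        const = _BatchConstants(batch)
        from graphmhc.autodiff import Tensor

        x = Tensor(batch.node_features.astype(np.float64))
        p = net.params
        Hn = x @ p["gat0.W"]
        n_src = Hn @ (p["gat0.a_src"] * net._head_mask)
        n_dst = Hn @ (p["gat0.a_dst"] * net._head_mask)
        scores = const.gather_dst(n_dst) + const.gather_src(n_src)
        scores = (scores + const.edge_features @ p["gat0.a_edge"]).leaky_relu(0.2)
        seg_max = np.maximum.reduceat(scores.data, const.dst_starts, axis=0)
        ex = (scores - Tensor(seg_max[const.dst])).exp()
        denom = const.scatter_to_dst(ex)
        alpha = (ex / const.gather_dst(denom)).data
        sums = np.add.reduceat(alpha, const.dst_starts, axis=0)
        assert np.all(alpha >= 0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_isolated_node_attends_to_itself(self):
        # a single-node graph has only its self-loop: alpha == 1
        x = np.ones((1, 31), dtype=np.float32)
        sample = GraphSample(
            node_features=x,
            edge_index=np.empty((2, 0), dtype=np.int64),
            edge_features=np.empty((0, 12), dtype=np.float32),
            label=0,
        )
        batch = _make_batch([sample])
        const = _BatchConstants(batch)
        assert const.src.tolist() == [0] and const.dst.tolist() == [0]
        net = GraphMHCNetwork(small_config(), rng=np.random.default_rng(0))
        out = net.forward(batch)
        assert np.isfinite(out.data).all()

    def test_symmetric_two_node_graph_gives_equal_outputs(self):
        x = np.tile(np.eye(31)[1], (2, 1)).astype(np.float32)
        sample = GraphSample(
            node_features=x,
            edge_index=np.array([[0, 1], [1, 0]]),
            edge_features=np.zeros((2, 12), dtype=np.float32),
            label=0,
        )
        batch = _make_batch([sample])
        net = GraphMHCNetwork(small_config(), rng=np.random.default_rng(1))
        const = _BatchConstants(batch)
        from graphmhc.autodiff import Tensor

        h = net.gat_layer(0, Tensor(x.astype(np.float64)), const, False, None)
        np.testing.assert_allclose(h.data[0], h.data[1], atol=1e-12)


class TestForwardInvariances:
    @pytest.fixture(scope="class")
    def net_and_samples(self):
        net = GraphMHCNetwork(small_config(), rng=np.random.default_rng(3))
        samples = [
            featurize_pair("GAS", "GG", label=1),
            featurize_pair("CVW", "AA", label=0),
            featurize_pair("PT", "WY", label=1),
        ]
        return net, samples

    def test_eval_forward_is_deterministic(self, net_and_samples):
        net, samples = net_and_samples
        batch = _make_batch(samples)
        a = net.forward(batch).data
        b = net.forward(batch).data
        assert np.array_equal(a, b)

    def test_graph_order_permutes_outputs(self, net_and_samples):
        net, samples = net_and_samples
        out = net.forward(_make_batch(samples)).data
        perm_out = net.forward(_make_batch(samples[::-1])).data
        np.testing.assert_allclose(out[::-1], perm_out, atol=1e-10)

    def test_atom_relabelling_leaves_output_unchanged(self, net_and_samples):
        net, samples = net_and_samples
        s = samples[0]
        rng = np.random.default_rng(11)
        perm = rng.permutation(s.num_nodes)
        inv = np.argsort(perm)
        permuted = GraphSample(
            node_features=s.node_features[perm],
            edge_index=inv[s.edge_index],
            edge_features=s.edge_features,
            label=s.label,
        )
        a = net.forward(_make_batch([s])).data
        b = net.forward(_make_batch([permuted])).data
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_zeroed_head_outputs_half(self, net_and_samples):
        net, samples = net_and_samples
        saved = net.state_dict()
        for name in ("fc.W", "fc.b"):
            net.params[name].data = np.zeros_like(net.params[name].data)
        probs = net.predict_proba(_make_batch(samples))
        np.testing.assert_allclose(probs, 0.5, atol=1e-15)
        net.load_state_dict(saved)

    def test_probabilities_strictly_inside_unit_interval(self, net_and_samples):
        net, samples = net_and_samples
        probs = net.predict_proba(_make_batch(samples))
        assert np.all((probs > 0) & (probs < 1))


class TestReadout:
    def test_mean_readout_of_constant_graph_is_identity(self):
        batch = _make_batch([featurize_pair("G", "G", label=0)])
        const = _BatchConstants(batch)
        from graphmhc.autodiff import Tensor

        v = np.ones((batch.num_nodes, 4)) * 3.25
        np.testing.assert_allclose(const.graph_mean(Tensor(v)).data, 3.25)

    def test_one_row_per_graph(self):
        samples = [featurize_pair("G", "A", label=0)] * 5
        batch = _make_batch(samples)
        const = _BatchConstants(batch)
        from graphmhc.autodiff import Tensor

        out = const.graph_mean(Tensor(batch.node_features.astype(float)))
        assert out.shape == (5, 31)


class TestTraining:
    def test_loss_decreases_on_learnable_toy_set(self, tiny_labelled_samples):
        est = GraphMHCClassifier(
            attention_heads=2,
            gat_hidden=4,
            conv_channels=3,
            epochs=30,
            learning_rate=3e-3,
            random_state=0,
        ).fit(tiny_labelled_samples * 4)
        assert est.loss_history_[-1] < est.loss_history_[0]

    def test_same_seed_reproduces_final_loss(self, tiny_labelled_samples):
        kw = dict(attention_heads=2, gat_hidden=2, conv_channels=2, epochs=3,
                  random_state=7)
        a = GraphMHCClassifier(**kw).fit(tiny_labelled_samples)
        b = GraphMHCClassifier(**kw).fit(tiny_labelled_samples)
        assert a.loss_history_ == b.loss_history_

    def test_predict_proba_shape_and_classes(self, tiny_labelled_samples):
        est = train_model(
            tiny_labelled_samples,
            attention_heads=2,
            gat_hidden=2,
            conv_channels=2,
            epochs=2,
        )
        proba = est.predict_proba(tiny_labelled_samples)
        assert proba.shape == (len(tiny_labelled_samples), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(tiny_labelled_samples)) <= {0, 1}
        assert est.classes_.tolist() == [0, 1]

    def test_labels_can_come_from_y(self, tiny_labelled_samples):
        y = [s.label for s in tiny_labelled_samples]
        est = GraphMHCClassifier(
            attention_heads=2, gat_hidden=2, conv_channels=2, epochs=1
        ).fit(tiny_labelled_samples, y)
        assert hasattr(est, "network_")

    def test_rejects_unlabelled_fit(self, tiny_labelled_samples):
        unlabelled = [
            GraphSample(s.node_features, s.edge_index, s.edge_features)
            for s in tiny_labelled_samples
        ]
        with pytest.raises(ValueError, match="label"):
            GraphMHCClassifier(epochs=1).fit(unlabelled)

    def test_sklearn_get_set_params_roundtrip(self):
        est = GraphMHCClassifier(attention_heads=4)
        params = est.get_params()
        assert params["attention_heads"] == 4
        est.set_params(epochs=5)
        assert est.epochs == 5

    def test_save_load_reproduces_predictions(self, tiny_labelled_samples, tmp_path):
        est = GraphMHCClassifier(
            attention_heads=2, gat_hidden=2, conv_channels=2, epochs=2
        ).fit(tiny_labelled_samples)
        est.save(tmp_path / "model.npz")
        loaded = GraphMHCClassifier.load(tmp_path / "model.npz")
        np.testing.assert_allclose(
            est.predict_proba(tiny_labelled_samples),
            loaded.predict_proba(tiny_labelled_samples),
        )

    def test_ablation_config_without_conv_head(self, tiny_labelled_samples):
        est = GraphMHCClassifier(
            attention_heads=2, gat_hidden=2, conv_layers=0, epochs=2
        ).fit(tiny_labelled_samples)
        proba = est.predict_proba(tiny_labelled_samples)
        assert np.all((proba > 0) & (proba < 1))


class TestModelConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"gat_layers": 0},
            {"dropout": 1.0},
            {"conv_kernel": 4},
            {"conv_layers": 1},
            {"attention_heads": 1, "gat_hidden": 3},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelConfig(**kw)
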