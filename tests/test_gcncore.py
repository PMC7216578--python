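"""Layer forwards vs dense oracles, training contracts, evaluation, CV."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import molgcn as mg
from molgcn import gcncore
from molgcn._autograd import Tensor
from molgcn.errors import SpecError, TrainingError

from conftest import random_normalized_graph, record_from_smiles


def dense_oracle_forward(ng, weights_conv, w_dense):
    """Independent plain-NumPy evaluation of conv(relu) -> graph dense -> gather."""
    x = ng.features
    acc = np.zeros((x.shape[0], next(iter(weights_conv.values())).shape[1]))
    for t, a in ng.norm_adjacency.items():
        acc += a @ x @ weights_conv[t]
    x = np.maximum(acc, 0.0)
    x = x @ w_dense
    return x.sum(axis=0)


class TestLayerForwards:
    def test_single_node_identity_conv(self):
        x = np.array([[1.0, 2.0]])
        out = gcncore.graph_conv_forward(x, {"t": np.array([[1.0]])},
                                         {"t": np.eye(2)}, "identity")
        assert np.allclose(out.data, x)

    def test_zero_weights_relu_gives_zero(self):
        rng = np.random.default_rng(0)
        ng = random_normalized_graph(rng)
        w = {t: np.zeros((5, 4)) for t in ng.norm_adjacency}
        out = gcncore.graph_conv_forward(ng.features, ng.norm_adjacency, w, "relu")
        assert not out.data.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_conv_matches_explicit_matrix_products(self, seed):
        rng = np.random.default_rng(seed)
        ng = random_normalized_graph(rng, n_max=4, n_types=2, d=3)
        w = {t: rng.normal(size=(3, 4)) for t in ng.norm_adjacency}
        out = gcncore.graph_conv_forward(ng.features, ng.norm_adjacency, w, "identity")
        expected = sum(ng.norm_adjacency[t] @ ng.features @ w[t] for t in w)
        assert np.allclose(out.data, expected, atol=1e-6)

    def test_graph_dense_is_nodewise(self):
        x = np.eye(3)  # one-hot rows select W rows
        w = np.random.default_rng(1).normal(size=(3, 4))
        out = gcncore.graph_dense_forward(x, w)
        assert np.allclose(out.data, w)
        assert np.allclose(gcncore.graph_dense_forward(x, np.eye(3)).data, x)

    def test_gather_column_sums(self):
        out = gcncore.graph_gather(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.allclose(out.data, [4.0, 6.0])
        assert np.allclose(gcncore.graph_gather(np.zeros((3, 2))).data, 0.0)
        assert np.allclose(gcncore.graph_gather(np.array([[5.0, 7.0]])).data, [5.0, 7.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_composed_pass_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        ng = random_normalized_graph(rng, n_max=8, n_types=2, d=5)
        wc = {t: rng.normal(size=(5, 6)) for t in ng.norm_adjacency}
        wd = rng.normal(size=(6, 3))
        x = gcncore.graph_conv_forward(ng.features, ng.norm_adjacency, wc, "relu")
        x = gcncore.graph_dense_forward(x, wd)
        got = gcncore.graph_gather(x).data
        assert np.allclose(got, dense_oracle_forward(ng, wc, wd), atol=1e-5)


class TestModelSpec:
    def test_default_architecture_builds_and_runs(self):
        spec = mg.default_model_spec(seed=0)
        model = mg.build_model(spec)
        ds = mg.assemble_dataset(
            [record_from_smiles("CC(=O)NO", "m0")],
            mg.LabelTable(["m0"], ["t"], np.array([[1.0]])),
        )
        probs = mg.predict(model, ds)
        assert probs.shape == (1, 1)

    def test_same_seed_identical_initial_parameters(self):
        a = mg.build_model(mg.default_model_spec(seed=5))
        b = mg.build_model(mg.default_model_spec(seed=5))
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_gather_before_conv_rejected(self):
        with pytest.raises(SpecError):
            mg.ModelSpec(layers=[
                mg.LayerSpec("graph_gather"),
                mg.LayerSpec("graph_conv", 8, "relu"),
                mg.LayerSpec("dense", 2, "softmax"),
            ])

    def test_missing_or_duplicate_gather_rejected(self):
        with pytest.raises(SpecError):
            mg.ModelSpec(layers=[mg.LayerSpec("dense", 2, "softmax")])

    def test_head_must_have_two_logits_per_task(self):
        with pytest.raises(SpecError):
            mg.ModelSpec(layers=[
                mg.LayerSpec("graph_gather"),
                mg.LayerSpec("dense", 3, "softmax"),
            ], n_tasks=2)


@pytest.fixture(scope="module")
def small_dataset():
    fx = mg.generate_fixture(mg.FixtureSpec(n_molecules=40, label_noise=0.0, seed=2))
    return mg.assemble_dataset(fx.records, fx.labels)


class TestTraining:
    def test_loss_decreases_on_planted_rule(self, small_dataset):
        res = mg.GraphConvModel(mg.default_model_spec(seed=0), small_dataset).fit(
            epochs=15, seed=0)
        assert res.history[-1] < res.history[0]

    def test_zero_learning_rate_leaves_parameters_unchanged(self, small_dataset):
        spec = mg.default_model_spec(seed=1)
        init = mg.build_model(spec, small_dataset.feature_config)
        fitted = mg.train(init, small_dataset,
                          mg.TrainConfig(epochs=2, learning_rate=0.0, seed=0))
        assert all(np.array_equal(init.params[k], fitted.params[k]) for k in init.params)

    def test_fully_masked_dataset_is_a_training_error(self, small_dataset):
        bad = small_dataset.subset(np.arange(4))
        bad.label_mask[:] = 0.0
        with pytest.raises(TrainingError):
            mg.train(mg.build_model(mg.default_model_spec(seed=0)), bad, mg.TrainConfig(epochs=1))

    def test_same_seed_reproduces_trajectory(self, small_dataset):
        fit = lambda: mg.GraphConvModel(mg.default_model_spec(seed=0), small_dataset).fit(
            epochs=3, dropout_rate=0.2, seed=4)
        a, b = fit(), fit()
        assert a.history == b.history
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)


class TestMaskedMultiTask:
    def _two_task_data(self):
        fx = mg.generate_fixture(mg.FixtureSpec(n_molecules=30, label_noise=0.0,
                                                n_tasks=2, seed=5))
        ds = mg.assemble_dataset(fx.records, fx.labels)
        ds.label_mask[:, 1] = 0.0  # task 1 entirely unobserved
        return ds

    def test_masked_task_head_parameters_bit_unchanged(self):
        ds = self._two_task_data()
        spec = mg.default_model_spec(n_tasks=2, seed=0)
        init = mg.build_model(spec, ds.feature_config)
        fitted = mg.train(init, ds, mg.TrainConfig(epochs=5, seed=0))
        head = f"L{len(spec.layers) - 1}_W"
        # task-1 logit columns (2, 3) receive zero gradient -> bitwise equal
        assert np.array_equal(init.params[head][:, 2:4], fitted.params[head][:, 2:4])
        assert not np.array_equal(init.params[head][:, 0:2], fitted.params[head][:, 0:2])

    def test_finite_difference_gradient_of_masked_entry_is_zero(self):
        ds = self._two_task_data().subset(np.arange(6))
        spec = mg.default_model_spec(n_tasks=2, seed=0)
        model = mg.build_model(spec, ds.feature_config)
        batch = gcncore.dataset_batch(ds)
        head = f"L{len(spec.layers) - 1}_W"

        def loss_with(delta):
            m = model.copy()
            m.params[head] = m.params[head].copy()
            m.params[head][0, 2] += delta  # a masked task's head weight
            logits = m.logits(batch)
            return float(gcncore.masked_cross_entropy(
                logits, ds.labels, ds.label_mask).data)

        h = 1e-4
        assert (loss_with(h) - loss_with(-h)) / (2 * h) == pytest.approx(0.0, abs=1e-10)


class TestPrediction:
    def test_probabilities_lie_in_unit_interval(self, small_dataset, planted_model):
        probs = planted_model.predict(small_dataset)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_softmax_head_normalizes_per_task(self, small_dataset, planted_model):
        batch = gcncore.dataset_batch(small_dataset)
        logits = planted_model.trained.logits(batch).data
        p = np.exp(logits - logits.max(axis=2, keepdims=True))
        p /= p.sum(axis=2, keepdims=True)
        assert np.allclose(p.sum(axis=2), 1.0, atol=1e-6)

    def test_inference_is_deterministic(self, small_dataset, planted_model):
        a = planted_model.predict(small_dataset)
        b = planted_model.predict(small_dataset)
        assert np.array_equal(a, b)

    def test_padding_invariance(self, small_dataset, planted_model):
        graphs = [mg.normalize_adjacency(g) for g in small_dataset.graphs[:5]]
        tight = mg.pad_and_batch(graphs)
        loose = mg.pad_and_batch(graphs, max_nodes=tight.max_nodes + 7)
        a = planted_model.trained.logits(tight).data
        b = planted_model.trained.logits(loose).data
        assert np.allclose(a, b, atol=1e-5)

    def test_permutation_invariance_of_predictions(self, small_dataset, planted_model):
        rng = np.random.default_rng(0)
        g = small_dataset.graphs[3]
        ng = mg.normalize_adjacency(g)
        base = planted_model.trained.logits(mg.pad_and_batch([ng])).data
        for _ in range(5):
            perm = rng.permutation(g.n_nodes)
            permuted = mg.MolecularGraph(
                n_nodes=g.n_nodes,
                adjacency={t: a[np.ix_(perm, perm)] for t, a in g.adjacency.items()},
                features=g.features[perm],
                atom_symbols=[g.atom_symbols[i] for i in perm],
                id=g.id,
            )
            out = planted_model.trained.logits(
                mg.pad_and_batch([mg.normalize_adjacency(permuted)])).data
            assert np.allclose(out, base, atol=1e-5)


class TestModelSerialization:
    def test_save_load_roundtrip_is_lossless(self, small_dataset, planted_model, tmp_path):
        path = str(tmp_path / "model.npz")
        planted_model.save(path)
        back = mg.TrainedModel.load(path)
        assert back.spec.to_dict() == planted_model.trained.spec.to_dict()
        assert all(np.array_equal(back.params[k], planted_model.params[k])
                   for k in back.params)
        a = mg.predict(back, small_dataset)
        b = planted_model.predict(small_dataset)
        assert np.array_equal(a, b)


class TestSequenceEncoder:
    def test_identical_sequences_encode_identically(self):
        enc = gcncore.default_sequence_encoder(max_len=20)
        r = gcncore.tokenize_sequence("MKVLAA", 20)
        a = gcncore.encode_sequence(r, enc, seed=1)
        b = gcncore.encode_sequence(r, enc, seed=1)
        assert np.array_equal(a, b)

    def test_padding_does_not_change_encoding(self):
        enc = gcncore.default_sequence_encoder(max_len=30)
        short = gcncore.encode_sequence(gcncore.tokenize_sequence("ACDKW", 8), enc, seed=2)
        long = gcncore.encode_sequence(gcncore.tokenize_sequence("ACDKW", 30), enc, seed=2)
        assert np.allclose(short, long, atol=1e-12)

    def test_all_pad_sequence_pools_to_zero_input_output(self):
        enc = gcncore.default_sequence_encoder(max_len=10)
        rec = gcncore.SequenceRecord(np.zeros(10, dtype=int), 10)
        out = gcncore.encode_sequence(rec, enc, seed=3)
        assert np.allclose(out, 0.0)  # zero pooled vector through zero-bias dense

    def test_token_outside_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            gcncore.SequenceRecord(np.array([0, 99, 1]), 3)

    def test_multimodal_training_runs_and_learns(self):
        fx = mg.generate_fixture(mg.FixtureSpec(n_molecules=30, label_noise=0.0, seed=3))
        ds = mg.assemble_dataset(fx.records, fx.labels)
        rng = np.random.default_rng(0)
        ds.modalities["protein"] = np.stack([
            gcncore.tokenize_sequence(
                "".join(rng.choice(list(gcncore.AA_ALPHABET), 25)), 30).tokens
            for _ in range(len(ds))
        ])
        enc = gcncore.default_sequence_encoder(max_len=30)
        spec = mg.default_model_spec(modality_encoders={"protein": enc}, seed=0)
        res = mg.GraphConvModel(spec, ds).fit(epochs=8, seed=0)
        assert res.history[-1] < res.history[0]
        assert res.predict().shape == (30, 1)


class TestAUC:
    def test_hand_counted_three_of_four_pairs(self):
        # pairs: (0.9 vs 0.8) c, (0.9 vs 0.2) c, (0.3 vs 0.8) d, (0.3 vs 0.2) c
        auc = mg.evaluate_auc(np.array([0.9, 0.3, 0.8, 0.2]),
                              np.array([1, 1, 0, 0]))
        assert auc[0] == pytest.approx(0.75)

    def test_perfect_separation_and_all_ties(self):
        assert mg.evaluate_auc(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0]))[0] == 1.0
        assert mg.evaluate_auc(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0]))[0] == 0.5

    def test_single_class_task_flagged_not_fatal(self):
        out = mg.evaluate_auc(np.array([[0.1], [0.9]]), np.array([[1], [1]]))
        assert np.isnan(out[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_on_random_scores(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50).round(1)  # force ties
        assert mg.evaluate_auc(s, y)[0] == pytest.approx(roc_auc_score(y, s))


class TestCrossValidation:
    def test_report_structure_and_determinism(self, small_dataset):
        spec = mg.default_model_spec(seed=0)
        cfg = mg.TrainConfig(epochs=4, seed=0)
        a = mg.run_cross_validation(spec, small_dataset, k=5, config=cfg, seed=11)
        b = mg.run_cross_validation(spec, small_dataset, k=5, config=cfg, seed=11)
        assert a == b
        assert len(a["tasks"]["task0"]["fold_aucs"]) == 5
        assert a["fold_sizes"] == [8, 8, 8, 8, 8]
        assert a["tasks"]["task0"]["mean_auc"] is not None
        assert a["tasks"]["task0"]["sd_auc"] >= 0.0

    def test_k_exceeding_n_is_an_error(self, small_dataset):
        from molgcn.errors import SplitError
        with pytest.raises(SplitError):
            mg.run_cross_validation(mg.default_model_spec(seed=0),
                                    small_dataset.subset(np.arange(3)), k=5)

    def test_results_summary_mentions_auc(self, small_dataset):
        res = mg.GraphConvModel(mg.default_model_spec(seed=0), small_dataset).fit(
            epochs=5, seed=0)
        text = res.summary()
        assert "ROC-AUC" in text and "graph_conv" in text
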