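"""Multi-task network forward/loss/training contracts and baselines."""

import math
from dataclasses import replace

import numpy as np
import pytest

import kinoscreen as ks
from kinoscreen.datasets import TrainingView, ViewMode
from kinoscreen.models import (
    DegenerateTaskError,
    NetworkSpec,
    TaskLossWeights,
    TrainedModel,
    _MLPParams,
    load_model,
    save_model,
)


def make_view(features, labels, mask=None, mode=ViewMode.KA_PI):
    n, t = labels.shape
    return TrainingView(
        mode=mode,
        compounds=[f"c{i:04d}" for i in range(n)],
        tasks=[f"k{j}" for j in range(t)],
        features=np.asarray(features, dtype=np.uint8),
        label_matrix=np.asarray(labels, dtype=np.int8),
        mask=np.ones((n, t), dtype=bool) if mask is None else np.asarray(mask, dtype=bool),
    )


def separable_view(n=200, seed=0):
    """Two tasks with disjoint defining bit signatures; linearly separable."""
    rng = np.random.default_rng(seed)
    x = (rng.random((n, 64)) < 0.1).astype(np.uint8)
    x[:, :20] = 0
    labels = np.zeros((n, 2), dtype=np.int8)
    a0 = rng.choice(n, 30, replace=False)
    rest = np.setdiff1d(np.arange(n), a0)
    a1 = rng.choice(rest, 30, replace=False)
    x[np.ix_(a0, range(0, 10))] = 1
    x[np.ix_(a1, range(10, 20))] = 1
    labels[a0, 0] = 1
    labels[a1, 1] = 1
    return make_view(x, labels)


def untrained_model(spec, seed=0):
    return TrainedModel(model_type="mtdnn", tasks=[f"k{j}" for j in range(spec.n_tasks)],
                        spec=spec, params=_MLPParams(spec, np.random.default_rng(seed)))


class TestForward:
    def test_zero_head_gives_half_everywhere(self):
        spec = NetworkSpec(input_dim=16, hidden_sizes=(8,), n_tasks=3)
        model = untrained_model(spec)
        p = model.predict_proba(np.eye(16, dtype=np.uint8))
        assert np.allclose(p, 0.5)

    def test_class_pair_probabilities_sum_to_one(self):
        spec = NetworkSpec(input_dim=16, hidden_sizes=(8,), n_tasks=2)
        model = untrained_model(spec)
        rng = np.random.default_rng(1)
        model.params.W[-1][:] = rng.normal(size=model.params.W[-1].shape)
        from kinoscreen.models import _forward_trunk, _head_probs

        x = (rng.random((9, 16)) < 0.4).astype(np.float32)
        probs = _head_probs(model.params, _forward_trunk(model.params, x)[-1], 2)
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-6)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_hand_computed_relu_softmax_chain(self):
        # 2-bit input, one hidden unit: h = relu(w1.x + b1), logits = w2*h
        spec = NetworkSpec(input_dim=2, hidden_sizes=(1,), n_tasks=1)
        model = untrained_model(spec)
        model.params.W[0][:, 0] = [1.5, -2.0]
        model.params.b[0][0] = 0.25
        model.params.W[1][0, :] = [0.5, 1.0]  # inactive, active neuron
        model.params.b[1][:] = [0.0, -0.3]
        x = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.uint8)
        h = np.maximum(np.array([1.75, -1.75, -0.25]), 0.0)
        z_in, z_act = 0.5 * h, 1.0 * h - 0.3
        expected = np.exp(z_act) / (np.exp(z_act) + np.exp(z_in))
        assert np.allclose(model.predict_proba(x)[:, 0], expected, atol=1e-6)

    def test_feature_width_mismatch(self):
        spec = NetworkSpec(input_dim=16, hidden_sizes=(4,), n_tasks=1)
        with pytest.raises(ValueError):
            untrained_model(spec).predict_proba(np.zeros((3, 8)))

    def test_invariant_to_batch_partitioning(self, kapi_view):
        spec = NetworkSpec(input_dim=1024, hidden_sizes=(16,), n_tasks=5, epochs=2)
        plan = ks.random_stratified_split(kapi_view, seed=0)
        model = ks.train_mtdnn(kapi_view, plan, spec)
        x = kapi_view.features
        assert np.allclose(model.predict_proba(x, batch_size=17),
                           model.predict_proba(x, batch_size=100_000), atol=1e-6)


class TestMaskedCrossEntropy:
    def test_perfect_predictions_near_zero(self):
        y = np.array([[1, 0], [0, 1]], dtype=float)
        p = np.where(y == 1, 1.0, 0.0)
        loss = ks.masked_cross_entropy(p, y, np.ones_like(y))
        assert loss <= 2 * 1e-7 * abs(math.log(1e-7))

    def test_coin_flip_is_log_two(self):
        y = np.array([[1, 0, 1]], dtype=float)
        p = np.full_like(y, 0.5)
        assert ks.masked_cross_entropy(p, y, np.ones_like(y)) == pytest.approx(math.log(2))

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = rng.uniform(0.01, 0.99, size=(7, 4))
            y = (rng.random((7, 4)) < 0.5).astype(float)
            m = (rng.random((7, 4)) < 0.7).astype(float)
            w = TaskLossWeights(rng.uniform(0.5, 2.0, size=4).astype(np.float32))
            total, count = 0.0, 0.0
            for i in range(7):
                for t in range(4):
                    if m[i, t]:
                        ce = -(y[i, t] * math.log(p[i, t])
                               + (1 - y[i, t]) * math.log(1 - p[i, t]))
                        total += float(w.weights[t]) * ce
                        count += 1
            assert ks.masked_cross_entropy(p, y, m, w) == pytest.approx(
                total / count, abs=1e-6)

    def test_fully_masked_input_is_zero(self):
        y = np.ones((3, 2))
        assert ks.masked_cross_entropy(np.full((3, 2), 0.7), y, np.zeros((3, 2))) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ks.masked_cross_entropy(np.ones((2, 2)), np.ones((2, 3)), np.ones((2, 2)))


class TestTrainMTDNN:
    def test_separable_two_task_reaches_train_auc_one(self):
        view = separable_view()
        plan = ks.random_stratified_split(view, fractions=(1.0, 0.0, 0.0), seed=0)
        # 200 compounds is only 2 batches/epoch at batch size 128, so the
        # epoch budget is sized in SGD steps, not epochs
        spec = NetworkSpec(input_dim=64, hidden_sizes=(32,), n_tasks=2, epochs=500,
                           patience=500, seed=0)
        model = ks.train_mtdnn(view, plan, spec)
        scores = model.predict_proba(view.features)
        for t in range(2):
            task = ks.RankedTask(scores=scores[:, t], labels=view.label_matrix[:, t])
            assert ks.roc_auc(task) == 1.0

    def test_fixed_seed_reproduces_training_log(self, kapi_view):
        plan = ks.random_stratified_split(kapi_view, seed=1)
        spec = NetworkSpec(input_dim=1024, hidden_sizes=(16,), n_tasks=5, epochs=3, seed=4)
        log_a = ks.train_mtdnn(kapi_view, plan, spec).training_log
        log_b = ks.train_mtdnn(kapi_view, plan, spec).training_log
        assert log_a == log_b

    def test_loss_decreases_on_learnable_data(self, kapi_view):
        plan = ks.random_stratified_split(kapi_view, seed=1)
        spec = NetworkSpec(input_dim=1024, hidden_sizes=(32,), n_tasks=5, epochs=8,
                           patience=8, seed=0)
        log = ks.train_mtdnn(kapi_view, plan, spec).training_log
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_refuses_task_without_actives(self):
        view = separable_view()
        view.label_matrix[:, 1] = 0
        plan = ks.random_stratified_split(view, fractions=(1.0, 0.0, 0.0), seed=0)
        spec = NetworkSpec(input_dim=64, hidden_sizes=(8,), n_tasks=2, epochs=2)
        with pytest.raises(DegenerateTaskError) as err:
            ks.train_mtdnn(view, plan, spec)
        assert "k1" in str(err.value)

    def test_fully_masked_task_receives_no_gradient(self):
        """KA-KI contract: unlabeled tasks contribute no parameter update."""
        view = separable_view()
        mask = np.ones_like(view.label_matrix, dtype=bool)
        mask[:, 1] = False  # task k1 entirely unlabeled
        masked = make_view(view.features, view.label_matrix, mask=mask,
                           mode=ViewMode.KA_KI)
        plan = ks.random_stratified_split(masked, fractions=(1.0, 0.0, 0.0), seed=0)
        spec = NetworkSpec(input_dim=64, hidden_sizes=(8,), n_tasks=2, epochs=5,
                           patience=5, seed=0)
        model = ks.train_mtdnn(masked, plan, spec, check_degenerate=False)
        head = model.params.W[-1]
        # heads start at zero; the masked task's columns must remain zero
        assert np.all(head[:, 2:4] == 0.0)
        assert np.any(head[:, 0:2] != 0.0)
        assert np.all(model.params.b[-1][2:4] == 0.0)


class TestBaselines:
    def test_stdnn_equals_mtdnn_single_task(self):
        view = separable_view()
        single = make_view(view.features, view.label_matrix[:, [0]])
        plan = ks.random_stratified_split(single, seed=0)
        spec = NetworkSpec(input_dim=64, hidden_sizes=(16,), n_tasks=1, epochs=5, seed=2)
        mt = ks.train_mtdnn(single, plan, spec)
        st = ks.train_baseline(single, plan, "stdnn", task="k0", spec=spec)
        assert np.allclose(mt.predict_proba(view.features)[:, 0],
                           st.predict_proba(view.features)[:, 0])

    def test_naive_bayes_unique_bit_forces_perfect_ranking(self):
        rng = np.random.default_rng(0)
        x = (rng.random((120, 32)) < 0.2).astype(np.uint8)
        x[:, 5] = 0
        labels = np.zeros((120, 1), dtype=np.int8)
        actives = rng.choice(120, 15, replace=False)
        labels[actives, 0] = 1
        x[actives, 5] = 1  # the defining bit
        view = make_view(x, labels)
        plan = ks.random_stratified_split(view, fractions=(1.0, 0.0, 0.0), seed=0)
        model = ks.train_baseline(view, plan, "naive_bayes", task="k0")
        task = ks.RankedTask(scores=model.predict_proba(x)[:, 0], labels=labels[:, 0])
        assert ks.roc_auc(task) == 1.0

    def test_mt_random_forest_default_tree_count(self, kapi_view):
        plan = ks.random_stratified_split(kapi_view, seed=0)
        model = ks.train_baseline(kapi_view, plan, "mt_random_forest")
        assert model.sk_model.n_estimators == 100
        p = model.predict_proba(kapi_view.features[:10])
        assert p.shape == (10, 5)
        assert np.all((p >= 0) & (p <= 1))

    def test_single_task_models_fill_only_their_column(self, kapi_view):
        plan = ks.random_stratified_split(kapi_view, seed=0)
        model = ks.train_baseline(kapi_view, plan, "logreg", task="KIN002")
        p = model.predict_proba(kapi_view.features[:8])
        assert np.all(np.isnan(p[:, [0, 1, 3, 4]]))
        assert np.all(~np.isnan(p[:, 2]))

    def test_single_task_requires_task_id(self, kapi_view):
        plan = ks.random_stratified_split(kapi_view, seed=0)
        with pytest.raises(ValueError):
            ks.train_baseline(kapi_view, plan, "logreg")

    def test_unknown_algorithm(self, kapi_view):
        plan = ks.random_stratified_split(kapi_view, seed=0)
        with pytest.raises(ValueError):
            ks.train_baseline(kapi_view, plan, "svm", task="KIN000")


class TestScreen:
    def _model(self, scores):
        class Stub:
            tasks = [f"k{j}" for j in range(scores.shape[1])]

            def predict_proba(self, x, batch_size=4096):
                return scores

        return Stub()

    def test_full_fraction_is_permutation(self):
        rng = np.random.default_rng(0)
        scores = rng.random((50, 2))
        out = ks.screen(self._model(scores), np.zeros((50, 4)), 1.0)
        for t in ("k0", "k1"):
            sub = out[out.task_id == t]
            assert sorted(sub.compound_id) == [f"C{i:06d}" for i in range(50)]

    def test_ceiling_arithmetic(self):
        rng = np.random.default_rng(1)
        scores = rng.random((10_000, 1))
        out = ks.screen(self._model(scores), np.zeros((10_000, 4)), 0.001)
        assert len(out) == 10

    def test_ranks_agree_with_argsort_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.random((40, 1))
        out = ks.screen(self._model(scores), np.zeros((40, 4)), 1.0)
        oracle = np.argsort(-scores[:, 0], kind="stable")
        assert list(out.compound_id) == [f"C{i:06d}" for i in oracle]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.1])
    def test_fraction_bounds(self, bad):
        with pytest.raises(ValueError):
            ks.screen(self._model(np.ones((5, 1))), np.zeros((5, 4)), bad)


def test_checkpoint_round_trip(tmp_path):
    view = separable_view()
    plan = ks.random_stratified_split(view, seed=0)
    spec = NetworkSpec(input_dim=64, hidden_sizes=(8,), n_tasks=2, epochs=2, seed=1)
    model = ks.train_mtdnn(view, plan, spec)
    save_model(model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    assert back.spec == model.spec
    assert np.allclose(back.predict_proba(view.features),
                       model.predict_proba(view.features))
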