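"""Multi-task and single-task classifiers behind one train/predict contract.

The centerpiece is a feed-forward multi-task deep neural network
(MTDNN): hidden ReLU layers shared across all kinase tasks, and for
each task a two-neuron softmax output head giving P(active | compound).
The training objective is the weighted sum over tasks of the per-task
cross-entropy, with a per-entry mask so that unlabeled (compound, task)
cells — the empty cells of a KA-KI view — contribute no loss and no
gradient. Optimization is plain mini-batch SGD with momentum and
inverted dropout on the hidden activations, implemented directly in
NumPy so the whole chain (forward, backward, update) is explicit and
seed-reproducible on a single thread.

Baselines sharing the same forward contract (a per-task probability
matrix): a single-task DNN (the same network with T=1), per-task
logistic regression / random forest / Bernoulli naive Bayes from
scikit-learn, and a multi-task random forest fit jointly on the label
matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import TrainingView
from .splits import SplitPlan

EPS = 1e-7

BASELINE_ALGORITHMS = ("logreg", "random_forest", "naive_bayes", "stdnn", "mt_random_forest")


class DegenerateTaskError(ValueError):
    """Raised when training is requested on tasks with no active labels."""

    def __init__(self, tasks: Sequence[str]):
        self.tasks = list(tasks)
        super().__init__(f"no active labels in the training partition for tasks: {self.tasks}")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and optimization hyperparameters of the (MT/ST)DNN.

    Defaults follow the tuned configuration of the reference study:
    1024-bit fingerprint input, two hidden layers of 2000 and 500 ReLU
    units, 25% dropout, SGD at learning rate 3e-4 with batch size 128.
    Momentum, decay and epoch budget are exposed because they were tuned
    but not printed; the defaults are conventional SGD settings.
    """

    input_dim: int = 1024
    hidden_sizes: tuple[int, ...] = (2000, 500)
    n_tasks: int = 1
    dropout_rate: float = 0.25
    learning_rate: float = 3e-4
    batch_size: int = 128
    momentum: float = 0.9
    decay: float = 0.0
    epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def desk_scale(cls, n_tasks: int, seed: int = 0, epochs: int = 150) -> "NetworkSpec":
        """A reduced profile (256x128 hidden units) for laptop-scale runs.

        Same architecture family and optimizer; only the layer widths
        and epoch budget shrink so that cross-validation on tens of
        thousands of compounds completes in minutes on one CPU core.
        """
        return cls(hidden_sizes=(256, 128), n_tasks=n_tasks, seed=seed, epochs=epochs)


@dataclass
class TaskLossWeights:
    """Per-task weights w_t of the summed cross-entropy objective."""

    weights: np.ndarray  # (T,) positive

    @classmethod
    def uniform(cls, n_tasks: int) -> "TaskLossWeights":
        return cls(np.ones(n_tasks, dtype=np.float32))

    @classmethod
    def inverse_prevalence(cls, view: TrainingView) -> "TaskLossWeights":
        """w_t proportional to 1 / active-fraction, normalized to mean 1."""
        counts = view.active_counts().astype(np.float64)
        totals = view.mask.sum(axis=0).astype(np.float64)
        prev = np.clip(counts / np.maximum(totals, 1), 1e-6, None)
        w = 1.0 / prev
        w = w / w.mean()
        return cls(w.astype(np.float32))

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float32)
        if np.any(self.weights <= 0):
            raise ValueError("task loss weights must be positive")


def masked_cross_entropy(
    probabilities: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    weights: TaskLossWeights | None = None,
) -> float:
    """Weighted masked binary cross-entropy, averaged over unmasked entries.

    ``probabilities`` holds P(active) per (compound, task); values are
    clamped to [EPS, 1-EPS] before the log. Masked cells contribute
    nothing to either the sum or the normalizer.
    """
    p = np.clip(np.asarray(probabilities, dtype=np.float64), EPS, 1 - EPS)
    y = np.asarray(labels, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    if not (p.shape == y.shape == m.shape):
        raise ValueError("probabilities, labels and mask must have identical shapes")
    w = np.ones(p.shape[1]) if weights is None else weights.weights.astype(np.float64)
    ce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    total = float((ce * m * w[None, :]).sum())
    n_unmasked = float(m.sum())
    if n_unmasked == 0:
        return 0.0
    return total / n_unmasked


class _MLPParams:
    """Weight matrices and biases of the shared trunk plus the 2T-wide head."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        sizes = [spec.input_dim, *spec.hidden_sizes, 2 * spec.n_tasks]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He-style fan-in uniform initialization, seeded
            limit = math.sqrt(6.0 / fan_in)
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32))
            self.b.append(np.zeros(fan_out, dtype=np.float32))
        # zero-initialized softmax heads: every task starts at P(active)=0.5,
        # so initial rankings carry no random-projection bias
        self.W[-1][:] = 0.0

    def copy(self) -> "_MLPParams":
        new = object.__new__(_MLPParams)
        new.W = [w.copy() for w in self.W]
        new.b = [b.copy() for b in self.b]
        return new


def _forward_trunk(params: _MLPParams, x: np.ndarray, dropout_rate: float = 0.0,
                   rng: np.random.Generator | None = None):
    """Hidden-layer pass; returns activations per layer (pre-head)."""
    acts = [x]
    h = x
    for W, b in zip(params.W[:-1], params.b[:-1]):
        z = h @ W + b
        h = np.maximum(z, 0.0)
        if dropout_rate > 0.0 and rng is not None:
            keep = (rng.random(h.shape) >= dropout_rate).astype(np.float32)
            h = h * keep / (1.0 - dropout_rate)
        acts.append(h)
    return acts


def _head_probs(params: _MLPParams, h: np.ndarray, n_tasks: int) -> np.ndarray:
    """Per-task two-neuron softmax; returns (batch, T, 2) probabilities."""
    logits = (h @ params.W[-1] + params.b[-1]).reshape(h.shape[0], n_tasks, 2)
    logits = logits - logits.max(axis=2, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=2, keepdims=True)


@dataclass
class TrainedModel:
    """A fitted classifier exposing the per-task P(active) contract.

    ``model_type`` is one of mtdnn | stdnn | logreg | random_forest |
    naive_bayes | mt_random_forest. Single-task models fill only their
    own task's column; the others are NaN.
    """

    model_type: str
    tasks: list[str]
    spec: NetworkSpec | None = None
    params: _MLPParams | None = None
    sk_model: object | None = None
    task_index: int | None = None
    training_log: list[dict] = field(default_factory=list)

    def predict_proba(self, features: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """P(active) matrix of shape (n_compounds, n_tasks); dropout off."""
        x = np.asarray(features, dtype=np.float32)
        T = len(self.tasks)
        if self.params is not None:
            if x.shape[1] != self.spec.input_dim:
                raise ValueError(
                    f"feature width {x.shape[1]} != input_dim {self.spec.input_dim}"
                )
            chunks = []
            for start in range(0, x.shape[0], batch_size):
                h = _forward_trunk(self.params, x[start : start + batch_size])[-1]
                probs = _head_probs(self.params, h, self.spec.n_tasks)
                chunks.append(probs[:, :, 1])
            p = np.concatenate(chunks, axis=0) if chunks else np.zeros((0, self.spec.n_tasks))
            if self.task_index is not None:  # STDNN: one task's column only
                out = np.full((x.shape[0], T), np.nan)
                out[:, self.task_index] = p[:, 0]
                return out
            return p.astype(np.float64)
        if self.model_type == "mt_random_forest":
            out = np.empty((x.shape[0], T))
            per_output = self.sk_model.predict_proba(x)
            classes_list = self.sk_model.classes_
            if isinstance(per_output, np.ndarray):  # sklearn collapses T=1 output
                per_output, classes_list = [per_output], [classes_list]
            for t, probs in enumerate(per_output):
                classes = list(classes_list[t])
                out[:, t] = probs[:, classes.index(1)] if 1 in classes else 0.0
            return out
        # per-task scikit-learn single-task model
        out = np.full((x.shape[0], T), np.nan)
        classes = list(self.sk_model.classes_)
        out[:, self.task_index] = (
            self.sk_model.predict_proba(x)[:, classes.index(1)] if 1 in classes else 0.0
        )
        return out


def _check_trainable(labels: np.ndarray, mask: np.ndarray, tasks: Sequence[str]) -> None:
    active = (labels * mask).sum(axis=0)
    empty = [tasks[t] for t in np.flatnonzero(active == 0)]
    if empty:
        raise DegenerateTaskError(empty)


def train_mtdnn(
    view: TrainingView,
    split: SplitPlan,
    spec: NetworkSpec,
    weights: TaskLossWeights | None = None,
    test_fold: int | None = None,
    check_degenerate: bool = True,
) -> TrainedModel:
    """Fit the multi-task network on the split's train partition.

    Uses the plan's named train/valid partitions when present (holdout
    plans), otherwise derives them from the fold assignment with
    ``test_fold`` held out. Returns the parameters of the best
    validation-loss epoch (early stopping, patience from the spec).
    """
    if split.partitions:
        parts = split.partitions
    else:
        parts = split.cv_partitions(split.n_folds - 1 if test_fold is None else test_fold)
    train_idx, valid_idx = parts["train"], parts.get("valid", np.empty(0, dtype=int))

    if spec.n_tasks != view.n_tasks:
        spec = replace(spec, n_tasks=view.n_tasks)
    x = np.asarray(view.features, dtype=np.float32)
    y = view.label_matrix.astype(np.float32)
    m = view.mask.astype(np.float32)
    if check_degenerate:
        _check_trainable(y[train_idx], m[train_idx], view.tasks)
    if weights is None:
        weights = TaskLossWeights.uniform(view.n_tasks)
    w = weights.weights

    rng = np.random.default_rng(spec.seed)
    params = _MLPParams(spec, rng)
    velocity = _MLPParams(spec, np.random.default_rng(0))
    for vw, vb in zip(velocity.W, velocity.b):
        vw[:] = 0.0
        vb[:] = 0.0

    def eval_loss(idx: np.ndarray) -> float:
        if len(idx) == 0:
            return float("nan")
        h = _forward_trunk(params, x[idx])[-1]
        p = _head_probs(params, h, spec.n_tasks)[:, :, 1]
        return masked_cross_entropy(p, y[idx], m[idx], weights)

    best_params, best_valid, best_epoch = params.copy(), float("inf"), -1
    log: list[dict] = []
    lr = spec.learning_rate
    n_train = len(train_idx)
    for epoch in range(spec.epochs):
        order = rng.permutation(train_idx)
        for start in range(0, n_train, spec.batch_size):
            batch = order[start : start + spec.batch_size]
            xb, yb, mb = x[batch], y[batch], m[batch]
            acts = _forward_trunk(params, xb, spec.dropout_rate, rng)
            probs = _head_probs(params, acts[-1], spec.n_tasks)  # (B, T, 2)
            # objective: sum_t w_t * mean over unmasked batch entries of CE_t
            counts = mb.sum(axis=0)  # (T,)
            scale = np.where(counts > 0, w / np.maximum(counts, 1.0), 0.0)  # (T,)
            onehot = np.stack([1.0 - yb, yb], axis=2)
            grad_logits = (probs - onehot) * (mb * scale)[:, :, None]
            grad = grad_logits.reshape(xb.shape[0], 2 * spec.n_tasks).astype(np.float32)
            # backprop through the linear stack
            for layer in range(len(params.W) - 1, -1, -1):
                a_in = acts[layer]
                gW = a_in.T @ grad
                gb = grad.sum(axis=0)
                if spec.decay > 0:
                    gW = gW + spec.decay * params.W[layer]
                if layer > 0:
                    grad = (grad @ params.W[layer].T) * (acts[layer] > 0)
                velocity.W[layer] = spec.momentum * velocity.W[layer] - lr * gW
                velocity.b[layer] = spec.momentum * velocity.b[layer] - lr * gb
                params.W[layer] += velocity.W[layer]
                params.b[layer] += velocity.b[layer]
        entry = {"epoch": epoch, "train_loss": eval_loss(train_idx),
                 "valid_loss": eval_loss(valid_idx)}
        log.append(entry)
        monitor = entry["valid_loss"] if len(valid_idx) else entry["train_loss"]
        if monitor < best_valid - 1e-9:
            best_valid, best_params, best_epoch = monitor, params.copy(), epoch
        elif epoch - best_epoch >= spec.patience:
            break
    return TrainedModel(model_type="mtdnn", tasks=list(view.tasks), spec=spec,
                        params=best_params, training_log=log)


def train_baseline(
    view: TrainingView,
    split: SplitPlan,
    algorithm: str,
    task: str | None = None,
    spec: NetworkSpec | None = None,
    test_fold: int | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one of the comparison models under the shared forward contract.

    ``logreg`` / ``random_forest`` / ``naive_bayes`` / ``stdnn`` are
    single-task and require a task id; ``mt_random_forest`` fits 100
    trees jointly on the full label matrix. The STDNN reuses the MTDNN
    hyperparameters with a single output task.
    """
    if algorithm not in BASELINE_ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    single_task = algorithm in ("logreg", "random_forest", "naive_bayes", "stdnn")
    if single_task and task is None:
        raise ValueError(f"algorithm {algorithm!r} requires a task id")

    if split.partitions:
        parts = split.partitions
    else:
        parts = split.cv_partitions(split.n_folds - 1 if test_fold is None else test_fold)
    train_idx = parts["train"]

    if algorithm == "stdnn":
        t = view.tasks.index(task)
        sub = TrainingView(
            mode=view.mode, compounds=list(view.compounds), tasks=[task],
            features=view.features, label_matrix=view.label_matrix[:, [t]],
            mask=view.mask[:, [t]],
        )
        if spec is None:
            spec = NetworkSpec(n_tasks=1)
        model = train_mtdnn(sub, split, replace(spec, n_tasks=1), test_fold=test_fold)
        return TrainedModel(model_type="stdnn", tasks=list(view.tasks), spec=model.spec,
                            params=model.params, task_index=t,
                            training_log=model.training_log)

    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import BernoulliNB

    x = np.asarray(view.features, dtype=np.float32)
    if algorithm == "mt_random_forest":
        y = np.asarray(view.label_matrix[train_idx], dtype=int)
        _check_trainable(y, np.ones_like(y), view.tasks)
        clf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        clf.fit(x[train_idx], y)
        return TrainedModel(model_type=algorithm, tasks=list(view.tasks), sk_model=clf)

    t = view.tasks.index(task)
    rows = train_idx[view.mask[train_idx, t]]
    y = view.label_matrix[rows, t].astype(int)
    if y.sum() == 0:
        raise DegenerateTaskError([task])
    if algorithm == "logreg":
        clf = LogisticRegression(max_iter=1000, random_state=seed)
    elif algorithm == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    else:
        clf = BernoulliNB()
    clf.fit(x[rows], y)
    return TrainedModel(model_type=algorithm, tasks=list(view.tasks), sk_model=clf,
                        task_index=t)


def screen(
    model: TrainedModel,
    library: np.ndarray,
    top_fraction: float,
    compound_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank a screening library per task and keep the top fraction.

    Returns a DataFrame (task_id, compound_id, p_active, rank) with
    ceil(top_fraction * N) rows per task; descending score, ties broken
    by compound id so the ranking is stable.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    probs = model.predict_proba(library)
    n = probs.shape[0]
    if compound_ids is None:
        compound_ids = [f"C{i:06d}" for i in range(n)]
    compound_ids = np.asarray([str(c) for c in compound_ids])
    k = math.ceil(top_fraction * n)
    frames = []
    for t, task in enumerate(model.tasks):
        scores = probs[:, t]
        if np.all(np.isnan(scores)):
            continue
        order = np.lexsort((compound_ids, -scores))[:k]
        frames.append(pd.DataFrame({
            "task_id": task,
            "compound_id": compound_ids[order],
            "p_active": scores[order],
            "rank": np.arange(1, len(order) + 1),
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["task_id", "compound_id", "p_active", "rank"]
    )


def cross_validate(
    view: TrainingView,
    split: SplitPlan,
    spec: NetworkSpec | None = None,
    algorithm: str = "mtdnn",
    eval_view: TrainingView | None = None,
    check_degenerate: bool = True,
):
    """k-fold cross-validation of the MTDNN (or mt_random_forest).

    For each fold: train on the remaining folds (with a 10% validation
    carve-out for early stopping), score the held-out fold, and compute
    per-task reports. Labels come from ``eval_view`` when given (the
    KA-KI-trained / KA-PI-evaluated protocol), else from ``view``.
    Returns a list of per-fold TaskReport lists.
    """
    from .metrics import evaluate_tasks

    if eval_view is None:
        eval_view = view
    fold_reports = []
    for fold in range(split.n_folds):
        parts = split.cv_partitions(fold)
        plan = SplitPlan(strategy=split.strategy, n_folds=split.n_folds,
                         assignments=split.assignments, seed=split.seed,
                         partitions=parts)
        if algorithm == "mtdnn":
            model = train_mtdnn(view, plan, spec or NetworkSpec(n_tasks=view.n_tasks),
                                check_degenerate=check_degenerate)
        elif algorithm == "mt_random_forest":
            model = train_baseline(view, plan, algorithm)
        else:
            raise ValueError("cross_validate covers the multi-task models")
        test = parts["test"]
        scores = model.predict_proba(view.features[test])
        reports = evaluate_tasks(scores, eval_view.label_matrix[test],
                                 view.tasks, mask=eval_view.mask[test])
        fold_reports.append(reports)
    return fold_reports


def mean_cv_auc(fold_reports) -> float:
    """Mean AUC over all folds and tasks, skipping degenerate tasks."""
    aucs = [r.auc for reports in fold_reports for r in reports if r.auc is not None]
    return float(np.mean(aucs))


def save_model(model: TrainedModel, prefix) -> None:
    """Checkpoint a DNN model: layer arrays in .npz plus a JSON spec block."""
    if model.params is None:
        raise ValueError("only DNN models have array checkpoints")
    prefix = Path(prefix)
    arrays = {}
    for i, (w, b) in enumerate(zip(model.params.W, model.params.b)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(prefix.with_suffix(".npz"), **arrays)
    spec_block = {
        "model_type": model.model_type,
        "tasks": model.tasks,
        "task_index": model.task_index,
        "spec": {
            "input_dim": model.spec.input_dim,
            "hidden_sizes": list(model.spec.hidden_sizes),
            "n_tasks": model.spec.n_tasks,
            "dropout_rate": model.spec.dropout_rate,
            "learning_rate": model.spec.learning_rate,
            "batch_size": model.spec.batch_size,
            "momentum": model.spec.momentum,
            "decay": model.spec.decay,
            "epochs": model.spec.epochs,
            "patience": model.spec.patience,
            "seed": model.spec.seed,
        },
    }
    prefix.with_suffix(".json").write_text(json.dumps(spec_block, indent=1))


def load_model(prefix) -> TrainedModel:
    """Inverse of :func:`save_model`."""
    prefix = Path(prefix)
    block = json.loads(prefix.with_suffix(".json").read_text())
    spec = NetworkSpec(**{**block["spec"], "hidden_sizes": tuple(block["spec"]["hidden_sizes"])})
    data = np.load(prefix.with_suffix(".npz"))
    params = object.__new__(_MLPParams)
    n_layers = len([k for k in data.files if k.startswith("W")])
    params.W = [data[f"W{i}"] for i in range(n_layers)]
    params.b = [data[f"b{i}"] for i in range(n_layers)]
    return TrainedModel(model_type=block["model_type"], tasks=block["tasks"], spec=spec,
                        params=params, task_index=block["task_index"])
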