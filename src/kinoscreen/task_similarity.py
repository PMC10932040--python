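"""Inter-task chemical similarity of active sets.

For each kinase task, up to 25 structurally diverse actives are picked
by greedy max-min selection on Tanimoto distance; the task's similarity
profile value is then the mean, over all other tasks, of the average
maximum Tanimoto similarity of its diverse actives against the other
task's diverse actives. Tasks whose actives overlap chemically with
many other tasks score near 1 — exactly the regime where a multi-task
model can borrow statistical strength across tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemprep import bulk_tanimoto
from .datasets import ActivityMatrix, Label


@dataclass
class TaskSimilarityMatrix:
    """Diverse representative actives per task and the directed profile."""

    tasks: list[str]
    diverse_sets: dict[str, np.ndarray]  # task -> (k, n_bits) fingerprints
    avg_max_sim: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "task_id": self.tasks,
                "n_diverse": [len(self.diverse_sets[t]) for t in self.tasks],
                "avg_max_sim": [self.avg_max_sim[t] for t in self.tasks],
            }
        )


def select_diverse(actives: np.ndarray, k: int = 25) -> np.ndarray:
    """Greedy max-min selection of ``k`` diverse fingerprints.

    Seeds with the compound of lowest mean similarity to all others,
    then repeatedly adds the compound maximizing its minimum Tanimoto
    distance to the selected set. Ties break toward the lowest row
    index, so selection is deterministic. Returns row indices.
    """
    actives = np.asarray(actives)
    n = actives.shape[0]
    if n == 0:
        raise ValueError("need at least one active to select from")
    if k >= n:
        return np.arange(n)
    sim = bulk_tanimoto(actives, actives)
    mean_sim = (sim.sum(axis=1) - np.diag(sim)) / max(n - 1, 1)
    selected = [int(np.argmin(mean_sim))]
    # min distance (1 - max similarity) from each candidate to the set
    min_dist = 1.0 - sim[:, selected[0]]
    for _ in range(k - 1):
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, 1.0 - sim[:, nxt])
    return np.array(sorted(selected))


def avg_max_similarity(reference_set: np.ndarray, other_set: np.ndarray) -> float:
    """Mean over reference compounds of their max Tanimoto to the other set.

    Directed: the reference task asks how well each of its diverse
    actives is covered by the other task's chemistry, so swapping the
    arguments generally changes the value.
    """
    reference_set = np.asarray(reference_set)
    other_set = np.asarray(other_set)
    if reference_set.shape[0] == 0 or other_set.shape[0] == 0:
        raise ValueError("both fingerprint sets must be non-empty")
    sim = bulk_tanimoto(reference_set, other_set)
    return float(sim.max(axis=1).mean())


def task_similarity_profile(
    matrix: ActivityMatrix,
    fingerprints: np.ndarray,
    k: int = 25,
) -> TaskSimilarityMatrix:
    """Per-task mean of avg-max similarity against every other task.

    ``fingerprints`` rows follow ``matrix.compounds`` order. Expects a
    filtered matrix (tasks with enough actives); raises with fewer than
    two tasks.
    """
    if len(matrix.tasks) < 2:
        raise ValueError("need at least two tasks for a similarity profile")
    cid_index = {c: i for i, c in enumerate(matrix.compounds)}
    diverse: dict[str, np.ndarray] = {}
    for t in matrix.tasks:
        rows = [cid_index[c] for (c, tt), lab in matrix.labels.items()
                if tt == t and lab is Label.ACTIVE and c in cid_index]
        rows = np.array(sorted(rows))
        if len(rows) == 0:
            raise ValueError(f"task {t!r} has no actives with fingerprints")
        fps = fingerprints[rows]
        diverse[t] = fps[select_diverse(fps, k)]
    profile = {}
    for t in matrix.tasks:
        vals = [avg_max_similarity(diverse[t], diverse[u]) for u in matrix.tasks if u != t]
        profile[t] = float(np.mean(vals))
    return TaskSimilarityMatrix(tasks=list(matrix.tasks), diverse_sets=diverse,
                                avg_max_sim=profile)
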