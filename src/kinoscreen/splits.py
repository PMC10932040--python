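"""Cross-validation split strategies and the label-randomization controls.

Three ways of assigning compounds to folds, ordered by how hard they
make the generalization problem:

* random stratified — folds share chemotypes with the training set;
  measures interpolation.
* scaffold/cluster — whole chemical clusters (average-linkage
  agglomerative clustering on Tanimoto distance) are held out together;
  measures generalization to new chemotypes.
* molecular weight — contiguous blocks of the MW-sorted library;
  a crude but independent axis of chemical difference.

Also here: per-task label permutation (the y-randomization control that
should collapse any honest model to AUC 0.5) and nested fractional
subsampling for data-scaling experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .chemprep import bulk_tanimoto
from .datasets import TrainingView, ViewMode

DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)
PARTITION_NAMES = ("train", "valid", "test")


@dataclass
class SplitPlan:
    """Fold assignment of compounds under one strategy.

    ``assignments`` maps each compound position to a fold in
    [0, n_folds); for holdout-style plans ``partitions`` additionally
    names train/valid/test index arrays.
    """

    strategy: str
    n_folds: int
    assignments: np.ndarray  # (N,) int fold index
    seed: int | None = None
    partitions: dict[str, np.ndarray] = field(default_factory=dict)
    cluster_ids: np.ndarray | None = None

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def cv_partitions(self, test_fold: int, valid_fraction: float = 0.1,
                      seed: int | None = None) -> dict[str, np.ndarray]:
        """Train/valid/test indices for one CV iteration.

        The held-out fold is the test set; a random ``valid_fraction``
        of the remaining compounds is carved out for early stopping.
        """
        test = self.fold_indices(test_fold)
        rest = np.flatnonzero(self.assignments != test_fold)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        rest = rng.permutation(rest)
        n_valid = int(round(valid_fraction * len(rest)))
        return {"train": np.sort(rest[n_valid:]), "valid": np.sort(rest[:n_valid]),
                "test": np.sort(test)}


def _check_partition(assignments: np.ndarray, n: int, n_folds: int) -> None:
    assert assignments.shape == (n,)
    assert assignments.min() >= 0 and assignments.max() < n_folds


def random_stratified_split(
    view: TrainingView,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitPlan:
    """Shuffle compounds into train/valid/test holdout partitions.

    Stratified on each compound's total active-label count (binned
    0, 1, 2, >=3): exact per-task stratification across hundreds of
    sparse tasks is infeasible, but preserving the distribution of
    activity-rich compounds keeps each partition's active fraction near
    the global one.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = view.n_compounds
    n_parts = len(fractions)
    n_active = (view.label_matrix * view.mask).sum(axis=1)
    strata = np.minimum(n_active, 3)
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=np.int64)

    # global targets by largest-remainder rounding (sizes exact to +-1)
    targets = np.array(fractions) * n
    global_quota = np.floor(targets).astype(np.int64)
    frac_part = targets - global_quota
    for k in np.argsort(-frac_part)[: n - global_quota.sum()]:
        global_quota[k] += 1

    # per-stratum floor quotas, then hand stratum leftovers to the
    # partitions still short of their global quota (largest local
    # remainder first) — stratified AND exactly sized
    stratum_ids = np.unique(strata)
    stratum_idx = {s: rng.permutation(np.flatnonzero(strata == s)) for s in stratum_ids}
    quotas = {}
    allocated = np.zeros(n_parts, dtype=np.int64)
    remainders = {}
    for s in stratum_ids:
        t = np.array(fractions) * len(stratum_idx[s])
        q = np.floor(t).astype(np.int64)
        quotas[s] = q
        remainders[s] = t - q
        allocated += q
    for s in stratum_ids:
        leftover = len(stratum_idx[s]) - quotas[s].sum()
        for p in np.argsort(-remainders[s]):
            if leftover == 0:
                break
            if allocated[p] < global_quota[p]:
                quotas[s][p] += 1
                allocated[p] += 1
                leftover -= 1
        # any residue (all preferred partitions full) goes wherever room remains
        for p in range(n_parts):
            while leftover > 0 and allocated[p] < global_quota[p]:
                quotas[s][p] += 1
                allocated[p] += 1
                leftover -= 1
    for s in stratum_ids:
        start = 0
        for p in range(n_parts):
            stop = start + quotas[s][p]
            assignments[stratum_idx[s][start:stop]] = p
            start = stop
    _check_partition(assignments, n, n_parts)
    partitions = {
        name: np.sort(np.flatnonzero(assignments == k))
        for k, name in enumerate(PARTITION_NAMES[: len(fractions)])
    }
    return SplitPlan(strategy="random_stratified", n_folds=len(fractions),
                     assignments=assignments, seed=seed, partitions=partitions)


def random_kfold_split(view: TrainingView, n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Plain stratified k-fold assignment for cross-validation.

    Same stratification rule as :func:`random_stratified_split` but with
    equal-size folds instead of holdout fractions.
    """
    n = view.n_compounds
    n_active = (view.label_matrix * view.mask).sum(axis=1)
    strata = np.minimum(n_active, 3)
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=np.int64)
    offset = 0
    for s in np.unique(strata):
        idx = rng.permutation(np.flatnonzero(strata == s))
        folds = (np.arange(len(idx)) + offset) % n_folds
        assignments[idx] = folds
        offset += len(idx)
    _check_partition(assignments, n, n_folds)
    return SplitPlan(strategy="random_stratified", n_folds=n_folds,
                     assignments=assignments, seed=seed)


def cluster_fingerprints(
    fingerprints: np.ndarray,
    target_n_clusters: int = 300,
    linkage: str = "average",
) -> np.ndarray:
    """Agglomerative clustering on Tanimoto distance, cut to ~``target_n_clusters``."""
    n = fingerprints.shape[0]
    n_clusters = min(target_n_clusters, n)
    dist = 1.0 - bulk_tanimoto(fingerprints, fingerprints)
    np.fill_diagonal(dist, 0.0)
    model = AgglomerativeClustering(
        n_clusters=n_clusters, metric="precomputed", linkage=linkage
    )
    return model.fit_predict(dist)


def scaffold_cluster_split(
    fingerprints: np.ndarray,
    target_n_clusters: int = 300,
    n_folds: int = 5,
    seed: int = 0,
    cluster_ids: np.ndarray | None = None,
) -> SplitPlan:
    """Assign whole chemical clusters to folds (no cluster spans two folds).

    Clusters are packed largest-first onto the currently smallest fold
    (greedy size balancing with a seed-shuffled tie order), so fold
    sizes differ by at most the largest cluster size. Precomputed
    ``cluster_ids`` (e.g. Murcko-scaffold groups) may be supplied to
    bypass the clustering step.
    """
    n = fingerprints.shape[0]
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} compounds, got {n}")
    if cluster_ids is None:
        cluster_ids = cluster_fingerprints(fingerprints, target_n_clusters)
    cluster_ids = np.asarray(cluster_ids)
    uniq, sizes = np.unique(cluster_ids, return_counts=True)
    rng = np.random.default_rng(seed)
    tie_order = rng.permutation(len(uniq))
    # sort clusters by decreasing size; shuffled secondary key breaks ties
    order = sorted(range(len(uniq)), key=lambda i: (-sizes[i], tie_order[i]))
    fold_sizes = np.zeros(n_folds, dtype=np.int64)
    assignments = np.empty(n, dtype=np.int64)
    for i in order:
        fold = int(np.argmin(fold_sizes))
        assignments[cluster_ids == uniq[i]] = fold
        fold_sizes[fold] += sizes[i]
    _check_partition(assignments, n, n_folds)
    return SplitPlan(strategy="scaffold_cluster", n_folds=n_folds,
                     assignments=assignments, seed=seed, cluster_ids=cluster_ids)


def murcko_cluster_ids(smiles_list: Sequence[str]) -> np.ndarray:
    """Group compounds by Bemis-Murcko scaffold (optional alternative grouping).

    With diverse libraries the scaffold count approaches the compound
    count, at which point scaffold folds behave like random folds; the
    fingerprint-cluster split is therefore the default.
    """
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    keys = {}
    ids = np.empty(len(smiles_list), dtype=np.int64)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        core = MurckoScaffold.MurckoScaffoldSmiles(mol=mol) if mol is not None else smi
        ids[i] = keys.setdefault(core, len(keys))
    return ids


def molweight_split(
    weights: Sequence[float],
    n_folds: int = 5,
    compound_ids: Sequence[str] | None = None,
) -> SplitPlan:
    """Sort by increasing molecular weight and cut into contiguous fifths.

    Ties are broken by compound id so the assignment is deterministic.
    """
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    if compound_ids is None:
        compound_ids = [str(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (weights[i], str(compound_ids[i])))
    assignments = np.empty(n, dtype=np.int64)
    bounds = [round(k * n / n_folds) for k in range(n_folds + 1)]
    for fold in range(n_folds):
        for pos in range(bounds[fold], bounds[fold + 1]):
            assignments[order[pos]] = fold
    _check_partition(assignments, n, n_folds)
    return SplitPlan(strategy="molweight", n_folds=n_folds, assignments=assignments)


def permute_labels(view: TrainingView, seed: int = 0) -> TrainingView:
    """y-randomization: per task, replace the active set by a random one
    of the same size; features untouched.

    Only meaningful for the KA-PI surface, where every cell carries a
    label. A model trained on the permuted view has nothing to learn and
    should score AUC ~= 0.5.
    """
    if view.mode is not ViewMode.KA_PI:
        raise ValueError("label permutation is defined on the KA-PI view")
    rng = np.random.default_rng(seed)
    n = view.n_compounds
    labels = np.zeros_like(view.label_matrix)
    for t in range(view.n_tasks):
        n_active = int(view.label_matrix[:, t].sum())
        chosen = rng.choice(n, size=n_active, replace=False)
        labels[chosen, t] = 1
    return TrainingView(mode=view.mode, compounds=list(view.compounds),
                        tasks=list(view.tasks), features=view.features,
                        label_matrix=labels, mask=np.ones_like(view.mask))


def subsample_fraction(view: TrainingView, fraction: float, seed: int = 0) -> TrainingView:
    """Uniform compound subsample of the stated fraction; task list unchanged.

    Implemented as a prefix of one seed-shuffled order, so subsamples at
    increasing fractions under the same seed are nested.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = view.n_compounds
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    keep = np.sort(order[: int(round(fraction * n))])
    return TrainingView(
        mode=view.mode,
        compounds=[view.compounds[i] for i in keep],
        tasks=list(view.tasks),
        features=view.features[keep],
        label_matrix=view.label_matrix[keep],
        mask=view.mask[keep],
    )


def write_split_plan(plan: SplitPlan, compound_ids: Sequence[str], prefix) -> None:
    """Serialize a SplitPlan as CSV (compound_id, fold, partition) + JSON manifest."""
    prefix = Path(prefix)
    partition_of = {}
    for name, idx in plan.partitions.items():
        for i in idx:
            partition_of[int(i)] = name
    pd.DataFrame(
        {
            "compound_id": list(compound_ids),
            "fold": plan.assignments,
            "partition": [partition_of.get(i, "") for i in range(len(compound_ids))],
        }
    ).to_csv(prefix.with_suffix(".csv"), index=False)
    manifest = {"strategy": plan.strategy, "n_folds": plan.n_folds, "seed": plan.seed}
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
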