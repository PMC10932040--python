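"""Synthetic sparse multi-task bioactivity data.

Real kinome bioactivity matrices have three structural features this
generator reproduces: (i) per-task active fractions spanning orders of
magnitude (a long-tailed active-count distribution across tasks),
(ii) heavy chemical sharing between tasks — many kinases are inhibited
by overlapping chemotypes — and (iii) features in which activity is
carried by a sparse subset of fingerprint bits (a pharmacophore-like
latent pattern) on top of random background bits.

Mechanism: ``k_latent`` latent bit-patterns are sampled; each compound
carries each pattern independently with a small probability and its
fingerprint is the union of background noise bits and the bits of the
patterns it carries. Each task is assigned one pattern (drawn from a
small shared pool with probability ``task_sharing``, otherwise from all
patterns); its actives are a random subset of that pattern's carriers,
sized to a log-uniformly drawn active fraction. A label-noise knob
swaps actives with random non-carriers, and a hidden-active knob
removes true carriers from the labeled active set to emulate the
errors introduced by the presumed-inactive assumption.

There is also a SMILES mode that assembles small valid molecules from a
scaffold-core x decoration grammar, so the standardization, scaffold
splitting and molecular-weight splitting layers can be exercised
end-to-end without any external compound library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ActivityMatrix, Label

#: scaffold cores of the SMILES grammar; "{}" is the decoration site.
#: Cores are multi-ring and chemically distinctive so that circular
#: fingerprints cluster the library by core, not by substituent.
GRAMMAR_CORES = (
    "c1ccc2cc({})ccc2c1",                 # naphthalene
    "c1ccc2[nH]c({})cc2c1",               # indole
    "c1cnc2nc({})ccc2c1",                 # 1,8-naphthyridine
    "O=C(Nc1ccccc1)c1ccc({})cc1",         # benzanilide
    "c1ccc(-c2ccc({})cc2)cc1",            # biphenyl
    "O=C1CCCN1c1ccc({})cc1",              # phenyl-pyrrolidinone
)

#: small decoration fragments appended at the core's substitution site
GRAMMAR_DECORATIONS = (
    "C", "CC", "O", "N", "F", "Cl", "Br", "C#N", "OC", "CO",
)


@dataclass
class SimConfig:
    """Study conditions of the synthetic multi-task dataset.

    Defaults describe the standard benchmark used throughout the test
    suite: 20,000 compounds, 50 kinase tasks, 1024-bit features, and
    per-task active fractions drawn log-uniformly from 0.05% to 10%
    (the long-tailed skew of real kinome data).

    Carrier sizing: by default each pattern's carrier set is sized to
    the largest active count demanded by the tasks assigned to it,
    times (1 + ``carrier_surplus``) — the surplus carriers are true
    binders that never got labeled, the kind of error the
    presumed-inactive assumption introduces. Setting ``carrier_prob``
    switches to independent Bernoulli carrying, where a task's demand
    can exceed its pattern's carriers (that raises, with a diagnostic).

    ``pattern_overlap`` makes every pattern share that fraction of its
    bits with one common base pattern, emulating tasks whose
    active-defining chemistry overlaps without being identical.
    ``active_fractions`` pins per-task fractions exactly (overrides the
    log-uniform draw), which experiments on data-poor tasks use.
    """

    n_compounds: int = 20_000
    n_tasks: int = 50
    n_bits: int = 1024
    k_latent: int = 16
    task_sharing: float = 0.5
    active_fraction: tuple[float, float] = (0.0005, 0.1)
    active_fractions: tuple[float, ...] | None = None
    label_noise: float = 0.0
    hidden_active_fraction: float = 0.0
    pattern_bits: int = 32
    pattern_overlap: float = 0.0
    background_bits: int = 40
    carrier_prob: float | None = None
    carrier_surplus: float = 0.0
    shared_pool_size: int = 3
    seed: int = 0

    def __post_init__(self):
        for p in (self.task_sharing, self.label_noise, self.hidden_active_fraction,
                  self.pattern_overlap):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.carrier_prob is not None and not 0 <= self.carrier_prob <= 1:
            raise ValueError("carrier_prob must lie in [0, 1]")
        if not self.n_compounds > self.n_tasks >= 2:
            raise ValueError("need n_compounds > n_tasks >= 2")
        lo, hi = self.active_fraction
        if not 0 < lo <= hi <= 1:
            raise ValueError("active_fraction range must satisfy 0 < lo <= hi <= 1")
        if self.active_fractions is not None and len(self.active_fractions) != self.n_tasks:
            raise ValueError("active_fractions must list one fraction per task")


@dataclass
class SimTruth:
    """Ground truth of one generated dataset, for recovery tests."""

    patterns: list[np.ndarray]  # per pattern: sorted bit indices
    carriers: np.ndarray  # (N, k_latent) bool
    task_pattern: np.ndarray  # (T,) pattern index per task
    active_fraction: np.ndarray  # (T,) drawn fraction per task
    swapped_in: dict[str, list[int]] = field(default_factory=dict)


def generate(config: SimConfig) -> tuple[np.ndarray, ActivityMatrix, SimTruth]:
    """Generate (fingerprints, activity matrix, ground truth).

    Byte-identical for a fixed config (one seeded generator drives every
    draw). Raises when a task's requested active count exceeds its
    pattern's carrier count, with the numbers in the message.
    """
    rng = np.random.default_rng(config.seed)
    N, T, B = config.n_compounds, config.n_tasks, config.n_bits

    # latent pharmacophore bit-patterns, optionally overlapping a base
    n_shared_bits = int(round(config.pattern_overlap * config.pattern_bits))
    base = rng.choice(B, size=config.pattern_bits, replace=False)
    rest = np.setdiff1d(np.arange(B), base)
    patterns = []
    for _ in range(config.k_latent):
        shared = rng.choice(base, size=n_shared_bits, replace=False)
        own = rng.choice(rest, size=config.pattern_bits - n_shared_bits, replace=False)
        patterns.append(np.sort(np.concatenate([shared, own])))

    # task -> pattern: shared pool with prob task_sharing; at exactly 0,
    # round-robin so tasks get distinct patterns whenever k_latent >= T
    pool = min(config.shared_pool_size, config.k_latent)
    if config.task_sharing == 0:
        task_pattern = np.arange(T) % config.k_latent
    else:
        task_pattern = np.where(
            rng.random(T) < config.task_sharing,
            rng.integers(0, pool, size=T),
            rng.integers(0, config.k_latent, size=T),
        )

    if config.active_fractions is not None:
        fractions = np.asarray(config.active_fractions, dtype=float)
    else:
        lo, hi = config.active_fraction
        fractions = np.exp(rng.uniform(np.log(lo), np.log(hi), size=T))
    n_targets = np.maximum(1, np.round(fractions * N).astype(int))

    if config.carrier_prob is not None:
        carriers = rng.random((N, config.k_latent)) < config.carrier_prob
    else:
        # demand-sized carriers: largest assigned task count plus surplus
        carriers = np.zeros((N, config.k_latent), dtype=bool)
        for k in range(config.k_latent):
            demand = [n_targets[t] for t in range(T) if task_pattern[t] == k]
            need = int(np.ceil(max(demand, default=0) * (1 + config.carrier_surplus)))
            if need > 0:
                carriers[rng.choice(N, size=min(need, N), replace=False), k] = True

    fps = (rng.random((N, B)) < config.background_bits / B)
    for k, pat in enumerate(patterns):
        fps[np.ix_(carriers[:, k], pat)] = True
    fps = fps.astype(np.uint8)

    compounds = [f"C{i:06d}" for i in range(N)]
    tasks = [f"KIN{t:03d}" for t in range(T)]
    labels: dict[tuple[str, str], Label] = {}
    pact: dict[tuple[str, str], float] = {}
    swapped: dict[str, list[int]] = {}
    for t in range(T):
        carrier_rows = np.flatnonzero(carriers[:, task_pattern[t]])
        n_target = int(n_targets[t])
        if n_target > len(carrier_rows):
            raise ValueError(
                f"task {tasks[t]}: requested {n_target} actives but pattern "
                f"{task_pattern[t]} has only {len(carrier_rows)} carriers"
            )
        chosen = rng.choice(carrier_rows, size=n_target, replace=False)
        if config.hidden_active_fraction > 0:
            keep = rng.random(len(chosen)) >= config.hidden_active_fraction
            chosen = chosen[keep]
        if config.label_noise > 0:
            non_carriers = np.flatnonzero(~carriers[:, task_pattern[t]])
            flip = rng.random(len(chosen)) < config.label_noise
            n_flip = int(flip.sum())
            if n_flip:
                replacements = rng.choice(non_carriers, size=n_flip, replace=False)
                chosen = np.concatenate([chosen[~flip], replacements])
                swapped[tasks[t]] = replacements.tolist()
        for i in np.sort(chosen):
            labels[(compounds[i], tasks[t])] = Label.ACTIVE
            # a plausible potency: uniform pActivity in [6, 9]
            pact[(compounds[i], tasks[t])] = float(rng.uniform(6.0, 9.0))

    matrix = ActivityMatrix(compounds=compounds, tasks=tasks, labels=labels,
                            pactivity=pact)
    truth = SimTruth(patterns=patterns, carriers=carriers, task_pattern=task_pattern,
                     active_fraction=fractions, swapped_in=swapped)
    return fps, matrix, truth


def generate_smiles_mode(
    n_compounds: int = 600,
    n_tasks: int = 4,
    active_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], ActivityMatrix, dict]:
    """Assemble a toy SMILES library from the core x decoration grammar.

    Every compound is one scaffold core carrying one decoration; each
    task is assigned a core and its actives are a random subset of that
    core's members. Returns ((compound_id, smiles) pairs, activity
    matrix, {task -> core index}).
    """
    if n_compounds > 5000:
        raise ValueError("SMILES mode is for small libraries (<= 5000 compounds)")
    if n_tasks > len(GRAMMAR_CORES):
        raise ValueError(f"at most {len(GRAMMAR_CORES)} tasks (one core each)")
    rng = np.random.default_rng(seed)
    core_idx = rng.integers(0, len(GRAMMAR_CORES), size=n_compounds)
    deco_idx = rng.integers(0, len(GRAMMAR_DECORATIONS), size=n_compounds)
    entries = []
    for i in range(n_compounds):
        smiles = GRAMMAR_CORES[core_idx[i]].format(GRAMMAR_DECORATIONS[deco_idx[i]])
        entries.append((f"C{i:06d}", smiles))

    tasks = [f"KIN{t:03d}" for t in range(n_tasks)]
    task_core = {tasks[t]: t % len(GRAMMAR_CORES) for t in range(n_tasks)}
    labels: dict[tuple[str, str], Label] = {}
    for t, task in enumerate(tasks):
        members = np.flatnonzero(core_idx == task_core[task])
        n_active = max(1, int(round(active_fraction * len(members))))
        for i in rng.choice(members, size=min(n_active, len(members)), replace=False):
            labels[(entries[i][0], task)] = Label.ACTIVE
    matrix = ActivityMatrix(compounds=[e[0] for e in entries], tasks=tasks, labels=labels)
    return entries, matrix, {"task_core": task_core, "core_idx": core_idx}
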