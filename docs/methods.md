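# Methods

## Data model and curation

A bioactivity record is one concentration endpoint (Kd, Ki, IC50 or
Potency, in molar units; the CSV reader accepts nM/µM/M dialects and
normalizes before anything else) for a (compound, kinase-task) pair.
Aggregation is a two-stage median: replicates are collapsed within each
endpoint type first, then the per-endpoint medians are collapsed across
endpoints, so an endpoint with many replicates cannot dominate the
aggregate. The −log10 transform is applied after aggregation; the scale
is anchored by pActivity 6 ↔ 1 µM.

Labeling: an aggregated pair at or above the threshold (default 6) is
ACTIVE; a tested pair below it is a *reported inactive*; an untested
pair is UNKNOWN. Tasks with fewer than 15 unique actives are dropped
(strict "fewer than": 15 actives survive). Compounds are retained on
the compound axis even when all their labels are filtered away — in the
KA–PI view every compound is a presumed-inactive row for every task.

Two training views materialize the sparse matrix into dense label and
mask arrays. KA–PI labels every cell (active = 1, everything else = 0)
with an all-ones mask; presumed-inactive cells carry full loss weight,
treating them as decoys rather than soft labels. KA–KI masks every cell
that is neither ACTIVE nor reported-INACTIVE, so unlabeled cells
contribute no gradient. Models trained on KA–KI are conventionally
evaluated on the KA–PI label surface (`cross_validate(eval_view=...)`).

One reading note: "received no label otherwise" describes the global
matrix, but a KA–KI view with no negative class would be vacuous; we
therefore treat tested-but-below-threshold pairs as the reported
inactive set. External profiling tables are binarized at ≥80%
inhibition (single-dose % inhibition panels) or pKd ≥ 6 (binding
panels); missing cells stay UNKNOWN.

## Chemistry layer

Standardization keeps the largest fragment by heavy-atom count (ties
broken by canonical-SMILES lexicographic order), neutralizes charges,
canonicalizes the tautomer with the RDKit canonicalizer, and strips all
stereo/E-Z annotations (circular fingerprints do not see them, and
keeping them would create duplicate feature rows). The procedure is a
fixed point: standardizing its own output is a no-op, which the suite
property-tests. Features are radius-2 Morgan fingerprints folded to
1024 bits; molecular weight is the average (isotope-abundance-weighted)
weight with implicit hydrogens. Tanimoto similarity of two all-zero
fingerprints is defined as 0 — an empty fingerprint carries no evidence
of similarity.

## Network and optimization

Architecture: 1024 → hidden ReLU layers (default 2000 × 500) → one
two-neuron softmax head per task (kept as two neurons rather than a
sigmoid to preserve the per-task softmax formulation; the two are
equivalent for ranking). Defaults: dropout 0.25 on hidden activations
(inverted dropout, hidden layers only — not the input), SGD with
learning rate 3e-4, batch size 128, momentum 0.9, weight decay 0,
up to 100 epochs with early stopping on validation loss (patience 10).
Momentum, decay and the epoch budget are conventional choices exposed
in `NetworkSpec`; the rest follow the tuned configuration the model
family is known for.

Initialization: hidden layers use seeded He-style fan-in uniform
weights; the output heads start at exactly zero, so every task begins
at P(active) = 0.5. This matters at small learning rates: a random head
projects the strongly correlated active compounds (they share pattern
bits) to an arbitrary common score offset, and undoing that transient
costs tens of epochs that a zero head never spends.

The training objective is the weighted **sum over tasks** of the
per-task batch-mean masked cross-entropy (per-task weights w_t default
to 1; an inverse-prevalence mode is available but not default — at the
prevalence ratios of the default generator it amplifies rare-task
gradient noise enough to hurt). The *reported* loss
(`masked_cross_entropy`) is the per-unmasked-entry mean of the same
per-entry cross-entropies; probabilities are clamped to
[1e-7, 1 − 1e-7] before the log. A fully masked task receives exactly
zero gradient — with zero-initialized heads its parameters remain
bit-for-bit zero, which the suite asserts.

Everything (init, shuffling, dropout) is driven by one seeded
generator; training logs are reproducible run-to-run on one thread.
`forward` is batch-partition invariant and dropout-free at inference.

Baselines: per-task logistic regression, 100-tree random forest and
Bernoulli naive Bayes (scikit-learn); a single-task DNN that is
literally the multi-task network with T = 1 (same hyperparameters); and
a 100-tree multi-task random forest fit jointly on the label matrix.
All expose the same per-task P(active) prediction contract;
single-task models fill only their own column (NaN elsewhere).

## Splits

* **Random stratified** — compounds are stratified on their total
  active-label count (binned 0/1/2/≥3); per-stratum largest-remainder
  quotas are reconciled against exact global partition sizes, so
  80/10/10 on 10,000 compounds lands within one compound. Exact
  per-task stratification across hundreds of sparse tasks is
  infeasible; the binned total preserves the balance the loss sees.
* **Scaffold-cluster** — average-linkage agglomerative clustering on
  Tanimoto distance, cut at ≈300 clusters (configurable); whole
  clusters go to folds largest-first onto the smallest fold, so no
  cluster spans folds and fold sizes differ by at most the largest
  cluster. Murcko-scaffold grouping is available as an alternative
  cluster assignment but is not the default: with diverse libraries the
  scaffold count approaches the compound count and the split behaves
  like a random one.
* **Molecular weight** — sort ascending, cut into contiguous fifths,
  ties broken by compound id. Contiguous blocks are the literal reading
  of holding out a fifth of the weight-sorted library.

y-randomization replaces each task's active set with a uniform random
set of the same size (KA–PI only; feature matrix untouched). Fractional
subsampling takes a prefix of one seed-shuffled order, which makes
subsamples at increasing fractions nested under a shared seed.

## Metrics

AUC is computed by the cumulative-count rank formula, generalized to
tied scores by mid-rank averaging (walk the descending list in tie
groups; a group with a actives and b inactives adds A_before·b + a·b/2
concordant pairs). This is exactly the normalized Mann–Whitney U, and
the suite checks it exhaustively against brute-force pair counting at
small N. Degenerate tasks (n = 0 or n = N) raise; report builders
record None.

EF windows use ⌊XN⌋ (matching the integer-rank condition r_i ≤ XN);
ties straddling the window boundary resolve pessimistically (actives
last), so reported enrichment is conservative. EFmax = min(n, ⌊XN⌋)/(nX)
— note the closed form EFmax = 1/X holds when *all* actives fit the
window (n ≤ ⌊XN⌋). Confusion metrics threshold P(active) at 0.5
(configurable) and report None, not 0, when a denominator is empty.
Model comparisons are unpaired two-sided Mann–Whitney U or two-sample
t-tests on per-task metric vectors, with the direction reported as the
sign of the mean difference.

## Task similarity

Per task, up to 25 diverse actives are selected by greedy max-min on
Tanimoto distance (seeded with the compound of lowest mean similarity;
ties break toward the lowest index; greedy max-min is the standard open
equivalent of proprietary diverse-subset pickers and is a
2-approximation, not an exact optimizer). The profile value of a task
is the mean over other tasks of the *directed* average-maximum
similarity of its representatives to theirs; the direction is kept
because the statistic asks how well the reference task's chemistry is
covered elsewhere.

## Synthetic data: what it emulates, what it does not

The generator reproduces three structural features of real kinome
matrices: long-tailed per-task active fractions (log-uniform in
[5·10⁻⁴, 0.1] by default over 20,000 compounds × 50 tasks), inter-task
chemical sharing, and activity carried by sparse bit patterns over
random background bits (~40 background bits; 32-bit patterns; compounds
carry patterns independently). Each task draws one latent pattern —
from a small shared pool with probability `task_sharing`, uniformly
otherwise; at `task_sharing = 0` patterns are assigned round-robin so
tasks get distinct patterns whenever enough exist. Pattern carrier sets
are sized to the demand of the tasks assigned to them (plus a
configurable surplus, default 0). Two error knobs emulate real-data
pathologies: `label_noise` swaps actives with random non-carriers, and
`hidden_active_fraction` / `carrier_surplus` leave true pattern
carriers unlabeled — precisely the error the presumed-inactive
assumption introduces. `pattern_overlap` makes patterns share a
fraction of their bits with a common base, emulating tasks whose
active-defining chemistry overlaps without coinciding.

What passing tests on this generator do **not** show: real SAR is not a
union of fixed substructure patterns; activity cliffs, assay noise
correlated with chemotype, series-level publication bias and
inter-assay incompatibilities are absent. Results on synthetic data
validate the machinery and the qualitative orderings (multi-task >
single-task under sharing; random > scaffold folds; label permutation
→ chance), not absolute performance on real kinase data. The SMILES
mode builds small valid molecules from six multi-ring scaffold cores ×
ten small decorations; cores are deliberately distinctive so
fingerprint clustering recovers them, which is what the scaffold-split
machinery needs to be exercised end-to-end.

## Desk-scale configurations

The reference configuration (2000 × 500 hidden units, 315k+ compounds)
is a GPU-scale workload. The package's experiments use a desk-scale
profile (`NetworkSpec.desk_scale`: 256 × 128 hidden units, same
optimizer settings) and problem sizes chosen so each phenomenon is
measurable on one CPU core in minutes. Because an epoch over 16k
training compounds contains ~20× fewer SGD steps than an epoch over the
full-scale data, epoch budgets are correspondingly larger:

* **y-randomization** — default dataset (20,000 × 50), 5-fold CV,
  20 epochs per fold: the permuted labels carry no learnable signal, so
  the chance-level readout is insensitive to training length.
* **Noise-free recovery** — 10,000 × 20, one pattern per task, active
  fractions 0.005–0.05, 600 epochs: every task with ≥50 actives reaches
  held-out AUC > 0.95.
* **Multi-task transfer** — 3,000 × 10, patterns sharing 90% of their
  bits, one task limited to ~20 training actives, 200 epochs, 5 seeds:
  the multi-task net beats the single-task net on the data-poor task
  (one-sided Mann–Whitney). With 90% shared bits a single-task model
  cannot identify its few unique bits from 20 positives, while the
  shared trunk has already learned every pattern from the data-rich
  siblings — the mechanism the transfer claim is about.

## Numerical choices and degenerate inputs

Probability clamp 1e-7 before logs; float32 parameters and activations
(float64 for reported losses and metrics); stable sorts everywhere a
ranking is produced, with compound-id tie-breaks in screening output;
largest-remainder rounding for partition sizes; equal-size fragment
ties in salt stripping broken lexicographically. Training refuses tasks
with no active labels in the training partition (explicit error listing
the tasks) unless the degenerate-task guard is deliberately relaxed for
control experiments. AUC/EF on one-class tasks raise typed errors that
report builders convert to None.

## Known limitations

The NumPy network is single-threaded and CPU-bound; at the reference
scale (hundreds of tasks, 10⁵–10⁶ compounds) a GPU framework would be
the right substrate. Hierarchical clustering materializes an N × N
distance matrix, capping the scaffold splitter at roughly 20k compounds
as implemented. Standardization approximates a proprietary pipeline's
protocol with open tooling: internal consistency (idempotence,
determinism) is guaranteed, exact string agreement with other tools is
not. The KA–PI assumption is deliberately conservative — presumed
inactives that are in fact active depress measured performance, and the
generator's error knobs exist to study exactly that degradation.
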