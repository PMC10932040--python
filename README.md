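# kinoscreen

Multi-task deep learning for kinome-wide ligand-based virtual screening.

Protein kinases are one of the largest families of drug targets, and
resistance to single-target kinase inhibitors routinely arises through
kinome reprogramming — which makes compound prioritization across the
*whole* kinome, not one kinase at a time, the practically relevant
problem. Public and commercial bioactivity sources cover hundreds of
kinases, but sparsely: most compounds are measured against a handful of
targets, active fractions per kinase range from far below 0.1% to ~10%,
and reported data are biased toward actives. `kinoscreen` is a toolkit
for building models under exactly these conditions: it curates sparse
compounds × kinase-tasks label matrices, trains a shared-hidden-layer
multi-task neural classifier on topological fingerprints, and evaluates
it with the ranking metrics that matter when you screen a million
compounds to pick a thousand.

It is intended for cheminformatics practitioners who work from Python:
the library API is the main interface, `examples/` holds short
narrative scripts, and a thin `kinoscreen` CLI wraps the pipeline
stages for shell use.

## The model

Compounds are standardized (largest fragment, neutralized, canonical
tautomer, stereo stripped) and featurized as 1024-bit ECFP4 (Morgan
radius-2) fingerprints **x**. A feed-forward network shares its hidden
layers across all T kinase tasks:

    x_0 = x,    z_i = W_i x_{i-1} + b_i,    x_i = max(0, z_i)

with two hidden ReLU layers (2000 × 500 by default) and, per task *t*, a
two-neuron softmax head giving

    P(y = t-active | x) = exp(w_t^T x_L) / Σ_m exp(w_m^T x_L).

Training minimizes the weighted sum over tasks of the masked
cross-entropy — unlabeled (compound, task) cells contribute no loss and
no gradient — by mini-batch SGD (batch 128, learning rate 3·10⁻⁴,
momentum 0.9, 25% dropout on hidden activations). Two labeling
assumptions are supported: **KA–KI** (only explicitly reported actives
and inactives enter the loss) and **KA–PI** (every compound not
reported active on a task is a presumed-inactive decoy — the realistic
virtual-screening regime).

Evaluation uses the rank-based ROC AUC

    AUC = 1/(n(N−n)) · Σ_i A_i (I_i − I_{i−1}),

with A_i, I_i the cumulative active/inactive counts at rank *i*, and the
enrichment factor at fraction X,

    EF_X = (# actives ranked ≤ ⌊XN⌋) / (n·X),   EFmax = min(n, ⌊XN⌋)/(n·X),

reported as the normalized ratio EF/EFmax so tasks with different
active fractions are comparable. Cross-validation comes in three
flavors — random stratified, scaffold-cluster (whole chemical clusters
held out), and molecular-weight — plus a y-randomization control and
nested data-fraction subsampling. Single-task baselines (logistic
regression, random forest, Bernoulli naive Bayes, a single-task DNN)
and a multi-task random forest sit behind the same train/predict
contract, with Mann–Whitney / t-test comparisons across per-task
scores.

A synthetic-data module generates sparse multi-task datasets with the
statistical structure the method assumes — latent pharmacophore-like
bit patterns, long-tailed per-task active fractions, tunable
inter-task chemical sharing and label noise — so the whole pipeline is
testable without any licensed download.

## Worked example

`python examples/03_train_and_screen.py` generates a 4,000-compound,
10-task dataset, trains the multi-task network on the KA–PI view, and
evaluates the held-out 10%:

```
trained 300 epochs; final train loss 0.0163

task     n_act    AUC  EF/EFmax@5%
KIN000       1  1.000        1.000
KIN001       4  0.985        0.750
KIN002      10  1.000        1.000
KIN003      11  1.000        1.000
KIN004      18  1.000        1.000
...
mean held-out AUC 0.998
```

Per task, `n_act` is the number of held-out actives, AUC measures how
well actives are ranked above inactives, and EF/EFmax = 1 means the top
5% of the ranked list contains as many actives as arithmetically
possible. `examples/04_splits_and_y_randomization.py` shows the two
controls: scaffold-cluster folds collapse performance on this
single-chemotype-per-task synthetic data (random folds 0.992 vs
scaffold folds 0.173), and label permutation drives AUC to 0.503 —
chance level, confirming the model learns structure–activity signal.

The same pipeline runs from the shell:

```sh
kinoscreen simulate --config run.yaml --seed 7 --out data/
kinoscreen split    --data data/ --strategy random --seed 7 --out splits/
kinoscreen train    --data data/ --split splits/ --seed 7 --out model/
kinoscreen predict  --model model/ --data data/ --out preds/
kinoscreen evaluate --predictions preds/predictions.csv --data data/ --out eval/
```

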