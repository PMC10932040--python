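"""Inter-task chemical similarity of kinase active sets.

For each task, 25 structurally diverse actives are chosen by max-min
Tanimoto selection; the profile value is the mean over other tasks of
the average maximum similarity of those representatives. Tasks whose
inhibitors overlap chemically with other tasks sit near 1 — the regime
where multi-task learning shares the most signal.
"""

from kinoscreen import SimConfig, generate
from kinoscreen.task_similarity import task_similarity_profile

# half the tasks draw from a shared pattern pool, half get their own
cfg = SimConfig(n_compounds=2000, n_tasks=6, k_latent=6, task_sharing=0.6,
                active_fraction=(0.03, 0.06), seed=9)
fps, matrix, truth = generate(cfg)

profile = task_similarity_profile(matrix, fps, k=25)
print(f"{'task':8s} {'pattern':>7s} {'avg max similarity to other tasks':>35s}")
for t, task in enumerate(profile.tasks):
    print(f"{task:8s} {truth.task_pattern[t]:7d} {profile.avg_max_sim[task]:35.3f}")
print("\ntasks assigned the same latent pattern show clearly higher values:")
print("their diverse actives are nearly interchangeable chemotypes.")
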