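"""From raw concentration records to a labeled activity matrix.

Replicate measurements are aggregated by a two-stage median (within
endpoint, then across endpoints), transformed to pActivity = -log10(M),
and labeled active at pActivity >= 6 (1 uM). The KA-PI view then treats
every unlabeled (compound, task) cell as a presumed-inactive decoy.
"""

from kinoscreen import (
    BioactivityRecord,
    aggregate_records,
    build_view,
    filter_tasks,
    to_pactivity,
)

records = [
    # three replicate IC50s for c1 on ABL1: median 1 uM -> boundary active
    BioactivityRecord("c1", "ABL1", "IC50", 1e-5),
    BioactivityRecord("c1", "ABL1", "IC50", 1e-6),
    BioactivityRecord("c1", "ABL1", "IC50", 1e-7),
    # one weak Kd for c2: tested but below threshold -> reported inactive
    BioactivityRecord("c2", "ABL1", "Kd", 2e-6),
    # a potent binder for c3
    BioactivityRecord("c3", "ABL1", "Ki", 5e-9),
]

print(f"pActivity(1 uM)   = {to_pactivity(1e-6):.2f}  (the active threshold)")
print(f"pActivity(100 nM) = {to_pactivity(100e-9):.2f}\n")

matrix = aggregate_records(records)
for (cid, tid), label in sorted(matrix.labels.items()):
    print(f"{cid} x {tid}: pActivity {matrix.pactivity[(cid, tid)]:.2f} -> {label.value}")

# tasks need >= 15 unique actives to be modeled; this toy task is dropped
filtered = filter_tasks(matrix)
print(f"\ntasks surviving the >=15-actives filter: {filtered.tasks or 'none'}")

view = build_view(matrix, "kapi")
print(f"KA-PI label surface: {view.label_matrix.sum()} active cells of "
      f"{view.mask.sum()} (every cell labeled, unknowns presumed inactive)")
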