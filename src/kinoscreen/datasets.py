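"""Bioactivity aggregation and the KA-KI / KA-PI training views.

Raw concentration-response records (Kd, Ki, IC50, Potency) are
normalized to molar units, aggregated per (compound, kinase task) by a
two-stage median — first within each endpoint type, then across
endpoints — and transformed to pActivity = -log10(M). A compound is
labeled ACTIVE on a task when its aggregated pActivity reaches the
threshold (default 6, i.e. 1 uM); a tested pair below the threshold is
the reported-inactive set; untested pairs are UNKNOWN.

Two training views are derived from the resulting sparse matrix:

* KA-KI ("known active - known inactive") uses only explicitly tested
  pairs; all other cells are masked out of the loss.
* KA-PI ("known active - presumed inactive") treats every compound not
  reported active on a task as an inactive decoy, which matches the
  base-rate structure of a real virtual-screening library.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENDPOINTS = ("Kd", "Ki", "IC50", "Potency")
DEFAULT_THRESHOLD = 6.0
DEFAULT_MIN_ACTIVES = 15

#: multiply a value in these units by the factor to obtain molar
UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


class Label(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    UNKNOWN = "unknown"


class ViewMode(str, Enum):
    KA_KI = "kaki"
    KA_PI = "kapi"


@dataclass(frozen=True)
class BioactivityRecord:
    """One concentration measurement for a (compound, kinase) pair."""

    compound_id: str
    target_id: str
    endpoint: str  # Kd | Ki | IC50 | Potency
    value: float  # molar
    source: str = "public"

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if not self.value > 0:
            raise ValueError("concentration must be positive")


@dataclass
class ActivityMatrix:
    """Sparse compounds x kinase-tasks label matrix.

    ``labels`` and ``pactivity`` are keyed by (compound_id, target_id);
    absent keys are UNKNOWN cells.
    """

    compounds: list[str]
    tasks: list[str]
    labels: dict[tuple[str, str], Label]
    pactivity: dict[tuple[str, str], float] = field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD

    def label_of(self, compound_id: str, target_id: str) -> Label:
        return self.labels.get((compound_id, target_id), Label.UNKNOWN)

    def active_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in self.tasks}
        for (_, t), lab in self.labels.items():
            if lab is Label.ACTIVE and t in counts:
                counts[t] += 1
        return counts

    def n_cells(self) -> int:
        return len(self.compounds) * len(self.tasks)


@dataclass
class TrainingView:
    """Dense per-task binary labels with a per-entry inclusion mask."""

    mode: ViewMode
    compounds: list[str]
    tasks: list[str]
    features: np.ndarray  # (N, n_bits)
    label_matrix: np.ndarray  # (N, T) int8
    mask: np.ndarray  # (N, T) bool

    @property
    def n_compounds(self) -> int:
        return self.label_matrix.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.label_matrix.shape[1]

    def active_counts(self) -> np.ndarray:
        return (self.label_matrix * self.mask).sum(axis=0)


def to_pactivity(value_molar: float) -> float:
    """pActivity = -log10 of a molar concentration (1 uM -> 6.0)."""
    if not value_molar > 0:
        raise ValueError("concentration must be positive to take -log10")
    return float(-np.log10(value_molar))


def normalize_to_molar(value: float, unit: str) -> float:
    """Convert a concentration to molar given its unit string (ChEMBL uses nM)."""
    try:
        return value * UNIT_TO_MOLAR[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def aggregate_records(
    records: Iterable[BioactivityRecord],
    threshold: float = DEFAULT_THRESHOLD,
    compounds: Sequence[str] | None = None,
    tasks: Sequence[str] | None = None,
) -> ActivityMatrix:
    """Collapse replicate measurements into one pActivity per (compound, task).

    Two-stage median: within each endpoint type first, then across the
    per-endpoint medians, so an endpoint with many replicates cannot
    dominate the aggregate. The -log10 transform is applied after
    aggregation. Pairs at or above ``threshold`` are ACTIVE; tested
    pairs below it are the reported-inactive set.
    """
    rows = []
    for rec in records:
        rows.append((rec.compound_id, rec.target_id, rec.endpoint, rec.value))
    if rows:
        df = pd.DataFrame(rows, columns=["compound_id", "target_id", "endpoint", "value"])
        per_endpoint = (
            df.groupby(["compound_id", "target_id", "endpoint"], sort=False)["value"]
            .median()
            .reset_index()
        )
        agg = (
            per_endpoint.groupby(["compound_id", "target_id"], sort=False)["value"]
            .median()
            .reset_index()
        )
    else:
        agg = pd.DataFrame(columns=["compound_id", "target_id", "value"])

    labels: dict[tuple[str, str], Label] = {}
    pact: dict[tuple[str, str], float] = {}
    for cid, tid, value in agg.itertuples(index=False):
        p = to_pactivity(value)
        pact[(cid, tid)] = p
        labels[(cid, tid)] = Label.ACTIVE if p >= threshold else Label.INACTIVE

    if compounds is None:
        compounds = list(dict.fromkeys(agg["compound_id"])) if len(agg) else []
    if tasks is None:
        tasks = list(dict.fromkeys(agg["target_id"])) if len(agg) else []
    return ActivityMatrix(
        compounds=list(compounds), tasks=list(tasks), labels=labels, pactivity=pact,
        threshold=threshold,
    )


def filter_tasks(matrix: ActivityMatrix, min_actives: int = DEFAULT_MIN_ACTIVES) -> ActivityMatrix:
    """Drop tasks with fewer than ``min_actives`` unique active compounds.

    Idempotent. Compounds are all retained on the compound axis: in the
    KA-PI view every compound is a presumed-inactive row for every task,
    and the KA-KI view masks unlabeled cells anyway.
    """
    counts = matrix.active_counts()
    kept = [t for t in matrix.tasks if counts.get(t, 0) >= min_actives]
    kept_set = set(kept)
    labels = {k: v for k, v in matrix.labels.items() if k[1] in kept_set}
    pact = {k: v for k, v in matrix.pactivity.items() if k[1] in kept_set}
    return ActivityMatrix(
        compounds=list(matrix.compounds), tasks=kept, labels=labels, pactivity=pact,
        threshold=matrix.threshold,
    )


def build_view(
    matrix: ActivityMatrix,
    mode: ViewMode | str,
    features: np.ndarray | None = None,
) -> TrainingView:
    """Materialize the dense KA-KI or KA-PI label/mask surface.

    KA-PI: cell = 1 iff ACTIVE, else 0; mask all ones (presumed
    inactives are decoys with full loss weight). KA-KI: ACTIVE -> 1,
    reported INACTIVE -> 0, everything else masked out.
    """
    mode = ViewMode(mode)
    n, t = len(matrix.compounds), len(matrix.tasks)
    cid_index = {c: i for i, c in enumerate(matrix.compounds)}
    tid_index = {k: j for j, k in enumerate(matrix.tasks)}
    label_matrix = np.zeros((n, t), dtype=np.int8)
    if mode is ViewMode.KA_PI:
        mask = np.ones((n, t), dtype=bool)
    else:
        mask = np.zeros((n, t), dtype=bool)
    for (cid, tid), lab in matrix.labels.items():
        i, j = cid_index.get(cid), tid_index.get(tid)
        if i is None or j is None:
            continue
        if lab is Label.ACTIVE:
            label_matrix[i, j] = 1
            mask[i, j] = True
        elif lab is Label.INACTIVE and mode is ViewMode.KA_KI:
            mask[i, j] = True
    if features is None:
        features = np.zeros((n, 0), dtype=np.uint8)
    if features.shape[0] != n:
        raise ValueError("feature row count does not match compound axis")
    return TrainingView(
        mode=mode, compounds=list(matrix.compounds), tasks=list(matrix.tasks),
        features=features, label_matrix=label_matrix, mask=mask,
    )


def binarize_external(
    table: pd.DataFrame,
    scheme: str,
    training_tasks: Sequence[str],
) -> ActivityMatrix:
    """Binarize an external profiling table into an ActivityMatrix.

    ``kinomescan``: rows carry % inhibition at 10 uM; ACTIVE iff >= 80.
    ``idg``: rows carry pKd; ACTIVE iff >= 6. Tasks absent from
    ``training_tasks`` are dropped; missing values stay UNKNOWN.
    Expected columns: compound_id, target_id, value.
    """
    if scheme == "kinomescan":
        cut = 80.0
    elif scheme == "idg":
        cut = 6.0
    else:
        raise ValueError(f"unknown binarization scheme {scheme!r}")
    task_set = set(training_tasks)
    df = table[table["target_id"].isin(task_set)]
    labels: dict[tuple[str, str], Label] = {}
    for cid, tid, value in df[["compound_id", "target_id", "value"]].itertuples(index=False):
        if pd.isna(value):
            continue  # null stays an UNKNOWN cell
        labels[(str(cid), str(tid))] = Label.ACTIVE if value >= cut else Label.INACTIVE
    compounds = list(dict.fromkeys(str(c) for c in df["compound_id"])) if len(df) else []
    tasks = [t for t in training_tasks if t in set(df["target_id"])]
    return ActivityMatrix(compounds=compounds, tasks=tasks, labels=labels)


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

#: column map for the bioactivity reader; values are the expected header names
READER_COLUMNS = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "target_id": "target_id",
    "endpoint": "endpoint",
    "value": "value",
    "unit": "unit",
    "variant_flag": "variant_flag",
    "confidence": "confidence",
}


def read_bioactivity_table(
    path,
    column_map: Mapping[str, str] | None = None,
    min_confidence: float = 5.0,
) -> list[BioactivityRecord]:
    """Read a bioactivity CSV/TSV into validated records.

    Rows with a variant flag (mutant targets) are dropped; if a
    confidence column exists, rows below ``min_confidence`` are dropped;
    rows with an unknown endpoint are skipped with a warning rather than
    aborting the load.
    """
    cols = dict(READER_COLUMNS)
    if column_map:
        cols.update(column_map)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if cols["variant_flag"] in df.columns:
        df = df[df[cols["variant_flag"]].isna() | (df[cols["variant_flag"]] == "")]
    if cols["confidence"] in df.columns:
        df = df[df[cols["confidence"]] >= min_confidence]
    records = []
    for _, row in df.iterrows():
        endpoint = row[cols["endpoint"]]
        if endpoint not in ENDPOINTS:
            logger.warning("skipping record with unknown endpoint %r", endpoint)
            continue
        unit = row[cols["unit"]] if cols["unit"] in df.columns else "nM"
        records.append(
            BioactivityRecord(
                compound_id=str(row[cols["compound_id"]]),
                target_id=str(row[cols["target_id"]]),
                endpoint=endpoint,
                value=normalize_to_molar(float(row[cols["value"]]), unit),
            )
        )
    return records


def write_activity_matrix(matrix: ActivityMatrix, prefix) -> None:
    """Write sparse triplets (CSV) plus a JSON manifest."""
    prefix = Path(prefix)
    rows = [
        {
            "compound_id": cid,
            "target_id": tid,
            "label": lab.value,
            "pactivity": matrix.pactivity.get((cid, tid), ""),
        }
        for (cid, tid), lab in sorted(matrix.labels.items())
    ]
    pd.DataFrame(rows, columns=["compound_id", "target_id", "label", "pactivity"]).to_csv(
        prefix.with_suffix(".csv"), index=False
    )
    manifest = {
        "threshold": matrix.threshold,
        "compounds": matrix.compounds,
        "tasks": matrix.tasks,
        "n_labels": len(matrix.labels),
        "active_counts": matrix.active_counts(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_activity_matrix(prefix) -> ActivityMatrix:
    """Inverse of :func:`write_activity_matrix`."""
    prefix = Path(prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".csv"))
    labels: dict[tuple[str, str], Label] = {}
    pact: dict[tuple[str, str], float] = {}
    for cid, tid, lab, p in df.itertuples(index=False):
        labels[(str(cid), str(tid))] = Label(lab)
        if pd.notna(p) and p != "":
            pact[(str(cid), str(tid))] = float(p)
    return ActivityMatrix(
        compounds=[str(c) for c in manifest["compounds"]],
        tasks=[str(t) for t in manifest["tasks"]],
        labels=labels,
        pactivity=pact,
        threshold=float(manifest["threshold"]),
    )
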