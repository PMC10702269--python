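"""Inter-seizure-interval (ISI) taxonomy of seizures.

Seizures are categorized by their temporal neighbourhood: an *isolated*
seizure has no other seizure within the ISI cutoff (24 h by default, 8 h for
robustness analyses) before or after it; the remaining seizures form
*clusters*, whose members are sub-categorized as *cluster-last* (last in the
cluster) and *cluster-non-last* (all other members). The first seizure of a
cluster additionally carries the *cluster-first* flag; in a two-seizure
cluster the first member is both cluster-first and cluster-non-last.

Two binary prediction tasks derive from the taxonomy:

- ``next_seizure``: will another seizure occur within the cutoff after this
  one? positive = cluster-non-last, negative = isolated + cluster-last.
- ``cluster_onset``: is this seizure the start of a cluster? positive =
  cluster-first, negative = isolated; other seizures are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .events import SeizureEvent, check_ordered

Category = Literal["isolated", "cluster_non_last", "cluster_last"]
Task = Literal["next_seizure", "cluster_onset"]

TASKS = ("next_seizure", "cluster_onset")
CATEGORIES = ("isolated", "cluster_non_last", "cluster_last")

#: Minimum members per task class for a patient to enter prediction analyses.
DEFAULT_MIN_PER_CLASS = 10


@dataclass(frozen=True)
class TaxonomyConfig:
    """ISI cutoff and how the interval between seizures is measured.

    The interval is measured from the offset of one seizure to the onset of
    the next (``offset_to_onset``) by default — the clinically relevant gap
    during which a further seizure may strike — with ``onset_to_onset``
    available as an alternative convention. Gaps exactly equal to the
    threshold count as *within* the cluster (``<=``).
    """

    isi_threshold_h: float = 24.0
    isi_reference: Literal["offset_to_onset", "onset_to_onset"] = "offset_to_onset"

    def __post_init__(self) -> None:
        if not self.isi_threshold_h > 0:
            raise ValueError("isi_threshold_h must be positive")
        if self.isi_reference not in ("offset_to_onset", "onset_to_onset"):
            raise ValueError(f"unknown isi_reference {self.isi_reference!r}")

    @property
    def threshold_s(self) -> float:
        return self.isi_threshold_h * 3600.0


@dataclass(frozen=True)
class LabeledSeizure:
    """Taxonomy label of one seizure (index refers to the ordered events)."""

    index: int
    category: Category
    is_cluster_first: bool
    cluster_id: int | None

    def __post_init__(self) -> None:
        if self.is_cluster_first and self.category == "isolated":
            raise ValueError("an isolated seizure cannot be cluster-first")
        if (self.cluster_id is None) != (self.category == "isolated"):
            raise ValueError("cluster_id must be set iff the seizure is clustered")


def _gaps_h(events: Sequence[SeizureEvent], cfg: TaxonomyConfig) -> list[float]:
    if cfg.isi_reference == "offset_to_onset":
        return [
            (nxt.onset_s - cur.offset_s) / 3600.0
            for cur, nxt in zip(events, events[1:])
        ]
    return [
        (nxt.onset_s - cur.onset_s) / 3600.0 for cur, nxt in zip(events, events[1:])
    ]


def label_seizures(
    events: Sequence[SeizureEvent], cfg: TaxonomyConfig | None = None
) -> list[LabeledSeizure]:
    """Assign the ISI taxonomy label to every seizure of one patient.

    Consecutive seizures whose gap is ``<=`` the cutoff share a cluster; a
    seizure whose gaps to both neighbours exceed the cutoff is isolated.
    A single linear scan over the ordered events suffices because cluster
    membership is transitive along consecutive links.
    """
    cfg = cfg or TaxonomyConfig()
    events = list(events)
    check_ordered(events)
    n = len(events)
    if n == 0:
        return []

    gaps = _gaps_h(events, cfg)
    linked = [g <= cfg.isi_threshold_h for g in gaps]

    labels: list[LabeledSeizure] = []
    cluster_id = -1
    i = 0
    while i < n:
        j = i
        while j < n - 1 and linked[j]:
            j += 1
        if j == i:
            labels.append(LabeledSeizure(i, "isolated", False, None))
        else:
            cluster_id += 1
            for k in range(i, j + 1):
                category: Category = "cluster_last" if k == j else "cluster_non_last"
                labels.append(LabeledSeizure(k, category, k == i, cluster_id))
        i = j + 1
    return labels


def task_classes(
    labels: Sequence[LabeledSeizure], task: Task
) -> list[int | None]:
    """Binary class per seizure for a prediction task; ``None`` = excluded.

    ``next_seizure`` keeps every seizure (positive = cluster-non-last);
    ``cluster_onset`` keeps only cluster-first (positive) and isolated
    (negative) seizures.
    """
    if task == "next_seizure":
        return [1 if lab.category == "cluster_non_last" else 0 for lab in labels]
    if task == "cluster_onset":
        out: list[int | None] = []
        for lab in labels:
            if lab.is_cluster_first:
                out.append(1)
            elif lab.category == "isolated":
                out.append(0)
            else:
                out.append(None)
        return out
    raise ValueError(f"unknown task {task!r}")


def patient_eligible(
    labels: Sequence[LabeledSeizure],
    task: Task,
    min_per_class: int = DEFAULT_MIN_PER_CLASS,
) -> tuple[bool, str]:
    """Whether a patient has enough seizures of both task classes.

    Patients with fewer than ``min_per_class`` members in either class are
    excluded from prediction analyses for that task.
    """
    classes = [c for c in task_classes(labels, task) if c is not None]
    n_pos = sum(classes)
    n_neg = len(classes) - n_pos
    if n_pos >= min_per_class and n_neg >= min_per_class:
        return True, f"eligible ({n_neg} negative, {n_pos} positive)"
    return False, (
        f"ineligible for {task}: {n_neg} negative, {n_pos} positive; "
        f"need >= {min_per_class} in each class"
    )


def labels_to_frame(labels: Sequence[LabeledSeizure]) -> pd.DataFrame:
    """Tidy per-seizure label table (columns appended to the annotations)."""
    return pd.DataFrame(
        {
            "seizure_index": [lab.index for lab in labels],
            "category": [lab.category for lab in labels],
            "is_cluster_first": [lab.is_cluster_first for lab in labels],
            "cluster_id": [lab.cluster_id for lab in labels],
        }
    )
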