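"""The five classification task datasets.

Each task filters and relabels the epoch feature matrix:

1. normal vs abnormal — A -> ``normal``; B, C, D -> ``abnormal``
2. abnormal subtype — A excluded; labels B, C, D
3. full stratification — four classes A, B, C, D
4. normal vs ictal — only A and D kept
5. interictal vs ictal — A excluded; B, C -> ``interictal``; D -> ``ictal``

Relabeling is label-only: feature rows are passed through bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

__all__ = ["TaskSpec", "TASK_REGISTRY", "TaskDataset", "build_task_dataset"]


@dataclass(frozen=True)
class TaskSpec:
    task_id: int
    name: str
    included: tuple[str, ...]
    label_map: dict[str, str] = field(hash=False)


TASK_REGISTRY: dict[int, TaskSpec] = {
    1: TaskSpec(1, "normal vs abnormal", ("A", "B", "C", "D"),
                {"A": "normal", "B": "abnormal", "C": "abnormal", "D": "abnormal"}),
    2: TaskSpec(2, "abnormal subtype", ("B", "C", "D"),
                {"B": "B", "C": "C", "D": "D"}),
    3: TaskSpec(3, "four-class stratification", ("A", "B", "C", "D"),
                {"A": "A", "B": "B", "C": "C", "D": "D"}),
    4: TaskSpec(4, "normal vs ictal", ("A", "D"),
                {"A": "normal", "D": "ictal"}),
    5: TaskSpec(5, "interictal vs ictal", ("B", "C", "D"),
                {"B": "interictal", "C": "interictal", "D": "ictal"}),
}


@dataclass
class TaskDataset:
    """Rows of a FeatureMatrix restricted and relabeled for one task."""

    task_id: int
    X: np.ndarray
    y: np.ndarray  # task labels
    subjects: np.ndarray
    source_labels: np.ndarray  # original A-D classes of the kept rows

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.y))

    def __len__(self) -> int:
        return len(self.y)


def build_task_dataset(fm: FeatureMatrix, task_id: int) -> TaskDataset:
    """Filter ``fm`` to a task's classes and remap labels per its spec."""
    if task_id not in TASK_REGISTRY:
        raise KeyError(f"unknown task_id {task_id}; known: {sorted(TASK_REGISTRY)}")
    spec = TASK_REGISTRY[task_id]
    present = set(np.unique(fm.labels))
    missing = [c for c in spec.included if c not in present]
    if missing:
        raise ValueError(
            f"task {task_id} requires class(es) {missing} absent from the data"
        )
    mask = np.isin(fm.labels, spec.included)
    y = np.array([spec.label_map[lab] for lab in fm.labels[mask]])
    return TaskDataset(
        task_id=task_id,
        X=fm.values[mask],
        y=y,
        subjects=fm.subjects[mask],
        source_labels=fm.labels[mask],
    )
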