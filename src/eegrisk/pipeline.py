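"""End-to-end convenience: cohort -> filter -> epochs -> features -> metrics."""

from __future__ import annotations

import numpy as np

from .epoching import EpochSet, epoch_recording
from .evaluation import MetricsReport, evaluate_task, subject_wise_split
from .features import FeatureMatrix, build_feature_matrix
from .preprocessing import FilterSpec, bandpass_recording
from .synthetic import CohortConfig, SubjectRecording, generate_cohort
from .tasks import TASK_REGISTRY, build_task_dataset

__all__ = [
    "preprocess_cohort",
    "cohort_feature_matrix",
    "run_task",
    "run_all_tasks",
]


def preprocess_cohort(cohort: list[SubjectRecording],
                      spec: FilterSpec = FilterSpec()) -> list[SubjectRecording]:
    """Zero-phase band-pass every recording, preserving annotations."""
    return [
        SubjectRecording(
            subject_id=rec.subject_id,
            signal=bandpass_recording(rec.signal, spec),
            fs=rec.fs,
            channel_names=list(rec.channel_names),
            annotations=list(rec.annotations),
        )
        for rec in cohort
    ]


def cohort_feature_matrix(cohort: list[SubjectRecording],
                          epoch_len: float = 1.0) -> FeatureMatrix:
    """Epoch and featurize a (filtered) cohort into one matrix."""
    all_epochs = []
    for rec in cohort:
        all_epochs.extend(epoch_recording(rec, epoch_len).epochs)
    return build_feature_matrix(EpochSet(all_epochs))


def run_task(fm: FeatureMatrix, task_id: int, model: str,
             seed: int = 0, test_fraction: float = 0.2) -> MetricsReport:
    dataset = build_task_dataset(fm, task_id)
    split = subject_wise_split(dataset, test_fraction, seed)
    return evaluate_task(dataset, model, seed=seed, split=split)


def run_all_tasks(fm: FeatureMatrix, models: tuple[str, ...] = ("svm", "rf", "knn"),
                  seed: int = 0, test_fraction: float = 0.2,
                  task_ids: tuple[int, ...] | None = None) -> list[MetricsReport]:
    """One report per (task, model); the split is shared within each task."""
    reports = []
    for task_id in (task_ids or tuple(TASK_REGISTRY)):
        dataset = build_task_dataset(fm, task_id)
        split = subject_wise_split(dataset, test_fraction, seed)
        for model in models:
            reports.append(evaluate_task(dataset, model, seed=seed, split=split))
    return reports


def simulate_and_featurize(config: CohortConfig,
                           filter_spec: FilterSpec = FilterSpec()) -> FeatureMatrix:
    """Generate, filter, epoch and featurize a cohort in one call."""
    cohort = generate_cohort(config)
    filtered = preprocess_cohort(cohort, filter_spec)
    return cohort_feature_matrix(filtered)
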