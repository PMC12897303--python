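"""Fixed-length epoch segmentation and annotation-driven labeling.

Recordings are cut into consecutive non-overlapping 1-s windows aligned to
t = 0; a trailing partial window is dropped. An epoch is retained only if at
least one annotation interval overlaps it, and takes that annotation's class
label. When several classes overlap one window the most severe wins
(D > C > B > A), so an ictal second is never masked by a benign label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .synthetic import CLASS_LABELS, AnnotationEvent, SubjectRecording

__all__ = ["Epoch", "EpochSet", "segment_epochs", "label_epochs", "epoch_recording"]

#: clinical severity, most severe first
_SEVERITY = ("D", "C", "B", "A")


@dataclass
class Epoch:
    subject_id: str
    start: float  # seconds from recording start
    data: np.ndarray  # channels x (epoch_len * fs)
    label: str | None = None


@dataclass
class EpochSet:
    """Labeled epochs with per-class counts and the contributing subjects."""

    epochs: list[Epoch] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(ep.label for ep in self.epochs))

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for ep in self.epochs:
            seen.setdefault(ep.subject_id)
        return list(seen)

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)


def segment_epochs(rec: SubjectRecording, epoch_len: float = 1.0) -> list[Epoch]:
    """Cut ``rec`` into unlabeled candidate epochs on the t = 0 grid."""
    n_per = epoch_len * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"epoch_len {epoch_len} s is not an integer number of samples at "
            f"fs={rec.fs}"
        )
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    return [
        Epoch(
            subject_id=rec.subject_id,
            start=i * epoch_len,
            data=rec.signal[:, i * n_per:(i + 1) * n_per],
        )
        for i in range(n_epochs)
    ]


def label_epochs(candidates: list[Epoch], annotations: list[AnnotationEvent],
                 epoch_len: float = 1.0) -> EpochSet:
    """Keep annotated candidates, assigning the most severe overlapping class."""
    for ev in annotations:
        if ev.label not in CLASS_LABELS:
            raise ValueError(f"annotation label {ev.label!r} outside {CLASS_LABELS}")
    kept: list[Epoch] = []
    for ep in candidates:
        lo, hi = ep.start, ep.start + epoch_len
        overlapping = {
            ev.label for ev in annotations if ev.onset < hi and ev.end > lo
        }
        if not overlapping:
            continue
        label = next(lab for lab in _SEVERITY if lab in overlapping)
        kept.append(Epoch(ep.subject_id, ep.start, ep.data, label))
    return EpochSet(kept)


def epoch_recording(rec: SubjectRecording, epoch_len: float = 1.0) -> EpochSet:
    """Segment and label one recording in a single call."""
    return label_epochs(segment_epochs(rec, epoch_len), rec.annotations, epoch_len)
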