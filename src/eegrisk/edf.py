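"""EDF+ persistence for annotated recordings.

The writer emits standard EDF+C files directly: the format is a fixed-layout
ASCII header followed by little-endian 16-bit data records, with label
intervals stored as time-stamped annotation lists (TALs) in an
``EDF Annotations`` signal. Reading goes through :func:`mne.io.read_raw_edf`,
so every file we write is validated by an independent parser.

Samples are quantized to the 16-bit digital range over a symmetric physical
range chosen per file; the worst-case round-trip error is half of one
quantization step, i.e. < (physical range) / 2**15.
"""

from __future__ import annotations

import math
import os
import warnings

import numpy as np

from .synthetic import AnnotationEvent, SubjectRecording

__all__ = ["write_recording", "read_recording"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} ascii bytes")
    return b.ljust(width)


def _fmt_time(value: float) -> str:
    """Shortest decimal representation, exact for integral seconds."""
    if value == int(value):
        return str(int(value))
    return f"{value:.7f}".rstrip("0").rstrip(".")


def _annotation_tals(rec: SubjectRecording, n_records: int) -> list[bytes]:
    """Per-record annotation byte streams (timekeeping TAL + event TALs)."""
    per_record: list[bytes] = []
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for ev in rec.annotations:
            if int(math.floor(ev.onset)) == r:
                tal += (
                    f"+{_fmt_time(ev.onset)}\x15{_fmt_time(ev.duration)}"
                    f"\x14{ev.label}\x14\x00"
                ).encode("ascii")
        per_record.append(tal)
    return per_record


def write_recording(rec: SubjectRecording, path: str | os.PathLike) -> None:
    """Write ``rec`` as an EDF+C file with a 1-s data-record duration.

    Recordings whose length is not a whole number of seconds are zero-padded
    to the next full record (with a warning).
    """
    fs = rec.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(fs - spr) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    n_ch, n_samp = rec.signal.shape
    n_records = int(math.ceil(n_samp / spr))
    pad = n_records * spr - n_samp
    signal = rec.signal
    if pad:
        warnings.warn(
            f"padding {pad} samples to complete the last 1-s EDF record",
            stacklevel=2,
        )
        signal = np.pad(signal, ((0, 0), (0, pad)))

    # symmetric physical range wide enough for the data, >= ±1 µV
    phys = max(1.0, float(np.ceil(np.max(np.abs(signal)))))
    scale = (_DIG_MAX - _DIG_MIN) / (2 * phys)
    digital = np.clip(
        np.round((signal + phys) * scale) + _DIG_MIN, _DIG_MIN, _DIG_MAX
    ).astype("<i2")

    tals = _annotation_tals(rec, n_records)
    ann_bytes = max(60, max(len(t) for t in tals))
    ann_bytes += ann_bytes % 2  # int16-aligned
    ann_spr = ann_bytes // 2

    ns = n_ch + 1  # data channels + annotation channel
    header_bytes = 256 * (1 + ns)

    with open(path, "wb") as fh:
        fh.write(_fixed("0", 8))
        fh.write(_fixed(f"{rec.subject_id} X X X", 80))
        fh.write(_fixed("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_fixed("01.01.00", 8))
        fh.write(_fixed("00.00.00", 8))
        fh.write(_fixed(str(header_bytes), 8))
        fh.write(_fixed("EDF+C", 44))
        fh.write(_fixed(str(n_records), 8))
        fh.write(_fixed("1", 8))
        fh.write(_fixed(str(ns), 4))

        labels = list(rec.channel_names) + ["EDF Annotations"]
        for lab in labels:
            fh.write(_fixed(lab, 16))
        for _ in labels:
            fh.write(_fixed("", 80))  # transducer
        for i in range(ns):
            fh.write(_fixed("uV" if i < n_ch else "", 8))
        for i in range(ns):
            fh.write(_fixed(f"{-phys:g}" if i < n_ch else "-1", 8))
        for i in range(ns):
            fh.write(_fixed(f"{phys:g}" if i < n_ch else "1", 8))
        for _ in range(ns):
            fh.write(_fixed(str(_DIG_MIN), 8))
        for _ in range(ns):
            fh.write(_fixed(str(_DIG_MAX), 8))
        for _ in labels:
            fh.write(_fixed("", 80))  # prefiltering
        for i in range(ns):
            fh.write(_fixed(str(spr if i < n_ch else ann_spr), 8))
        for _ in range(ns):
            fh.write(_fixed("", 32))

        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes(order="C"))
            fh.write(tals[r].ljust(ann_bytes, b"\x00"))


def read_recording(path: str | os.PathLike) -> SubjectRecording:
    """Read an EDF+ file back into a :class:`SubjectRecording` (signal in µV)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # MNE loads EDF in volts
    annotations = [
        AnnotationEvent(onset=float(on), duration=float(du), label=str(desc))
        for on, du, desc in zip(
            raw.annotations.onset, raw.annotations.duration,
            raw.annotations.description,
        )
    ]
    info = raw.info.get("subject_info") or {}
    subject_id = info.get("his_id") or os.path.splitext(os.path.basename(path))[0]
    return SubjectRecording(
        subject_id=str(subject_id),
        signal=signal,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        annotations=annotations,
    )
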