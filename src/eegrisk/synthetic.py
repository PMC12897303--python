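"""Seeded synthetic EEG cohorts with four annotated clinical classes.

Generates multi-subject, multi-channel recordings in which every second of
signal belongs to exactly one annotated interval of class

* ``A`` — normal background: 1/f noise plus posterior-dominant alpha (8–13 Hz),
* ``B`` — slowing: delta/theta (0.5–7 Hz) power gain with attenuated alpha,
* ``C`` — epileptiform discharges: class-A background plus sparse
  spike-and-slow-wave transients (~70 ms spike + ~300 ms wave) on a channel
  subset,
* ``D`` — electrographic seizure: rhythmic chirp (default 3→6 Hz) with a
  monotonically growing amplitude envelope on most channels.

The generator is a pure function of ``(config, seed)``: one root
``numpy.random.SeedSequence`` spawns an independent stream per subject.
Amplitudes are in microvolts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CLASS_LABELS",
    "CHANNEL_NAMES_23",
    "AnnotationEvent",
    "SubjectRecording",
    "CohortConfig",
    "synthesize_class_segment",
    "generate_cohort",
]

CLASS_LABELS = ("A", "B", "C", "D")

#: 19 scalp electrodes of the 10–20 montage plus A1/A2 references and two
#: midline auxiliaries to fill out the 23-channel acquisition layout.
CHANNEL_NAMES_23 = (
    "Fp2", "F4", "C4", "P4", "O2", "F8", "T4", "T6",
    "Fz", "Cz", "Pz",
    "Fp1", "F3", "C3", "P3", "O1", "F7", "T3", "T5",
    "A1", "A2", "Fpz", "Oz",
)


@dataclass(frozen=True)
class AnnotationEvent:
    """One expert-style label interval: (onset s, duration s, class)."""

    onset: float
    duration: float
    label: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class SubjectRecording:
    """Continuous multi-channel EEG (µV) with its annotation events."""

    subject_id: str
    signal: np.ndarray  # channels x samples, µV
    fs: float
    channel_names: list[str]
    annotations: list[AnnotationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a channels x samples matrix")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        dur = self.duration
        for ev in self.annotations:
            if ev.end > dur + 1e-9:
                raise ValueError(
                    f"annotation {ev} extends past recording end ({dur:.3f} s)"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for cohort synthesis.

    Default class mix follows the empirical label proportions of a clinical
    interictal/ictal EEG corpus (normal most frequent, discharges rarest):
    A 47.1%, B 26.2%, C 2.9%, D 23.7% of annotated time.
    """

    n_subjects: int = 20
    fs: float = 250.0
    n_channels: int = 23
    recording_length: float = 600.0  # seconds per subject
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"A": 0.4714, "B": 0.2622, "C": 0.0294, "D": 0.2370}
    )
    seed: int = 0

    # per-class signal parameters
    background_amp_uv: float = 10.0   # RMS of the 1/f floor
    alpha_amp_uv: float = 20.0        # class-A alpha rhythm amplitude
    slowing_gain: float = 3.0         # delta/theta amplitude gain in class B
    slowing_alpha_atten: float = 0.3  # alpha attenuation factor in class B
    spike_rate_hz: float = 1.0        # expected spike-wave transients per second
    spike_amp_uv: float = 120.0       # spike peak amplitude
    spike_n_channels: int = 4         # focal channel subset carrying discharges
    seizure_chirp_hz: tuple[float, float] = (3.0, 6.0)
    seizure_amp_growth: float = 4.0   # envelope growth factor start -> end
    seizure_base_amp_uv: float = 20.0
    event_len_range_s: tuple[int, int] = (5, 15)  # annotated interval lengths

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix fractions must sum to 1, got {total}")
        for lab, frac in self.class_mix.items():
            if lab not in CLASS_LABELS:
                raise ValueError(f"unknown class {lab!r} in class_mix")
            if frac < 0:
                raise ValueError(f"negative fraction for class {lab}")
        highest = max(
            13.0 * 1.0,  # alpha top
            self.seizure_chirp_hz[1],
            45.0,  # spectral content of the spike transient
        )
        if self.fs <= 2 * highest:
            raise ValueError(f"fs={self.fs} violates Nyquist for {highest} Hz content")
        if self.recording_length < 1.0:
            raise ValueError("recording_length must be >= 1 s")

    def channel_names(self) -> list[str]:
        if self.n_channels <= len(CHANNEL_NAMES_23):
            return list(CHANNEL_NAMES_23[: self.n_channels])
        extra = [f"X{i}" for i in range(self.n_channels - len(CHANNEL_NAMES_23))]
        return list(CHANNEL_NAMES_23) + extra


def _pink_background(rng: np.random.Generator, n_channels: int, n_samples: int,
                     fs: float, rms_uv: float, exponent: float = 1.0) -> np.ndarray:
    """Per-channel 1/f^(exponent/2)-amplitude noise floor, scaled to a target RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    sig = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(sig**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return sig / rms * rms_uv


def _spike_wave_kernel(fs: float, amp_uv: float) -> np.ndarray:
    """~70 ms sharp spike followed by a ~300 ms slow wave of opposite polarity."""
    n_spike = max(3, int(round(0.070 * fs)))
    n_wave = max(3, int(round(0.300 * fs)))
    t_s = np.linspace(-1.0, 1.0, n_spike)
    spike = amp_uv * (1.0 - np.abs(t_s))  # sharp triangular apex
    t_w = np.linspace(0.0, np.pi, n_wave)
    wave = -0.45 * amp_uv * np.sin(t_w)
    return np.concatenate([spike, wave])


def synthesize_class_segment(label: str, duration: float, n_channels: int,
                             fs: float, rng: np.random.Generator,
                             config: CohortConfig | None = None) -> np.ndarray:
    """Generate one (n_channels x round(duration*fs)) signal block for a class.

    Parameters are taken from ``config`` (a default ``CohortConfig`` if None);
    ``rng`` supplies all randomness so blocks are reproducible per stream.
    """
    cfg = config if config is not None else CohortConfig()
    n_samples = int(round(duration * fs))
    if n_samples < 1:
        raise ValueError(f"duration {duration} s yields no samples at fs={fs}")
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {label!r}")

    t = np.arange(n_samples) / fs

    if label in ("A", "C"):
        sig = _pink_background(rng, n_channels, n_samples, fs, cfg.background_amp_uv)
        f_alpha = rng.uniform(8.5, 12.5)
        phases = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
        # slow waxing/waning envelope typical of a posterior alpha rhythm
        env = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.05, 0.2) * t
                                 + rng.uniform(0, 2 * np.pi))
        amps = cfg.alpha_amp_uv * rng.uniform(0.6, 1.0, size=(n_channels, 1))
        sig += amps * env * np.sin(2 * np.pi * f_alpha * t + phases)
        if label == "C":
            kernel = _spike_wave_kernel(fs, cfg.spike_amp_uv)
            n_events = rng.poisson(cfg.spike_rate_hz * duration)
            n_focal = min(cfg.spike_n_channels, n_channels)
            focal = rng.choice(n_channels, size=n_focal, replace=False)
            max_start = n_samples - len(kernel)
            for _ in range(n_events):
                if max_start <= 0:
                    break
                start = rng.integers(0, max_start)
                jitter = rng.uniform(0.7, 1.0, size=n_focal)
                polarity = rng.choice([-1.0, 1.0])
                for ch, j in zip(focal, jitter):
                    sig[ch, start:start + len(kernel)] += polarity * j * kernel
        return sig

    if label == "B":
        # heavier low-frequency tilt plus explicit delta and theta rhythms
        sig = _pink_background(rng, n_channels, n_samples, fs,
                               cfg.background_amp_uv, exponent=1.5)
        slow_amp = cfg.slowing_gain * cfg.alpha_amp_uv
        for f_lo, frac in ((rng.uniform(1.0, 3.0), 0.7), (rng.uniform(4.0, 6.5), 0.5)):
            phases = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
            amps = frac * slow_amp * rng.uniform(0.6, 1.0, size=(n_channels, 1))
            sig += amps * np.sin(2 * np.pi * f_lo * t + phases)
        f_alpha = rng.uniform(8.5, 12.5)
        phases = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
        amps = (cfg.slowing_alpha_atten * cfg.alpha_amp_uv
                * rng.uniform(0.6, 1.0, size=(n_channels, 1)))
        sig += amps * np.sin(2 * np.pi * f_alpha * t + phases)
        return sig

    # label == "D": evolving rhythmic discharge with growing envelope
    sig = _pink_background(rng, n_channels, n_samples, fs, cfg.background_amp_uv)
    f0, f1 = cfg.seizure_chirp_hz
    # linear chirp: instantaneous frequency f0 -> f1 across the segment
    inst_freq = f0 + (f1 - f0) * t / max(t[-1], 1.0 / fs)
    phase = 2 * np.pi * np.cumsum(inst_freq) / fs
    envelope = cfg.seizure_base_amp_uv * (
        1.0 + (cfg.seizure_amp_growth - 1.0) * t / max(t[-1], 1.0 / fs)
    )
    n_involved = max(1, int(round(0.85 * n_channels)))
    involved = rng.choice(n_channels, size=n_involved, replace=False)
    offsets = rng.uniform(0, 0.4, size=(n_involved, 1))  # slight phase lags
    gains = rng.uniform(0.7, 1.0, size=(n_involved, 1))
    sig[involved] += gains * envelope * np.sin(phase + offsets)
    return sig


def _plan_events(cfg: CohortConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Plan an integer-second, shuffled tiling of one recording by class.

    Per-class total seconds follow ``class_mix``; totals are split into chunks
    of ``event_len_range_s`` seconds. Raises if a nonzero-fraction class cannot
    receive at least one whole second.
    """
    total = int(round(cfg.recording_length))
    targets: dict[str, int] = {}
    active = [c for c in CLASS_LABELS if cfg.class_mix.get(c, 0.0) > 0]
    for lab in active:
        secs = int(round(cfg.class_mix[lab] * total))
        if secs < 1:
            raise ValueError(
                f"class {lab} has fraction {cfg.class_mix[lab]} but the "
                f"{total}-s recording is too short to place a 1-s event"
            )
        targets[lab] = secs
    # nudge so totals sum exactly to the recording length (largest class absorbs)
    drift = total - sum(targets.values())
    targets[max(targets, key=targets.get)] += drift
    lo, hi = cfg.event_len_range_s
    chunks: list[tuple[str, int]] = []
    for lab in active:
        remaining = targets[lab]
        while remaining > 0:
            size = int(min(remaining, rng.integers(lo, hi + 1)))
            if remaining - size < lo and remaining - size > 0:
                size = remaining  # avoid a trailing sliver shorter than lo
            chunks.append((lab, size))
            remaining -= size
    order = rng.permutation(len(chunks))
    return [chunks[i] for i in order]


def generate_cohort(config: CohortConfig) -> list[SubjectRecording]:
    """Generate the full annotated cohort; deterministic for a fixed seed."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_subjects)
    names = config.channel_names()
    cohort: list[SubjectRecording] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        plan = _plan_events(config, rng)
        blocks: list[np.ndarray] = []
        events: list[AnnotationEvent] = []
        t0 = 0.0
        for lab, secs in plan:
            blocks.append(
                synthesize_class_segment(lab, float(secs), config.n_channels,
                                         config.fs, rng, config)
            )
            events.append(AnnotationEvent(onset=t0, duration=float(secs), label=lab))
            t0 += secs
        cohort.append(
            SubjectRecording(
                subject_id=f"S{i + 1:02d}",
                signal=np.concatenate(blocks, axis=1),
                fs=config.fs,
                channel_names=names,
                annotations=events,
            )
        )
    # every active class must be usable for subject-wise splitting
    for lab in (c for c in CLASS_LABELS if config.class_mix.get(c, 0.0) > 0):
        carriers = sum(any(ev.label == lab for ev in rec.annotations) for rec in cohort)
        if carriers < 2 and config.n_subjects >= 2:
            raise RuntimeError(
                f"class {lab} appears in {carriers} subject(s); "
                "subject-wise splits need at least 2"
            )
    return cohort


def cohort_manifest(config: CohortConfig, cohort: list[SubjectRecording]) -> dict:
    """JSON-serializable provenance record for a generated cohort."""
    return {
        "subjects": [rec.subject_id for rec in cohort],
        "seed": config.seed,
        "config": {
            "n_subjects": config.n_subjects,
            "fs": config.fs,
            "n_channels": config.n_channels,
            "recording_length": config.recording_length,
            "class_mix": dict(config.class_mix),
        },
    }


def with_class_mix(config: CohortConfig, mix: dict[str, float]) -> CohortConfig:
    """Convenience: derive a config with a different class mix."""
    return replace(config, class_mix=mix)
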