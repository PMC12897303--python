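"""Zero-phase FIR band-pass filtering and min–max scaling.

The band-pass is a linear-phase (symmetric) Hamming-window FIR whose length
follows the classic window-design rule

    n_taps = smallest odd integer >= 3.3 * fs / min(transition bandwidths)

with half-amplitude band edges placed at ``l_freq - l_trans_bw/2`` and
``h_freq + h_trans_bw/2``. At the defaults (0.5–40 Hz pass band, 0.50 Hz and
10.00 Hz transitions, 250 Hz sampling) this yields 1651 taps (6.604 s).
Zero-phase response is obtained by compensating the (L-1)/2-sample group
delay of a single forward convolution against a reflect-padded signal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import warnings

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "ScalerParams",
    "design_bandpass_fir",
    "apply_zero_phase",
    "bandpass_recording",
    "fit_minmax",
    "apply_minmax",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design parameters (Hz)."""

    l_freq: float = 0.5
    h_freq: float = 40.0
    l_trans_bw: float = 0.50
    h_trans_bw: float = 10.00
    fs: float = 250.0
    window: str = "hamming"

    def validate(self) -> None:
        if not (0 < self.l_freq < self.h_freq < self.fs / 2):
            raise ValueError(
                f"need 0 < l_freq < h_freq < fs/2, got "
                f"({self.l_freq}, {self.h_freq}) at fs={self.fs}"
            )
        if self.l_trans_bw <= 0 or self.h_trans_bw <= 0:
            raise ValueError("transition bandwidths must be > 0")
        if self.l_freq - self.l_trans_bw / 2 <= 0:
            raise ValueError("lower transition pushes the band edge below 0 Hz")
        if self.h_freq + self.h_trans_bw / 2 >= self.fs / 2:
            raise ValueError("upper transition pushes the band edge past Nyquist")

    @property
    def n_taps(self) -> int:
        n = int(np.ceil(3.3 * self.fs / min(self.l_trans_bw, self.h_trans_bw)))
        return n if n % 2 == 1 else n + 1

    def to_dict(self) -> dict:
        return asdict(self)


def design_bandpass_fir(spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Design the symmetric band-pass tap vector for ``spec``."""
    spec.validate()
    edges = [spec.l_freq - spec.l_trans_bw / 2, spec.h_freq + spec.h_trans_bw / 2]
    return sps.firwin(
        spec.n_taps, edges, fs=spec.fs, window=spec.window, pass_zero=False
    )


def apply_zero_phase(signal: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Filter ``signal`` (channels x samples or 1-D) with zero net phase delay.

    The signal is reflect-padded by the group delay on both sides, convolved
    once with the symmetric taps, and the delayed segment is extracted, so
    passband components line up sample-for-sample with the input.
    """
    arr = np.asarray(signal, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if not np.all(np.isfinite(arr)):
        raise ValueError("signal contains non-finite values")
    taps = np.asarray(taps, dtype=float)
    delay = (len(taps) - 1) // 2
    mode = "reflect" if arr.shape[1] > 1 else "edge"
    padded = np.pad(arr, ((0, 0), (delay, delay)), mode=mode)
    out = sps.oaconvolve(padded, taps[None, :], mode="full", axes=1)
    start = 2 * delay
    out = out[:, start:start + arr.shape[1]]
    return out[0] if squeeze else out


def bandpass_recording(signal: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Convenience: design for ``spec`` and apply zero-phase to a recording."""
    return apply_zero_phase(signal, design_bandpass_fir(spec))


@dataclass
class ScalerParams:
    """Per-row (channel or feature) min–max bounds fitted on training data."""

    minimum: np.ndarray
    maximum: np.ndarray
    population: str = ""

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("min/max shape mismatch")
        if np.any(self.maximum < self.minimum):
            raise ValueError("maximum < minimum in fitted scaler")

    def to_dict(self) -> dict:
        return {
            "minimum": self.minimum.tolist(),
            "maximum": self.maximum.tolist(),
            "population": self.population,
        }


def fit_minmax(train_arrays: list[np.ndarray] | np.ndarray,
               population: str = "train") -> ScalerParams:
    """Fit per-row bounds over one or more (rows x samples) training arrays.

    Only training-population data may be passed here; applying the fitted map
    to held-out data can legitimately produce values outside [0, 1].
    """
    if isinstance(train_arrays, np.ndarray):
        train_arrays = [train_arrays]
    if not train_arrays:
        raise ValueError("no training data to fit")
    mins = np.min([np.min(a, axis=-1) for a in train_arrays], axis=0)
    maxs = np.max([np.max(a, axis=-1) for a in train_arrays], axis=0)
    return ScalerParams(minimum=mins, maximum=maxs, population=population)


def apply_minmax(signal: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Linear per-row map sending fitted min -> 0 and max -> 1 (no clipping).

    Constant rows (max == min) map to 0 everywhere, with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    span = params.maximum - params.minimum
    degenerate = span == 0
    if np.any(degenerate):
        warnings.warn("constant row(s) in fitted scaler mapped to 0", stacklevel=2)
    safe = np.where(degenerate, 1.0, span)
    out = (signal - params.minimum[..., None]) / safe[..., None]
    out[degenerate, :] = 0.0
    return out
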