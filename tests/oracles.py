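"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the defining formulas with plain Python
loops / direct numpy calls, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sps


def brute_force_features(x) -> dict[str, float]:
    """The 16 band statistics computed naively from their definitions."""
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    std = math.sqrt(var)
    median = float(np.median(x))
    mean_abs = sum(abs(v) for v in x) / n
    max_abs = max(abs(v) for v in x)
    energy = sum(v * v for v in x)
    avg_power = energy / n
    if var > 0:
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        skew = m3 / std**3
        kurt = m4 / var**2 - 3.0
    else:
        skew = kurt = 0.0
    if energy > 0:
        probs = [v * v / energy for v in x]
        entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    else:
        entropy = 0.0
    zcr = sum(1 for a, b in zip(x, x[1:]) if a * b < 0) / (n - 1)
    wl = sum(abs(b - a) for a, b in zip(x, x[1:]))
    dx = [b - a for a, b in zip(x, x[1:])]
    mean_d = sum(dx) / len(dx)
    var_d = sum((v - mean_d) ** 2 for v in dx) / len(dx)
    mobility = math.sqrt(var_d / var) if var > 0 else 0.0
    ddx = [b - a for a, b in zip(dx, dx[1:])]
    mean_dd = sum(ddx) / len(ddx)
    var_dd = sum((v - mean_dd) ** 2 for v in ddx) / len(ddx)
    mob_d = math.sqrt(var_dd / var_d) if var_d > 0 else 0.0
    complexity = mob_d / mobility if mobility > 0 else 0.0
    return {
        "mean": mean, "std": std, "variance": var, "median": median,
        "mean_abs": mean_abs, "max_abs": max_abs, "energy": energy,
        "avg_power": avg_power, "skewness": skew, "kurtosis": kurt,
        "shannon_entropy": entropy, "zero_crossing_rate": zcr,
        "waveform_length": wl, "hjorth_activity": var,
        "hjorth_mobility": mobility, "hjorth_complexity": complexity,
    }


def relative_band_power(signal_1d, fs, f_lo, f_hi) -> float:
    """Welch-periodogram fraction of total power inside [f_lo, f_hi]."""
    freqs, psd = sps.welch(signal_1d, fs=fs, nperseg=min(len(signal_1d), 1024))
    band = (freqs >= f_lo) & (freqs <= f_hi)
    return float(psd[band].sum() / psd.sum())


def count_transients(signal_1d, threshold) -> int:
    """Amplitude-threshold peak counter with a 200 ms refractory gap."""
    peaks, _ = sps.find_peaks(np.abs(signal_1d), height=threshold, distance=50)
    return len(peaks)


def xcorr_peak_lag(x, y) -> int:
    """Lag (samples) of the maximum of the full cross-correlation of x and y."""
    c = sps.correlate(y, x, mode="full")
    return int(np.argmax(c) - (len(x) - 1))
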