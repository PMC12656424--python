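"""Filtering, normalization and channel averaging.

sEMG: 50 Hz mains notch (second-order IIR, Q = 30) followed by a 1-400 Hz
4th-order Butterworth band-pass, both applied forward-backward so the net
phase is zero (the bidirectional pass doubles the effective magnitude
order).  Accelerometer: 0.1-5 Hz 4th-order Butterworth, zero-phase, per
axis.  Edge transients are suppressed by reflective padding of up to 1 s
before the bidirectional pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal

from .errors import ConfigError, DegenerateInputError, SchemaError, ValidationError
from .types import N_CHANNELS

SEMG_BAND = (1.0, 400.0)
ACC_BAND = (0.1, 5.0)
NOTCH_FREQ = 50.0
NOTCH_Q = 30.0
FILTER_ORDER = 4


@dataclass(frozen=True)
class FilterSpec:
    """Descriptor of one filtering stage."""

    kind: str                 # "notch" | "bandpass"
    edges: Tuple[float, ...]  # Hz
    order: int = FILTER_ORDER
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ConfigError(f"filter order must be >= 1, got {self.order}")
        for e in self.edges:
            if not 0.0 < e < fs / 2:
                raise ConfigError(
                    f"filter edge {e} Hz outside (0, {fs / 2}) Hz at fs = {fs} Hz")


def _padlen(fs: float, n: int) -> int:
    # reflective padding of up to 1 s, capped for short inputs
    return max(1, min(int(round(fs)), n - 2))


def _zero_phase_sos(sos: np.ndarray, x: np.ndarray, fs: float) -> np.ndarray:
    return signal.sosfiltfilt(sos, x, axis=0, padtype="even",
                              padlen=_padlen(fs, x.shape[0]))


def filter_semg(semg: np.ndarray, fs: float, notch: bool = True) -> np.ndarray:
    """Notch (50 Hz) then band-pass (1-400 Hz) each channel, zero-phase."""
    semg = np.asarray(semg, dtype=float)
    if not np.all(np.isfinite(semg)):
        raise ValidationError("sEMG contains non-finite samples")
    spec = FilterSpec("bandpass", SEMG_BAND)
    if fs <= 800.0:
        raise ConfigError(f"sEMG sampling rate must exceed 800 Hz, got {fs}")
    spec.validate(fs)
    flat = semg.ndim == 1
    x = semg[:, None] if flat else semg
    if notch:
        b, a = signal.iirnotch(NOTCH_FREQ, NOTCH_Q, fs=fs)
        x = signal.filtfilt(b, a, x, axis=0, padtype="even",
                            padlen=_padlen(fs, x.shape[0]))
    sos = signal.butter(FILTER_ORDER, SEMG_BAND, btype="bandpass", fs=fs, output="sos")
    y = _zero_phase_sos(sos, x, fs)
    return y[:, 0] if flat else y


def filter_acc(acc: np.ndarray, fs: float) -> np.ndarray:
    """Band-pass each accelerometer axis between 0.1 and 5 Hz, zero-phase."""
    acc = np.asarray(acc, dtype=float)
    if not np.all(np.isfinite(acc)):
        raise ValidationError("accelerometer contains non-finite samples")
    if fs <= 10.0:
        raise ConfigError(f"accelerometer sampling rate must exceed 10 Hz, got {fs}")
    FilterSpec("bandpass", ACC_BAND).validate(fs)
    flat = acc.ndim == 1
    x = acc[:, None] if flat else acc
    sos = signal.butter(FILTER_ORDER, ACC_BAND, btype="bandpass", fs=fs, output="sos")
    y = _zero_phase_sos(sos, x, fs)
    return y[:, 0] if flat else y


def normalize(x: np.ndarray, method: str = "zscore") -> np.ndarray:
    """Normalize a vector.

    ``zscore``: (x - mean) / sample SD (ddof = 1).
    ``robust``: (x - median) / IQR, IQR = 75th - 25th percentile with linear
    interpolation.
    ``minmax``: (x - min) / (max - min), mapped onto [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if method == "zscore":
        scale = x.std(ddof=1) if x.size > 1 else 0.0
        center = x.mean()
    elif method == "robust":
        q25, q75 = np.percentile(x, [25.0, 75.0])
        scale = q75 - q25
        center = np.median(x)
    elif method == "minmax":
        lo, hi = x.min(), x.max()
        scale = hi - lo
        center = lo
    else:
        raise ConfigError(f"unknown normalization method {method!r}")
    if scale <= 0:
        raise DegenerateInputError(f"zero scale: cannot {method}-normalize a constant signal")
    return (x - center) / scale


def grid_average(semg: np.ndarray) -> np.ndarray:
    """Per-sample arithmetic mean across the 32 grid channels."""
    semg = np.asarray(semg, dtype=float)
    if semg.ndim != 2 or semg.shape[1] != N_CHANNELS:
        raise SchemaError(
            f"grid_average expects [n, {N_CHANNELS}], got shape {semg.shape}")
    return semg.mean(axis=1)
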