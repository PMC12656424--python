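"""Swallow localization by windowed multimodal energy fusion.

Both preprocessed streams are scanned with 0.5-s windows stepped by 0.2 s
(0.3-s overlap) on a shared continuous-time clock, so the two sampling
rates need no resampling.  Per window we take the RMS of the grid-averaged
sEMG and of the accelerometer vector magnitude; each trace is min-max
normalized over the trial, the two are fused by an unweighted mean, and the
swallow peak is the center of the argmax window (earliest window wins
ties).  Windows overlapping annotated intake/mastication intervals are
excluded.  The analysis epoch is the 2-s segment centered on the peak,
shifted minimally to fit the trial boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .errors import DetectionError, EpochError, SchemaError
from .preprocess import grid_average
from .types import Epoch, Recording, N_CHANNELS

WIN_LEN_S = 0.5
STEP_S = 0.2


@dataclass(frozen=True)
class WindowGrid:
    """Common analysis-window clock for both sensor streams."""

    duration_s: float
    win_len_s: float = WIN_LEN_S
    step_s: float = STEP_S
    starts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.win_len_s:
            raise SchemaError("window grid needs 0 < step <= window length")
        if self.duration_s < self.win_len_s:
            raise SchemaError("trial shorter than one analysis window")
        n = int(np.floor((self.duration_s - self.win_len_s) / self.step_s + 1e-9)) + 1
        object.__setattr__(self, "starts", np.arange(n) * self.step_s)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.win_len_s / 2.0


def _to_trace(signal: np.ndarray) -> np.ndarray:
    """Collapse a stream to one scalar series: grid mean or vector magnitude."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        return signal
    if signal.shape[1] == N_CHANNELS:
        return grid_average(signal)
    if signal.shape[1] == 3:
        return np.sqrt((signal ** 2).sum(axis=1))
    raise SchemaError(
        f"expected {N_CHANNELS}-channel sEMG, 3-axis accelerometer or 1-D signal, "
        f"got shape {signal.shape}")


def window_energy(signal: np.ndarray, fs: float, grid: WindowGrid) -> np.ndarray:
    """Per-window RMS energy of a (preprocessed) stream on the shared grid."""
    x = _to_trace(signal)
    out = np.empty(len(grid.starts))
    for i, t0 in enumerate(grid.starts):
        a = int(round(t0 * fs))
        b = int(round((t0 + grid.win_len_s) * fs))
        b = min(b, x.shape[0])
        seg = x[a:b]
        out[i] = np.sqrt(np.mean(seg ** 2)) if seg.size else 0.0
    return out


def _minmax_or_zeros(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def fuse_and_peak(
    semg_energy: np.ndarray,
    acc_energy: np.ndarray,
    grid: WindowGrid,
    exclusion: Optional[Iterable[Tuple[float, float]]] = None,
    weights: Tuple[float, float] = (0.5, 0.5),
) -> float:
    """Fuse the two energy traces and return the swallow peak time (s).

    ``weights`` are the per-modality fusion weights (sEMG, accelerometer);
    the default is the unweighted mean.
    """
    semg_energy = np.asarray(semg_energy, dtype=float)
    acc_energy = np.asarray(acc_energy, dtype=float)
    if semg_energy.shape != acc_energy.shape or len(semg_energy) != len(grid.starts):
        raise SchemaError("energy traces must share the window grid")
    w_semg, w_acc = weights
    fused = w_semg * _minmax_or_zeros(semg_energy) \
        + w_acc * _minmax_or_zeros(acc_energy)
    if exclusion is not None:
        for (a, b) in exclusion:
            overlap = (grid.starts < b) & (grid.starts + grid.win_len_s > a)
            fused[overlap] = -np.inf
    if not np.any(np.isfinite(fused)):
        raise DetectionError("all analysis windows fall inside exclusion intervals")
    # np.argmax returns the first maximum: earliest window wins ties.
    return float(grid.centers[int(np.argmax(fused))])


def extract_epoch(rec: Recording, t_peak: float,
                  semg: Optional[np.ndarray] = None,
                  acc: Optional[np.ndarray] = None) -> Epoch:
    """Cut the 2-s epoch centered on ``t_peak`` from both streams.

    ``semg``/``acc`` default to the recording's raw arrays; pass filtered
    arrays to epoch the preprocessed signals.  If the centered window would
    overrun a boundary it is shifted minimally to fit and the shift recorded.
    """
    if rec.duration < 2.0:
        raise EpochError(f"trial of {rec.duration:.2f} s is shorter than the 2-s epoch")
    semg = rec.semg if semg is None else np.asarray(semg, dtype=float)
    acc = rec.acc if acc is None else np.asarray(acc, dtype=float)

    n_epoch = int(round(2 * rec.fs_semg))
    t0 = min(max(t_peak - 1.0, 0.0), rec.duration - 2.0)
    shift_s = t0 - (t_peak - 1.0)
    start_clamped = min(max(int(round(t0 * rec.fs_semg)), 0),
                        semg.shape[0] - n_epoch)
    t0 = start_clamped / rec.fs_semg

    m_epoch = int(round(2 * rec.fs_acc))
    a_start = int(round(t0 * rec.fs_acc))
    a_start = min(max(a_start, 0), acc.shape[0] - m_epoch)

    return Epoch(
        subject_id=rec.subject_id,
        task=rec.task,
        trial=rec.trial,
        t_peak=float(t_peak),
        semg_seg=semg[start_clamped:start_clamped + n_epoch],
        acc_seg=acc[a_start:a_start + m_epoch],
        fs_semg=rec.fs_semg,
        fs_acc=rec.fs_acc,
        left_channels=rec.left_channels,
        right_channels=rec.right_channels,
        shift_s=float(shift_s),
        group=rec.group,
    )


def detect_peak(rec: Recording, semg_filt: np.ndarray, acc_filt: np.ndarray,
                grid: Optional[WindowGrid] = None) -> float:
    """Run the fused detector on a preprocessed recording."""
    if grid is None:
        grid = WindowGrid(rec.duration)
    se = window_energy(semg_filt, rec.fs_semg, grid)
    ae = window_energy(acc_filt, rec.fs_acc, grid)
    return fuse_and_peak(se, ae, grid, exclusion=rec.events.exclusion_intervals())
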