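"""Shared data model: recordings, event annotations and analysis epochs.

A :class:`Recording` holds one synchronized swallowing trial: a 32-channel
submental HD-sEMG stream (4x8 electrode grid, default 2048 Hz) and a triaxial
laryngeal accelerometer stream (default 1024 Hz), plus task/trial metadata and
event annotations.  An :class:`Epoch` is the fixed 2-s multichannel segment
centered on the detected swallow peak, the unit of all feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import ValidationError

TASKS = ("WT", "GT", "ST")  # water / gelled water / solid (bread) bolus
GROUPS = ("PD", "HC")

N_CHANNELS = 32
GRID_ROWS = 4
GRID_COLS = 8

#: Grid-half convention: the electrode grid is laid out row-major
#: (channel = row * 8 + col); rows 0-1 are the "left" half, rows 2-3 the
#: "right" half.  The mapping is stored per recording so alternative
#: montages remain configurable.
DEFAULT_LEFT_CHANNELS = tuple(range(0, 16))
DEFAULT_RIGHT_CHANNELS = tuple(range(16, 32))


@dataclass
class EventAnnotations:
    """Per-trial event times in seconds from recording start.

    Mastication start/end (MS/ME) come from manual video annotation; swallow
    start/end (SS/SE) from the automated detector.  ``intake_interval`` marks
    an optional oral-intake window excluded from detection.
    """

    mastication_start: Optional[float] = None
    mastication_end: Optional[float] = None
    swallow_start: Optional[float] = None
    swallow_end: Optional[float] = None
    intake_interval: Optional[Tuple[float, float]] = None

    def exclusion_intervals(self) -> list[tuple[float, float]]:
        """Intervals (intake, mastication) that detection must skip."""
        out = []
        if self.mastication_start is not None and self.mastication_end is not None:
            out.append((float(self.mastication_start), float(self.mastication_end)))
        if self.intake_interval is not None:
            out.append((float(self.intake_interval[0]), float(self.intake_interval[1])))
        return out

    def validate(self, duration: float) -> None:
        for name, a, b in [
            ("mastication", self.mastication_start, self.mastication_end),
            ("swallow", self.swallow_start, self.swallow_end),
        ]:
            if a is not None and b is not None and not a < b:
                raise ValidationError(f"{name} start must precede {name} end ({a} >= {b})")
        times = [self.mastication_start, self.mastication_end,
                 self.swallow_start, self.swallow_end]
        if self.intake_interval is not None:
            if not self.intake_interval[0] < self.intake_interval[1]:
                raise ValidationError("intake interval start must precede its end")
            times += list(self.intake_interval)
        for t in times:
            if t is not None and not 0.0 <= t <= duration:
                raise ValidationError(
                    f"event time {t} s outside recording duration [0, {duration}] s")


@dataclass
class Recording:
    """One synchronized HD-sEMG + accelerometer swallowing trial."""

    subject_id: str
    group: str                  # "PD" | "HC"
    task: str                   # "WT" | "GT" | "ST"
    trial: int
    semg: np.ndarray            # [n_samples, 32] in mV
    acc: np.ndarray             # [m_samples, 3] in g
    fs_semg: float = 2048.0
    fs_acc: float = 1024.0
    grid_rows: int = GRID_ROWS
    grid_cols: int = GRID_COLS
    left_channels: Tuple[int, ...] = DEFAULT_LEFT_CHANNELS
    right_channels: Tuple[int, ...] = DEFAULT_RIGHT_CHANNELS
    events: EventAnnotations = field(default_factory=EventAnnotations)

    def __post_init__(self) -> None:
        self.semg = np.asarray(self.semg, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.validate()

    @property
    def duration(self) -> float:
        """Trial duration in seconds (from the sEMG stream)."""
        return self.semg.shape[0] / self.fs_semg

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.task not in TASKS:
            raise ValidationError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.trial < 1:
            raise ValidationError(f"trial index must be >= 1, got {self.trial}")
        if self.fs_semg <= 0 or self.fs_acc <= 0:
            raise ValidationError("sampling rates must be positive")
        if self.semg.ndim != 2 or self.semg.shape[1] != N_CHANNELS:
            raise ValidationError(
                f"sEMG must be [n_samples, {N_CHANNELS}], got shape {self.semg.shape}")
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValidationError(f"accelerometer must be [m_samples, 3], got {self.acc.shape}")
        left, right = set(self.left_channels), set(self.right_channels)
        if left & right:
            raise ValidationError("left/right channel sets must be disjoint")
        if len(left) != 16 or len(right) != 16 or (left | right) != set(range(N_CHANNELS)):
            raise ValidationError(
                "left and right halves must each hold 16 channels and partition 0..31")
        # Streams are synchronized: durations agree within one accelerometer
        # sample period.
        d_semg = self.semg.shape[0] / self.fs_semg
        d_acc = self.acc.shape[0] / self.fs_acc
        if abs(d_semg - d_acc) > 1.0 / self.fs_acc + 1e-9:
            raise ValidationError(
                f"stream durations disagree: sEMG {d_semg:.4f} s vs acc {d_acc:.4f} s")
        self.events.validate(self.duration)


@dataclass
class Epoch:
    """A 2-s multichannel segment centered on a detected swallow peak."""

    subject_id: str
    task: str
    trial: int
    t_peak: float               # detected peak time, seconds
    semg_seg: np.ndarray        # [2*fs_semg, 32]
    acc_seg: np.ndarray         # [2*fs_acc, 3]
    fs_semg: float = 2048.0
    fs_acc: float = 1024.0
    left_channels: Tuple[int, ...] = DEFAULT_LEFT_CHANNELS
    right_channels: Tuple[int, ...] = DEFAULT_RIGHT_CHANNELS
    shift_s: float = 0.0        # boundary adjustment applied to fit the trial
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.semg_seg = np.asarray(self.semg_seg, dtype=float)
        self.acc_seg = np.asarray(self.acc_seg, dtype=float)
        n_expect = int(round(2 * self.fs_semg))
        m_expect = int(round(2 * self.fs_acc))
        if self.semg_seg.shape != (n_expect, N_CHANNELS):
            raise ValidationError(
                f"epoch sEMG segment must be [{n_expect}, {N_CHANNELS}], got {self.semg_seg.shape}")
        if self.acc_seg.shape != (m_expect, 3):
            raise ValidationError(
                f"epoch accelerometer segment must be [{m_expect}, 3], got {self.acc_seg.shape}")

    @property
    def t_start(self) -> float:
        return self.t_peak - 1.0 + self.shift_s

    @property
    def t_end(self) -> float:
        return self.t_peak + 1.0 + self.shift_s
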