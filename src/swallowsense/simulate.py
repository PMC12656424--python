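"""Synthetic annotated swallowing recordings and clinical tables.

The generator emulates the phenomenology the pipeline assumes: each trial
carries per-channel wideband instrumentation noise plus a swallow burst —
band-limited Gaussian noise (zero-phase band-pass of white noise, so center
frequency and bandwidth are controlled directly) shaped by a smooth
rise-plateau-fall (Tukey) envelope, shared across channels with left/right
gains set by the configured asymmetry ratio.  The accelerometer stream gets
a low-frequency (<= 5 Hz) biphasic laryngeal-elevation bump centered on the
swallow plus noise.  Solid-bolus (ST) trials prepend an irregular 1.5-Hz
train of low-amplitude mastication bursts with MS/ME annotations.  Group
differences are injected only through burst amplitude, spectral center and
asymmetry ratio — the knobs that map one-to-one onto the feature families
the analysis screens (RMS/WL, PF/AF/TP, AS).

Clinical covariates are drawn from the study cohort's statistics: ages
Normal(69.5, 7.5) for PD and Normal(67, 4.8) for controls, truncated to
[50, 90]; clinical scores uniform within the cohort table ranges.

All output is deterministic given (seed, subject, task, trial).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal
from scipy.signal.windows import tukey, hann

from .errors import ConfigError
from .types import EventAnnotations, Recording, TASKS, N_CHANNELS, \
    DEFAULT_LEFT_CHANNELS, DEFAULT_RIGHT_CHANNELS


@dataclass(frozen=True)
class GroupParams:
    """Per-group signal parameters (amplitudes in mV, accelerations in g)."""

    burst_amplitude_mv: float = 0.15
    burst_duration_s: float = 1.0
    emg_center_freq_hz: float = 120.0
    emg_bandwidth_hz: float = 40.0
    asymmetry_ratio: float = 1.0       # left/right RMS ratio
    noise_floor_mv: float = 0.01
    acc_bump_amplitude_g: float = 0.05
    acc_bump_duration_s: float = 0.8
    acc_noise_g: float = 0.005

    def validate(self) -> None:
        if self.emg_center_freq_hz + self.emg_bandwidth_hz / 2 > 400.0:
            raise ConfigError("EMG band must stay within the 1-400 Hz passband")
        if self.emg_center_freq_hz - self.emg_bandwidth_hz / 2 <= 0:
            raise ConfigError("EMG band lower edge must be positive")
        if self.asymmetry_ratio <= 0:
            raise ConfigError("asymmetry_ratio must be positive")
        for name in ("burst_amplitude_mv", "burst_duration_s", "noise_floor_mv",
                     "acc_bump_amplitude_g", "acc_bump_duration_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


#: Default PD parameters: weaker, slower submental activation with a mild
#: bilateral imbalance relative to controls.
PD_DEFAULTS = GroupParams(burst_amplitude_mv=0.075, emg_center_freq_hz=90.0,
                          asymmetry_ratio=1.2)
HC_DEFAULTS = GroupParams()

_MAST_RATE_HZ = 1.5
_MAST_BURST_S = 0.2
_MAST_AMPL_FACTOR = 0.6
_ACC_AXIS_GAINS = (1.0, 0.35, 0.2)   # superior-inferior dominant


@dataclass(frozen=True)
class SimConfig:
    """Study-condition configuration for a synthetic cohort."""

    n_pd: int = 15
    n_hc: int = 7
    tasks: Tuple[str, ...] = TASKS
    trials_per_task: int = 3
    trial_duration_s: float = 12.0
    seed: int = 0
    pd_params: GroupParams = field(default_factory=lambda: PD_DEFAULTS)
    hc_params: GroupParams = field(default_factory=lambda: HC_DEFAULTS)
    mastication_enabled: bool = True
    fs_semg: float = 2048.0
    fs_acc: float = 1024.0

    def validate(self) -> None:
        for task in self.tasks:
            if task not in TASKS:
                raise ConfigError(f"unknown task {task!r}")
        for p in (self.pd_params, self.hc_params):
            p.validate()
            if p.burst_duration_s >= self.trial_duration_s:
                raise ConfigError("burst duration must be shorter than the trial")

    def params_for(self, group: str) -> GroupParams:
        return self.pd_params if group == "PD" else self.hc_params


def _rng_for(cfg: SimConfig, subject_id: str, task: str, trial: int,
             stream: int = 0) -> np.random.Generator:
    key = [cfg.seed % (2 ** 31), zlib.crc32(subject_id.encode()),
           TASKS.index(task) if task in TASKS else 99, trial, stream]
    return np.random.default_rng(np.random.SeedSequence(key))


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       center: float, bandwidth: float) -> np.ndarray:
    lo = center - bandwidth / 2.0
    hi = center + bandwidth / 2.0
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal(n)
    return signal.sosfiltfilt(sos, white)


def _burst(rng: np.random.Generator, n: int, fs: float, t_center: float,
           duration: float, amplitude: float, center_freq: float,
           bandwidth: float) -> np.ndarray:
    """Band-limited noise burst with a Tukey rise-plateau-fall envelope,
    scaled to the requested RMS amplitude over its support."""
    carrier = _bandlimited_noise(rng, n, fs, center_freq, bandwidth)
    L = int(round(duration * fs))
    start = int(round((t_center - duration / 2.0) * fs))
    env = np.zeros(n)
    env[start:start + L] = tukey(L, alpha=0.5)
    x = carrier * env
    support = env > 0
    rms = np.sqrt(np.mean(x[support] ** 2))
    return x * (amplitude / rms)


def simulate_recording(cfg: SimConfig, subject_id: str, group: str, task: str,
                       trial: int) -> Recording:
    """One synthetic trial with ground-truth swallow annotations."""
    cfg.validate()
    p = cfg.params_for(group)
    fs, fsa = cfg.fs_semg, cfg.fs_acc
    n = int(round(cfg.trial_duration_s * fs))
    m = int(round(cfg.trial_duration_s * fsa))
    half = p.burst_duration_s / 2.0

    mastication = cfg.mastication_enabled and task == "ST"
    ms = me = None
    if mastication:
        ms, me = 0.5, 3.5
    lo = (me + 0.7 if mastication else 0.5) + half
    hi = cfg.trial_duration_s - 0.5 - half
    if hi <= lo:
        raise ConfigError(
            f"infeasible schedule: no room for a {p.burst_duration_s}-s burst "
            f"in a {cfg.trial_duration_s}-s trial")

    rng = _rng_for(cfg, subject_id, task, trial)
    t_swallow = float(rng.uniform(lo, hi))

    # channel gains: left/right RMS ratio = asymmetry_ratio, mean gain = 1
    gain_r = 2.0 / (1.0 + p.asymmetry_ratio)
    gain_l = p.asymmetry_ratio * gain_r
    gains = np.empty(N_CHANNELS)
    gains[list(DEFAULT_LEFT_CHANNELS)] = gain_l
    gains[list(DEFAULT_RIGHT_CHANNELS)] = gain_r

    semg = rng.normal(0.0, p.noise_floor_mv, size=(n, N_CHANNELS))
    burst = _burst(rng, n, fs, t_swallow, p.burst_duration_s,
                   p.burst_amplitude_mv, p.emg_center_freq_hz, p.emg_bandwidth_hz)
    semg += np.outer(burst, gains)

    if mastication:
        n_bursts = int(np.floor((me - ms - _MAST_BURST_S) * _MAST_RATE_HZ)) + 1
        for k in range(n_bursts):
            tc = ms + _MAST_BURST_S / 2 + k / _MAST_RATE_HZ \
                + float(rng.uniform(-0.05, 0.05))
            ampl = p.burst_amplitude_mv * _MAST_AMPL_FACTOR \
                * float(rng.uniform(0.7, 1.3))
            chew = _burst(rng, n, fs, tc, _MAST_BURST_S, ampl,
                          p.emg_center_freq_hz, p.emg_bandwidth_hz)
            semg += np.outer(chew, gains)

    acc = rng.normal(0.0, p.acc_noise_g, size=(m, 3))
    La = int(round(p.acc_bump_duration_s * fsa))
    a_start = int(round((t_swallow - p.acc_bump_duration_s / 2.0) * fsa))
    tt = np.arange(La) / fsa
    bump = np.sin(2 * np.pi * tt / p.acc_bump_duration_s) * hann(La)
    for ax, g in enumerate(_ACC_AXIS_GAINS):
        acc[a_start:a_start + La, ax] += p.acc_bump_amplitude_g * g * bump

    events = EventAnnotations(
        mastication_start=ms, mastication_end=me,
        swallow_start=t_swallow - half, swallow_end=t_swallow + half)

    return Recording(subject_id=subject_id, group=group, task=task, trial=trial,
                     semg=semg, acc=acc, fs_semg=fs, fs_acc=fsa, events=events)


def true_swallow_time(rec: Recording) -> float:
    """Ground-truth swallow peak time of a simulated recording."""
    ev = rec.events
    return (ev.swallow_start + ev.swallow_end) / 2.0


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

_AGE_DIST = {"PD": (69.5, 7.5), "HC": (67.0, 4.8)}
_AGE_RANGE = (50.0, 90.0)
# Uniform score ranges spanning the study cohort tables.
_SCORE_RANGES = {
    "disease_duration": (3, 23),
    "updrs3": (20, 58),
    "updrs_axial": (4, 20),
    "ledd": (300, 1610),
}
_SDQ_RANGE = {"PD": (2, 15), "HC": (1, 6)}


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float,
                      lo: float, hi: float) -> float:
    while True:
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return float(v)


def simulate_clinical(cfg: SimConfig) -> pd.DataFrame:
    """Synthetic per-subject clinical table for the configured cohort."""
    if cfg.n_pd < 1 or cfg.n_hc < 1:
        raise ConfigError("need at least one subject per group")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed % (2 ** 31), 0xC11]))
    rows = []
    for group, count in (("PD", cfg.n_pd), ("HC", cfg.n_hc)):
        mu, sd = _AGE_DIST[group]
        for i in range(count):
            sid = f"{group}{i + 1:02d}"
            row = {
                "id": sid,
                "gender": "M" if rng.uniform() < 0.6 else "F",
                "age": round(_truncated_normal(rng, mu, sd, *_AGE_RANGE)),
                "sdq": float(rng.integers(_SDQ_RANGE[group][0],
                                          _SDQ_RANGE[group][1] + 1)),
                "group": group,
            }
            for col, (lo, hi) in _SCORE_RANGES.items():
                row[col] = float(rng.integers(lo, hi + 1)) if group == "PD" else np.nan
            rows.append(row)
    cols = ["id", "gender", "age", "disease_duration", "updrs3", "updrs_axial",
            "sdq", "ledd", "group"]
    return pd.DataFrame(rows)[cols]


def iter_cohort(cfg: SimConfig,
                clinical: Optional[pd.DataFrame] = None) -> Iterator[Recording]:
    """Stream the cohort's recordings (subject x task x trial) one at a time."""
    cfg.validate()
    if clinical is None:
        clinical = simulate_clinical(cfg)
    for _, row in clinical.iterrows():
        for task in cfg.tasks:
            for trial in range(1, cfg.trials_per_task + 1):
                yield simulate_recording(cfg, row["id"], row["group"], task, trial)


def simulate_cohort(cfg: SimConfig) -> Tuple[List[Recording], pd.DataFrame]:
    """Full cohort in memory: all recordings plus the clinical table."""
    clinical = simulate_clinical(cfg)
    return list(iter_cohort(cfg, clinical)), clinical
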