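"""Electrophysiological feature extraction per 2-s swallow epoch.

Two layers live here:

* the six core descriptors — RMS, waveform length, the left/right RMS
  asymmetry index, peak frequency, magnitude-weighted average frequency and
  total spectral power — computed exactly as defined for the
  clinical-correlation screen;
* a frozen, versioned registry of exactly 50 named features covering
  time-domain amplitude/shape statistics, spectral descriptors and
  short-time (time-frequency) measures.

Conventions (fixed so results are reproducible across implementations):

* Time-domain registry features are computed on each channel after per-channel
  min-max normalization to [0, 1]; a normalized signal never crosses literal
  zero, so zero crossings and peak amplitude are taken about the channel mean.
* Frequency-domain features are computed on the *non-normalized* channel:
  unnormalized forward FFT of the full segment (FFT length = segment length),
  one-sided magnitudes, restricted to the 1-400 Hz filter passband, with no
  additional scaling.
* Time-frequency features use a short-time transform with 0.25-s Hann frames
  and 50% overlap, band-restricted the same way.
* Central moments are population moments (normalized by N); kurtosis is the
  Pearson ratio m4/m2^2 (not excess).
* Sample/fuzzy entropy use m = 2, r = 0.2 x SD, on the channel subsampled to
  <= 256 Hz (plain stride); fuzzy entropy uses an exponential membership of
  gradient 2 with baseline-removed templates.  SVD entropy embeds with
  dimension 10, delay 1.  AR coefficients are order-4 Yule-Walker (biased
  autocorrelation) prediction coefficients.

Every registry feature is computed per channel and averaged across the 32
grid channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.linalg import solve_toeplitz, svdvals
from scipy.signal.windows import hann

from .errors import DegenerateInputError, JoinError, ValidationError
from .types import Epoch

logger = logging.getLogger(__name__)

SPECTRAL_BAND = (1.0, 400.0)
STFT_WIN_S = 0.25
ENTROPY_TARGET_FS = 256.0
AR_ORDER = 4
SVD_EMBED_DIM = 10
CONCENTRATION_HALF_WIDTH_HZ = 20.0
MAVS_SEGMENTS = 8

REGISTRY_VERSION = "1.0"


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """One-sided FFT magnitudes restricted to the analysis band."""

    freqs: np.ndarray
    mags: np.ndarray
    fs: float
    n_fft: int

    @property
    def power(self) -> np.ndarray:
        return self.mags ** 2


def compute_spectrum(x: np.ndarray, fs: float,
                     band: Tuple[float, float] = SPECTRAL_BAND) -> Spectrum:
    """Unnormalized one-sided FFT of the full segment, band-restricted."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    freqs = rfftfreq(n, 1.0 / fs)
    mags = np.abs(rfft(x))
    lo, hi = band
    hi = min(hi, fs / 2.0)
    mask = (freqs >= lo) & (freqs <= hi)
    return Spectrum(freqs=freqs[mask], mags=mags[mask], fs=fs, n_fft=n)


# ---------------------------------------------------------------------------
# Scalar helpers (shared by several registry entries)
# ---------------------------------------------------------------------------

def _moments(x: np.ndarray) -> Tuple[float, float, float, float]:
    xc = x - x.mean()
    m2 = float(np.mean(xc ** 2))
    m3 = float(np.mean(xc ** 3))
    m4 = float(np.mean(xc ** 4))
    return float(x.mean()), m2, m3, m4


def _minmax01(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        raise DegenerateInputError("constant channel: min-max normalization undefined")
    return (x - lo) / (hi - lo)


def _median_frequency(freqs: np.ndarray, power: np.ndarray) -> float:
    total = power.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero spectrum: median frequency undefined")
    cum = np.cumsum(power)
    return float(freqs[int(np.searchsorted(cum, total / 2.0))])


def _mean_frequency(freqs: np.ndarray, power: np.ndarray) -> float:
    total = power.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero spectrum: mean frequency undefined")
    return float((freqs * power).sum() / total)


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """SampEn(m, r): -ln(A/B) with Chebyshev template matching, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    r = r_factor * x.std()
    if r <= 0:
        raise DegenerateInputError("constant signal: sample entropy undefined")
    n = x.shape[0] - m
    # Chebyshev template distances built incrementally from the pairwise
    # sample-difference matrix: d_{k+1}(i,j) = max(d_k(i,j), |x_{i+k}-x_{j+k}|)
    D = np.abs(x[:, None] - x[None, :])
    db = D[:n, :n].copy()
    for k in range(1, m):
        np.maximum(db, D[k:k + n, k:k + n], out=db)
    da = np.maximum(db, D[m:m + n, m:m + n])
    off = ~np.eye(n, dtype=bool)
    b = int(np.count_nonzero(db[off] < r))
    a = int(np.count_nonzero(da[off] < r))
    if a == 0 or b == 0:
        raise DegenerateInputError("no template matches: sample entropy undefined")
    return float(-np.log(a / b))


def fuzzy_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2,
                  gradient: int = 2) -> float:
    """FuzzyEn(m, r, n): ln(phi_m) - ln(phi_{m+1}) with exp(-(d/r)^n) membership."""
    x = np.asarray(x, dtype=float)
    r = r_factor * x.std()
    if r <= 0:
        raise DegenerateInputError("constant signal: fuzzy entropy undefined")

    n = x.shape[0] - m
    S = x[:, None] - x[None, :]

    def phi(k: int) -> float:
        # baseline-removed templates: d(i,j) = max_o |(x_{i+o}-x_{j+o}) - (mu_i-mu_j)|
        t = np.lib.stride_tricks.sliding_window_view(x, k)[:n]
        means = t.mean(axis=1)
        md = means[:, None] - means[None, :]
        d = np.abs(S[:n, :n] - md)
        for o in range(1, k):
            np.maximum(d, np.abs(S[o:o + n, o:o + n] - md), out=d)
        mu = np.exp(-((d / r) ** gradient))
        return float((mu.sum() - n) / (n * (n - 1)))

    return float(np.log(phi(m)) - np.log(phi(m + 1)))


def svd_entropy(x: np.ndarray, order: int = SVD_EMBED_DIM, delay: int = 1) -> float:
    """Shannon entropy (nats) of normalized singular values of the delay embedding."""
    x = np.asarray(x, dtype=float)
    emb = np.lib.stride_tricks.sliding_window_view(x, order)[::delay]
    s = svdvals(emb)
    total = s.sum()
    if total <= 0:
        raise DegenerateInputError("zero embedding: SVD entropy undefined")
    p = s / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def ar_coefficients(x: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Order-p Yule-Walker prediction coefficients (biased autocorrelation)."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    n = xc.shape[0]
    r = np.array([np.dot(xc[: n - k], xc[k:]) / n for k in range(order + 1)])
    if r[0] <= 0:
        raise DegenerateInputError("constant signal: AR model undefined")
    return solve_toeplitz(r[:order], r[1: order + 1])


def _entropy_subsample(x: np.ndarray, fs: float) -> np.ndarray:
    k = max(1, int(round(fs / ENTROPY_TARGET_FS)))
    return x[::k]


def stft_power(x: np.ndarray, fs: float, win_s: float = STFT_WIN_S,
               band: Tuple[float, float] = SPECTRAL_BAND
               ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power spectra: Hann frames of ``win_s`` s, 50% overlap.

    Returns ``(freqs, P, frames)`` where ``P[k]`` is the band-restricted power
    spectrum of frame k and ``frames`` holds the raw (unwindowed) frame
    samples.  Partial trailing frames are dropped.
    """
    x = np.asarray(x, dtype=float)
    L = int(round(win_s * fs))
    hop = L // 2
    starts = range(0, x.shape[0] - L + 1, hop)
    frames = np.stack([x[s: s + L] for s in starts])
    w = hann(L, sym=False)
    spec = np.abs(rfft(frames * w, axis=1)) ** 2
    freqs = rfftfreq(L, 1.0 / fs)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= min(hi, fs / 2.0))
    return freqs[mask], spec[:, mask], frames


# ---------------------------------------------------------------------------
# Per-channel evaluation context
# ---------------------------------------------------------------------------

class ChannelContext:
    """Lazily cached per-channel views consumed by the registry entries."""

    def __init__(self, raw: np.ndarray, fs: float):
        self.raw = np.asarray(raw, dtype=float)
        self.fs = float(fs)

    @cached_property
    def norm(self) -> np.ndarray:
        return _minmax01(self.raw)

    @cached_property
    def norm_centered(self) -> np.ndarray:
        return self.norm - self.norm.mean()

    @cached_property
    def spectrum(self) -> Spectrum:
        return compute_spectrum(self.raw, self.fs)

    @cached_property
    def pnorm(self) -> np.ndarray:
        p = self.spectrum.power
        total = p.sum()
        if total <= 0:
            raise DegenerateInputError("all-zero spectrum")
        return p / total

    @cached_property
    def stft(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return stft_power(self.raw, self.fs)

    @cached_property
    def sub(self) -> np.ndarray:
        return _entropy_subsample(self.norm, self.fs)

    @cached_property
    def ar(self) -> np.ndarray:
        return ar_coefficients(self.raw)

    @cached_property
    def frame_mean_freqs(self) -> np.ndarray:
        freqs, P, _ = self.stft
        totals = P.sum(axis=1)
        if np.any(totals <= 0):
            raise DegenerateInputError("empty STFT frame")
        return (P * freqs).sum(axis=1) / totals


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    name: str
    domain: str  # "time" | "frequency" | "time-frequency"
    fn: Callable[[ChannelContext], float]


def _mav_slope(x: np.ndarray, k: int = MAVS_SEGMENTS) -> float:
    seg = x.shape[0] // k
    mavs = [np.abs(x[i * seg:(i + 1) * seg]).mean() for i in range(k)]
    return float(np.mean(np.diff(mavs)))


def _band_power(sp: Spectrum, lo: float, hi: float, closed_hi: bool) -> float:
    mask = (sp.freqs >= lo) & ((sp.freqs <= hi) if closed_hi else (sp.freqs < hi))
    return float(sp.power[mask].sum())


def _band_mean_power(sp: Spectrum, lo: float, hi: float, closed_hi: bool) -> float:
    mask = (sp.freqs >= lo) & ((sp.freqs <= hi) if closed_hi else (sp.freqs < hi))
    if not mask.any():
        raise DegenerateInputError(f"no spectral bins in [{lo}, {hi}] Hz")
    return float(sp.power[mask].mean())


def _spectral_moment(c: ChannelContext, order: int) -> float:
    f = c.spectrum.freqs
    mu = float((f * c.pnorm).sum())
    var = float(((f - mu) ** 2 * c.pnorm).sum())
    if order == 2:
        return float(np.sqrt(var))
    if var <= 0:
        raise DegenerateInputError("zero spectral spread")
    dev = float(((f - mu) ** order * c.pnorm).sum())
    return dev / var ** (order / 2.0)


def _frame_median_freqs(c: ChannelContext) -> np.ndarray:
    freqs, P, _ = c.stft
    return np.array([_median_frequency(freqs, row) for row in P])


def _hjorth_mobility(x: np.ndarray, fs: float) -> float:
    v0 = np.mean((x - x.mean()) ** 2)
    d = np.diff(x)
    v1 = np.mean((d - d.mean()) ** 2)
    if v0 <= 0:
        raise DegenerateInputError("constant signal: Hjorth mobility undefined")
    return float(fs * np.sqrt(v1 / v0))


def _hjorth_complexity(x: np.ndarray) -> float:
    d = np.diff(x)
    d2 = np.diff(d)
    v0 = np.mean((x - x.mean()) ** 2)
    v1 = np.mean((d - d.mean()) ** 2)
    v2 = np.mean((d2 - d2.mean()) ** 2)
    if v0 <= 0 or v1 <= 0:
        raise DegenerateInputError("constant signal: Hjorth complexity undefined")
    return float(np.sqrt(v2 / v1) / np.sqrt(v1 / v0))


def _build_registry() -> List[FeatureDef]:
    T, F, TF = "time", "frequency", "time-frequency"
    defs: List[FeatureDef] = []

    def add(name, domain, fn):
        defs.append(FeatureDef(name, domain, fn))

    # --- time domain (per-channel min-max normalized signal) ----------------
    add("mean_absolute_value", T, lambda c: float(np.abs(c.norm).mean()))
    add("median_absolute_value", T, lambda c: float(np.median(np.abs(c.norm))))
    add("mean_absolute_value_slope", T, lambda c: _mav_slope(c.norm))
    add("integrated_emg", T, lambda c: float(np.abs(c.norm).sum()))
    add("mean", T, lambda c: float(c.norm.mean()))
    add("variance", T, lambda c: _moments(c.norm)[1])
    add("standard_deviation", T, lambda c: float(np.sqrt(_moments(c.norm)[1])))
    add("rms", T, lambda c: float(np.sqrt(np.mean(c.norm ** 2))))
    add("skewness", T, lambda c: _moments(c.norm)[2] / _moments(c.norm)[1] ** 1.5)
    add("kurtosis", T, lambda c: _moments(c.norm)[3] / _moments(c.norm)[1] ** 2)
    add("waveform_length", T, lambda c: float(np.abs(np.diff(c.norm)).sum()))
    add("amplitude_change", T, lambda c: float(np.abs(np.diff(c.norm)).mean()))
    add("zero_crossings", T,
        lambda c: float(np.count_nonzero(c.norm_centered[:-1] * c.norm_centered[1:] < 0)))
    add("slope_sign_changes", T,
        lambda c: float(np.count_nonzero(np.diff(c.norm)[:-1] * np.diff(c.norm)[1:] < 0)))
    add("peak_amplitude", T, lambda c: float(np.abs(c.norm_centered).max()))
    add("crest_factor", T,
        lambda c: float(np.abs(c.norm_centered).max() / np.sqrt(_moments(c.norm)[1])))
    add("mean_abs_sqrt", T, lambda c: float(np.sqrt(np.abs(c.norm)).mean()))
    add("interquartile_range", T,
        lambda c: float(np.percentile(c.norm, 75.0) - np.percentile(c.norm, 25.0)))
    add("difference_moments_4_2", T,
        lambda c: _moments(c.norm)[3] - _moments(c.norm)[1])
    add("hjorth_mobility", T, lambda c: _hjorth_mobility(c.norm, c.fs))
    add("hjorth_complexity", T, lambda c: _hjorth_complexity(c.norm))
    add("sample_entropy", T, lambda c: sample_entropy(c.sub))
    add("fuzzy_entropy", T, lambda c: fuzzy_entropy(c.sub))
    add("svd_entropy", T, lambda c: svd_entropy(c.norm))
    add("energy", T, lambda c: float(np.sum(c.norm ** 2)))

    # --- frequency domain (non-normalized signal, band 1-400 Hz) ------------
    add("peak_frequency", F,
        lambda c: float(c.spectrum.freqs[int(np.argmax(c.spectrum.mags))]))
    add("mean_frequency", F,
        lambda c: _mean_frequency(c.spectrum.freqs, c.spectrum.power))
    add("median_frequency", F,
        lambda c: _median_frequency(c.spectrum.freqs, c.spectrum.power))
    add("ratio_mean_median_frequency", F,
        lambda c: _mean_frequency(c.spectrum.freqs, c.spectrum.power)
        / _median_frequency(c.spectrum.freqs, c.spectrum.power))
    add("total_power", F, lambda c: float(c.spectrum.power.sum()))
    add("mean_power", F, lambda c: float(c.spectrum.power.mean()))
    add("peak_to_average_power_ratio", F,
        lambda c: float(c.spectrum.power.max() / c.spectrum.power.mean()))
    add("spectral_entropy", F,
        lambda c: float(-(c.pnorm[c.pnorm > 0] * np.log(c.pnorm[c.pnorm > 0])).sum()))
    add("renyi_entropy", F, lambda c: float(-np.log((c.pnorm ** 2).sum())))
    add("spectral_spread", F, lambda c: _spectral_moment(c, 2))
    add("spectral_skewness", F, lambda c: _spectral_moment(c, 3))
    add("spectral_kurtosis", F, lambda c: _spectral_moment(c, 4))
    add("spectral_concentration", F,
        lambda c: float(c.pnorm[np.abs(c.spectrum.freqs
                                       - _mean_frequency(c.spectrum.freqs, c.spectrum.power))
                                <= CONCENTRATION_HALF_WIDTH_HZ].sum()))
    add("frequency_ratio", F,
        lambda c: _band_power(c.spectrum, 1.0, 60.0, False)
        / _band_power(c.spectrum, 60.0, 400.0, True))
    add("mean_power_ratio", F,
        lambda c: _band_mean_power(c.spectrum, 1.0, 200.0, False)
        / _band_mean_power(c.spectrum, 200.0, 400.0, True))
    for k in range(AR_ORDER):
        add(f"ar_coeff_{k + 1}", F, lambda c, k=k: float(c.ar[k]))
    add("multiplied_power_peak_amplitude", F,
        lambda c: float(c.spectrum.power.sum() * np.abs(c.raw).max()))

    # --- time-frequency (STFT, 0.25-s Hann frames, 50% overlap) -------------
    add("stft_energy_mean", TF, lambda c: float(c.stft[1].sum(axis=1).mean()))
    add("signal_stability", TF,
        lambda c: float(np.var(np.sqrt(np.mean(c.stft[2] ** 2, axis=1)))))
    add("instantaneous_median_frequency", TF,
        lambda c: float(_frame_median_freqs(c).mean()))
    add("instantaneous_mean_frequency", TF,
        lambda c: float(c.frame_mean_freqs.mean()))
    add("variance_central_frequency", TF,
        lambda c: float(np.var(c.frame_mean_freqs)))

    return defs


class FeatureRegistry:
    """Ordered, frozen catalogue of the 50 per-epoch features."""

    def __init__(self, defs: Optional[Sequence[FeatureDef]] = None,
                 version: str = REGISTRY_VERSION):
        self.defs: Tuple[FeatureDef, ...] = tuple(defs if defs is not None
                                                  else _build_registry())
        self.version = version
        names = [d.name for d in self.defs]
        if len(set(names)) != len(names):
            raise ValidationError("registry feature names must be unique")

    @property
    def names(self) -> List[str]:
        return [d.name for d in self.defs]

    def __len__(self) -> int:
        return len(self.defs)

    def compute_channel(self, x: np.ndarray, fs: float) -> np.ndarray:
        """All registry features for one channel."""
        ctx = ChannelContext(x, fs)
        out = np.empty(len(self.defs))
        for i, d in enumerate(self.defs):
            v = d.fn(ctx)
            if not np.isfinite(v):
                raise ValidationError(f"feature {d.name!r} evaluated non-finite")
            out[i] = v
        return out

    def compute_epoch(self, epoch: Epoch) -> np.ndarray:
        """Per-channel features averaged across the 32 grid channels."""
        vals = np.empty((epoch.semg_seg.shape[1], len(self.defs)))
        for ch in range(epoch.semg_seg.shape[1]):
            try:
                vals[ch] = self.compute_channel(epoch.semg_seg[:, ch], epoch.fs_semg)
            except (DegenerateInputError, ValidationError) as exc:
                raise ValidationError(
                    f"channel {ch} of epoch ({epoch.subject_id}, {epoch.task}, "
                    f"{epoch.trial}): {exc}") from exc
        return vals.mean(axis=0)


_DEFAULT_REGISTRY: Optional[FeatureRegistry] = None


def default_registry() -> FeatureRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = FeatureRegistry()
        assert len(_DEFAULT_REGISTRY) == 50
    return _DEFAULT_REGISTRY


#: Registry names of the 15 features retained by the mRMR screen.
MRMR_TABLE_FEATURES = [
    "slope_sign_changes",
    "hjorth_complexity",
    "variance",
    "multiplied_power_peak_amplitude",
    "svd_entropy",
    "zero_crossings",
    "ratio_mean_median_frequency",
    "variance_central_frequency",
    "median_frequency",
    "spectral_concentration",
    "standard_deviation",
    "difference_moments_4_2",
    "instantaneous_median_frequency",
    "mean_power_ratio",
    "mean_absolute_value",
]


# ---------------------------------------------------------------------------
# Core descriptors (clinical-correlation screen)
# ---------------------------------------------------------------------------

def core_time_features(epoch: Epoch) -> Dict[str, float]:
    """RMS and WL (per channel, channel-averaged) and the L/R asymmetry index.

    ``AS_val`` is the signed RMS of the left-half channel average minus the
    RMS of the right-half channel average within the 2-s epoch.
    """
    if not epoch.left_channels or not epoch.right_channels:
        raise ValidationError("epoch lacks the grid left/right mapping")
    x = epoch.semg_seg
    rms_ch = np.sqrt(np.mean(x ** 2, axis=0))
    wl_ch = np.abs(np.diff(x, axis=0)).sum(axis=0)
    left_avg = x[:, list(epoch.left_channels)].mean(axis=1)
    right_avg = x[:, list(epoch.right_channels)].mean(axis=1)
    as_val = float(np.sqrt(np.mean(left_avg ** 2)) - np.sqrt(np.mean(right_avg ** 2)))
    return {
        "RMS_val": float(rms_ch.mean()),
        "WL_val": float(wl_ch.mean()),
        "AS_val": as_val,
    }


def core_freq_features(epoch: Epoch) -> Dict[str, float]:
    """PF, AF and TP from the FFT of the 32-channel average.

    PF is the frequency of the spectral maximum (lowest frequency wins ties);
    AF is the magnitude-weighted average frequency; TP the sum of squared
    magnitudes over the 1-400 Hz band, with no extra normalization.
    """
    avg = epoch.semg_seg.mean(axis=1)
    sp = compute_spectrum(avg, epoch.fs_semg)
    if sp.mags.sum() <= 0:
        raise DegenerateInputError("all-zero spectrum: PF/AF undefined")
    pf = float(sp.freqs[int(np.argmax(sp.mags))])
    af = float((sp.freqs * sp.mags).sum() / sp.mags.sum())
    tp = float(sp.power.sum())
    return {"PF_val": pf, "AF_val": af, "TP_val": tp}


def extended_features(epoch: Epoch,
                      registry: Optional[FeatureRegistry] = None) -> np.ndarray:
    """The 50-feature vector for one epoch, in registry order."""
    registry = registry or default_registry()
    return registry.compute_epoch(epoch)


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

KEY_COLUMNS = ["subject_id", "task", "trial", "group"]


def build_feature_table(epochs: Sequence[Epoch],
                        registry: Optional[FeatureRegistry] = None,
                        clinical: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """One row per epoch: keys, group label, and the 50 registry features."""
    registry = registry or default_registry()
    groups = None
    if clinical is not None:
        groups = dict(zip(clinical["id"], clinical["group"]))
    rows = []
    for ep in epochs:
        if groups is not None:
            if ep.subject_id not in groups:
                raise JoinError(f"epoch subject {ep.subject_id!r} has no clinical row")
            group = groups[ep.subject_id]
        else:
            group = ep.group
        vec = registry.compute_epoch(ep)
        rows.append({"subject_id": ep.subject_id, "task": ep.task,
                     "trial": ep.trial, "group": group,
                     **dict(zip(registry.names, vec))})
    table = pd.DataFrame(rows)
    if len(table):
        counts = table.groupby(["subject_id", "task"]).size()
        if counts.nunique() > 1:
            logger.warning("uneven trial counts across subjects/tasks: %s",
                           counts[counts != counts.mode()[0]].to_dict())
    return table


def per_task_means(table: pd.DataFrame) -> pd.DataFrame:
    """Trial-averaged view: one row per (subject, task)."""
    feature_cols = [c for c in table.columns if c not in KEY_COLUMNS]
    out = (table.groupby(["subject_id", "task", "group"], as_index=False)[feature_cols]
           .mean())
    return out
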