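"""Independent brute-force oracles for the feature registry and core descriptors.

Everything here is computed from the bare definitions: direct DFT via an
explicit transform matrix, explicit Toeplitz Yule-Walker system, Gram-matrix
singular values, explicit frame loops for the short-time transform, and
3-D broadcast template matching for the entropies.  No code is shared with
the package implementation beyond numpy primitives.
"""

from __future__ import annotations

import math

import numpy as np

_DFT_CACHE: dict = {}

SPECTRAL_LO, SPECTRAL_HI = 1.0, 400.0
ENTROPY_FS = 256.0


def dft_band(x: np.ndarray, fs: float):
    """One-sided magnitudes via an explicit DFT matrix, band-restricted."""
    n = len(x)
    if n not in _DFT_CACHE:
        k = np.arange(n // 2 + 1)
        _DFT_CACHE[n] = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    W = _DFT_CACHE[n]
    mags = np.abs(W @ x)
    freqs = np.arange(n // 2 + 1) * fs / n
    mask = (freqs >= SPECTRAL_LO) & (freqs <= min(SPECTRAL_HI, fs / 2))
    return freqs[mask], mags[mask]


def minmax(x):
    lo, hi = min(x), max(x)
    return (np.asarray(x, dtype=float) - lo) / (hi - lo)


def central_moment(x, k):
    mu = sum(x) / len(x)
    return sum((v - mu) ** k for v in x) / len(x)


def percentile_linear(x, q):
    s = sorted(x)
    h = (len(s) - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def hjorth_mobility(x, fs):
    d = np.diff(x)
    return fs * math.sqrt(central_moment(d, 2) / central_moment(x, 2))


def hjorth_complexity(x):
    d = np.diff(x)
    d2 = np.diff(d)
    mob_x = math.sqrt(central_moment(d, 2) / central_moment(x, 2))
    mob_d = math.sqrt(central_moment(d2, 2) / central_moment(d, 2))
    return mob_d / mob_x


def sample_entropy(x, m=2, r_factor=0.2):
    x = np.asarray(x, dtype=float)
    r = r_factor * x.std()
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:-1]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    db = np.abs(tm[:, None, :] - tm[None, :, :]).max(axis=2)
    da = np.abs(tm1[:, None, :] - tm1[None, :, :]).max(axis=2)
    n = tm.shape[0]
    off = ~np.eye(n, dtype=bool)
    return -math.log(np.count_nonzero(da[off] < r) / np.count_nonzero(db[off] < r))


def fuzzy_entropy(x, m=2, r_factor=0.2, gradient=2):
    x = np.asarray(x, dtype=float)
    r = r_factor * x.std()
    n = len(x) - m

    def phi(k):
        t = np.lib.stride_tricks.sliding_window_view(x, k)[:n]
        t = t - t.mean(axis=1, keepdims=True)
        d = np.abs(t[:, None, :] - t[None, :, :]).max(axis=2)
        mu = np.exp(-((d / r) ** gradient))
        return (mu.sum() - n) / (n * (n - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))


def svd_entropy(x, order=10, delay=1):
    emb = np.lib.stride_tricks.sliding_window_view(np.asarray(x, float), order)[::delay]
    gram = emb.T @ emb                    # order x order
    eig = np.linalg.eigvalsh(gram)
    s = np.sqrt(np.clip(eig, 0.0, None))
    p = s / s.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def ar_coefficients(x, order=4):
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    n = len(xc)
    r = [sum(xc[i] * xc[i + k] for i in range(n - k)) / n for k in range(order + 1)]
    R = np.array([[r[abs(i - j)] for j in range(order)] for i in range(order)])
    return np.linalg.solve(R, np.array(r[1: order + 1]))


def _entropy_sub(x, fs):
    k = max(1, int(round(fs / ENTROPY_FS)))
    return np.asarray(x, dtype=float)[::k]


def _mean_freq(freqs, power):
    return sum(f * p for f, p in zip(freqs, power)) / sum(power)


def _median_freq(freqs, power):
    total = sum(power)
    cum = 0.0
    for f, p in zip(freqs, power):
        cum += p
        if cum >= total / 2.0:
            return f
    return freqs[-1]


def _hann_periodic(L):
    k = np.arange(L)
    return 0.5 - 0.5 * np.cos(2 * np.pi * k / L)


def stft_frames(x, fs, win_s=0.25):
    """Frame loop: (band freqs, list of power rows, list of raw frames)."""
    L = int(round(win_s * fs))
    hop = L // 2
    w = _hann_periodic(L)
    rows, raws = [], []
    freqs = None
    for s in range(0, len(x) - L + 1, hop):
        frame = np.asarray(x[s: s + L], dtype=float)
        f, mags = dft_band(frame * w, fs)
        freqs = f
        rows.append(mags ** 2)
        raws.append(frame)
    return freqs, rows, raws


def channel_features(x, fs):
    """All 50 registry features of one channel, brute force, keyed by name."""
    x = np.asarray(x, dtype=float)
    y = minmax(x)                      # time-domain input
    yc = y - y.mean()
    dy = np.diff(y)
    freqs, mags = dft_band(x, fs)      # frequency-domain input (non-normalized)
    power = mags ** 2
    ptot = power.sum()
    pn = power / ptot
    mnf = _mean_freq(freqs, power)
    mdf = _median_freq(freqs, power)
    spread = math.sqrt(sum(p * (f - mnf) ** 2 for f, p in zip(freqs, pn)))

    out = {}
    out["mean_absolute_value"] = np.abs(y).sum() / len(y)
    srt = np.sort(np.abs(y))
    mid = len(y) // 2
    out["median_absolute_value"] = (srt[mid] if len(y) % 2 else
                                    (srt[mid - 1] + srt[mid]) / 2.0)
    seg = len(y) // 8
    mavs = [np.abs(y[i * seg:(i + 1) * seg]).sum() / seg for i in range(8)]
    out["mean_absolute_value_slope"] = sum(
        mavs[i + 1] - mavs[i] for i in range(7)) / 7.0
    out["integrated_emg"] = np.abs(y).sum()
    out["mean"] = y.sum() / len(y)
    m2 = central_moment(y, 2)
    m3 = central_moment(y, 3)
    m4 = central_moment(y, 4)
    out["variance"] = m2
    out["standard_deviation"] = math.sqrt(m2)
    out["rms"] = math.sqrt((y ** 2).sum() / len(y))
    out["skewness"] = m3 / m2 ** 1.5
    out["kurtosis"] = m4 / m2 ** 2
    out["waveform_length"] = np.abs(dy).sum()
    out["amplitude_change"] = np.abs(dy).sum() / len(dy)
    out["zero_crossings"] = float(sum(
        1 for i in range(len(yc) - 1) if yc[i] * yc[i + 1] < 0))
    out["slope_sign_changes"] = float(sum(
        1 for i in range(len(dy) - 1) if dy[i] * dy[i + 1] < 0))
    out["peak_amplitude"] = np.abs(yc).max()
    out["crest_factor"] = np.abs(yc).max() / math.sqrt(m2)
    out["mean_abs_sqrt"] = np.sqrt(np.abs(y)).sum() / len(y)
    out["interquartile_range"] = (percentile_linear(y, 75)
                                  - percentile_linear(y, 25))
    out["difference_moments_4_2"] = m4 - m2
    out["hjorth_mobility"] = hjorth_mobility(y, fs)
    out["hjorth_complexity"] = hjorth_complexity(y)
    sub = _entropy_sub(y, fs)
    out["sample_entropy"] = sample_entropy(sub)
    out["fuzzy_entropy"] = fuzzy_entropy(sub)
    out["svd_entropy"] = svd_entropy(y)
    out["energy"] = (y ** 2).sum()

    out["peak_frequency"] = freqs[int(np.argmax(mags))]
    out["mean_frequency"] = mnf
    out["median_frequency"] = mdf
    out["ratio_mean_median_frequency"] = mnf / mdf
    out["total_power"] = ptot
    out["mean_power"] = ptot / len(power)
    out["peak_to_average_power_ratio"] = power.max() / (ptot / len(power))
    out["spectral_entropy"] = -sum(p * math.log(p) for p in pn if p > 0)
    out["renyi_entropy"] = -math.log(sum(p ** 2 for p in pn))
    out["spectral_spread"] = spread
    out["spectral_skewness"] = sum(
        p * (f - mnf) ** 3 for f, p in zip(freqs, pn)) / spread ** 3
    out["spectral_kurtosis"] = sum(
        p * (f - mnf) ** 4 for f, p in zip(freqs, pn)) / spread ** 4
    out["spectral_concentration"] = sum(
        p for f, p in zip(freqs, pn) if abs(f - mnf) <= 20.0)
    out["frequency_ratio"] = (
        sum(p for f, p in zip(freqs, power) if 1.0 <= f < 60.0)
        / sum(p for f, p in zip(freqs, power) if 60.0 <= f <= 400.0))
    lo_band = [p for f, p in zip(freqs, power) if 1.0 <= f < 200.0]
    hi_band = [p for f, p in zip(freqs, power) if 200.0 <= f <= 400.0]
    out["mean_power_ratio"] = (sum(lo_band) / len(lo_band)) / (sum(hi_band) / len(hi_band))
    a = ar_coefficients(x)
    for k in range(4):
        out[f"ar_coeff_{k + 1}"] = a[k]
    out["multiplied_power_peak_amplitude"] = ptot * np.abs(x).max()

    sfreqs, srows, sraws = stft_frames(x, fs)
    frame_totals = [row.sum() for row in srows]
    frame_mnf = [_mean_freq(sfreqs, row) for row in srows]
    frame_mdf = [_median_freq(sfreqs, row) for row in srows]
    frame_rms = [math.sqrt((fr ** 2).sum() / len(fr)) for fr in sraws]
    out["stft_energy_mean"] = sum(frame_totals) / len(frame_totals)
    out["signal_stability"] = central_moment(frame_rms, 2)
    out["instantaneous_median_frequency"] = sum(frame_mdf) / len(frame_mdf)
    out["instantaneous_mean_frequency"] = sum(frame_mnf) / len(frame_mnf)
    out["variance_central_frequency"] = central_moment(frame_mnf, 2)
    return out


# ---------------------------------------------------------------------------
# Core descriptors (direct-summation / direct-DFT)
# ---------------------------------------------------------------------------

def core_features(semg_seg, fs, left, right):
    """Brute-force RMS/WL/AS/PF/AF/TP of one multichannel epoch."""
    n, n_ch = semg_seg.shape
    rms_ch = [math.sqrt(sum(v * v for v in semg_seg[:, c]) / n) for c in range(n_ch)]
    wl_ch = [sum(abs(semg_seg[i + 1, c] - semg_seg[i, c]) for i in range(n - 1))
             for c in range(n_ch)]
    left_avg = semg_seg[:, list(left)].mean(axis=1)
    right_avg = semg_seg[:, list(right)].mean(axis=1)
    as_val = (math.sqrt((left_avg ** 2).sum() / n)
              - math.sqrt((right_avg ** 2).sum() / n))
    avg = semg_seg.mean(axis=1)
    freqs, mags = dft_band(avg, fs)
    pf = freqs[int(np.argmax(mags))]
    af = sum(f * m for f, m in zip(freqs, mags)) / mags.sum()
    tp = (mags ** 2).sum()
    return {"RMS_val": sum(rms_ch) / n_ch, "WL_val": sum(wl_ch) / n_ch,
            "AS_val": as_val, "PF_val": pf, "AF_val": af, "TP_val": tp}


def pearson_r(x, y):
    """Direct evaluation of the correlation-coefficient formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = math.sqrt(sum((v - mx) ** 2 for v in x)) \
        * math.sqrt(sum((v - my) ** 2 for v in y))
    return num / den


def pca_eig(X):
    """Covariance eigendecomposition: (explained ratios desc, components)."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    comps = eigvec[:, order].T
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return eigval / eigval.sum(), comps
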