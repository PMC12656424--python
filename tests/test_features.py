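"""Core descriptors (worked examples), registry properties, feature table logic."""

import numpy as np
import pandas as pd
import pytest

from swallowsense.errors import JoinError, ValidationError
from swallowsense.features import (FeatureDef, FeatureRegistry, MRMR_TABLE_FEATURES,
                                   build_feature_table, compute_spectrum,
                                   core_freq_features, core_time_features,
                                   default_registry, per_task_means)
from swallowsense.types import Epoch

FS = 2048.0
FSA = 1024.0


def _epoch(semg, subject="s1", task="WT", trial=1, group="HC",
           fs=FS, fsa=FSA):
    acc = np.zeros((int(2 * fsa), 3))
    return Epoch(subject_id=subject, task=task, trial=trial, t_peak=5.0,
                 semg_seg=semg, acc_seg=acc, fs_semg=fs, fs_acc=fsa,
                 group=group)


def _tone_epoch(freq, amplitude=1.0, phase=0.3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(2 * FS)) / FS
    x = amplitude * np.sin(2 * np.pi * freq * t + phase)
    semg = np.tile(x[:, None], (1, 32)) + noise * rng.standard_normal((len(t), 32))
    return _epoch(semg)


def _feature(name):
    reg = default_registry()
    return next(d for d in reg.defs if d.name == name)


class TestCoreTimeFeatures:
    def test_constant_channel_rms_and_wl(self):
        semg = np.full((int(2 * FS), 32), -0.7)
        f = core_time_features(_epoch(semg))
        assert f["RMS_val"] == pytest.approx(0.7)
        assert f["WL_val"] == 0.0

    def test_waveform_length_hand_example(self):
        # WL of [0, 1, 3, 2] = 1 + 2 + 1 = 4 on every channel
        semg = np.tile(np.array([0.0, 1.0, 3.0, 2.0])[:, None], (1, 32))
        ep = Epoch(subject_id="s", task="WT", trial=1, t_peak=1.0,
                   semg_seg=semg, acc_seg=np.zeros((4, 3)),
                   fs_semg=2.0, fs_acc=2.0)
        f = core_time_features(ep)
        assert f["WL_val"] == pytest.approx(4.0)

    def test_rms_hand_example(self):
        semg = np.tile(np.array([3.0, 4.0])[:, None], (1, 32))
        ep = Epoch(subject_id="s", task="WT", trial=1, t_peak=0.5,
                   semg_seg=semg, acc_seg=np.zeros((2, 3)),
                   fs_semg=1.0, fs_acc=1.0)
        assert core_time_features(ep)["RMS_val"] == pytest.approx(np.sqrt(12.5))

    def test_symmetric_halves_zero_asymmetry(self):
        rng = np.random.default_rng(1)
        half = rng.standard_normal((int(2 * FS), 16))
        semg = np.concatenate([half, half], axis=1)
        assert core_time_features(_epoch(semg))["AS_val"] == pytest.approx(0.0)

    def test_asymmetry_flips_sign_under_side_swap(self):
        rng = np.random.default_rng(2)
        semg = rng.standard_normal((int(2 * FS), 32))
        ep = _epoch(semg)
        swapped = _epoch(np.concatenate([semg[:, 16:], semg[:, :16]], axis=1))
        assert core_time_features(swapped)["AS_val"] == \
            pytest.approx(-core_time_features(ep)["AS_val"])


class TestCoreFreqFeatures:
    def test_pure_tone_peak_frequency(self):
        f = core_freq_features(_tone_epoch(100.0))
        assert abs(f["PF_val"] - 100.0) <= 0.25   # half a bin at 0.5 Hz spacing

    def test_pure_tone_average_frequency(self):
        f = core_freq_features(_tone_epoch(100.0))
        assert abs(f["AF_val"] - 100.0) <= 2.0

    def test_total_power_parseval(self):
        # one-sided band power of a zero-mean in-band signal ~= N * sum(x^2) / 2
        rng = np.random.default_rng(4)
        from scipy import signal as sg
        sos = sg.butter(8, (50, 300), btype="bandpass", fs=FS, output="sos")
        x = sg.sosfiltfilt(sos, rng.standard_normal(int(2 * FS)))
        semg = np.tile(x[:, None], (1, 32))
        tp = core_freq_features(_epoch(semg))["TP_val"]
        expect = len(x) * (x ** 2).sum() / 2.0
        assert tp == pytest.approx(expect, rel=0.01)


class TestRegistryExamples:
    def test_registry_has_exactly_50_unique_names(self):
        reg = default_registry()
        assert len(reg) == 50
        assert len(set(reg.names)) == 50

    def test_all_mrmr_selected_names_resolve(self):
        reg = default_registry()
        assert len(MRMR_TABLE_FEATURES) == 15
        assert set(MRMR_TABLE_FEATURES) <= set(reg.names)

    def test_zero_crossings_of_10hz_tone(self):
        # 10 Hz over 2 s: 20 cycles -> 40 crossings about the mean
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t + 0.3)
        from swallowsense.features import ChannelContext
        assert _feature("zero_crossings").fn(ChannelContext(x, FS)) == 40.0

    def test_slope_sign_changes_of_monotone_ramp(self):
        from swallowsense.features import ChannelContext
        x = np.linspace(0.0, 1.0, int(2 * FS))
        assert _feature("slope_sign_changes").fn(ChannelContext(x, FS)) == 0.0

    def test_median_frequency_of_flat_band_noise(self):
        # flat spectrum over [1, 400] -> cumulative-power midpoint near 200.5 Hz
        from swallowsense.features import ChannelContext
        vals = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(int(2 * FS))
            vals.append(_feature("median_frequency").fn(ChannelContext(x, FS)))
        assert abs(np.mean(vals) - 200.5) <= 5.0

    def test_hjorth_mobility_of_pure_tone(self):
        from swallowsense.features import ChannelContext
        freq = 37.0
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        got = _feature("hjorth_mobility").fn(ChannelContext(x, FS))
        assert got == pytest.approx(2 * np.pi * freq, rel=0.02)


class TestEquivariance:
    def test_amplitude_scaling_laws(self):
        rng = np.random.default_rng(9)
        from swallowsense.preprocess import filter_semg
        x = filter_semg(rng.standard_normal(int(2 * FS)), FS)
        semg = np.tile(x[:, None], (1, 32)) \
            + 0.01 * rng.standard_normal((len(x), 32))
        a = 3.0
        e1, e2 = _epoch(semg), _epoch(a * semg)
        t1, t2 = core_time_features(e1), core_time_features(e2)
        f1, f2 = core_freq_features(e1), core_freq_features(e2)
        assert t2["RMS_val"] == pytest.approx(a * t1["RMS_val"], rel=1e-9)
        assert t2["WL_val"] == pytest.approx(a * t1["WL_val"], rel=1e-9)
        assert f2["TP_val"] == pytest.approx(a ** 2 * f1["TP_val"], rel=1e-9)
        assert f2["PF_val"] == f1["PF_val"]
        assert f2["AF_val"] == pytest.approx(f1["AF_val"], rel=1e-12)

    def test_scale_invariant_registry_features(self):
        reg = default_registry()
        rng = np.random.default_rng(10)
        x = rng.standard_normal(int(2 * FS))
        v1 = reg.compute_channel(x, FS)
        v2 = reg.compute_channel(5.0 * x, FS)
        idx = {n: i for i, n in enumerate(reg.names)}
        for name in ("zero_crossings", "median_frequency", "mean_frequency",
                     "peak_frequency", "spectral_entropy"):
            assert v2[idx[name]] == pytest.approx(v1[idx[name]], rel=1e-9), name

    def test_epoch_features_average_per_channel_values(self):
        reg = default_registry()
        rng = np.random.default_rng(12)
        semg = rng.standard_normal((int(2 * FS), 32))
        ep = _epoch(semg)
        got = reg.compute_epoch(ep)
        expect = np.mean([reg.compute_channel(semg[:, c], FS) for c in range(32)],
                         axis=0)
        np.testing.assert_allclose(got, expect, rtol=1e-12)


class TestFeatureTable:
    @staticmethod
    def _mini_registry():
        return FeatureRegistry(defs=[
            FeatureDef("f_rms", "time",
                       lambda c: float(np.sqrt(np.mean(c.raw ** 2)))),
            FeatureDef("f_max", "time", lambda c: float(np.abs(c.raw).max())),
        ], version="test")

    @staticmethod
    def _epochs(n_subj=22, tasks=("WT", "GT", "ST"), trials=3, fs=256.0):
        rng = np.random.default_rng(0)
        eps, ids = [], []
        for s in range(n_subj):
            sid = f"PD{s:02d}" if s < 15 else f"HC{s - 15:02d}"
            ids.append(sid)
            for task in tasks:
                for trial in range(1, trials + 1):
                    eps.append(Epoch(
                        subject_id=sid, task=task, trial=trial, t_peak=2.0,
                        semg_seg=rng.standard_normal((int(2 * fs), 32)),
                        acc_seg=np.zeros((int(2 * fs / 2), 3)),
                        fs_semg=fs, fs_acc=fs / 2))
        clinical = pd.DataFrame({
            "id": ids,
            "group": ["PD"] * 15 + ["HC"] * (n_subj - 15),
        })
        return eps, clinical

    def test_full_cohort_row_counts(self):
        eps, clinical = self._epochs()
        table = build_feature_table(eps, self._mini_registry(), clinical)
        assert len(table) == 198
        view = per_task_means(table)
        assert len(view) == 66

    def test_missing_trial_warns_and_keeps_197_rows(self, caplog):
        eps, clinical = self._epochs()
        eps = [e for e in eps
               if not (e.subject_id == "PD00" and e.task == "ST" and e.trial == 3)]
        import logging
        with caplog.at_level(logging.WARNING):
            table = build_feature_table(eps, self._mini_registry(), clinical)
        assert len(table) == 197
        assert any("uneven" in r.message for r in caplog.records)

    def test_identical_epochs_identical_rows(self):
        eps, clinical = self._epochs(n_subj=16, tasks=("WT",), trials=2)
        eps[1] = Epoch(**{**eps[0].__dict__, "trial": 2})
        table = build_feature_table(eps, self._mini_registry(), clinical)
        cols = ["f_rms", "f_max"]
        assert table.iloc[0][cols].equals(table.iloc[1][cols])

    def test_unmatched_subject_is_join_error(self):
        eps, clinical = self._epochs(n_subj=16, tasks=("WT",), trials=1)
        with pytest.raises(JoinError, match="PD00"):
            build_feature_table(eps, self._mini_registry(),
                                clinical[clinical["id"] != "PD00"])

    def test_constant_channel_raises_named_error(self):
        rng = np.random.default_rng(0)
        semg = rng.standard_normal((int(2 * FS), 32))
        semg[:, 3] = 1.0
        with pytest.raises(ValidationError, match="channel 3"):
            default_registry().compute_epoch(_epoch(semg))
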