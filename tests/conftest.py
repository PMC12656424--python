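"""Shared fixtures: small synthetic cohorts reused across the suite.

The two cohorts share the study's structure (both groups, all three bolus
tasks, balanced 2+2 fold construction possible) at a reduced size so the
whole suite stays fast: 8 PD + 6 HC subjects, 2 trials per task, 8-s trials.
``null_cohort`` draws both groups from identical signal parameters (no
group effect); ``separated_cohort`` gives the patient group half the burst
amplitude and a 40-Hz-lower spectral center, a strong planted effect.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from swallowsense.pipeline import extract_cohort_features
from swallowsense.simulate import GroupParams, HC_DEFAULTS, SimConfig, \
    simulate_clinical

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

COHORT_KW = dict(n_pd=8, n_hc=6, tasks=("WT", "GT", "ST"), trials_per_task=2,
                 trial_duration_s=8.0)

NULL_CFG = SimConfig(seed=20260901, pd_params=HC_DEFAULTS,
                     hc_params=HC_DEFAULTS, **COHORT_KW)
SEP_CFG = SimConfig(
    seed=20260902,
    pd_params=GroupParams(burst_amplitude_mv=HC_DEFAULTS.burst_amplitude_mv / 2,
                          emg_center_freq_hz=HC_DEFAULTS.emg_center_freq_hz - 40.0,
                          asymmetry_ratio=1.2),
    hc_params=HC_DEFAULTS, **COHORT_KW)


@pytest.fixture(scope="session")
def null_cohort():
    """(clinical, features, detections) with no planted group effect."""
    clinical = simulate_clinical(NULL_CFG)
    features, detections = extract_cohort_features(NULL_CFG, clinical)
    return clinical, features, detections


@pytest.fixture(scope="session")
def separated_cohort():
    """(clinical, features, detections) with a strong planted group effect."""
    clinical = simulate_clinical(SEP_CFG)
    features, detections = extract_cohort_features(SEP_CFG, clinical)
    return clinical, features, detections


def make_feature_table(rng, n_pd=8, n_hc=8, trials=4, n_features=50,
                       informative=(), shift=0.0, feature_names=None):
    """Synthetic per-trial feature table: Gaussian features, optional planted
    group-mean shift on the ``informative`` columns."""
    if feature_names is None:
        feature_names = [f"f{i:02d}" for i in range(n_features)]
    rows = []
    for group, count in (("PD", n_pd), ("HC", n_hc)):
        for s in range(count):
            sid = f"{group}{s:02d}"
            for t in range(trials):
                vals = rng.standard_normal(len(feature_names))
                if group == "PD":
                    for idx in informative:
                        vals[idx] += shift
                rows.append({"subject_id": sid, "task": "WT", "trial": t + 1,
                             "group": group,
                             **dict(zip(feature_names, vals))})
    return pd.DataFrame(rows)
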