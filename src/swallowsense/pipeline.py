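"""End-to-end glue: raw recording -> epoch -> feature table -> study results."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .classification import CVReport, make_fold_assignments, run_cv
from .detection import WindowGrid, detect_peak, extract_epoch
from .features import FeatureRegistry, build_feature_table, default_registry
from .preprocess import filter_acc, filter_semg
from .reduction import SelectionResult, fit_pca, mrmr_select, project, \
    standardize_features
from .simulate import SimConfig, iter_cohort, simulate_clinical, true_swallow_time
from .types import Epoch, Recording


def preprocess_recording(rec: Recording) -> Tuple[np.ndarray, np.ndarray]:
    """Filtered copies of both streams (sEMG notch+band-pass, acc band-pass)."""
    return filter_semg(rec.semg, rec.fs_semg), filter_acc(rec.acc, rec.fs_acc)


def detect_and_epoch(rec: Recording) -> Epoch:
    """Preprocess, localize the swallow, and cut the 2-s analysis epoch."""
    semg_f, acc_f = preprocess_recording(rec)
    t_peak = detect_peak(rec, semg_f, acc_f)
    return extract_epoch(rec, t_peak, semg=semg_f, acc=acc_f)


def extract_cohort_features(
    cfg: SimConfig,
    clinical: Optional[pd.DataFrame] = None,
    registry: Optional[FeatureRegistry] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the cohort, detect swallows, and build the feature table.

    Returns ``(feature_table, detections)`` where ``detections`` has one row
    per trial with detected vs ground-truth swallow times.
    """
    registry = registry or default_registry()
    if clinical is None:
        clinical = simulate_clinical(cfg)
    epochs: List[Epoch] = []
    det_rows = []
    for rec in iter_cohort(cfg, clinical):
        ep = detect_and_epoch(rec)
        epochs.append(ep)
        det_rows.append({
            "subject_id": rec.subject_id, "task": rec.task, "trial": rec.trial,
            "t_peak_s": ep.t_peak, "shift_s": ep.shift_s,
            "t_true_s": true_swallow_time(rec),
        })
    table = build_feature_table(epochs, registry, clinical)
    return table, pd.DataFrame(det_rows)


@dataclass
class StudyResult:
    clinical: pd.DataFrame
    features: pd.DataFrame
    detections: pd.DataFrame
    selection: SelectionResult
    cv: CVReport
    silhouette_all: float
    silhouette_mrmr: float


def run_study(cfg: SimConfig, n_cv_seeds: int = 500, cv_base_seed: int = 0,
              k: int = 15, components: Tuple[int, int] = (1, 3)) -> StudyResult:
    """The full analysis on one synthetic cohort.

    Simulation -> detection -> 50-feature extraction -> mRMR(k) on the
    pooled per-trial rows -> balanced subject-wise CV on the requested PCA
    component pair over ``n_cv_seeds`` random fold assignments.  Also
    reports the between-group silhouette of the 3-component PCA projection
    before vs after mRMR.
    """
    from sklearn.metrics import silhouette_score

    clinical = simulate_clinical(cfg)
    features, detections = extract_cohort_features(cfg, clinical)
    selection = mrmr_select(features, features["group"], k=k)

    def _silhouette(cols):
        std, _ = standardize_features(features, cols)
        model = fit_pca(std, cols, n_components=3)
        return float(silhouette_score(project(model, std),
                                      features["group"].to_numpy()))

    all_cols = [c for c in features.columns
                if c not in ("subject_id", "task", "trial", "group")]
    sil_all = _silhouette(all_cols)
    sil_mrmr = _silhouette(list(selection.selected))

    assignments = make_fold_assignments(clinical, n_seeds=n_cv_seeds,
                                        base_seed=cv_base_seed)
    cv = run_cv(features, selection, assignments, components=components)
    return StudyResult(clinical=clinical, features=features,
                       detections=detections, selection=selection, cv=cv,
                       silhouette_all=sil_all, silhouette_mrmr=sil_mrmr)
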