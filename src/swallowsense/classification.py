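"""RBF-SVM classification of PD vs HC swallow trials.

Two regimes are kept deliberately separate:

* the *visualization* regime (:func:`fit_plane_svm`) trains on all rows of a
  2-D PCA plane and reports training-set metrics — overfitted by design, it
  exists to draw decision boundaries on the projection plots;
* the *evaluation* regime (:func:`run_cv`) is balanced subject-wise
  cross-validation: subjects are partitioned into folds of exactly 2 PD + 2
  HC, the scaler and PCA are refitted on training rows only (no leakage),
  the weighted RBF-SVM classifies the held-out subjects' trials, and test
  predictions are pooled per seed.  Repeating over many random fold
  assignments gives the aggregate mean +/- SD and the best seed.

The sample unit is one swallow trial; its label is the subject's group
(positive class = PD).  Training samples are weighted by inverse class
frequency to offset the 15-vs-7 cohort imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ConfigError, ValidationError
from .reduction import SelectionResult, fit_pca, project, standardize_features

POSITIVE = "PD"
METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "kappa")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(confusion: Dict[str, int]) -> Dict[str, Optional[float]]:
    """Standard binary metrics from {tp, fn, fp, tn} counts (positive = PD).

    Cohen's kappa uses marginal-product expected agreement.  A metric whose
    denominator is zero is reported as None (not-computable), never as 0.
    """
    tp, fn = confusion["tp"], confusion["fn"]
    fp, tn = confusion["fp"], confusion["tn"]
    for k, v in confusion.items():
        if v < 0:
            raise ValidationError(f"negative confusion count {k} = {v}")
    total = tp + fn + fp + tn
    if total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    po = accuracy
    pe = ((tp + fn) * (tp + fp) + (fp + tn) * (fn + tn)) / total ** 2
    kappa = 0.0 if abs(1.0 - pe) < 1e-12 else (po - pe) / (1.0 - pe)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "kappa": kappa}


def _tally(y_true: np.ndarray, y_pred: np.ndarray) -> Dict[str, int]:
    pos_t = y_true == POSITIVE
    pos_p = y_pred == POSITIVE
    return {
        "tp": int(np.count_nonzero(pos_t & pos_p)),
        "fn": int(np.count_nonzero(pos_t & ~pos_p)),
        "fp": int(np.count_nonzero(~pos_t & pos_p)),
        "tn": int(np.count_nonzero(~pos_t & ~pos_p)),
    }


# ---------------------------------------------------------------------------
# Visualization regime
# ---------------------------------------------------------------------------

@dataclass
class PlaneSVM:
    """Overfit 2-D boundary model for projection plots."""

    model: SVC
    training_metrics: Dict[str, Optional[float]]

    def decision_grid(self, x_range: Tuple[float, float],
                      y_range: Tuple[float, float], n: int = 200
                      ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        xs = np.linspace(*x_range, n)
        ys = np.linspace(*y_range, n)
        gx, gy = np.meshgrid(xs, ys)
        z = self.model.decision_function(np.column_stack([gx.ravel(), gy.ravel()]))
        return gx, gy, z.reshape(gx.shape)


def fit_plane_svm(scores: np.ndarray, labels: Sequence[str],
                  C: float = 1.0, gamma="scale") -> PlaneSVM:
    """Train an RBF-SVM on a 2-D projection with inverse-class-frequency weights."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ConfigError(f"expected a 2-column score matrix, got {scores.shape}")
    if len(set(labels.tolist())) < 2:
        raise ConfigError("need both classes to train the boundary SVM")
    svc = SVC(kernel="rbf", C=C, gamma=gamma, class_weight="balanced")
    svc.fit(scores, labels)
    pred = svc.predict(scores)
    return PlaneSVM(model=svc, training_metrics=compute_metrics(_tally(labels, pred)))


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """One random balanced partition: folds of exactly 2 PD + 2 HC subjects."""

    seed: int
    folds: Tuple[frozenset, ...]
    leftover: frozenset          # training-only subjects in every split


def make_fold_assignments(clinical: pd.DataFrame, n_seeds: int = 500,
                          base_seed: int = 0) -> List[FoldAssignment]:
    """Deterministic balanced subject-wise fold assignments, one per seed."""
    pd_ids = sorted(clinical.loc[clinical["group"] == "PD", "id"])
    hc_ids = sorted(clinical.loc[clinical["group"] == "HC", "id"])
    if len(pd_ids) < 2 or len(hc_ids) < 2:
        raise ConfigError("need at least 2 subjects per class for 2+2 folds")
    n_folds = min(len(pd_ids), len(hc_ids)) // 2
    out = []
    for seed in range(n_seeds):
        rng = np.random.default_rng(
            np.random.SeedSequence([base_seed % (2 ** 31), seed]))
        pd_perm = list(rng.permutation(pd_ids))
        hc_perm = list(rng.permutation(hc_ids))
        folds = tuple(
            frozenset(pd_perm[2 * i: 2 * i + 2] + hc_perm[2 * i: 2 * i + 2])
            for i in range(n_folds))
        used = frozenset().union(*folds)
        leftover = frozenset(pd_ids + hc_ids) - used
        out.append(FoldAssignment(seed=seed, folds=folds, leftover=leftover))
    return out


# ---------------------------------------------------------------------------
# Evaluation regime
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedResult:
    seed: int
    confusion: Dict[str, int]
    metrics: Dict[str, Optional[float]]


@dataclass(frozen=True)
class CVReport:
    per_seed: Tuple[SeedResult, ...]
    aggregate: Dict[str, Dict[str, float]]   # metric -> {mean, sd}
    best: SeedResult

    def summary(self) -> pd.DataFrame:
        rows = [{"metric": m,
                 "mean": self.aggregate[m]["mean"],
                 "sd": self.aggregate[m]["sd"],
                 "best": self.best.metrics[m]}
                for m in METRIC_NAMES]
        return pd.DataFrame(rows)


def run_cv(features: pd.DataFrame, selection: Optional[SelectionResult],
           assignments: Sequence[FoldAssignment],
           components: Tuple[int, int] = (1, 3),
           C: float = 1.0, gamma="scale") -> CVReport:
    """Balanced subject-wise CV over many fold assignments.

    ``features`` holds per-trial rows pooled over tasks with a ``group``
    column.  Per fold the scaler and a 3-component PCA are fitted on training
    rows only; test trials are projected onto the requested component pair
    and classified by the weighted RBF-SVM.  Test predictions are pooled per
    seed before computing metrics.
    """
    feat_cols = list(selection.selected) if selection is not None else \
        [c for c in features.columns
         if c not in ("subject_id", "task", "trial", "group")]
    n_comp = max(components)
    results = []
    for fa in assignments:
        y_true_all, y_pred_all = [], []
        for fold in fa.folds:
            test_mask = features["subject_id"].isin(fold)
            train = features[~test_mask]
            test = features[test_mask]
            shared = set(train["subject_id"]) & set(test["subject_id"])
            if shared:
                raise ValidationError(f"subject leakage across split: {shared}")
            train_std, scaler = standardize_features(train, feat_cols)
            test_std = scaler.transform(test)
            model = fit_pca(train_std, feat_cols, n_components=n_comp)
            Xtr = project(model, train_std, plane=components)
            Xte = project(model, test_std, plane=components)
            svc = SVC(kernel="rbf", C=C, gamma=gamma, class_weight="balanced")
            svc.fit(Xtr, train["group"].to_numpy())
            y_pred_all.append(svc.predict(Xte))
            y_true_all.append(test["group"].to_numpy())
        y_true = np.concatenate(y_true_all)
        y_pred = np.concatenate(y_pred_all)
        confusion = _tally(y_true, y_pred)
        results.append(SeedResult(seed=fa.seed, confusion=confusion,
                                  metrics=compute_metrics(confusion)))

    aggregate = {}
    for m in METRIC_NAMES:
        vals = np.array([r.metrics[m] for r in results
                         if r.metrics[m] is not None], dtype=float)
        aggregate[m] = {"mean": float(vals.mean()) if vals.size else float("nan"),
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0}
    best = max(results, key=lambda r: (r.metrics["accuracy"], -r.seed))
    return CVReport(per_seed=tuple(results), aggregate=aggregate, best=best)


def subject_majority_vote(features: pd.DataFrame, y_pred: np.ndarray) -> pd.DataFrame:
    """Optional subject-level view: majority vote over a subject's trial predictions."""
    df = features[["subject_id", "group"]].copy()
    df["pred"] = y_pred
    def vote(s):
        counts = s.value_counts()
        top = counts[counts == counts.max()].index.sort_values()
        return top[0]
    return df.groupby("subject_id").agg(group=("group", "first"),
                                        pred=("pred", vote)).reset_index()
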