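#!/usr/bin/env python
"""Balanced subject-wise SVM cross-validation over 500 fold assignments.

Pools the three tasks' per-trial rows, projects the mRMR-selected features
onto PC1 and PC3 (refitted per training split), and classifies PD vs HC
with an inverse-class-frequency-weighted RBF-SVM.  Writes
results/cv_report.json with per-seed and aggregate metrics.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import STUDY_SEED, results_dir

from swallowsense.classification import make_fold_assignments, run_cv
from swallowsense.reduction import mrmr_select

N_SEEDS = 500


def main():
    out = results_dir()
    feat_path = out / "features.csv"
    if not feat_path.exists():
        print("features.csv missing; run analysis/03_features.py first")
        sys.exit(1)
    features = pd.read_csv(feat_path)

    sel = mrmr_select(features, features["group"], k=15)
    clinical = features[["subject_id", "group"]].drop_duplicates() \
        .rename(columns={"subject_id": "id"})
    assignments = make_fold_assignments(clinical, n_seeds=N_SEEDS,
                                        base_seed=STUDY_SEED)
    report = run_cv(features, sel, assignments, components=(1, 3))

    payload = {
        "n_seeds": N_SEEDS,
        "aggregate": report.aggregate,
        "best_seed": report.best.seed,
        "best_metrics": report.best.metrics,
        "best_confusion": report.best.confusion,
        "per_seed": [{"seed": r.seed, **{k: v for k, v in r.metrics.items()}}
                     for r in report.per_seed],
    }
    (out / "cv_report.json").write_text(json.dumps(payload, indent=2) + "\n")

    print(f"balanced subject-wise CV, {N_SEEDS} fold assignments, "
          f"PC1-PC3, pooled tasks:")
    print(report.summary().to_string(index=False,
                                     float_format=lambda v: f"{v:.3f}"))
    print(f"best seed: {report.best.seed} "
          f"(confusion {report.best.confusion})")
    print(f"wrote {out / 'cv_report.json'}")


if __name__ == "__main__":
    main()
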