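#!/usr/bin/env python
"""Screen swallowing features against clinical/demographic covariates.

Correlates trial-averaged time features (RMS, WL, SD, asymmetry proxies)
with MDS-UPDRS III, axial score, SDQ, age, and disease duration per task,
writing results/correlations.csv.  Expects results/features_per_task.csv
from 03_features.py (regenerates it if absent).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from study_config import STUDY_CFG, results_dir

from swallowsense.correlation import correlation_screen
from swallowsense.simulate import simulate_clinical

SCREEN_FEATURES = ["rms", "waveform_length", "standard_deviation",
                   "mean_frequency", "total_power"]


def main():
    out = results_dir()
    per_task_path = out / "features_per_task.csv"
    if not per_task_path.exists():
        print("features_per_task.csv missing; run analysis/03_features.py first")
        sys.exit(1)
    table = pd.read_csv(per_task_path)
    clinical = simulate_clinical(STUDY_CFG)

    res = correlation_screen(table, clinical, features=SCREEN_FEATURES)
    res.to_csv(out / "correlations.csv", index=False)

    n_sig = int(res["significant"].sum())
    n_comp = int(res["computable"].sum())
    print(f"{n_comp} computable correlations; {n_sig} flagged at alpha = 0.05 "
          f"({100 * n_sig / n_comp:.1f}% ~ the type-I rate expected when "
          f"covariates are independent of the signal)")
    if n_sig:
        print(res[res["significant"]][["feature", "covariate", "task", "r", "p"]]
              .to_string(index=False))
    print(f"wrote {out / 'correlations.csv'}")


if __name__ == "__main__":
    main()
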