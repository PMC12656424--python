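#!/usr/bin/env python
"""Generate the synthetic study cohort and its clinical table.

Writes the per-subject clinical table to results/clinical_synthetic.csv and
one example recording directory (CSV + JSON interchange format) under
scratch/example_recording/ for inspection.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import SCRATCH, STUDY_CFG, results_dir

from swallowsense.io import write_recording
from swallowsense.simulate import simulate_clinical, simulate_recording


def main():
    out = results_dir()
    clinical = simulate_clinical(STUDY_CFG)
    clinical.to_csv(out / "clinical_synthetic.csv", index=False)

    n_rec = len(clinical) * len(STUDY_CFG.tasks) * STUDY_CFG.trials_per_task
    print(f"cohort: {sum(clinical['group'] == 'PD')} PD + "
          f"{sum(clinical['group'] == 'HC')} HC subjects, "
          f"{n_rec} recordings of {STUDY_CFG.trial_duration_s:.0f} s "
          f"({len(STUDY_CFG.tasks)} tasks x {STUDY_CFG.trials_per_task} trials)")
    print(f"PD age {clinical[clinical['group'] == 'PD']['age'].mean():.1f} "
          f"+/- {clinical[clinical['group'] == 'PD']['age'].std(ddof=1):.1f} y; "
          f"HC age {clinical[clinical['group'] == 'HC']['age'].mean():.1f} y")

    SCRATCH.mkdir(exist_ok=True)
    rec = simulate_recording(STUDY_CFG, clinical["id"].iloc[0], "PD", "ST", 1)
    write_recording(rec, SCRATCH / "example_recording")
    print(f"wrote {out / 'clinical_synthetic.csv'} and an example recording "
          f"directory under {SCRATCH / 'example_recording'}")


if __name__ == "__main__":
    main()
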