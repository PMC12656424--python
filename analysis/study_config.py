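"""Shared configuration for the numbered analysis drivers.

The synthetic cohort mirrors the study conditions: 15 PD patients and 7
healthy controls, three bolus tasks (water, gelled water, solid), three
trials per task, 12-s trials.  One fixed seed keeps every driver on the
same cohort; drivers regenerate recordings in memory (simulation is
deterministic), so no bulky intermediate signal files are needed.
"""

from pathlib import Path

from swallowsense.simulate import SimConfig

STUDY_SEED = 11
STUDY_CFG = SimConfig(seed=STUDY_SEED)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
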