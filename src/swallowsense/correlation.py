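"""Pearson screening of swallowing features against clinical covariates.

For each (feature, covariate, task) triple the screen correlates the
trial-averaged per-subject feature values with the covariate: disease
scores (MDS-UPDRS III, axial subscore, disease duration) are defined for PD
subjects only, while age and SDQ pair over all subjects.  Raw two-sided
p-values are reported at the conventional alpha = 0.05 with no
multiple-testing correction by default; a Benjamini-Hochberg adjustment is
available as an option.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

ALPHA = 0.05

#: Covariates defined only for the patient group.
PD_ONLY_COVARIATES = frozenset({"updrs3", "updrs_axial", "disease_duration"})
DEFAULT_COVARIATES = ("updrs3", "updrs_axial", "sdq", "age", "disease_duration")


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r and its two-sided p-value (t on n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    if x.size < 3:
        raise ValidationError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_screen(
    per_task_table: pd.DataFrame,
    clinical: pd.DataFrame,
    features: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Screen features against covariates, one result row per triple.

    ``per_task_table`` holds trial-averaged feature values keyed by
    (subject_id, task).  Rows with fewer than 3 valid pairs are marked
    not-computable rather than dropped.
    """
    merged = per_task_table.merge(clinical, left_on="subject_id", right_on="id",
                                  how="left", suffixes=("", "_clin"))
    rows = []
    for task in sorted(per_task_table["task"].unique()):
        sub = merged[merged["task"] == task]
        for feat in features:
            for cov in covariates:
                pool = sub if cov not in PD_ONLY_COVARIATES \
                    else sub[sub["group"] == "PD"]
                pairs = pool[[feat, cov]].dropna()
                row = {"feature": feat, "covariate": cov, "task": task,
                       "n": len(pairs), "r": np.nan, "p": np.nan,
                       "computable": False, "significant": False}
                if len(pairs) >= 3 and np.ptp(pairs[feat].to_numpy()) > 0 \
                        and np.ptp(pairs[cov].to_numpy()) > 0:
                    r, p = pearson(pairs[feat].to_numpy(), pairs[cov].to_numpy())
                    row.update(r=r, p=p, computable=True)
                rows.append(row)
    out = pd.DataFrame(rows)
    if fdr:
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["computable"] & (out["p_adj"] < alpha)
    else:
        out["significant"] = out["computable"] & (out["p"] < alpha)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out
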