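"""Feature standardization, mRMR selection and PCA projection.

mRMR uses the difference (MID) form of the greedy criterion: at each step
the candidate maximizing relevance(feature; group) minus the mean
redundancy against the already-selected set is added, with mutual
information estimated on equal-frequency 4-bin discretized values.  The
quotient (MIQ) form is available via ``variant="quotient"``.  Ties break
lexicographically by feature name so selection is deterministic.

PCA components follow a fixed sign convention — the largest-magnitude
loading entry of each component is positive — so projections are
reproducible across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import mutual_info_score

from .errors import ConfigError, DegenerateInputError, SchemaError

MRMR_K = 15
N_BINS = 4


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaler:
    """Column-wise z-scoring (sample SD) fitted on training rows."""

    means: pd.Series
    sds: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.means.index if c not in table.columns]
        if missing:
            raise SchemaError(f"rows lack fitted feature columns: {missing}")
        out = table.copy()
        cols = list(self.means.index)
        out[cols] = (table[cols] - self.means) / self.sds
        return out


def standardize_features(table: pd.DataFrame,
                         feature_cols: Optional[Sequence[str]] = None
                         ) -> Tuple[pd.DataFrame, Scaler]:
    """Z-score each feature column (mean 0, sample SD 1); returns the scaler."""
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in ("subject_id", "task", "trial", "group")]
    means = table[list(feature_cols)].mean()
    sds = table[list(feature_cols)].std(ddof=1)
    dead = sds[sds <= 0].index.tolist()
    if dead:
        raise DegenerateInputError(f"constant feature columns: {dead}")
    scaler = Scaler(means=means, sds=sds)
    return scaler.transform(table), scaler


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionStep:
    name: str
    relevance: float
    redundancy: float
    score: float


@dataclass(frozen=True)
class SelectionResult:
    selected: Tuple[str, ...]
    steps: Tuple[SelectionStep, ...]
    variant: str = "difference"


def discretize(values: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Equal-frequency binning into ``n_bins`` levels (quantile edges)."""
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def mrmr_select(table: pd.DataFrame, labels: Sequence,
                k: int = MRMR_K,
                feature_cols: Optional[Sequence[str]] = None,
                variant: str = "difference") -> SelectionResult:
    """Greedy forward mRMR selection of ``k`` features against binary labels."""
    if k <= 0:
        raise ConfigError(f"k must be positive, got {k}")
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in ("subject_id", "task", "trial", "group")]
    feature_cols = list(feature_cols)
    if k > len(feature_cols):
        raise ConfigError(f"k = {k} exceeds the {len(feature_cols)} features")
    if variant not in ("difference", "quotient"):
        raise ConfigError(f"unknown mRMR variant {variant!r}")

    y = pd.factorize(pd.Series(labels))[0]
    disc = {c: discretize(table[c].to_numpy(dtype=float)) for c in feature_cols}
    relevance = {c: mutual_info_score(disc[c], y) for c in feature_cols}

    selected: List[str] = []
    steps: List[SelectionStep] = []
    pair_mi: dict = {}

    def mi_pair(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in pair_mi:
            pair_mi[key] = mutual_info_score(disc[key[0]], disc[key[1]])
        return pair_mi[key]

    for _ in range(k):
        best = None
        # lexicographic candidate order => deterministic tie-breaking
        for cand in sorted(c for c in feature_cols if c not in selected):
            red = (np.mean([mi_pair(cand, s) for s in selected])
                   if selected else 0.0)
            if variant == "difference":
                score = relevance[cand] - red
            else:
                score = relevance[cand] / (red + 1e-12)
            if best is None or score > best[1] + 1e-15:
                best = (cand, score, red)
        name, score, red = best
        selected.append(name)
        steps.append(SelectionStep(name=name, relevance=relevance[name],
                                   redundancy=red, score=score))
    return SelectionResult(selected=tuple(selected), steps=tuple(steps),
                           variant=variant)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAModel:
    """Fitted principal components over standardized feature rows."""

    feature_names: Tuple[str, ...]
    mean: np.ndarray                      # per-feature mean of the fit rows
    components: np.ndarray                # [n_components, n_features], orthonormal
    explained_variance_ratio: np.ndarray  # descending

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(table: pd.DataFrame,
            feature_cols: Optional[Sequence[str]] = None,
            n_components: int = 3) -> PCAModel:
    """PCA of the (standardized) feature rows via covariance eigenstructure."""
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in ("subject_id", "task", "trial", "group")]
    X = table[list(feature_cols)].to_numpy(dtype=float)
    if X.shape[0] < n_components:
        raise ConfigError(
            f"need at least {n_components} rows to fit {n_components} components")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    n_components = min(n_components, rank)
    model = PCA(n_components=n_components, svd_solver="full")
    model.fit(X)
    comps = model.components_.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAModel(feature_names=tuple(feature_cols),
                    mean=model.mean_,
                    components=comps,
                    explained_variance_ratio=model.explained_variance_ratio_)


def project(model: PCAModel, rows: pd.DataFrame,
            plane: Optional[Tuple[int, int]] = None) -> np.ndarray:
    """Project rows (standardized with the training scaler) onto components.

    ``plane`` selects two 1-based components, e.g. ``(1, 3)`` for PC1-PC3.
    """
    missing = [c for c in model.feature_names if c not in rows.columns]
    if missing:
        raise SchemaError(f"rows lack model features: {missing}")
    X = rows[list(model.feature_names)].to_numpy(dtype=float)
    scores = (X - model.mean) @ model.components.T
    if plane is None:
        return scores
    i, j = plane
    if not (1 <= i <= model.n_components and 1 <= j <= model.n_components):
        raise ConfigError(f"plane {plane} outside fitted components")
    return scores[:, [i - 1, j - 1]]
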