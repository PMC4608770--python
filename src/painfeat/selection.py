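"""Two-stage feature selection: manual pruning, then wrapper forward selection.

Stage 1 removes feature columns that are static (all-zero or constant for
all conditions, or carrying NaN sentinels from degenerate extraction) and
then columns that correlate with an already-retained column at |r| >= 0.95,
to keep noise and redundant information out of the classifier.

Stage 2 is a greedy forward selection wrapped around a classifier: starting
from the empty set, each round scores every remaining candidate by the
cross-validated accuracy of (current set + candidate) and adds the best one;
it stops as soon as the best candidate no longer strictly increases the
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, cross_val_score

from painfeat.core import feature_columns


@dataclass
class SelectionResult:
    """Outcome of the selection stages.

    ``forward_trace`` records, per round, the feature added and the
    cross-validated accuracy of the set after adding it; accuracies are
    strictly increasing by the stop rule.
    """

    kept_features: list[str] = field(default_factory=list)
    dropped_static: list[str] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    forward_trace: list[tuple[int, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kept_features": self.kept_features,
            "dropped_static": self.dropped_static,
            "dropped_correlated": [list(t) for t in self.dropped_correlated],
            "forward_trace": [list(t) for t in self.forward_trace],
        }


def prune_static(m: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop all-zero / constant columns and columns containing sentinels."""
    feats = feature_columns(m)
    dropped = []
    for c in feats:
        col = m[c].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)) or np.nanmax(col) == np.nanmin(col):
            dropped.append(c)
    return m.drop(columns=dropped), dropped


def prune_correlated(m: pd.DataFrame, threshold: float = 0.95
                     ) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Greedy correlation pruning in canonical column order.

    Scanning columns left to right, a column whose |Pearson r| with any
    already-retained column reaches ``threshold`` is dropped; the retained
    partner and r are recorded.  The earlier column of a correlated pair is
    always the survivor.
    """
    feats = feature_columns(m)
    X = m[feats].to_numpy(dtype=float)
    corr = np.corrcoef(X, rowvar=False) if len(feats) > 1 else np.ones((1, 1))
    kept_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(feats)):
        partner = None
        for i in kept_idx:
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                partner = (feats[j], feats[i], float(r))
                break
        if partner is None:
            kept_idx.append(j)
        else:
            dropped.append(partner)
    keep_cols = [c for c in m.columns if c in ("subject_id", "class_label")
                 or c in {feats[i] for i in kept_idx}]
    return m[keep_cols], dropped


def forward_select(X: pd.DataFrame, y: np.ndarray,
                   estimator, cv_folds: int = 3, random_state: int = 0,
                   max_features: int | None = None) -> SelectionResult:
    """SVM-wrapped (or any-estimator-wrapped) greedy forward selection.

    Each round evaluates every remaining candidate feature by ``cv_folds``
    stratified cross-validated accuracy of the estimator on (current set +
    candidate) and adds the best (ties break toward the lower column index);
    the loop stops when the best candidate does not strictly increase the
    accuracy.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("forward selection needs at least two classes")
    candidates = list(X.columns)
    if len(candidates) < 2:
        raise ValueError("forward selection needs at least two candidate features")

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=random_state)
    selected: list[str] = []
    trace: list[tuple[int, str, float]] = []
    best_acc = -np.inf
    round_no = 0
    limit = max_features or len(candidates)
    while candidates and len(selected) < limit:
        round_no += 1
        round_best, round_feat = -np.inf, None
        for feat in candidates:
            cols = selected + [feat]
            acc = float(np.mean(cross_val_score(
                clone(estimator), X[cols].to_numpy(), y, cv=cv, scoring="accuracy")))
            if acc > round_best:
                round_best, round_feat = acc, feat
        if round_best <= best_acc:
            break
        selected.append(round_feat)
        candidates.remove(round_feat)
        best_acc = round_best
        trace.append((round_no, round_feat, round_best))
    return SelectionResult(kept_features=selected, forward_trace=trace)


def select_features(m: pd.DataFrame, estimator, corr_threshold: float = 0.95,
                    cv_folds: int = 3, random_state: int = 0,
                    max_features: int | None = None) -> SelectionResult:
    """Run both stages on a labelled feature matrix."""
    m1, dropped_static = prune_static(m)
    m2, dropped_corr = prune_correlated(m1, corr_threshold)
    feats = feature_columns(m2)
    res = forward_select(m2[feats], m2["class_label"].to_numpy(),
                         estimator, cv_folds=cv_folds, random_state=random_state,
                         max_features=max_features)
    res.dropped_static = dropped_static
    res.dropped_correlated = dropped_corr
    return res
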