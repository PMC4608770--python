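"""RBF-SVM training, grid search, evaluation and validity measures.

The classifier is a support vector machine with radial-basis-function
kernel.  Its two hyperparameters are tuned by an exhaustive grid search
over exponentially growing sequences, C = 2^-5, 2^-3, ..., 2^15 and
gamma = 2^-15, 2^-13, ..., 2^3, scored by 3-fold cross-validated accuracy
on the training part of a stratified 75/25 split; the pair with the highest
accuracy wins (ties break toward smaller C, then smaller gamma).

Evaluation reports the confusion matrix, the accuracy (correctly predicted
test vectors over all test vectors), per-class sensitivity and specificity
(one-vs-others for more than two classes) and Cramer's V as an effect-size
measure of the association between true and predicted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.svm import SVC

from painfeat.core import EvalReport, feature_columns
from painfeat.selection import SelectionResult, prune_correlated, prune_static, forward_select

#: canonical two- and multi-class learning tasks
TASKS = {
    "B_vs_T1": ("B", "T1"),
    "B_vs_T2": ("B", "T2"),
    "B_vs_T3": ("B", "T3"),
    "B_vs_T4": ("B", "T4"),
    "B_vs_T1_vs_T4": ("B", "T1", "T4"),
    "five_class": ("B", "T1", "T2", "T3", "T4"),
}

#: Cramer's V interpretation bands (upper edge -> label)
ASSOCIATION_BANDS = (
    (0.1, "negligible"),
    (0.2, "weak"),
    (0.4, "moderate"),
    (0.6, "relatively strong"),
    (0.8, "strong"),
    (1.0 + 1e-12, "very strong"),
)


@dataclass
class SVMConfig:
    """Grid-search configuration (exponential grids, step 2^2)."""

    C_grid: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 16, 2))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** e for e in range(-15, 4, 2))
    cv_folds: int = 3
    #: coarse sub-grid used to fix (C, gamma) during forward selection
    coarse_C: tuple[float, ...] = (2.0 ** -1, 2.0 ** 3, 2.0 ** 7)
    coarse_gamma: tuple[float, ...] = (2.0 ** -7, 2.0 ** -3, 2.0 ** 1)


@dataclass
class SplitSpec:
    """Stratified random train/test split specification."""

    train_fraction: float = 0.75
    rng_seed: int = 0
    group_by_subject: bool = False


def split_data(m: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified 75/25 split of a labelled feature matrix.

    With ``group_by_subject`` all windows of a subject land on the same
    side (split over subjects instead of windows).
    """
    if spec.group_by_subject:
        subjects = m["subject_id"].unique()
        rng = np.random.default_rng(spec.rng_seed)
        rng.shuffle(subjects)
        n_train = int(round(spec.train_fraction * len(subjects)))
        train_subj = set(subjects[:n_train])
        train = m[m["subject_id"].isin(train_subj)]
        test = m[~m["subject_id"].isin(train_subj)]
        return train, test
    counts = m["class_label"].value_counts()
    if (counts < 4).any():
        raise ValueError(f"every class needs >= 4 samples to stratify, got {dict(counts)}")
    train, test = train_test_split(
        m, train_size=spec.train_fraction, stratify=m["class_label"],
        random_state=spec.rng_seed, shuffle=True)
    return train, test


def grid_search_train(X: np.ndarray, y: np.ndarray, cfg: SVMConfig | None = None,
                      random_state: int = 0) -> tuple[SVC, float, float, float]:
    """Exhaustive (C, gamma) grid search by cross-validated accuracy.

    Returns the model refit on all training data plus the winning pair and
    its CV accuracy.  Ties break toward the smaller C, then smaller gamma,
    by iterating the grids in ascending order with a strict improvement
    test.
    """
    cfg = cfg or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite for SVM training")
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs at least two classes")
    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=random_state)
    best = (-np.inf, None, None)
    for C in sorted(cfg.C_grid):
        for gamma in sorted(cfg.gamma_grid):
            acc = float(np.mean(cross_val_score(
                SVC(C=C, gamma=gamma, kernel="rbf"), X, y, cv=cv, scoring="accuracy")))
            if acc > best[0]:
                best = (acc, C, gamma)
    cv_acc, C, gamma = best
    model = SVC(C=C, gamma=gamma, kernel="rbf").fit(X, y)
    return model, C, gamma, cv_acc


def cramers_v(confusion: np.ndarray) -> tuple[float, str]:
    """Cramer's V of a contingency table, with its interpretation band.

    V = sqrt(chi2 / (n (min(rows, cols) - 1))) using the Pearson chi-square
    statistic without continuity correction.  Zero-margin rows/columns are
    removed first; a table with fewer than 2 informative rows or columns
    yields (nan, "undefined").
    """
    t = np.asarray(confusion, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return float("nan"), "undefined"
    chi2 = stats.chi2_contingency(t, correction=False)[0]
    n = t.sum()
    v = float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))
    for edge, label in ASSOCIATION_BANDS:
        if v < edge:
            return v, label
    return v, "very strong"


def metrics_from_confusion(confusion: pd.DataFrame) -> dict:
    """Accuracy and per-class one-vs-others sensitivity/specificity.

    ``confusion`` has true classes on rows, predicted on columns.  For a
    class c: sensitivity = correctly predicted c over all true c;
    specificity = correctly predicted non-c over all true non-c.
    """
    t = confusion.to_numpy(dtype=float)
    total = t.sum()
    accuracy = float(np.trace(t) / total)
    sens, spec = {}, {}
    for i, c in enumerate(confusion.index):
        tp = t[i, i]
        pos = t[i, :].sum()
        tn = total - t[i, :].sum() - t[:, i].sum() + tp
        neg = total - pos
        sens[str(c)] = float(tp / pos) if pos > 0 else float("nan")
        spec[str(c)] = float(tn / neg) if neg > 0 else float("nan")
    return {"accuracy": accuracy, "sensitivity": sens, "specificity": spec}


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray,
             classes: list[str] | None = None,
             selected_features: list[str] | None = None,
             svm_params: tuple[float, float] | None = None) -> EvalReport:
    """Predict the test set and build the full evaluation report."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    y_pred = model.predict(np.asarray(X_test, dtype=float))
    classes = classes or sorted(set(map(str, y_test)) | set(map(str, y_pred)))
    idx = {c: i for i, c in enumerate(classes)}
    t = np.zeros((len(classes), len(classes)))
    for yt, yp in zip(y_test, y_pred):
        t[idx[str(yt)], idx[str(yp)]] += 1
    confusion = pd.DataFrame(t, index=classes, columns=classes)
    metrics = metrics_from_confusion(confusion)
    v, band = cramers_v(t)
    return EvalReport(
        confusion=confusion,
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        cramers_v=v,
        association_band=band,
        selected_features=selected_features or [],
        svm_params=svm_params,
    )


# ---------------------------------------------------------------------------
# model-style task interface
# ---------------------------------------------------------------------------

@dataclass
class PainTaskResults:
    """Fitted-task results: report, selection trace and the final model."""

    task: str
    report: EvalReport
    selection: SelectionResult
    model: SVC
    train_cv_accuracy: float
    n_train: int
    n_test: int

    def summary(self) -> str:
        r = self.report
        lines = [
            f"Pain classification task: {self.task}",
            "=" * 46,
            f"train / test vectors     {self.n_train} / {self.n_test}",
            f"selected features        {len(r.selected_features)}",
            f"SVM (C, gamma)           ({r.svm_params[0]:g}, {r.svm_params[1]:g})",
            f"CV accuracy (train)      {self.train_cv_accuracy:.4f}",
            f"test accuracy            {r.accuracy:.4f}",
            f"Cramer's V               {r.cramers_v:.4f} ({r.association_band})",
            "-" * 46,
            "class   sensitivity   specificity",
        ]
        for c in r.confusion.index:
            lines.append(f"{c:<8}{r.sensitivity[str(c)]:>10.4f} {r.specificity[str(c)]:>13.4f}")
        lines.append("-" * 46)
        lines.append("selected: " + ", ".join(r.selected_features))
        return "\n".join(lines)


class PainClassificationTask:
    """A pain-level classification problem on an extracted feature matrix.

    Model-style front end over the full stage chain: filter the matrix to
    the task's classes, split 75/25 (stratified), prune static and
    correlated features, forward-select with a fixed coarse-grid SVM, tune
    (C, gamma) on the selected set by the full grid, and evaluate on the
    held-out test part.  Feature selection and grid search see training
    data only.

    Parameters
    ----------
    features : DataFrame
        Labelled (z-normalized) feature matrix with ``subject_id`` and
        ``class_label`` columns.
    task : str
        One of ``B_vs_T1`` .. ``B_vs_T4``, ``B_vs_T1_vs_T4``, ``five_class``.
    """

    def __init__(self, features: pd.DataFrame, task: str = "B_vs_T4",
                 svm_config: SVMConfig | None = None,
                 split: SplitSpec | None = None,
                 corr_threshold: float = 0.95,
                 max_selected: int | None = 22):
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
        self.task = task
        self.classes = TASKS[task]
        self.features = features[features["class_label"].isin(self.classes)].reset_index(drop=True)
        self.svm_config = svm_config or SVMConfig()
        self.split = split or SplitSpec()
        self.corr_threshold = corr_threshold
        self.max_selected = max_selected

    def fit(self) -> PainTaskResults:
        train, test = split_data(self.features, self.split)
        seed = self.split.rng_seed

        m1, dropped_static = prune_static(train)
        m2, dropped_corr = prune_correlated(m1, self.corr_threshold)
        feats = feature_columns(m2)
        y_train = m2["class_label"].to_numpy()

        # fix (C, gamma) for the wrapper with a coarse grid on all candidates
        coarse = SVMConfig(C_grid=self.svm_config.coarse_C,
                           gamma_grid=self.svm_config.coarse_gamma,
                           cv_folds=self.svm_config.cv_folds)
        _, C0, g0, _ = grid_search_train(m2[feats].to_numpy(), y_train, coarse,
                                         random_state=seed)
        sel = forward_select(m2[feats], y_train,
                             SVC(C=C0, gamma=g0, kernel="rbf"),
                             cv_folds=self.svm_config.cv_folds,
                             random_state=seed, max_features=self.max_selected)
        sel.dropped_static = dropped_static
        sel.dropped_correlated = dropped_corr

        X_train = m2[sel.kept_features].to_numpy()
        model, C, gamma, cv_acc = grid_search_train(
            X_train, y_train, self.svm_config, random_state=seed)

        X_test = test[sel.kept_features].to_numpy()
        report = evaluate(model, X_test, test["class_label"].to_numpy(),
                          classes=list(self.classes),
                          selected_features=sel.kept_features,
                          svm_params=(C, gamma))
        return PainTaskResults(task=self.task, report=report, selection=sel,
                               model=model, train_cv_accuracy=cv_acc,
                               n_train=len(train), n_test=len(test))


def run_task(features: pd.DataFrame, task: str, svm_config: SVMConfig | None = None,
             split: SplitSpec | None = None, **kwargs) -> EvalReport:
    """Functional shorthand: fit a :class:`PainClassificationTask`, return report."""
    results = PainClassificationTask(features, task, svm_config=svm_config,
                                     split=split, **kwargs).fit()
    return results.report
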