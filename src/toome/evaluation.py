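"""Per-class metrics, repeated stratified cross-validation, class-mean tables.

Metrics follow the usual one-vs-rest definitions: per class *k*,
``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``,
``F1 = 2*precision*recall/(precision+recall)``,
``specificity = TN/(TN+FP)``; overall accuracy is the fraction of correct
predictions. A zero denominator yields 0 with a warning flag (not NaN) so
cohort averages stay defined — with strongly imbalanced cohorts a class can
legitimately end up with no positive predictions.

The evaluation protocol is repeated k-fold cross-validation (default 10
repeats of 10 folds) with stratified folds, so rare classes appear in every
training split despite heavy imbalance. When feature selection is requested
it is re-fit inside each training split: ranking features on the full data
before splitting would leak the held-out labels into the selector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import forest as forest_mod
from . import selection as selection_mod
from .errors import EmptyInputError, ParameterError, ShapeError
from .io import FeatureMatrix


@dataclass
class ConfusionTally:
    """One-vs-rest TP/FP/TN/FN tallies per class plus the K x K matrix."""

    class_labels: list[str]
    matrix: np.ndarray  # K x K, rows = true, cols = predicted

    @property
    def n_samples(self) -> int:
        return int(self.matrix.sum())

    def tp(self, k: int) -> int:
        return int(self.matrix[k, k])

    def fp(self, k: int) -> int:
        return int(self.matrix[:, k].sum() - self.matrix[k, k])

    def fn(self, k: int) -> int:
        return int(self.matrix[k, :].sum() - self.matrix[k, k])

    def tn(self, k: int) -> int:
        return self.n_samples - self.tp(k) - self.fp(k) - self.fn(k)

    def support(self, k: int) -> int:
        return int(self.matrix[k, :].sum())


def confusion(y_true, y_pred, class_labels: list[str]) -> ConfusionTally:
    """Tally a K x K confusion matrix over the given label ordering."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ShapeError("y_true and y_pred must have equal length")
    index = {lab: i for i, lab in enumerate(class_labels)}
    matrix = np.zeros((len(class_labels), len(class_labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ParameterError(f"label {t if t not in index else p!r} not in class_labels")
        matrix[index[t], index[p]] += 1
    return ConfusionTally(class_labels=list(class_labels), matrix=matrix)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1/specificity/support and overall accuracy."""

    per_class: pd.DataFrame  # index = class, columns = precision..support
    accuracy: float
    zero_denominator_classes: list[str] = field(default_factory=list)

    def macro_mean(self) -> pd.Series:
        """Unweighted mean over classes (the cohort-level summary)."""
        return self.per_class[["precision", "recall", "f1", "specificity"]].mean()


def metrics(tally: ConfusionTally) -> ClassMetrics:
    """Compute per-class metrics and overall accuracy from a tally."""
    rows, flagged = [], []
    for k, lab in enumerate(tally.class_labels):
        tp, fp, tn, fn = tally.tp(k), tally.fp(k), tally.tn(k), tally.fn(k)
        zero = False
        if tp + fp == 0 or tp + fn == 0 or tn + fp == 0:
            zero = True
            flagged.append(lab)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        specificity = tn / (tn + fp) if tn + fp else 0.0
        rows.append(
            {
                "precision": precision,
                "recall": recall,
                "f1": f1_score(precision, recall),
                "specificity": specificity,
                "support": tally.support(k),
            }
        )
        if zero:
            warnings.warn(f"zero-denominator metric for class {lab!r}; reported as 0",
                          stacklevel=2)
    per_class = pd.DataFrame(rows, index=tally.class_labels)
    accuracy = float(np.trace(tally.matrix) / tally.n_samples) if tally.n_samples else 0.0
    return ClassMetrics(per_class=per_class, accuracy=accuracy,
                        zero_denominator_classes=flagged)


@dataclass
class CVReport:
    """Aggregate of R repeats x F folds of cross-validated evaluation."""

    folds: int
    repeats: int
    per_class_mean: pd.DataFrame
    per_class_std: pd.DataFrame
    accuracy_mean: float
    accuracy_std: float
    fold_accuracies: np.ndarray          # shape (repeats, folds)
    class_labels: list[str]

    @property
    def per_repeat_accuracies(self) -> np.ndarray:
        return self.fold_accuracies.mean(axis=1)

    def accuracy_standard_error(self) -> float:
        """Standard error of the mean over all R x F fold accuracies."""
        flat = self.fold_accuracies.ravel()
        return float(flat.std(ddof=1) / np.sqrt(flat.size))

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "repeats": self.repeats,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_std": self.accuracy_std,
            "per_class_mean": self.per_class_mean.round(10).to_dict(),
            "per_class_std": self.per_class_std.round(10).to_dict(),
            "fold_accuracies": self.fold_accuracies.tolist(),
            "class_labels": self.class_labels,
        }

    def per_class_table(self) -> pd.DataFrame:
        """Per-class mean metrics plus a final overall-accuracy row."""
        table = self.per_class_mean.copy()
        acc_row = pd.Series(
            {c: (self.accuracy_mean if c != "support" else 0.0) for c in table.columns},
            name="Accuracy",
        )
        return pd.concat([table, acc_row.to_frame().T])


def _fold_seed(seed_sequence: np.random.SeedSequence) -> int:
    # scikit-learn wants a plain int; keep it in the 31-bit range
    return int(seed_sequence.generate_state(1)[0] % (2**31 - 1))


def cross_validate(
    matrix: FeatureMatrix,
    folds: int = 10,
    repeats: int = 10,
    seed: int | None = None,
    top_h: int | None = None,
    n_trees: int = 100,
    mtry: int | None = None,
    ranking_trees: int | None = None,
    min_samples_split: int = 2,
    convention: forest_mod.Convention = "weighted",
    stratify: bool = True,
    rank_once: bool = False,
) -> CVReport:
    """Repeated (stratified) k-fold cross-validation of the forest classifier.

    When ``top_h`` is given, a ranking forest is fit on each training split,
    the top-H features are selected, and the evaluation forest is fit on that
    subset (``rank_once=True`` instead ranks a single time on the full data —
    the optimistic, leaky protocol — for comparison purposes only).
    If a class has fewer members than ``folds``, the fold count is capped to
    the smallest class size with a warning.
    """
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    X = matrix.X.to_numpy(dtype=float)
    y = matrix.y.to_numpy(dtype=object)
    class_labels = matrix.class_labels
    if len(class_labels) < 2:
        raise EmptyInputError("cross-validation needs at least 2 classes")

    min_class = int(pd.Series(y).value_counts().min())
    if stratify and min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} members < folds={folds}; capping folds",
            stacklevel=2,
        )
        folds = max(2, min_class)

    root = np.random.SeedSequence(seed)
    repeat_seqs = root.spawn(repeats)

    global_ranking = None
    if top_h is not None and rank_once:
        fullf = forest_mod.fit_forest(
            X, y, n_trees=ranking_trees or n_trees, mtry=mtry,
            rng_seed=_fold_seed(root.spawn(1)[0]),
            min_samples_split=min_samples_split, convention=convention,
        )
        global_ranking = selection_mod.rank_features(fullf, matrix.feature_names)

    total_matrix = np.zeros((len(class_labels), len(class_labels)), dtype=np.int64)
    fold_metrics: list[ClassMetrics] = []
    fold_acc = np.zeros((repeats, folds))
    names = np.asarray(matrix.feature_names, dtype=object)

    for r, rseq in enumerate(repeat_seqs):
        cv_seed, *fold_seeds = rseq.spawn(folds + 1)
        splitter = (
            StratifiedKFold(n_splits=folds, shuffle=True, random_state=_fold_seed(cv_seed))
            if stratify
            else KFold(n_splits=folds, shuffle=True, random_state=_fold_seed(cv_seed))
        )
        for f, (train, test) in enumerate(splitter.split(X, y)):
            fseed = _fold_seed(fold_seeds[f])
            cols = np.arange(X.shape[1])
            if top_h is not None:
                if global_ranking is not None:
                    ranking = global_ranking
                else:
                    rank_forest = forest_mod.fit_forest(
                        X[train], y[train], n_trees=ranking_trees or n_trees,
                        mtry=mtry, rng_seed=fseed,
                        min_samples_split=min_samples_split, convention=convention,
                    )
                    ranking = selection_mod.rank_features(rank_forest, list(names))
                keep = set(selection_mod.select_top(ranking, min(top_h, X.shape[1])))
                cols = np.asarray([i for i, nm in enumerate(names) if nm in keep])
            model = forest_mod.fit_forest(
                X[np.ix_(train, cols)], y[train], n_trees=n_trees, mtry=mtry,
                rng_seed=fseed + 1, min_samples_split=min_samples_split,
                convention=convention,
            )
            pred = model.predict(X[np.ix_(test, cols)])
            # held-out folds may miss rare classes; tally over the full label set
            tally = confusion(y[test], pred, class_labels)
            total_matrix += tally.matrix
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = metrics(tally)
            fold_metrics.append(m)
            fold_acc[r, f] = m.accuracy

    per_class_stack = np.stack([m.per_class.to_numpy() for m in fold_metrics])
    cols = fold_metrics[0].per_class.columns
    per_class_mean = pd.DataFrame(per_class_stack.mean(axis=0), index=class_labels, columns=cols)
    per_class_std = pd.DataFrame(per_class_stack.std(axis=0, ddof=0), index=class_labels, columns=cols)
    return CVReport(
        folds=folds,
        repeats=repeats,
        per_class_mean=per_class_mean,
        per_class_std=per_class_std,
        accuracy_mean=float(fold_acc.mean()),
        accuracy_std=float(fold_acc.std(ddof=0)),
        fold_accuracies=fold_acc,
        class_labels=class_labels,
    )


def class_means(matrix: FeatureMatrix, selected_features: list[str], pseudo: float = 1.0) -> pd.DataFrame:
    """Class x feature table of ``log10(mean + pseudo)``.

    The arithmetic mean of each selected feature is taken within each class,
    then log-transformed with a pseudocount so all-zero features map to 0.
    Intended as input to external heatmap/clustering tools.
    """
    missing = [f for f in selected_features if f not in matrix.X.columns]
    if missing:
        raise ParameterError(f"features not in matrix: {', '.join(missing[:5])}")
    counts = matrix.y.value_counts()
    if (counts < 1).any() or matrix.y.size == 0:
        raise EmptyInputError("every class needs at least one sample")
    grouped = matrix.X[selected_features].groupby(matrix.y).mean()
    return np.log10(grouped + pseudo)
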