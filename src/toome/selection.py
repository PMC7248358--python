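"""Feature ranking by forest-wide Gini importance and the gene-number sweep.

A feature's importance is the sum, over every tree and every node split on
that feature, of the Gini-impurity decrease at that node. Ranking all features
by this score and keeping the top *H* reduces the panel from thousands of
genes to a size a targeted assay could measure; the sweep re-runs
cross-validation over a schedule of *H* values to locate the smallest panel
that preserves accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import forest as forest_mod
from .errors import ParameterError
from .io import FeatureMatrix

#: Fig.-2-style default schedule: coarse below 50, then step 5 up to 120.
DEFAULT_SCHEDULE: tuple[int, ...] = (5, 10, 20, 30, 40, 50) + tuple(range(55, 125, 5))


@dataclass
class ImportanceRanking:
    """Features sorted by non-increasing importance, ties broken by name."""

    entries: list[tuple[str, float]]

    @property
    def feature_names(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def importances(self) -> list[float]:
        return [imp for _, imp in self.entries]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["feature", "importance"])
        df.insert(0, "rank", range(1, len(df) + 1))
        df["modality"] = [f.split(":", 1)[0] if ":" in f else "" for f in df["feature"]]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ImportanceRanking":
        df = pd.read_csv(path, sep="\t")
        return cls(entries=list(zip(df["feature"].astype(str), df["importance"].astype(float))))


def rank_features(forest: forest_mod.Forest, feature_names: list[str]) -> ImportanceRanking:
    """Rank features by summed per-tree importance.

    Features never used in any split get importance 0 and sort last,
    alphabetically among themselves.
    """
    if len(feature_names) != forest.n_features:
        raise ParameterError(
            f"{len(feature_names)} names for a forest with {forest.n_features} features"
        )
    imp = forest.feature_importances()
    order = sorted(range(len(feature_names)), key=lambda i: (-imp[i], feature_names[i]))
    return ImportanceRanking(entries=[(feature_names[i], float(imp[i])) for i in order])


def select_top(ranking: ImportanceRanking, top_h: int) -> list[str]:
    """First ``top_h`` feature names of the ranking."""
    if not 1 <= top_h <= len(ranking.entries):
        raise ParameterError(f"top_h={top_h} out of range [1, {len(ranking.entries)}]")
    return ranking.feature_names[:top_h]


@dataclass
class SweepResult:
    """Cross-validated accuracy across the H schedule."""

    records: list[dict] = field(default_factory=list)  # keys: H, accuracy, accuracy_std

    @property
    def schedule(self) -> list[int]:
        return [r["H"] for r in self.records]

    @property
    def best_H(self) -> int:
        """H attaining the maximum accuracy; ties go to the smallest H."""
        best = max(self.records, key=lambda r: (r["accuracy"], -r["H"]))
        return best["H"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def sweep(
    matrix: FeatureMatrix,
    schedule=DEFAULT_SCHEDULE,
    folds: int = 10,
    repeats: int = 10,
    seed: int | None = None,
    n_trees: int = 100,
    ranking_trees: int | None = None,
    mtry: int | None = None,
    convention: forest_mod.Convention = "weighted",
    stratify: bool = True,
    rank_once: bool = False,
) -> SweepResult:
    """Evaluate the classifier over a schedule of panel sizes H.

    For each H the feature ranking is re-fit inside every cross-validation
    training split (no selection leakage) and accuracy measured on the held-out
    folds. The schedule must be strictly increasing and bounded by the number
    of features.
    """
    from . import evaluation  # local import: evaluation also imports selection

    schedule = [int(h) for h in schedule]
    if not schedule:
        raise ParameterError("schedule must be non-empty")
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ParameterError("schedule must be strictly increasing")
    n_features = len(matrix.feature_names)
    if schedule[-1] > n_features:
        raise ParameterError(f"schedule max {schedule[-1]} exceeds N={n_features}")

    result = SweepResult()
    for h in schedule:
        report = evaluation.cross_validate(
            matrix, folds=folds, repeats=repeats, seed=seed, top_h=h,
            n_trees=n_trees, ranking_trees=ranking_trees, mtry=mtry,
            convention=convention, stratify=stratify, rank_once=rank_once,
        )
        result.records.append(
            {"H": h, "accuracy": report.accuracy_mean, "accuracy_std": report.accuracy_std}
        )
    return result
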