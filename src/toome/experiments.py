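"""Reproducible study protocols run on synthetic cohorts.

Each function here executes one self-contained computational experiment —
planted-feature recovery, modality comparison, permutation-null calibration,
pipeline determinism — at a fixed, documented problem size, returning plain
dictionaries of numbers. They are the package's own evidence that the
selection and classification machinery behaves as designed; the test suite
asserts on their outputs and the reproduction script reports them.

All randomness is derived from a single integer seed through named
substreams, so every experiment is exactly repeatable.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np

from . import cli, evaluation, forest, io, selection, synthetic


def _sub_seeds(seed: int, n: int, stream: str) -> list[int]:
    """n deterministic 31-bit child seeds for a named stream."""
    root = np.random.SeedSequence([seed, zlib.crc32(stream.encode()) % (2**31)])
    return [int(s) for s in root.generate_state(n) % (2**31 - 1)]


def _default_cohort_matrix(seed: int):
    """The generator's reference cohort: 20 classes with the published
    imbalance scaled to 400 samples, 500 expression + 200 mutation genes,
    20 + 5 planted informative features at the default effect sizes."""
    spec = synthetic.CohortSpec(
        class_sizes=synthetic.proportional_sizes(400),
        n_expr_genes=500, n_mut_genes=200,
        n_informative_expr=20, n_informative_mut=5,
        effect_size=2.0, seed=seed,
    )
    expr, records, labels, id_map, truth = synthetic.generate(spec)
    mut = io.count_mutations(records, id_map)
    return io.merge_modalities(expr, mut, labels), truth


def feature_recovery(seed: int = 1, n_seeds: int = 10, top_h: int = 80,
                     n_trees: int = 150) -> dict:
    """Fraction of planted informative features recovered in the top-H ranking.

    One ranking forest per replicate cohort; H defaults to the 80-gene panel
    size the method settles on. Returns per-replicate fractions and the mean.
    """
    fractions = []
    for s in _sub_seeds(seed, n_seeds, "recovery"):
        fm, truth = _default_cohort_matrix(s)
        f = forest.fit_forest(
            fm.X.to_numpy(float), fm.y.to_numpy(object),
            n_trees=n_trees, rng_seed=(s + 1) % (2**31 - 1),
        )
        ranking = selection.rank_features(f, fm.feature_names)
        top = set(selection.select_top(ranking, top_h))
        planted = set(truth.informative)
        fractions.append(len(top & planted) / len(planted))
    return {
        "per_seed": fractions,
        "mean_recovery": float(np.mean(fractions)),
        "n_seeds": n_seeds,
        "top_h": top_h,
    }


def _complementary_cohort_matrix(seed: int):
    """Six balanced classes of 40; 4 expression markers cover four classes and
    14 mutation markers (round-robin) give the two expression-dark classes two
    mutation markers each, so the modalities carry complementary signal."""
    spec = synthetic.CohortSpec(
        class_sizes={f"C{i:02d}": 40 for i in range(6)},
        n_expr_genes=60, n_mut_genes=40,
        n_informative_expr=4, n_informative_mut=14,
        effect_size=2.0, seed=seed,
    )
    expr, records, labels, id_map, truth = synthetic.generate(spec)
    mut = io.count_mutations(records, id_map)
    return io.merge_modalities(expr, mut, labels), truth


def modality_comparison(seed: int = 1, n_seeds: int = 6, top_h: int = 20,
                        folds: int = 3, repeats: int = 2,
                        n_trees: int = 80) -> dict:
    """Cross-validated accuracy of combined vs single-modality features.

    Feature selection (top-H) is re-fit inside every training fold for each
    view at the same matched H. Returns the mean accuracy per view over the
    replicate cohorts.
    """
    acc: dict[str, list[float]] = {"combined": [], "expression": [], "mutation": []}
    for s in _sub_seeds(seed, n_seeds, "modality"):
        fm, _ = _complementary_cohort_matrix(s)
        views = {
            "combined": fm,
            "expression": fm.modality_view("expr"),
            "mutation": fm.modality_view("mut"),
        }
        for name, view in views.items():
            rep = evaluation.cross_validate(
                view, folds=folds, repeats=repeats, seed=(s + 7) % (2**31 - 1),
                top_h=min(top_h, len(view.feature_names)), n_trees=n_trees,
                ranking_trees=n_trees,
            )
            acc[name].append(rep.accuracy_mean)
    return {name: float(np.mean(v)) for name, v in acc.items()} | {
        "per_seed": acc, "n_seeds": n_seeds, "top_h": top_h,
    }


def null_calibration(seed: int = 1, n_classes: int = 5, per_class: int = 24,
                     folds: int = 5, repeats: int = 2, n_trees: int = 60) -> dict:
    """Label-permuted balanced cohort: CV accuracy should sit at chance (1/K).

    Labels are randomly permuted after generation, destroying every
    feature-label association while preserving marginals. Returns the mean
    accuracy, the chance level, and the standard error over all fold
    accuracies.
    """
    s_gen, s_perm, s_cv = _sub_seeds(seed, 3, "null")
    spec = synthetic.CohortSpec(
        class_sizes={f"K{i}": per_class for i in range(n_classes)},
        n_expr_genes=40, n_mut_genes=20,
        n_informative_expr=5, n_informative_mut=2,
        effect_size=2.0, seed=s_gen,
    )
    expr, records, labels, id_map, _ = synthetic.generate(spec)
    mut = io.count_mutations(records, id_map)
    fm = io.merge_modalities(expr, mut, labels)
    rng = np.random.default_rng(s_perm)
    fm.y = fm.y.iloc[rng.permutation(len(fm.y))].set_axis(fm.y.index)
    rep = evaluation.cross_validate(
        fm, folds=folds, repeats=repeats, seed=s_cv, n_trees=n_trees
    )
    return {
        "accuracy": rep.accuracy_mean,
        "chance": 1.0 / n_classes,
        "standard_error": rep.accuracy_standard_error(),
        "abs_deviation": abs(rep.accuracy_mean - 1.0 / n_classes),
    }


def pipeline_determinism(workdir, seed: int = 1) -> dict:
    """Run the full pipeline twice with one seed; outputs must be identical.

    Simulates a cohort, writes it as TSV, and executes
    build-matrix -> select -> cv twice into separate directories, comparing
    the report, ranking and matrix byte-for-byte.
    """
    workdir = Path(workdir)
    s_sim, s_run = _sub_seeds(seed, 2, "determinism")
    spec = synthetic.CohortSpec.default(
        total_samples=120, n_classes=5, n_expr_genes=40, n_mut_genes=25,
        n_informative_expr=6, n_informative_mut=3, seed=s_sim,
    )
    expr, records, labels, id_map, _ = synthetic.generate(spec)
    paths = synthetic.write_cohort(workdir / "sim", expr, records, labels, id_map)
    config = {
        "expr": str(paths["expression"]), "mut": str(paths["mutations"]),
        "labels": str(paths["labels"]), "map": str(paths["id_map"]),
        "trees": 25, "folds": 3, "repeats": 1, "top": 12, "seed": s_run,
    }
    reports = []
    for name in ("run1", "run2"):
        report = cli.run_pipeline(dict(config), workdir / name)
        reports.append(report)
    identical = all(
        (reports[0].parent / f).read_bytes() == (reports[1].parent / f).read_bytes()
        for f in ("report.json", "ranking.tsv", "matrix.tsv", "per_class.tsv")
    )
    accuracy = json.loads(reports[0].read_text())["accuracy_mean"]
    return {"identical": bool(identical), "accuracy": accuracy}
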