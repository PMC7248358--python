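"""Synthetic multi-class expression + mutation cohorts with planted structure.

Every downstream stage — IO merging, forest fitting, importance ranking,
cross-validation — is exercised on cohorts generated here, so the whole
pipeline is testable without any external download.

The generative model:

* **Expression.** Gene *g* in sample *s* of class *k* is log-normal:
  ``exp(Normal(mu_{k,g}, sigma^2))``, TPM-like and non-negative. Informative
  genes get a mean shift ``delta_e`` (on the log scale) in their assigned
  class; all other (gene, class) pairs share the baseline ``mu0``.
* **Mutations.** Per-(sample, gene) counts are Poisson. Background rate
  ``lambda0`` is sparse (0.05 mutations/gene/sample, like real somatic data);
  an informative gene's rate is multiplied by ``rate_ratio`` in its assigned
  class. Counts are expanded into individual (donor, chromosome, locus,
  Ensembl-ID) records with distinct synthetic loci, and a configurable
  fraction of records is duplicated verbatim so deduplication logic is always
  exercised.

Class sizes default to the relative imbalance of the 20-solid-tumor ICGC
cohort distribution in :data:`COHORT_DISTRIBUTION` (7,008 samples, BRCA-heavy),
scaled to the requested total. Everything is determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import ExpressionMatrix

#: Published per-cancer sample counts of the 20-type ICGC training cohort
#: (solid tumors, SKCM removed). Used as the default class-imbalance profile.
COHORT_DISTRIBUTION: dict[str, int] = {
    "BLCA": 294, "BRCA": 970, "CESC": 241, "COAD": 390, "GBM": 148,
    "HNSC": 460, "KIRC": 345, "KIRP": 216, "LAML": 121, "LGG": 433,
    "LIHC": 282, "LUAD": 475, "LUSC": 411, "OV": 185, "PAAD": 134,
    "PRAD": 374, "READ": 137, "STAD": 412, "THCA": 486, "UCEC": 494,
}

#: Percentages as printed alongside the counts (two decimals).
COHORT_PERCENTAGES: dict[str, float] = {
    "BLCA": 4.20, "BRCA": 13.84, "CESC": 3.44, "COAD": 5.57, "GBM": 2.11,
    "HNSC": 6.56, "KIRC": 4.92, "KIRP": 3.08, "LAML": 1.73, "LGG": 6.18,
    "LIHC": 4.02, "LUAD": 6.78, "LUSC": 5.87, "OV": 2.64, "PAAD": 1.91,
    "PRAD": 5.34, "READ": 1.95, "STAD": 5.88, "THCA": 6.93, "UCEC": 7.05,
}


def recompute_percentages(counts: dict[str, int] | None = None, ndigits: int = 2) -> dict[str, float]:
    """Per-class percentage of the cohort, rounded to ``ndigits``."""
    counts = counts or COHORT_DISTRIBUTION
    total = sum(counts.values())
    return {k: round(100.0 * v / total, ndigits) for k, v in counts.items()}


def proportional_sizes(total: int, counts: dict[str, int] | None = None) -> dict[str, int]:
    """Scale the cohort distribution to ``total`` samples, at least 1 per class.

    Uses largest-remainder rounding so the sizes sum exactly to ``total``.
    """
    counts = counts or COHORT_DISTRIBUTION
    if total < len(counts):
        raise ParameterError(f"total={total} < number of classes ({len(counts)})")
    grand = sum(counts.values())
    raw = {k: total * v / grand for k, v in counts.items()}
    sizes = {k: max(1, int(np.floor(r))) for k, r in raw.items()}
    remainder = total - sum(sizes.values())
    order = sorted(counts, key=lambda k: (raw[k] - np.floor(raw[k]), counts[k]), reverse=True)
    i = 0
    while remainder > 0:
        sizes[order[i % len(order)]] += 1
        remainder -= 1
        i += 1
    while remainder < 0:
        k = order[i % len(order)]
        if sizes[k] > 1:
            sizes[k] -= 1
            remainder += 1
        i += 1
    return sizes


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``class_sizes`` maps class name -> sample count. ``n_informative_expr``
    expression genes and ``n_informative_mut`` mutation genes are planted
    with class-specific signal, assigned to classes round-robin.
    """

    class_sizes: dict[str, int]
    n_expr_genes: int = 500
    n_mut_genes: int = 200
    n_informative_expr: int = 20
    n_informative_mut: int = 5
    effect_size: float = 2.0       # delta_e, log-scale mean shift
    sigma: float = 0.5             # log-scale SD of expression
    mu0: float = 2.0               # baseline log-mean (exp(2) ~ 7.4 TPM)
    lambda0: float = 0.05          # background mutations/gene/sample
    rate_ratio: float = 10.0       # informative-class Poisson rate multiplier
    duplicate_rate: float = 0.05   # fraction of mutation records duplicated
    seed: int = 0

    def validate(self) -> None:
        if not self.class_sizes or len(self.class_sizes) < 2:
            raise ParameterError("need at least 2 classes")
        if any(n < 1 for n in self.class_sizes.values()):
            raise ParameterError("every class needs at least 1 sample")
        if self.n_informative_expr > self.n_expr_genes:
            raise ParameterError("n_informative_expr exceeds n_expr_genes")
        if self.n_informative_mut > self.n_mut_genes:
            raise ParameterError("n_informative_mut exceeds n_mut_genes")
        if self.lambda0 < 0 or self.rate_ratio < 0 or self.sigma < 0:
            raise ParameterError("rates and dispersions must be non-negative")
        if not 0 <= self.duplicate_rate < 1:
            raise ParameterError("duplicate_rate must be in [0, 1)")

    @classmethod
    def default(cls, total_samples: int = 400, n_classes: int | None = None, **kw) -> "CohortSpec":
        """Cohort with the published imbalance profile scaled to
        ``total_samples``; ``n_classes`` truncates to the largest classes."""
        counts = COHORT_DISTRIBUTION
        if n_classes is not None:
            keep = sorted(counts, key=counts.get, reverse=True)[:n_classes]
            counts = {k: counts[k] for k in sorted(keep)}
        return cls(class_sizes=proportional_sizes(total_samples, counts), **kw)


@dataclass
class CohortTruth:
    """Ground truth returned with a generated cohort, for recovery tests."""

    informative_expr: list[str]            # tagged names, e.g. "expr:EXPG007"
    informative_mut: list[str]             # tagged names, e.g. "mut:MUTG003"
    expr_gene_class: dict[str, str]        # informative gene -> assigned class
    mut_gene_class: dict[str, str]
    latent_counts: pd.DataFrame            # Poisson draws before record expansion

    @property
    def informative(self) -> list[str]:
        return self.informative_expr + self.informative_mut


def generate(spec: CohortSpec):
    """Draw one cohort.

    Returns ``(expression, mutation_records, labels, id_map, truth)`` where
    ``mutation_records`` is a raw record DataFrame (with injected duplicate
    rows) ready for :func:`toome.io.count_mutations`, ``labels`` is a
    sample -> class Series, and ``id_map`` maps the synthetic Ensembl IDs to
    symbols. Fully determined by ``spec.seed``.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rng_expr, rng_mut, rng_loci, rng_dup = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    classes = sorted(spec.class_sizes)
    sample_ids, y = [], []
    for k in classes:
        for i in range(spec.class_sizes[k]):
            sample_ids.append(f"S_{k}_{i:04d}")
            y.append(k)
    labels = pd.Series(y, index=sample_ids, name="cancer_type")
    M = len(sample_ids)
    class_index = np.asarray([classes.index(k) for k in y])

    expr_genes = [f"EXPG{i:04d}" for i in range(spec.n_expr_genes)]
    mut_symbols = [f"MUTG{i:04d}" for i in range(spec.n_mut_genes)]
    ensembl_ids = [f"ENSG{i:011d}" for i in range(spec.n_mut_genes)]

    # Round-robin assignment of informative genes to classes. Mutation markers
    # continue where the expression markers stopped, so when expression does
    # not cover every class the two modalities carry complementary signal.
    K = len(classes)
    expr_assign = {expr_genes[i]: classes[i % K] for i in range(spec.n_informative_expr)}
    offset = spec.n_informative_expr % K
    mut_assign = {mut_symbols[i]: classes[(offset + i) % K] for i in range(spec.n_informative_mut)}

    mu = np.full((M, spec.n_expr_genes), spec.mu0)
    for j, g in enumerate(expr_genes[: spec.n_informative_expr]):
        mu[class_index == classes.index(expr_assign[g]), j] += spec.effect_size
    expr_values = np.exp(rng_expr.normal(mu, spec.sigma))
    expression = ExpressionMatrix(
        values=pd.DataFrame(expr_values, index=sample_ids, columns=expr_genes)
    )

    lam = np.full((M, spec.n_mut_genes), spec.lambda0)
    for j, g in enumerate(mut_symbols[: spec.n_informative_mut]):
        lam[class_index == classes.index(mut_assign[g]), j] *= spec.rate_ratio
    latent = rng_mut.poisson(lam)
    latent_counts = pd.DataFrame(latent, index=sample_ids, columns=mut_symbols)

    # expand counts into per-mutation records with distinct loci per (sample, gene)
    s_idx, g_idx = np.nonzero(latent)
    rows = []
    for s, g in zip(s_idx, g_idx):
        c = latent[s, g]
        chrom = str(g % 22 + 1)
        offsets = rng_loci.choice(5000, size=c, replace=False)
        for off in offsets:
            rows.append((sample_ids[s], chrom, g * 10_000 + 1 + int(off), ensembl_ids[g]))
    records = pd.DataFrame(rows, columns=["donor_id", "chromosome", "locus", "gene_affected"])

    if spec.duplicate_rate > 0 and len(records) > 0:
        n_dup = int(round(spec.duplicate_rate * len(records)))
        if n_dup:
            dup_rows = records.iloc[rng_dup.choice(len(records), size=n_dup, replace=True)]
            records = pd.concat([records, dup_rows], ignore_index=True)
            records = records.iloc[rng_dup.permutation(len(records))].reset_index(drop=True)

    id_map = pd.DataFrame({"ensembl_gene_id": ensembl_ids, "gene_symbol": mut_symbols})
    truth = CohortTruth(
        informative_expr=[f"expr:{g}" for g in expr_genes[: spec.n_informative_expr]],
        informative_mut=[f"mut:{g}" for g in mut_symbols[: spec.n_informative_mut]],
        expr_gene_class={g: expr_assign[g] for g in expr_genes[: spec.n_informative_expr]},
        mut_gene_class={g: mut_assign[g] for g in mut_symbols[: spec.n_informative_mut]},
        latent_counts=latent_counts,
    )
    return expression, records, labels, id_map, truth


def write_cohort(outdir, expression: ExpressionMatrix, records: pd.DataFrame,
                 labels: pd.Series, id_map: pd.DataFrame) -> dict[str, Path]:
    """Write the four cohort tables as TSV in the formats the IO layer reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "mutations": outdir / "mutations.tsv",
        "labels": outdir / "labels.tsv",
        "id_map": outdir / "id_map.tsv",
    }
    expression.values.to_csv(paths["expression"], sep="\t", index_label="sample_id")
    records.to_csv(paths["mutations"], sep="\t", index=False)
    labels.rename_axis("sample_id").to_frame().to_csv(paths["labels"], sep="\t")
    id_map.to_csv(paths["id_map"], sep="\t", index=False)
    return paths
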