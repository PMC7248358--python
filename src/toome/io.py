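"""Reading, validation and merging of the two molecular modalities.

The pipeline consumes four tab-separated tables:

* an expression matrix (rows = samples, columns = gene symbols, TPM values),
* a simple-somatic-mutation record table (one row per mutation call:
  ``donor_id``, ``chromosome``, ``locus``, ``gene_affected`` as Ensembl ID),
* a sample -> cancer-type label table,
* an Ensembl-ID -> gene-symbol mapping table.

Mutation records are deduplicated on the full (donor, chromosome, locus, gene)
key — the same physical mutation reported twice counts once — and collapsed to
per-(sample, gene) counts. The two modalities are then merged into a single
labeled feature matrix over the samples present in *both*; a sample missing
from one modality is excluded rather than zero-filled, because a genuine zero
mutation count is informative and must not be conflated with missingness.

Feature names carry a modality prefix (``expr:``/``mut:``) so a gene measured
in both modalities yields two distinct features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ParseError

logger = logging.getLogger(__name__)

MUTATION_KEY_COLUMNS = ["donor_id", "chromosome", "locus", "gene_affected"]


def _normalize_chromosome(chrom: pd.Series) -> pd.Series:
    """'chr1' and '1' denote the same chromosome; compare case-insensitively."""
    s = chrom.astype(str).str.strip().str.lower()
    return s.str.removeprefix("chr")


@dataclass
class ExpressionMatrix:
    """Samples x genes TPM matrix. ``values``: DataFrame indexed by sample ID
    with gene-symbol columns; all entries finite and non-negative."""

    values: pd.DataFrame
    n_duplicate_samples_dropped: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MutationCountMatrix:
    """Samples x genes matrix of deduplicated mutation counts (symbols as
    columns, after Ensembl -> symbol mapping)."""

    counts: pd.DataFrame
    n_duplicates_removed: int = 0
    n_unmapped_dropped: int = 0
    n_ambiguous_dropped: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class FeatureMatrix:
    """The merged M x N analysis matrix with aligned labels.

    ``X``: DataFrame indexed by sample ID whose columns are modality-tagged
    feature names; ``y``: Series of cancer-type labels on the same index.
    """

    X: pd.DataFrame
    y: pd.Series
    provenance: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def class_labels(self) -> list[str]:
        return sorted(self.y.unique())

    def modality_view(self, modality: str) -> "FeatureMatrix":
        """Restrict to one modality ('expr' or 'mut'); labels unchanged."""
        cols = [c for c in self.X.columns if c.startswith(modality + ":")]
        return FeatureMatrix(X=self.X[cols], y=self.y, provenance=dict(self.provenance))

    def to_tsv(self, path, sidecar: bool = True) -> None:
        out = self.X.copy()
        out.insert(0, "label", self.y)
        out.to_csv(path, sep="\t", index_label="sample_id")
        if sidecar:
            with open(str(path) + ".json", "w") as fh:
                json.dump(self.provenance, fh, indent=2, sort_keys=True)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        if "label" not in df.columns:
            raise FormatError(f"{path}: missing 'label' column")
        y = df["label"].astype(str)
        X = df.drop(columns=["label"])
        X.index.name = None
        y.index.name = None
        y.name = None
        prov = {}
        try:
            with open(str(path) + ".json") as fh:
                prov = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(X=X, y=y, provenance=prov)


def read_expression(path) -> ExpressionMatrix:
    """Read and validate a TPM expression matrix.

    Duplicate sample rows are collapsed to the first occurrence (logged);
    duplicate gene columns and unparseable or negative cells are errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen, dup_genes = set(), []
    for g in header:
        if g in seen:
            dup_genes.append(g)
        seen.add(g)
    if dup_genes:
        raise FormatError(f"{path}: duplicate gene column(s): {', '.join(sorted(set(dup_genes)))}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)

    n_dup = int(df.index.duplicated().sum())
    if n_dup:
        logger.info("read_expression: dropping %d duplicate sample row(s), keeping first", n_dup)
        df = df[~df.index.duplicated(keep="first")]

    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = np.argwhere(values.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: unparseable numeric cell at sample {df.index[bad[0]]!r}, "
            f"gene {df.columns[bad[1]]!r} (value {df.iat[bad[0], bad[1]]!r})"
        )
    if (values.to_numpy() < 0).any():
        bad = np.argwhere(values.to_numpy() < 0)[0]
        raise ParseError(
            f"{path}: negative expression at sample {values.index[bad[0]]!r}, "
            f"gene {values.columns[bad[1]]!r}"
        )
    values.index = values.index.astype(str)
    return ExpressionMatrix(values=values, n_duplicate_samples_dropped=n_dup)


def read_id_map(path) -> pd.DataFrame:
    """Read an Ensembl-to-symbol mapping table (columns ``ensembl_gene_id``,
    ``gene_symbol``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"ensembl_gene_id", "gene_symbol"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing mapping column(s): {', '.join(sorted(missing))}")
    return df


def read_mutation_records(path) -> pd.DataFrame:
    """Read a raw mutation record table and check the four key columns."""
    df = pd.read_csv(path, sep="\t", dtype={"donor_id": str, "chromosome": str,
                                            "gene_affected": str})
    missing = [c for c in MUTATION_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing key column(s): {', '.join(missing)}")
    return df


def count_mutations(records: pd.DataFrame, id_map: pd.DataFrame) -> MutationCountMatrix:
    """Deduplicate mutation records and count them per (donor, gene symbol).

    Dedup key is (donor, normalized chromosome, locus, gene). Ensembl IDs
    absent from the map, and IDs mapping to more than one symbol, are dropped
    with logged counts.
    """
    missing = [c for c in MUTATION_KEY_COLUMNS if c not in records.columns]
    if missing:
        raise FormatError(f"mutation records: missing key column(s): {', '.join(missing)}")
    rec = records[MUTATION_KEY_COLUMNS].copy()
    rec["chromosome"] = _normalize_chromosome(rec["chromosome"])
    rec["locus"] = pd.to_numeric(rec["locus"], errors="raise").astype(np.int64)

    before = len(rec)
    rec = rec.drop_duplicates(subset=MUTATION_KEY_COLUMNS)
    n_dups = before - len(rec)

    sym_counts = id_map.groupby("ensembl_gene_id")["gene_symbol"].nunique()
    ambiguous = set(sym_counts[sym_counts > 1].index)
    mapping = (
        id_map[~id_map["ensembl_gene_id"].isin(ambiguous)]
        .drop_duplicates("ensembl_gene_id")
        .set_index("ensembl_gene_id")["gene_symbol"]
    )
    n_ambiguous = int(rec["gene_affected"].isin(ambiguous).sum())
    if n_ambiguous:
        logger.info("count_mutations: dropping %d record(s) with ambiguous gene mapping", n_ambiguous)
    rec = rec[~rec["gene_affected"].isin(ambiguous)]
    symbols = rec["gene_affected"].map(mapping)
    n_unmapped = int(symbols.isna().sum())
    if n_unmapped:
        logger.info("count_mutations: dropping %d record(s) with unmapped gene ID", n_unmapped)
    rec = rec.assign(gene_symbol=symbols).dropna(subset=["gene_symbol"])
    if rec.empty:
        raise EmptyInputError("no mutation records left after gene-symbol mapping")

    counts = (
        rec.groupby(["donor_id", "gene_symbol"], sort=True)
        .size()
        .unstack(fill_value=0)
        .astype(np.int64)
    )
    counts.index = counts.index.astype(str)
    counts.columns.name = None
    counts.index.name = None
    return MutationCountMatrix(
        counts=counts,
        n_duplicates_removed=n_dups,
        n_unmapped_dropped=n_unmapped,
        n_ambiguous_dropped=n_ambiguous,
    )


def read_mutations(path, id_map: pd.DataFrame | str) -> MutationCountMatrix:
    """Read a record table and reduce it to deduplicated per-gene counts."""
    if isinstance(id_map, (str, bytes)) or hasattr(id_map, "__fspath__"):
        id_map = read_id_map(id_map)
    return count_mutations(read_mutation_records(path), id_map)


def read_labels(path) -> pd.Series:
    """Read the sample -> cancer-type table (columns ``sample_id``,
    ``cancer_type``); conflicting duplicate labels are an error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "cancer_type"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing label column(s): {', '.join(sorted(missing))}")
    return labels_from_frame(df)


def labels_from_frame(df: pd.DataFrame) -> pd.Series:
    per_sample = df.drop_duplicates().groupby("sample_id")["cancer_type"].nunique()
    conflicts = per_sample[per_sample > 1]
    if len(conflicts):
        raise FormatError(
            f"conflicting labels for sample(s): {', '.join(conflicts.index[:5])}"
        )
    out = df.drop_duplicates("sample_id").set_index("sample_id")["cancer_type"]
    out.index = out.index.astype(str)
    return out


def merge_modalities(
    expr: ExpressionMatrix,
    mut: MutationCountMatrix,
    labels: pd.Series,
    drop_labels: set[str] | None = None,
    log_transform_expression: bool = False,
) -> FeatureMatrix:
    """Merge expression and mutation counts into one labeled feature matrix.

    Keeps exactly the samples present in both modalities and carrying a
    retained label. Classes in ``drop_labels`` (e.g. a dominant metastatic
    type) are removed before intersection. Expression enters as provided
    (TPM) unless ``log_transform_expression`` applies log2(TPM+1); mutation
    features are raw integer counts.
    """
    drop_labels = set(drop_labels or ())
    kept_labels = labels[~labels.isin(drop_labels)]
    shared = sorted(
        set(expr.sample_ids) & set(mut.sample_ids) & set(kept_labels.index)
    )
    if not shared:
        raise EmptyInputError(
            "no samples shared between expression, mutation and label tables"
        )
    ex = expr.values.loc[shared]
    if log_transform_expression:
        ex = np.log2(ex + 1.0)
    mu = mut.counts.loc[shared]
    X = pd.concat(
        [ex.add_prefix("expr:"), mu.add_prefix("mut:").astype(float)], axis=1
    )
    y = kept_labels.loc[shared].astype(str)
    provenance = {
        "n_expression_samples": len(expr.sample_ids),
        "n_mutation_samples": len(mut.sample_ids),
        "n_labeled_samples": int(labels.size),
        "n_label_dropped": int(labels.isin(drop_labels).sum()),
        "n_merged_samples": len(shared),
        "n_features": X.shape[1],
        "n_expression_duplicate_samples_dropped": expr.n_duplicate_samples_dropped,
        "n_mutation_duplicates_removed": mut.n_duplicates_removed,
        "n_mutation_unmapped_dropped": mut.n_unmapped_dropped,
        "n_mutation_ambiguous_dropped": mut.n_ambiguous_dropped,
    }
    return FeatureMatrix(X=X, y=y, provenance=provenance)
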