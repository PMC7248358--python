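import numpy as np
import pandas as pd
import pytest

from toome import io, synthetic


@pytest.fixture
def small_cohort():
    """Deterministic 5-class cohort exercising both modalities."""
    spec = synthetic.CohortSpec.default(
        total_samples=150, n_classes=5,
        n_expr_genes=60, n_mut_genes=40,
        n_informative_expr=10, n_informative_mut=5,
        seed=42,
    )
    return synthetic.generate(spec)


@pytest.fixture
def small_matrix(small_cohort):
    expr, records, labels, id_map, _ = small_cohort
    mut = io.count_mutations(records, id_map)
    return io.merge_modalities(expr, mut, labels)


@pytest.fixture
def tiny_tables(tmp_path):
    """Hand-written TSV fixtures for the IO layer."""
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "sample_id\tG1\tG2\tG3\tG4\n"
        "S1\t1.0\t0.0\t5.5\t2\n"
        "S2\t0.5\t3.0\t1.0\t0\n"
        "S3\t2.0\t2.0\t2.0\t2.0\n"
    )
    muts = tmp_path / "mut.tsv"
    muts.write_text(
        "donor_id\tchromosome\tlocus\tgene_affected\n"
        "S1\tchr1\t100\tENSG_A\n"
        "S1\t1\t100\tENSG_A\n"       # duplicate of the previous record
        "S1\tchr1\t200\tENSG_A\n"
        "S2\tchr2\t50\tENSG_B\n"
        "S2\tchr3\t70\tENSG_MISSING\n"
        "S4\tchr1\t100\tENSG_A\n"
    )
    labels = tmp_path / "labels.tsv"
    labels.write_text(
        "sample_id\tcancer_type\nS1\tBRCA\nS2\tCOAD\nS3\tSKCM\nS4\tBRCA\n"
    )
    id_map = tmp_path / "map.tsv"
    id_map.write_text(
        "ensembl_gene_id\tgene_symbol\nENSG_A\tA\nENSG_B\tB\n"
        "ENSG_AMB\tX\nENSG_AMB\tY\n"
    )
    return {"expr": expr, "mut": muts, "labels": labels, "map": id_map, "dir": tmp_path}
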