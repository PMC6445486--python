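"""Reading and writing the plain-text tables the pipeline exchanges.

All tables are tab-separated. Count matrices are features x samples with the
feature id in the first column and sample ids in the header row. The sample
design table has columns (sample_id, genotype, stage, replicate); the miRNA
target map has columns (mirna_id, target_gene_id, evidence).
"""

from __future__ import annotations

import pandas as pd

GENOTYPES = ("WT", "dKO")
STAGES = ("ESC", "RA")

#: significant digits used when writing real-valued tables; fixed so that
#: repeated runs of the same computation are byte-identical on disk.
FLOAT_FORMAT = "%.10g"


def read_counts(path) -> pd.DataFrame:
    """Read a features x samples integer count matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_counts(df)
    return df.astype("int64")


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate feature ids in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix")
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("count matrix contains negative entries")
    if values.dtype.kind not in "iu" and not (values == values.round()).all():
        raise ValueError("count matrix contains non-integer entries")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_design(path) -> pd.DataFrame:
    """Read the sample design table (sample_id, genotype, stage, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate": "int64"})
    required = {"sample_id", "genotype", "stage", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    validate_design(df)
    return df


def validate_design(design: pd.DataFrame) -> None:
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design table")
    bad_geno = set(design["genotype"]) - set(GENOTYPES)
    if bad_geno:
        raise ValueError(f"unknown genotypes {sorted(bad_geno)}; expected {GENOTYPES}")
    bad_stage = set(design["stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stages {sorted(bad_stage)}; expected {STAGES}")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_target_map(path) -> pd.DataFrame:
    """Read a miRNA -> target gene edge list (miRTarBase-like TSV).

    Expects at least two columns (mirna_id, target_gene_id); a third
    ``evidence`` column is kept if present, else filled with ``"NA"``.
    Duplicate edges are dropped with the first occurrence kept.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("target map needs at least (mirna_id, target_gene_id) columns")
    df = df.rename(
        columns=dict(zip(df.columns[:3], ["mirna_id", "target_gene_id", "evidence"]))
    )
    if "evidence" not in df.columns:
        df["evidence"] = "NA"
    df = df[["mirna_id", "target_gene_id", "evidence"]]
    df = df.drop_duplicates(subset=["mirna_id", "target_gene_id"], keep="first")
    return df.reset_index(drop=True)


def write_target_map(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, index: bool = False, index_label=None) -> None:
    """Write a real-valued result table with a fixed float format."""
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
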