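"""Tab-separated text I/O for expression matrices and phenotype tables.

Dialect: UTF-8 TSV, ``.`` decimal separator, no thousands separators,
missing values as empty fields. The expression file has analyte ids in
the first column and a header row of sample ids (a GEO series-matrix
table after metadata stripping has this shape); the phenotype file has
columns ``sample_id``, ``status`` (case/control) and any number of
covariate columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import CASE, CONTROL, LabeledMatrix
from .errors import MatrixFormatError

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "read_labeled_matrix",
    "write_labeled_matrix",
    "write_json",
]


def read_expression(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MatrixFormatError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: no sample columns found")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as e:
        raise MatrixFormatError(f"{path}: non-numeric expression value "
                                f"({e})") from e
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="analyte_id", na_rep="")


def read_phenotype(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MatrixFormatError(f"phenotype file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise MatrixFormatError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise MatrixFormatError(f"{path}: duplicate sample ids")
    bad = set(df["status"].unique()) - {CASE, CONTROL}
    if bad:
        raise MatrixFormatError(
            f"{path}: status must be '{CASE}'/'{CONTROL}', found {sorted(bad)}")
    return df.set_index("sample_id")


def write_phenotype(matrix: LabeledMatrix, path) -> None:
    df = pd.DataFrame({"status": matrix.labels})
    if matrix.covariates is not None:
        df = df.join(matrix.covariates)
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def read_labeled_matrix(expr_path, pheno_path) -> LabeledMatrix:
    """Assemble a LabeledMatrix from the two TSV files.

    Samples must agree between the files; a mismatch is an error naming
    the offending ids rather than a silent intersection.
    """
    values = read_expression(expr_path)
    pheno = read_phenotype(pheno_path)
    only_expr = values.columns.difference(pheno.index)
    only_pheno = pheno.index.difference(values.columns)
    if len(only_expr) or len(only_pheno):
        raise MatrixFormatError(
            f"sample mismatch between {expr_path} and {pheno_path}: "
            f"{list(only_expr[:5])} only in expression, "
            f"{list(only_pheno[:5])} only in phenotype")
    pheno = pheno.loc[values.columns]
    covariates = pheno.drop(columns=["status"])
    return LabeledMatrix(
        values=values,
        labels=pheno["status"],
        covariates=covariates if covariates.shape[1] else None,
    )


def write_labeled_matrix(matrix: LabeledMatrix, expr_path,
                         pheno_path) -> None:
    write_expression(matrix.values, expr_path)
    write_phenotype(matrix, pheno_path)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
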