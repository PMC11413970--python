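"""In-memory container for a labelled expression matrix."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import MatrixFormatError

__all__ = ["LabeledMatrix", "CASE", "CONTROL"]

CASE = "case"
CONTROL = "control"


@dataclass
class LabeledMatrix:
    """Analytes x samples matrix with per-sample case/control labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique analyte id, columns by sample id. Missing
        measurements are NaN.
    labels : pandas.Series
        Indexed by sample id, values ``"case"`` or ``"control"``; every
        sample column must be labelled.
    covariates : pandas.DataFrame, optional
        Per-sample categorical covariates (e.g. brain region), indexed by
        sample id.
    symbols : pandas.Series, optional
        Analyte id -> gene symbol, for reporting only.
    """

    values: pd.DataFrame
    labels: pd.Series
    covariates: Optional[pd.DataFrame] = None
    symbols: Optional[pd.Series] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()][:5]
            raise MatrixFormatError(f"duplicate analyte ids: {list(dupes)}")
        missing = self.values.columns.difference(self.labels.index)
        if len(missing) > 0:
            raise MatrixFormatError(
                f"{len(missing)} samples lack a case/control label, "
                f"e.g. {list(missing[:5])}"
            )
        self.labels = self.labels.loc[self.values.columns]
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise MatrixFormatError(
                f"labels must be '{CASE}' or '{CONTROL}', found {sorted(bad)}"
            )
        if self.covariates is not None:
            missing = self.values.columns.difference(self.covariates.index)
            if len(missing) > 0:
                raise MatrixFormatError(
                    f"{len(missing)} samples absent from covariate table"
                )
            self.covariates = self.covariates.loc[self.values.columns]

    # -- convenience accessors -------------------------------------------

    @property
    def analyte_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def case_ids(self) -> pd.Index:
        return self.labels.index[self.labels == CASE]

    @property
    def control_ids(self) -> pd.Index:
        return self.labels.index[self.labels == CONTROL]

    @property
    def n_cases(self) -> int:
        return int((self.labels == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == CONTROL).sum())

    def analyte_values(self, analyte_id: str) -> pd.Series:
        return self.values.loc[analyte_id]

    def group_arrays(self, analyte_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Finite case and control values for one analyte (NaN dropped)."""
        row = self.values.loc[analyte_id]
        cases = row[self.case_ids].to_numpy(dtype=float)
        controls = row[self.control_ids].to_numpy(dtype=float)
        return cases[np.isfinite(cases)], controls[np.isfinite(controls)]

    def subset_samples(self, sample_ids) -> "LabeledMatrix":
        ids = pd.Index(sample_ids)
        return LabeledMatrix(
            values=self.values[ids],
            labels=self.labels.loc[ids],
            covariates=None if self.covariates is None
            else self.covariates.loc[ids],
            symbols=self.symbols,
        )

    def subset_analytes(self, analyte_ids) -> "LabeledMatrix":
        ids = pd.Index(analyte_ids)
        return LabeledMatrix(
            values=self.values.loc[ids],
            labels=self.labels,
            covariates=self.covariates,
            symbols=self.symbols,
        )
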