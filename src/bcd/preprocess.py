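"""Winsorization at 3 x IQR fences, min/max normalization, sample filtering.

Outliers disproportionately inflate kurtosis and hence distort the
bimodality coefficient; rather than deleting them, values beyond
Q1 - 3*IQR or Q3 + 3*IQR are clamped to the fence. The identities of
clamped samples are retained because the set of fence hits *is* the
candidate second mode, and its covariate composition is the main
diagnostic for confounded signals (see :mod:`bcd.screen`).

By default the fences for a case/control analyte are computed on the
pooled values of both groups and the clamp applied to each group; this
"pooled" scope keeps the two groups on a common scale and is what the
group-difference statistic is calibrated against. A per-group scope is
available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .containers import LabeledMatrix
from .errors import (
    ConstantInputError,
    EmptySelectionError,
    TooFewValuesError,
    UnknownCovariateError,
)

__all__ = [
    "Fences",
    "WinsorizedVector",
    "compute_fences",
    "winsorize",
    "minmax_normalize",
    "filter_samples",
]

logger = logging.getLogger(__name__)

Scope = Literal["pooled", "per-group"]
QuantileMethod = str  # any numpy quantile method name; "linear" default


@dataclass(frozen=True)
class Fences:
    """Quartiles and the +/- 3*IQR clamping fences derived from them."""

    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    scope: Scope = "pooled"


@dataclass(frozen=True)
class WinsorizedVector:
    """A clamped vector plus the count and identity of clamped samples."""

    values: np.ndarray
    n_clamped_low: int
    n_clamped_high: int
    clamped_low_ids: tuple
    clamped_high_ids: tuple


def compute_fences(values, scope: Scope = "pooled",
                   method: QuantileMethod = "linear") -> Fences:
    """Quartiles (linear interpolation of order statistics by default)
    and fences at 3 IQR beyond them.

    ``method`` is forwarded to :func:`numpy.quantile`; at the 3*IQR
    distance the fence position is insensitive to the quantile dialect
    for all but tiny samples, but the knob is exposed for exactness
    comparisons against other software.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise TooFewValuesError(f"fences need n >= 4 values, got {x.size}")
    q1, q3 = np.quantile(x, [0.25, 0.75], method=method)
    iqr = q3 - q1
    return Fences(q1=float(q1), q3=float(q3), iqr=float(iqr),
                  lower=float(q1 - 3.0 * iqr), upper=float(q3 + 3.0 * iqr),
                  scope=scope)


def winsorize(values, fences: Fences,
              sample_ids: Optional[Sequence] = None) -> WinsorizedVector:
    """Clamp values to [fences.lower, fences.upper].

    NaNs pass through unchanged. ``sample_ids`` (parallel to ``values``)
    are recorded for clamped entries; positional indices are used when
    ids are not supplied. Idempotent for fixed fences.
    """
    x = np.asarray(values, dtype=float).ravel()
    low_mask = x < fences.lower
    high_mask = x > fences.upper
    out = np.clip(x, fences.lower, fences.upper)
    ids = np.asarray(sample_ids) if sample_ids is not None \
        else np.arange(x.size)
    if sample_ids is not None and ids.size != x.size:
        raise ValueError("sample_ids must parallel values")
    return WinsorizedVector(
        values=out,
        n_clamped_low=int(low_mask.sum()),
        n_clamped_high=int(high_mask.sum()),
        clamped_low_ids=tuple(ids[low_mask]),
        clamped_high_ids=tuple(ids[high_mask]),
    )


def minmax_normalize(values) -> np.ndarray:
    """Scale and shift to span exactly [0, 1]: (x - min) / (max - min).

    Needed before fold-change computation because simulated or
    background-corrected expression values can be negative.
    """
    x = np.asarray(values, dtype=float).ravel()
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        raise TooFewValuesError("cannot normalize an empty array")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise ConstantInputError("min/max normalization undefined for a "
                                 "constant array")
    return (x - lo) / (hi - lo)


def filter_samples(matrix: LabeledMatrix, covariate: str,
                   excluded_levels) -> LabeledMatrix:
    """Drop samples whose covariate takes an excluded level.

    Used to remove confounded strata identified by fence diagnostics
    (e.g. brain regions sampled with a strong case/control imbalance).
    Resulting group sizes are logged.
    """
    excluded = set(excluded_levels)
    if not excluded:
        return matrix
    if matrix.covariates is None or covariate not in matrix.covariates:
        available = [] if matrix.covariates is None \
            else list(matrix.covariates.columns)
        raise UnknownCovariateError(
            f"covariate {covariate!r} not found (available: {available})"
        )
    keep = ~matrix.covariates[covariate].isin(excluded)
    kept_ids = matrix.sample_ids[keep.to_numpy()]
    if len(kept_ids) == 0:
        raise EmptySelectionError(
            f"excluding {sorted(excluded, key=str)} from {covariate!r} "
            "removes every sample"
        )
    out = matrix.subset_samples(kept_ids)
    logger.info(
        "filter_samples: %s not in %s -> %d cases, %d controls "
        "(removed %d samples)",
        covariate, sorted(excluded, key=str), out.n_cases, out.n_controls,
        len(matrix.sample_ids) - len(kept_ids),
    )
    return out
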