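"""Comparator statistics: absolute log2 fold change and ROC AUC.

These are the two conventional case/control screening statistics the
bimodality-difference metric is benchmarked against. Both summarise a
shift of the whole case group and are therefore expected to under-call
biomarkers expressed by only a subset of cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import rankdata

from .errors import EmptyGroupError, UndefinedFoldChangeError

__all__ = ["FoldChangeResult", "AUCResult", "log2_fold_change", "auc"]

Center = Literal["median", "mean"]


@dataclass(frozen=True)
class FoldChangeResult:
    """Absolute log2 fold change plus the group centers that produced it."""

    log2fc: float
    direction: Literal["up", "down"]
    center_cases: float
    center_controls: float


@dataclass(frozen=True)
class AUCResult:
    """Rank AUC in both orientations.

    ``auc_raw`` scores cases-above-controls towards 1; ``auc`` is the
    folded, orientation-free value max(auc_raw, 1 - auc_raw), which is
    what an in-sample fitted classifier reports (it adapts its sign to
    the data, so even a null comparison sits slightly above 0.5).
    """

    auc_raw: float
    auc: float
    n_cases: int
    n_controls: int


def log2_fold_change(case_values, control_values,
                     center: Center = "median") -> FoldChangeResult:
    """|log2(center(cases) / center(controls))|.

    Callers are expected to pass min/max-normalized values (see
    :func:`bcd.preprocess.minmax_normalize`): raw intensities can be
    negative after background correction and the ratio is then
    meaningless. The default central tendency is the median; the mean is
    available via ``center="mean"``.

    Raises
    ------
    EmptyGroupError
        If either group is empty.
    UndefinedFoldChangeError
        If either center is not strictly positive.
    """
    cases = np.asarray(case_values, dtype=float).ravel()
    controls = np.asarray(control_values, dtype=float).ravel()
    if cases.size == 0 or controls.size == 0:
        raise EmptyGroupError("fold change needs non-empty groups")
    if center == "median":
        cc, cn = float(np.median(cases)), float(np.median(controls))
    elif center == "mean":
        cc, cn = float(np.mean(cases)), float(np.mean(controls))
    else:  # pragma: no cover - guarded by type hints in normal use
        raise ValueError(f"unknown center {center!r}")
    if cc <= 0.0 or cn <= 0.0:
        raise UndefinedFoldChangeError(
            f"non-positive group center (cases={cc:g}, controls={cn:g}); "
            "fold change is undefined near or below zero"
        )
    return FoldChangeResult(
        log2fc=abs(math.log2(cc / cn)),
        direction="up" if cc > cn else "down",
        center_cases=cc,
        center_controls=cn,
    )


def _rank_auc_raw(cases: np.ndarray, controls: np.ndarray) -> float:
    # Mann-Whitney U via midranks; ties contribute 1/2 a pair each.
    n1, n2 = cases.size, controls.size
    ranks = rankdata(np.concatenate([cases, controls]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def _logistic_auc_raw(cases: np.ndarray, controls: np.ndarray) -> float:
    # Fit a single-covariate logistic model and take the ROC area of its
    # predicted probabilities. The fit is monotone in the covariate, so
    # this equals the rank AUC up to orientation; kept for parity checks.
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    x = np.concatenate([cases, controls]).reshape(-1, 1)
    y = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    # default ridge penalty is harmless: predictions stay monotone in x,
    # and the ROC area depends only on their ordering
    model = LogisticRegression(solver="lbfgs", max_iter=1000)
    model.fit(x, y)
    return float(roc_auc_score(y, model.predict_proba(x)[:, 1]))


def auc(case_values, control_values,
        method: Literal["rank", "logistic"] = "rank") -> AUCResult:
    """Area under the ROC curve for one analyte.

    ``auc_raw`` equals the probability that a random case outranks a
    random control (pair counting with half-credit for ties), computed by
    rank sums. ``auc`` folds it to [0.5, 1]. ``method="logistic"`` routes
    through an in-sample logistic fit instead (requires scikit-learn);
    its folded value agrees with the rank AUC except in rare
    sign-disagreement cases at the null.

    Raises
    ------
    EmptyGroupError
        If either group is empty.
    """
    cases = np.asarray(case_values, dtype=float).ravel()
    controls = np.asarray(control_values, dtype=float).ravel()
    if cases.size == 0 or controls.size == 0:
        raise EmptyGroupError("AUC needs non-empty case and control groups")
    if method == "rank":
        raw = _rank_auc_raw(cases, controls)
    elif method == "logistic":
        raw = _logistic_auc_raw(cases, controls)
    else:  # pragma: no cover
        raise ValueError(f"unknown AUC method {method!r}")
    return AUCResult(
        auc_raw=raw,
        auc=max(raw, 1.0 - raw),
        n_cases=cases.size,
        n_controls=controls.size,
    )
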