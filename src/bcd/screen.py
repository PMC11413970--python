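"""Matrix-wide case/control screening with BCD, log2FC and AUC.

The screening pipeline applies, per analyte: pooled 3*IQR winsorization
(clamp identities recorded), BCD on the winsorized groups, the folded
rank AUC, and the absolute log2 fold change of medians on
min/max-normalized values. Significance is assessed empirically by
permuting the case/control labels and pooling the null statistics across
analytes; no multiple-testing correction is applied, so the p-values are
per-analyte screening quantities, not family-wise claims — downstream
results require validation in independent data.

Fence diagnostics cross-tabulate the samples clamped at the upper fence
(the putative second mode) against a covariate: when the second mode is
dominated by one covariate level that is rare in the background (e.g. a
brain region sampled almost only in cases), the signal reflects the
confound, not disease biology, and the stratum should be removed with
:func:`bcd.preprocess.filter_samples` before re-screening.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .bimodality import compute_bcd
from .containers import CASE, CONTROL, LabeledMatrix
from .errors import BCDError, EmptySelectionError
from .preprocess import compute_fences, minmax_normalize, winsorize
from .reference_metrics import auc, log2_fold_change

__all__ = [
    "ScreenConfig",
    "ClampRecord",
    "AnalyteScores",
    "FenceReport",
    "score_all",
    "empirical_pvalues",
    "top_fraction",
    "overlap_report",
    "fence_diagnostics",
    "histogram_counts",
]

logger = logging.getLogger(__name__)

METRICS = ("bcd", "log2fc", "auc")


@dataclass(frozen=True)
class ScreenConfig:
    """Knobs of the screening pipeline (defaults match the benchmark)."""

    winsorize_scope: str = "pooled"
    quantile_method: str = "linear"
    fc_center: str = "median"
    min_group_n: int = 4


@dataclass(frozen=True)
class ClampRecord:
    """Winsorization fence hits for one analyte, by group and fence."""

    lower: float
    upper: float
    case_low: tuple
    case_high: tuple
    control_low: tuple
    control_high: tuple

    @property
    def n_clamped_high(self) -> int:
        return len(self.case_high) + len(self.control_high)


@dataclass
class AnalyteScores:
    """Per-analyte metric table plus bookkeeping from the screen.

    ``table`` columns: bc_cases, bc_controls, bcd, log2fc, auc, auc_raw,
    rank_<metric> (1 = largest; ties broken by analyte id), and after
    :func:`empirical_pvalues` also p_bcd, p_fc, p_auc. ``skipped`` maps
    analyte id -> reason for analytes that could not be scored.
    ``cutoffs`` holds the permutation-null 95th-percentile value of each
    metric once p-values have been attached.
    """

    table: pd.DataFrame
    skipped: dict = field(default_factory=dict)
    clamps: dict = field(default_factory=dict)
    cutoffs: dict = field(default_factory=dict)
    n_permutations: Optional[int] = None
    permutation_seed: Optional[int] = None


@dataclass(frozen=True)
class FenceReport:
    """Covariate composition of the upper-fence clamp set of one analyte.

    ``crosstab`` has one row per (group, level) with the count and the
    proportion of that group's clamped samples at the level, next to the
    level's background proportion among all of that group's samples;
    ``enriched`` flags levels whose clamped proportion is at least
    ``enrichment_ratio`` times background.
    """

    analyte_id: str
    covariate: str
    n_clamped_cases: int
    n_clamped_controls: int
    clamped_case_ids: tuple
    clamped_control_ids: tuple
    crosstab: pd.DataFrame
    enrichment_ratio: float

    @property
    def enriched_levels(self) -> dict:
        if self.crosstab.empty:
            return {}
        hits = self.crosstab[self.crosstab["enriched"]]
        return {g: list(sub["level"]) for g, sub in hits.groupby("group")}


def _score_one(cases: np.ndarray, controls: np.ndarray,
               case_ids, control_ids, config: ScreenConfig):
    """Winsorize and score one analyte; returns (scores dict, ClampRecord)."""
    if config.winsorize_scope == "pooled":
        fences = compute_fences(np.concatenate([cases, controls]),
                                scope="pooled",
                                method=config.quantile_method)
        wc = winsorize(cases, fences, sample_ids=case_ids)
        wn = winsorize(controls, fences, sample_ids=control_ids)
        case_vals, control_vals = wc.values, wn.values
        clamp = ClampRecord(
            lower=fences.lower, upper=fences.upper,
            case_low=wc.clamped_low_ids, case_high=wc.clamped_high_ids,
            control_low=wn.clamped_low_ids,
            control_high=wn.clamped_high_ids,
        )
    elif config.winsorize_scope == "per-group":
        fc_ = compute_fences(cases, scope="per-group",
                             method=config.quantile_method)
        fn_ = compute_fences(controls, scope="per-group",
                             method=config.quantile_method)
        wc = winsorize(cases, fc_, sample_ids=case_ids)
        wn = winsorize(controls, fn_, sample_ids=control_ids)
        case_vals, control_vals = wc.values, wn.values
        clamp = ClampRecord(
            lower=min(fc_.lower, fn_.lower),
            upper=max(fc_.upper, fn_.upper),
            case_low=wc.clamped_low_ids, case_high=wc.clamped_high_ids,
            control_low=wn.clamped_low_ids,
            control_high=wn.clamped_high_ids,
        )
    elif config.winsorize_scope == "off":
        case_vals, control_vals = cases, controls
        clamp = ClampRecord(lower=-math.inf, upper=math.inf,
                            case_low=(), case_high=(),
                            control_low=(), control_high=())
    else:  # pragma: no cover
        raise ValueError(f"unknown scope {config.winsorize_scope!r}")

    bcd_res = compute_bcd(case_vals, control_vals)
    auc_res = auc(case_vals, control_vals)
    pooled = minmax_normalize(np.concatenate([case_vals, control_vals]))
    fc_res = log2_fold_change(pooled[:case_vals.size],
                              pooled[case_vals.size:],
                              center=config.fc_center)
    scores = {
        "bc_cases": bcd_res.bc_cases.bc,
        "bc_controls": bcd_res.bc_controls.bc,
        "bcd": bcd_res.bcd,
        "log2fc": fc_res.log2fc,
        "auc": auc_res.auc,
        "auc_raw": auc_res.auc_raw,
    }
    return scores, clamp


def _metric_rank(series: pd.Series) -> pd.Series:
    # Rank 1 = largest metric value; deterministic id tie-break.
    order = series.reset_index()
    order.columns = ["analyte_id", "value"]
    order = order.sort_values(["value", "analyte_id"],
                              ascending=[False, True], kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1),
                      index=order["analyte_id"])
    return ranks.loc[series.index]


def score_all(matrix: LabeledMatrix,
              config: ScreenConfig = ScreenConfig()) -> AnalyteScores:
    """Score every analyte of a labelled matrix with all three metrics.

    Analytes with fewer than ``config.min_group_n`` finite values in
    either group, or that are constant after winsorization, are skipped
    and logged with a reason. Deterministic given the matrix; analyte
    row order does not affect any score.
    """
    case_ids = matrix.case_ids
    control_ids = matrix.control_ids
    case_mat = matrix.values[case_ids].to_numpy(dtype=float)
    control_mat = matrix.values[control_ids].to_numpy(dtype=float)

    rows, skipped, clamps = {}, {}, {}
    for i, analyte in enumerate(matrix.analyte_ids):
        cases = case_mat[i]
        controls = control_mat[i]
        c_fin, n_fin = np.isfinite(cases), np.isfinite(controls)
        n_dropped = int((~c_fin).sum() + (~n_fin).sum())
        if n_dropped:
            logger.debug("analyte %s: dropped %d missing values",
                         analyte, n_dropped)
        if c_fin.sum() < config.min_group_n:
            skipped[analyte] = "too few case values"
            continue
        if n_fin.sum() < config.min_group_n:
            skipped[analyte] = "too few control values"
            continue
        try:
            scores, clamp = _score_one(
                cases[c_fin], controls[n_fin],
                case_ids[c_fin], control_ids[n_fin], config)
        except BCDError as e:
            skipped[analyte] = str(e)
            continue
        rows[analyte] = scores
        clamps[analyte] = clamp

    if not rows:
        raise EmptySelectionError("no analyte could be scored")
    for analyte, reason in skipped.items():
        logger.info("analyte %s skipped: %s", analyte, reason)

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "analyte_id"
    table = table.loc[[a for a in matrix.analyte_ids if a in rows]]
    for metric in METRICS:
        table[f"rank_{metric}"] = _metric_rank(table[metric])
    return AnalyteScores(table=table, skipped=skipped, clamps=clamps)


def empirical_pvalues(matrix: LabeledMatrix, scores: AnalyteScores,
                      n_permutations: int = 199, seed: int = 0,
                      config: ScreenConfig = ScreenConfig(),
                      ) -> AnalyteScores:
    """Attach permutation p-values (and null cutoffs) to a score table.

    Case/control labels are permuted ``n_permutations`` times; for each
    permutation every analyte is re-scored and the null statistics are
    pooled across analytes and permutations (assuming exchangeability of
    analytes under the label-permutation null). For each observed value
    the p-value is (b + 1) / (B_total + 1) with b the number of pooled
    null values at least as large. The 95th percentile of each pooled
    null is stored in ``cutoffs`` as the alpha = 0.05 reference value.
    """
    if n_permutations < 19:
        raise BCDError("need at least 19 permutations for alpha = 0.05")
    labels = matrix.labels.to_numpy()
    if len(set(labels)) < 2:
        raise EmptySelectionError("permutation null needs both labels")
    rng = np.random.default_rng(seed)
    sub = matrix.subset_analytes(scores.table.index)
    values = sub.values.to_numpy(dtype=float)
    sample_ids = sub.sample_ids

    null_values: dict[str, list] = {m: [] for m in METRICS}
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        case_cols = perm == CASE
        for i in range(values.shape[0]):
            row = values[i]
            cases = row[case_cols]
            controls = row[~case_cols]
            c_fin, n_fin = np.isfinite(cases), np.isfinite(controls)
            if c_fin.sum() < config.min_group_n or \
                    n_fin.sum() < config.min_group_n:
                continue
            try:
                s, _ = _score_one(cases[c_fin], controls[n_fin],
                                  sample_ids[case_cols][c_fin],
                                  sample_ids[~case_cols][n_fin], config)
            except BCDError:
                continue
            for m in METRICS:
                null_values[m].append(s[m])

    table = scores.table.copy()
    cutoffs = {}
    p_col = {"bcd": "p_bcd", "log2fc": "p_fc", "auc": "p_auc"}
    for m in METRICS:
        null = np.sort(np.asarray(null_values[m]))
        if null.size == 0:
            raise BCDError("permutation null is empty")
        obs = table[m].to_numpy()
        # b = number of null values >= observed, via sorted search
        b = null.size - np.searchsorted(null, obs, side="left")
        table[p_col[m]] = (b + 1) / (null.size + 1)
        cutoffs[m] = float(np.quantile(null, 0.95))
    return AnalyteScores(table=table, skipped=scores.skipped,
                         clamps=scores.clamps, cutoffs=cutoffs,
                         n_permutations=n_permutations,
                         permutation_seed=seed)


def top_fraction(scores: AnalyteScores, metric: str = "bcd",
                 fraction: float = 0.05) -> set:
    """Ids of the ceil(fraction * n) analytes with the largest metric.

    Ties at the boundary are broken by analyte id (ascending), so the
    selection is deterministic and matches the rank columns.
    """
    if metric not in METRICS:
        raise BCDError(f"metric must be one of {METRICS}, got {metric!r}")
    if not 0.0 < fraction <= 1.0:
        raise BCDError("fraction must be in (0, 1]")
    n_top = math.ceil(fraction * len(scores.table))
    ranks = scores.table[f"rank_{metric}"]
    return set(ranks.index[ranks <= n_top])


def overlap_report(sets: Mapping[str, set]) -> dict:
    """Pairwise and triple overlap percentages of top-fraction id sets.

    For each ordered pair (A, B) the percentage |A & B| / |A| * 100 is
    reported (the denominator is the first set, so both directions are
    present when sizes differ). The full intersection across all sets is
    reported with its percentage of each set's size.
    """
    if not sets:
        raise BCDError("no sets to compare")
    for name, ids in sets.items():
        if not ids:
            raise BCDError(f"set {name!r} is empty")
    names = list(sets)
    pairwise = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            inter = len(sets[a] & sets[b])
            pairwise[f"{a}&{b}"] = {
                "intersection": inter,
                "pct_of_first": 100.0 * inter / len(sets[a]),
            }
    common = set.intersection(*(set(s) for s in sets.values()))
    report = {
        "set_sizes": {n: len(sets[n]) for n in names},
        "pairwise": pairwise,
        "all": {
            "intersection": len(common),
            "pct_of_each": {n: 100.0 * len(common) / len(sets[n])
                            for n in names},
        },
    }
    return report


def fence_diagnostics(matrix: LabeledMatrix, scores: AnalyteScores,
                      analyte_id: str, covariate: str,
                      enrichment_ratio: float = 2.0) -> FenceReport:
    """Cross-tabulate an analyte's upper-fence clamp set by a covariate.

    An empty clamp set yields an empty (not erroneous) report. Missing
    covariate values form their own ``"(missing)"`` level.
    """
    if analyte_id not in scores.clamps:
        raise BCDError(f"no winsorization record for analyte {analyte_id!r}")
    if matrix.covariates is None or covariate not in matrix.covariates:
        raise BCDError(f"covariate {covariate!r} not available")
    clamp = scores.clamps[analyte_id]
    cov = matrix.covariates[covariate].astype(object).where(
        matrix.covariates[covariate].notna(), "(missing)")

    rows = []
    for group, clamped_ids, all_ids in (
            (CASE, clamp.case_high, matrix.case_ids),
            (CONTROL, clamp.control_high, matrix.control_ids)):
        if len(clamped_ids) == 0:
            continue
        background = cov.loc[all_ids].value_counts(normalize=True)
        counts = cov.loc[list(clamped_ids)].value_counts()
        total = counts.sum()
        for level, count in counts.items():
            prop = count / total
            bg = float(background.get(level, 0.0))
            rows.append({
                "group": group,
                "level": level,
                "count": int(count),
                "proportion": float(prop),
                "background_proportion": bg,
                "enriched": bool(bg > 0 and prop >= enrichment_ratio * bg),
            })
    crosstab = pd.DataFrame(
        rows, columns=["group", "level", "count", "proportion",
                       "background_proportion", "enriched"])
    return FenceReport(
        analyte_id=analyte_id,
        covariate=covariate,
        n_clamped_cases=len(clamp.case_high),
        n_clamped_controls=len(clamp.control_high),
        clamped_case_ids=clamp.case_high,
        clamped_control_ids=clamp.control_high,
        crosstab=crosstab,
        enrichment_ratio=enrichment_ratio,
    )


def histogram_counts(matrix: LabeledMatrix, analyte_id: str,
                     n_bins: int = 30) -> pd.DataFrame:
    """Shared-bin case/control counts for one analyte (for external
    plotting; no figures are rendered here)."""
    cases, controls = matrix.group_arrays(analyte_id)
    pooled = np.concatenate([cases, controls])
    if pooled.size == 0:
        raise EmptySelectionError(f"analyte {analyte_id!r} has no values")
    edges = np.histogram_bin_edges(pooled, bins=n_bins)
    case_counts, _ = np.histogram(cases, bins=edges)
    control_counts, _ = np.histogram(controls, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "cases": case_counts,
        "controls": control_counts,
    })
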