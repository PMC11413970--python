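"""Synthetic expression fixtures shaped like a cortex case/control study.

The generator emits a genes x samples matrix with per-sample phenotype
(case/control plus a categorical brain-region covariate) mimicking, at a
configurable scale, a public cortex expression study of 8,650 genes for
176 cases and 187 controls. Three kinds of analytes can be planted:

* null analytes — every sample draws from the background distribution
  N(0.03, 0.04) used throughout the simulation benchmark;
* subtype analytes — a designated fraction of the cases draws from the
  shifted subtype distribution N(0.40, 0.16), giving the case group a
  second mode the controls lack;
* confounded analytes — samples from one covariate level (default brain
  region 4, sampled with a strong case/control imbalance) draw from a
  far-outlier distribution, reproducing the spurious-second-mode
  artifact that fence diagnostics are designed to catch.

Region proportions default to a realistic imbalance: region 4 holds
12.5% of cases but only 4.8% of controls, and region 2 is likewise
unbalanced, so excluding regions {2, 4} is the expected cleanup move.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, LabeledMatrix

__all__ = [
    "PlantedSubtype",
    "PlantedConfound",
    "CovariateSpec",
    "generate_fixture",
]

# Background / subtype distributions shared with the simulation benchmark.
BACKGROUND = (0.03, 0.04)
SUBTYPE = (0.40, 0.16)


@dataclass(frozen=True)
class PlantedSubtype:
    """A planted subtype analyte: ``fraction`` of cases from N(mu, sigma)."""

    analyte_index: int
    fraction: float = 0.3
    mu: float = SUBTYPE[0]
    sigma: float = SUBTYPE[1]


@dataclass(frozen=True)
class PlantedConfound:
    """A planted covariate-confounded analyte.

    Samples (cases and controls alike) at ``level`` of ``covariate`` draw
    from a far-outlier distribution, so winsorization clamps them at the
    upper fence and the clamp set is dominated by that level.
    """

    analyte_index: int
    covariate: str = "region"
    level: object = 4
    mu: float = 1.2
    sigma: float = 0.05


@dataclass(frozen=True)
class CovariateSpec:
    """Categorical covariate with per-group level probabilities."""

    name: str = "region"
    levels: Sequence = (1, 2, 3, 4)
    case_probs: Sequence[float] = (0.60, 0.15, 0.125, 0.125)
    control_probs: Sequence[float] = (0.75, 0.052, 0.15, 0.048)

    def __post_init__(self) -> None:
        for p in (self.case_probs, self.control_probs):
            if len(p) != len(self.levels):
                raise ValueError("probabilities must match levels")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("probabilities must sum to 1")


def generate_fixture(n_analytes: int = 100,
                     n_cases: int = 176,
                     n_controls: int = 187,
                     planted: Sequence[PlantedSubtype] = (),
                     confounded: Sequence[PlantedConfound] = (),
                     covariate: Optional[CovariateSpec] = CovariateSpec(),
                     seed: int = 0) -> LabeledMatrix:
    """Generate a labelled synthetic expression matrix.

    All randomness flows from ``seed``. Analyte ids are ``A0000``,
    ``A0001``, ... and sample ids ``case_0000``/``ctrl_0000``, ...;
    planted analytes are addressed by row index.
    """
    for spec in planted:
        if not 0 <= spec.analyte_index < n_analytes:
            raise ValueError(f"planted index {spec.analyte_index} out of "
                             f"range for {n_analytes} analytes")
        if not 0.0 <= spec.fraction <= 1.0:
            raise ValueError("subtype fraction must be in [0, 1]")
    for spec in confounded:
        if not 0 <= spec.analyte_index < n_analytes:
            raise ValueError(f"confound index {spec.analyte_index} out of "
                             f"range for {n_analytes} analytes")
        if covariate is None or spec.covariate != covariate.name:
            raise ValueError(f"confound covariate {spec.covariate!r} not "
                             "generated by the covariate spec")
        if spec.level not in covariate.levels:
            raise ValueError(f"confound level {spec.level!r} not a "
                             "covariate level")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_analytes - 1)))
    analyte_ids = [f"A{i:0{width}d}" for i in range(n_analytes)]
    sample_ids = ([f"case_{i:04d}" for i in range(n_cases)]
                  + [f"ctrl_{i:04d}" for i in range(n_controls)])
    labels = pd.Series([CASE] * n_cases + [CONTROL] * n_controls,
                       index=sample_ids)

    covariates = None
    if covariate is not None:
        levels = list(covariate.levels)
        assignments = np.concatenate([
            rng.choice(levels, size=n_cases, p=covariate.case_probs),
            rng.choice(levels, size=n_controls, p=covariate.control_probs),
        ])
        covariates = pd.DataFrame({covariate.name: assignments},
                                  index=sample_ids)

    mu1, sd1 = BACKGROUND
    values = rng.normal(mu1, sd1, size=(n_analytes, n_cases + n_controls))

    for spec in planted:
        n_sub = round(spec.fraction * n_cases)
        members = rng.choice(n_cases, size=n_sub, replace=False)
        values[spec.analyte_index, members] = rng.normal(
            spec.mu, spec.sigma, size=n_sub)

    for spec in confounded:
        mask = (covariates[spec.covariate] == spec.level).to_numpy()
        values[spec.analyte_index, mask] = rng.normal(
            spec.mu, spec.sigma, size=int(mask.sum()))

    return LabeledMatrix(
        values=pd.DataFrame(values, index=analyte_ids, columns=sample_ids),
        labels=labels,
        covariates=covariates,
    )
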