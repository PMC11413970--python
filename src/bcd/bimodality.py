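"""Sarle's bimodality coefficient (BC) and the case/control difference (BCD).

The bimodality coefficient of a sample of size ``n`` with skewness ``s``
and excess kurtosis ``k`` is

    BC = (s^2 + 1) / (k + 3 * (n-1)^2 / ((n-2)(n-3)))

BC lies strictly between 0 and 1 (a consequence of the Pearson inequality
``k >= s^2 - 2`` together with the size correction exceeding 1); the
asymptotic value for a uniform distribution is 5/9 and larger values
indicate stronger bimodality or skew.

BCD = |BC(cases) - BC(controls)| is the screening statistic: a biomarker
expressed by only a subset of the diseased cases leaves the controls
unimodal while pushing the case distribution towards bimodality, so the
two coefficients separate even when group means barely move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConstantInputError, GroupInputError, TooFewValuesError

__all__ = [
    "SampleMoments",
    "BCValue",
    "BCDValue",
    "compute_moments",
    "compute_bc",
    "compute_bcd",
    "bc_asymptotic",
    "size_correction",
]


@dataclass(frozen=True)
class SampleMoments:
    """Central sample moments (averaged over n) plus derived shape statistics.

    ``s`` and ``k`` follow the plain moment-estimator convention
    (g1 = m3 / m2^(3/2), g2 = m4 / m2^2 - 3); both are NaN when the
    sample is constant (m2 = 0).
    """

    n: int
    mean: float
    m2: float
    m3: float
    m4: float
    s: float
    k: float


@dataclass(frozen=True)
class BCValue:
    """A bimodality coefficient together with the inputs that fix its scale."""

    bc: float
    n: int
    correction: float


@dataclass(frozen=True)
class BCDValue:
    """Bimodality coefficient difference with both per-group components."""

    bcd: float
    bc_cases: BCValue
    bc_controls: BCValue


def compute_moments(values, bias_corrected: bool = False) -> SampleMoments:
    """Compute central moments m2..m4 and the shape statistics s, k.

    Moments are taken about the sample mean (values are centred first to
    avoid catastrophic cancellation: expression intensities can be large
    relative to their spread). With ``bias_corrected`` the adjusted
    Fisher-Pearson estimators G1, G2 are reported instead of g1, g2.

    Raises
    ------
    TooFewValuesError
        If fewer than two finite values are supplied.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise TooFewValuesError(
            f"moments need at least 2 finite values, got {x.size} "
            "(drop missing values before calling)"
        )
    n = x.size
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d * d))
    m3 = float(np.mean(d * d * d))
    m4 = float(np.mean(d * d * d * d))
    # m2 * m2 > 0 guards against underflow of the kurtosis denominator
    # for pathologically tiny spreads; such samples are effectively
    # constant and get the same undefined markers.
    if m2 > 0.0 and m2 * m2 > 0.0:
        s = m3 / m2**1.5
        k = m4 / (m2 * m2) - 3.0
        if bias_corrected:
            if n < 4:
                raise TooFewValuesError(
                    "bias-corrected skewness/kurtosis need n >= 4"
                )
            s = s * math.sqrt(n * (n - 1)) / (n - 2)
            k = ((n + 1) * k + 6.0) * (n - 1) / ((n - 2) * (n - 3))
    else:
        s = math.nan
        k = math.nan
    return SampleMoments(n=n, mean=mean, m2=m2, m3=m3, m4=m4, s=s, k=k)


def size_correction(n: int) -> float:
    """Finite-sample factor (n-1)^2 / ((n-2)(n-3)); > 1, -> 1 as n grows."""
    if n < 4:
        raise TooFewValuesError(f"size correction undefined for n={n} < 4")
    return (n - 1) ** 2 / ((n - 2) * (n - 3))


def bc_asymptotic(s: float, k: float) -> float:
    """BC in the large-n limit (size correction = 1): (s^2+1)/(k+3).

    Handy for closed-form reference points, e.g. the uniform distribution
    (s=0, k=-6/5) gives 5/9.
    """
    return (s * s + 1.0) / (k + 3.0)


def compute_bc(values, bias_corrected: bool = False) -> BCValue:
    """Sarle's bimodality coefficient of a sample.

    Requires n >= 4 (the size correction involves n-2 and n-3) and a
    non-constant sample.

    Raises
    ------
    TooFewValuesError
        If n < 4.
    ConstantInputError
        If all values are equal.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise TooFewValuesError(f"BC needs n >= 4, got n={x.size}")
    mom = compute_moments(x, bias_corrected=bias_corrected)
    if mom.m2 == 0.0:
        raise ConstantInputError("BC undefined for a constant sample")
    corr = size_correction(mom.n)
    bc = (mom.s * mom.s + 1.0) / (mom.k + 3.0 * corr)
    return BCValue(bc=bc, n=mom.n, correction=corr)


def compute_bcd(case_values, control_values,
                bias_corrected: bool = False) -> BCDValue:
    """Bimodality coefficient difference |BC(cases) - BC(controls)|.

    The absolute value is deliberate: controls can be the more bimodal
    group (e.g. analytes that cycle within healthy individuals), and the
    screen should flag distributional difference in either direction.

    Raises
    ------
    GroupInputError
        If either group fails the BC preconditions; ``.group`` names it.
    """
    try:
        bc_cases = compute_bc(case_values, bias_corrected=bias_corrected)
    except (TooFewValuesError, ConstantInputError) as e:
        raise GroupInputError("cases", e) from e
    try:
        bc_controls = compute_bc(control_values, bias_corrected=bias_corrected)
    except (TooFewValuesError, ConstantInputError) as e:
        raise GroupInputError("controls", e) from e
    return BCDValue(
        bcd=abs(bc_cases.bc - bc_controls.bc),
        bc_cases=bc_cases,
        bc_controls=bc_controls,
    )
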