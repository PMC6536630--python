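"""Evaluation statistics: peb, coverage, power, ICC and effect sizes.

peb (parameter estimation bias) is the signed mean relative deviation of
estimates from the true value; |peb| > 0.10 conventionally flags a biased
parameter.  Coverage is judged against the 91-98% band for nominal 95%
intervals; power is the share of intervals excluding zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .lmm import VarianceComponents

__all__ = [
    "ICCValues",
    "compute_peb",
    "compute_coverage",
    "compute_power",
    "compute_icc",
    "effect_size_fixed",
    "effect_size_random",
    "PEB_BIAS_THRESHOLD",
    "COVERAGE_BAND",
]

PEB_BIAS_THRESHOLD = 0.10
COVERAGE_BAND = (0.91, 0.98)


@dataclass(frozen=True)
class ICCValues:
    """Intraclass correlations from the empty model.

    ``rho_level3`` is the share of total unexplained variance between
    classes; ``rho_level2_a`` the correlation of two observations of the
    same student (includes the class component); ``rho_level2_b`` the
    share of variance between students net of classes.  The identity
    rho_level3 + rho_level2_b = rho_level2_a holds by construction.
    """

    rho_level3: float
    rho_level2_a: float
    rho_level2_b: float


def compute_peb(estimates: Sequence[float], true_value: float) -> float:
    """Signed mean relative deviation of ``estimates`` from ``true_value``."""
    est = np.asarray(list(estimates), dtype=float)
    if est.size == 0:
        raise ValueError("compute_peb needs at least one estimate")
    if true_value == 0:
        raise ValueError("peb is undefined for a zero true value")
    return float(np.mean((est - true_value) / true_value))


def compute_coverage(
    intervals: Iterable[tuple[float, float]], true_value: float
) -> tuple[float, bool]:
    """Fraction of intervals containing the truth, plus a band flag.

    The flag is True when the coverage falls inside the acceptable
    [0.91, 0.98] band for nominal 95% intervals.
    """
    ivals = list(intervals)
    if not ivals:
        raise ValueError("compute_coverage needs at least one interval")
    hits = sum(1 for lo, hi in ivals if lo <= true_value <= hi)
    cov = hits / len(ivals)
    return cov, COVERAGE_BAND[0] <= cov <= COVERAGE_BAND[1]


def compute_power(intervals: Iterable[tuple[float, float]]) -> float:
    """Fraction of intervals excluding zero (two-sided)."""
    ivals = list(intervals)
    if not ivals:
        raise ValueError("compute_power needs at least one interval")
    hits = sum(1 for lo, hi in ivals if lo > 0 or hi < 0)
    return hits / len(ivals)


def compute_icc(varcomps: VarianceComponents) -> ICCValues:
    """Three intraclass correlations from empty-model variance components."""
    e2 = varcomps.resid
    tau2 = varcomps.l2_intercept
    sig2 = varcomps.l3_intercept
    total = e2 + tau2 + sig2
    if total <= 0:
        raise ValueError("total variance must be positive to form ICCs")
    return ICCValues(
        rho_level3=sig2 / total,
        rho_level2_a=(tau2 + sig2) / total,
        rho_level2_b=tau2 / total,
    )


def effect_size_fixed(
    coefficient: float,
    predictor_sd: float | None,
    resid_variance: float,
    kind: str,
) -> float:
    """Approximate effect size of a fixed effect relative to residual spread.

    Dichotomous predictors: beta / sd_e.  Continuous predictors:
    2 * beta * SD_predictor / sd_e (the coefficient's reach across minus/plus
    one predictor SD).  The denominator is the residual standard deviation.
    """
    if resid_variance <= 0:
        raise ValueError("resid_variance must be positive")
    sd_e = math.sqrt(resid_variance)
    if kind == "dichotomous":
        return coefficient / sd_e
    if kind == "continuous":
        if predictor_sd is None or predictor_sd <= 0:
            raise ValueError("continuous effect sizes need a positive predictor_sd")
        return 2.0 * coefficient * predictor_sd / sd_e
    raise ValueError("kind must be 'dichotomous' or 'continuous'")


def effect_size_random(icc: float, literal: bool = False) -> float:
    """Effect size of a random part from its ICC.

    Default: 2 * sqrt(icc / (1 - icc)), i.e. twice the between/within
    standard-deviation ratio, which is the reading consistent with the
    fixed-effect formulas above.  With ``literal=True`` the variance-ratio
    form 4 * icc / (1 - icc) is returned instead.
    """
    if not 0.0 <= icc < 1.0:
        raise ValueError("icc must lie in [0, 1)")
    ratio = icc / (1.0 - icc)
    if literal:
        return 4.0 * ratio
    return 2.0 * math.sqrt(ratio)
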