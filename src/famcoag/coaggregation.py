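"""Recurrence risk ratios (lambda_R) with one-sided inference.

lambda_R is the prevalence of a disorder among individuals with an affected
relative of degree R divided by the general-population prevalence; a ratio
above 1 indicates shared familial risk. The standard error follows by the
delta method treating numerator and denominator as independent (a
conservative choice: the exposed are part of the population). Inference is
one-sided against H0: lambda = 1, and only the lower 95% confidence bound is
reported (the upper bound is unbounded for a ratio and uninformative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .prevalence import PrevalenceEstimate

logger = logging.getLogger(__name__)

Z95 = float(norm.ppf(0.95))


@dataclass
class LambdaEstimate:
    lambda_hat: float
    se: float
    lower95: float  # one-sided 95% lower bound, ratio scale
    p_one_sided: float  # H0: lambda = 1 vs H1: lambda > 1
    pair: tuple[str, str] = ("", "")  # (outcome phenotype, relative phenotype)
    degree: str = "first"
    log_scale: bool = False


def recurrence_risk_ratio(
    p_exposed: PrevalenceEstimate,
    p_pop: PrevalenceEstimate,
    pair: tuple[str, str] = ("", ""),
    degree: str = "first",
    log_scale: bool = False,
) -> LambdaEstimate:
    """lambda = K_exposed / K_pop with delta-method SE.

    Var(lambda) = Var(p1)/p0^2 + p1^2 Var(p0)/p0^4 under independence of
    numerator and denominator. By default the confidence bound is on the
    ratio scale (simple ratio minus z * SE); ``log_scale=True`` instead builds
    the bound on log(lambda) and exponentiates, which cannot go negative.
    """
    p1, v1 = p_exposed.K_hat, p_exposed.se**2
    p0, v0 = p_pop.K_hat, p_pop.se**2
    if p0 <= 0.0:
        raise ValueError("population prevalence must be positive")
    lam = p1 / p0
    var = v1 / p0**2 + p1**2 * v0 / p0**4
    if var <= 0.0:
        raise ValueError("nonpositive delta-method variance")
    se = float(np.sqrt(var))
    if log_scale:
        se_log = se / lam
        lower = float(lam * np.exp(-Z95 * se_log))
        p = float(norm.sf(np.log(lam) / se_log))
    else:
        lower = lam - Z95 * se
        p = float(norm.sf((lam - 1.0) / se))
    return LambdaEstimate(
        lambda_hat=float(lam),
        se=se,
        lower95=float(lower),
        p_one_sided=p,
        pair=pair,
        degree=degree,
        log_scale=log_scale,
    )
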