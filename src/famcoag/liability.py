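"""Familial correlations under the liability threshold model.

A binary trait is modelled as a standard normal liability exceeding a
threshold t = Phi^-1(1 - K) set by the lifetime prevalence K. For a proband
trait A and a relative's trait B, the liabilities of a relative pair are
bivariate normal with correlation a_R * r_f, where a_R is the coefficient of
relationship (0.5 first degree, 0.25 second degree) and r_f the cross-trait
liability correlation attributable to familial factors (genetic plus shared
environment combined; with standardized liabilities this equals the
cross-trait familial covariance). The prevalence of A among individuals with
an affected relative for B then is

    K_pred = P(X > t_A, Y > t_B; rho = a_R * r_f) / K_B        (exact mode)

which is strictly increasing in r_f, so observing the prevalence among
exposed individuals identifies r_f by root finding. A Reich-type threshold
shift approximation is kept for comparability with the older literature:

    t* = (t_A - a_R r_f i_B) / sqrt(1 - a_R^2 r_f^2 i_B (i_B - t_B))
    K_pred = 1 - Phi(t*),   i_B = phi(t_B)/K_B (mean liability of affected).

Estimates from the available (degree x direction) components are combined by
an inverse-variance-weighted mean whose standard error accounts for the
components being estimated from the same families (cluster-level influence
covariance); see docs/methods.md.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri
from scipy.stats import norm

from .pedigree import RELATIONSHIP_COEFFICIENT
from .prevalence import PrevalenceEstimate

logger = logging.getLogger(__name__)

Z95 = float(norm.ppf(0.95))
RF_BOUND = 0.999
EXACT, APPROXIMATE = "exact", "approximate"

# Gauss-Legendre positive nodes/weights used by the bivariate normal routine
_GL = {
    n: (x[n // 2 :], w[n // 2 :])
    for n, (x, w) in ((n, np.polynomial.legendre.leggauss(n)) for n in (6, 12, 20))
}


def _phid(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def bvn_upper(h: float, k: float, r: float) -> float:
    """P(X > h, Y > k) for standard bivariate normal with correlation r.

    Genz's rearrangement of the Drezner-Wesolowsky quadrature: a Gauss-
    Legendre rule on the arcsine-transformed correlation for moderate |r| and
    an asymptotic expansion with quadrature correction near |r| = 1. Absolute
    accuracy is around 1e-15, well inside the 1e-10 the solver assumes.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation outside [-1, 1]")
    if abs(r) < 0.3:
        x, w = _GL[6]
    elif abs(r) < 0.75:
        x, w = _GL[12]
    else:
        x, w = _GL[20]

    hk = h * k
    bvn = 0.0
    if abs(r) < 0.925:
        if r != 0.0:
            hs = (h * h + k * k) / 2.0
            asr = math.asin(r) / 2.0
            sn = np.sin(asr * (1.0 - x))
            bvn = float(np.sum(w * np.exp((sn * hk - hs) / (1.0 - sn * sn))))
            sn = np.sin(asr * (1.0 + x))
            bvn += float(np.sum(w * np.exp((sn * hk - hs) / (1.0 - sn * sn))))
            bvn = bvn * asr / (2.0 * math.pi)
        return max(0.0, min(1.0, bvn + _phid(-h) * _phid(-k)))

    if r < 0.0:
        k = -k
        hk = -hk
    if abs(r) < 1.0:
        a_s = (1.0 - r) * (1.0 + r)
        a = math.sqrt(a_s)
        bs = (h - k) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asr = -(bs / a_s + hk) / 2.0
        if asr > -100.0:
            bvn = a * math.exp(asr) * (1.0 - c * (bs - a_s) * (1.0 - d * bs / 5.0) / 3.0 + c * d * a_s * a_s / 5.0)
        if -hk < 100.0:
            b = math.sqrt(bs)
            bvn -= math.exp(-hk / 2.0) * math.sqrt(2.0 * math.pi) * _phid(-b / a) * b * (
                1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0
            )
        a /= 2.0
        for xi, wi in zip(x, w):
            for s in (-1.0, 1.0):
                xs = (a * (s * xi + 1.0)) ** 2
                rs = math.sqrt(1.0 - xs)
                asr = -(bs / xs + hk) / 2.0
                if asr > -100.0:
                    bvn += (
                        a
                        * wi
                        * math.exp(asr)
                        * (math.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs - (1.0 + c * xs * (1.0 + d * xs)))
                    )
        bvn = -bvn / (2.0 * math.pi)
    if r > 0.0:
        bvn += _phid(-max(h, k))
    else:
        bvn = -bvn
        if k > h:
            bvn += _phid(k) - _phid(h)
    return max(0.0, min(1.0, bvn))


@dataclass(frozen=True)
class LiabilityParams:
    """Threshold-model quantities for one trait at prevalence K."""

    K: float
    t: float  # liability threshold Phi^-1(1-K)
    z: float  # normal density at the threshold
    i: float  # mean liability of affected individuals, z/K


def liability_params(K: float) -> LiabilityParams:
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence {K} outside (0,1)")
    t = float(-ndtri(K))  # = Phi^-1(1-K), avoiding distribution-call overhead
    z = math.exp(-0.5 * t * t) / math.sqrt(2.0 * math.pi)
    return LiabilityParams(K=float(K), t=t, z=z, i=z / K)


def _check_a_R(a_R: float) -> float:
    for deg, coeff in RELATIONSHIP_COEFFICIENT.items():
        if abs(a_R - coeff) < 1e-12:
            return coeff
    raise ValueError(f"a_R must be one of {sorted(RELATIONSHIP_COEFFICIENT.values())}, got {a_R}")


def predicted_relative_prevalence(
    A: LiabilityParams, B: LiabilityParams, a_R: float, r_f: float, mode: str = EXACT
) -> float:
    """Model-implied prevalence of trait A among individuals with an affected
    relative (coefficient a_R) for trait B."""
    a_R = _check_a_R(a_R)
    if not abs(r_f) < 1.0:
        raise ValueError("r_f must lie in (-1, 1)")
    if mode == EXACT:
        return bvn_upper(A.t, B.t, a_R * r_f) / B.K
    if mode == APPROXIMATE:
        rho = a_R * r_f
        denom_sq = 1.0 - rho * rho * B.i * (B.i - B.t)
        if denom_sq <= 0.0:
            raise ValueError("approximate mode degenerate: correlation too strong for this prevalence")
        t_star = (A.t - rho * B.i) / math.sqrt(denom_sq)
        return float(norm.sf(t_star))
    raise ValueError(f"unknown mode {mode!r}")


def solve_rf(K_obs: float, A: LiabilityParams, B: LiabilityParams, a_R: float, mode: str = EXACT) -> float:
    """Invert the threshold model: the r_f whose predicted prevalence among
    exposed individuals equals ``K_obs`` (bracketed root finding; the
    prediction is strictly increasing in r_f)."""
    if not 0.0 < K_obs < 1.0:
        raise ValueError(f"observed prevalence {K_obs} outside (0,1)")
    lo = predicted_relative_prevalence(A, B, a_R, -RF_BOUND, mode)
    hi = predicted_relative_prevalence(A, B, a_R, RF_BOUND, mode)
    if not lo <= K_obs <= hi:
        raise ValueError(
            f"observed prevalence {K_obs:.6g} outside attainable range [{lo:.6g}, {hi:.6g}] "
            f"for a_R={a_R}, K_A={A.K:.6g}, K_B={B.K:.6g}"
        )
    return float(
        brentq(
            lambda r: predicted_relative_prevalence(A, B, a_R, r, mode) - K_obs,
            -RF_BOUND,
            RF_BOUND,
            xtol=1e-10,
            rtol=1e-12,
        )
    )


@dataclass
class RfComponent:
    """One (degree, direction) ingredient of a familial correlation."""

    degree: str  # "first" or "second"
    direction: str  # e.g. "A|B": outcome A given an affected relative with B
    prevalence: PrevalenceEstimate  # AAP among exposed individuals
    outcome_params: LiabilityParams
    relative_params: LiabilityParams
    # filled by the estimator:
    rf: float = math.nan
    se: float = math.nan

    @property
    def a_R(self) -> float:
        return RELATIONSHIP_COEFFICIENT[self.degree]


@dataclass
class RfEstimate:
    rf: float
    se: float
    lower95: float
    p_one_sided: float  # H0: r_f = 0 vs H1: r_f > 0
    components: list[RfComponent] = field(default_factory=list)
    mode: str = EXACT


def _component_rf(comp: RfComponent, mode: str, fd_step: float) -> tuple[float, float, float]:
    """(rf, d rf / d K_obs, se) for one component; NaNs if unsolvable."""
    K = comp.prevalence.K_hat
    try:
        rf = solve_rf(K, comp.outcome_params, comp.relative_params, comp.a_R, mode)
        h = min(fd_step, 0.5 * K, 0.5 * (1.0 - K))
        r_hi = solve_rf(K + h, comp.outcome_params, comp.relative_params, comp.a_R, mode)
        r_lo = solve_rf(K - h, comp.outcome_params, comp.relative_params, comp.a_R, mode)
    except ValueError as err:
        warnings.warn(f"component {comp.direction} degree {comp.degree} unsolvable: {err}", stacklevel=3)
        return math.nan, math.nan, math.nan
    drdK = (r_hi - r_lo) / (2.0 * h)
    se = abs(drdK) * comp.prevalence.se
    return rf, drdK, se


def estimate_familial_correlation(
    components: list[RfComponent], mode: str = EXACT, fd_step: float = 1e-4
) -> RfEstimate | None:
    """Combine per-(degree, direction) familial correlations.

    Point estimate: inverse-variance-weighted mean of the solvable
    components. Its standard error uses the cluster-level influence functions
    of the component prevalences when available, so that the covariance
    between components estimated from the same families is respected;
    without influence data it falls back to the independence formula.
    """
    if not components:
        raise ValueError("no components given")
    finite: list[tuple[RfComponent, float, float, float]] = []
    for comp in components:
        rf, drdK, se = _component_rf(comp, mode, fd_step)
        comp.rf, comp.se = rf, se
        if math.isfinite(rf) and math.isfinite(se) and se > 0.0:
            finite.append((comp, rf, drdK, se))
    if not finite:
        warnings.warn("no solvable familial correlation components; returning missing result", stacklevel=2)
        return None
    if len(finite) < len(components):
        warnings.warn(
            f"only {len(finite)} of {len(components)} familial correlation components usable",
            stacklevel=2,
        )

    w = np.array([1.0 / se**2 for _, _, _, se in finite])
    r = np.array([rf for _, rf, _, _ in finite])
    rbar = float(np.sum(w * r) / np.sum(w))

    infl = [c.prevalence.influence for c, _, _, _ in finite]
    if all(v is not None and len(v) == len(infl[0]) for v in infl):
        IF = np.column_stack([drdK * v for (_, _, drdK, _), v in zip(finite, infl)])
        Sigma = IF.T @ IF
        var = float(w @ Sigma @ w) / float(np.sum(w)) ** 2
    else:
        var = 1.0 / float(np.sum(w))
    se = math.sqrt(max(var, 1e-300))
    return RfEstimate(
        rf=rbar,
        se=se,
        lower95=rbar - Z95 * se,
        p_one_sided=float(norm.sf(rbar / se)),
        components=[c for c, _, _, _ in finite],
        mode=mode,
    )
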