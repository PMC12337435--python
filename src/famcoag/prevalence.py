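"""Covariate-adjusted prevalence estimation by marginal standardization.

Lifetime prevalences are modelled by logistic regression (exposure indicator,
age, age squared, sex, number of relatives with data) and summarized as
average adjusted predictions (AAP): the mean of fitted probabilities over a
target group at observed covariate values. Because families contribute
correlated observations, coefficient variances use the cluster-robust
sandwich estimator with families as clusters: bread = inverse observed
information, meat = sum of outer products of per-family score sums. AAP
standard errors follow by the delta method.

Implementation notes: the solver is Newton-Raphson on internally
standardized covariates (the raw age-squared column has scale ~1e4, which
ruins the conditioning of the information matrix; logistic MLE, fitted
probabilities and delta-method variances are invariant to this affine
reparameterization, and coefficients are mapped back). A co-aggregation grid
fits hundreds of such models per run and the calibration suites tens of
thousands, so per-fit overhead is kept minimal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    pass


try:  # fused score/information accumulation; numpy fallback below is reference
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True)
    def _accum_kernel(Xs, resid, w):  # pragma: no cover - jitted
        """One pass over the design: grad = Xs'resid, A = Xs'diag(w)Xs."""
        n, k = Xs.shape
        grad = np.zeros(k)
        A = np.zeros((k, k))
        for i in range(n):
            r = resid[i]
            wi = w[i]
            for j in range(k):
                xj = Xs[i, j]
                grad[j] += xj * r
                wx = wi * xj
                for l in range(j, k):
                    A[j, l] += wx * Xs[i, l]
        for j in range(k):
            for l in range(j + 1, k):
                A[l, j] = A[j, l]
        return grad, A

    @_numba.njit(cache=True, fastmath=True)
    def _accum_kernel6(Xs, resid, w):  # pragma: no cover - jitted
        """Unrolled 6-column variant of the accumulation pass (the study
        design matrix always has 6 columns, and unrolling lets the compiler
        vectorize across rows)."""
        n = Xs.shape[0]
        g0 = g1 = g2 = g3 = g4 = g5 = 0.0
        a00 = a01 = a02 = a03 = a04 = a05 = 0.0
        a11 = a12 = a13 = a14 = a15 = 0.0
        a22 = a23 = a24 = a25 = 0.0
        a33 = a34 = a35 = 0.0
        a44 = a45 = a55 = 0.0
        for i in range(n):
            x0 = Xs[i, 0]; x1 = Xs[i, 1]; x2 = Xs[i, 2]
            x3 = Xs[i, 3]; x4 = Xs[i, 4]; x5 = Xs[i, 5]
            r = resid[i]; wi = w[i]
            g0 += x0 * r; g1 += x1 * r; g2 += x2 * r
            g3 += x3 * r; g4 += x4 * r; g5 += x5 * r
            w0 = wi * x0; w1 = wi * x1; w2 = wi * x2
            w3 = wi * x3; w4 = wi * x4; w5 = wi * x5
            a00 += w0 * x0; a01 += w0 * x1; a02 += w0 * x2
            a03 += w0 * x3; a04 += w0 * x4; a05 += w0 * x5
            a11 += w1 * x1; a12 += w1 * x2; a13 += w1 * x3
            a14 += w1 * x4; a15 += w1 * x5
            a22 += w2 * x2; a23 += w2 * x3; a24 += w2 * x4; a25 += w2 * x5
            a33 += w3 * x3; a34 += w3 * x4; a35 += w3 * x5
            a44 += w4 * x4; a45 += w4 * x5
            a55 += w5 * x5
        grad = np.array([g0, g1, g2, g3, g4, g5])
        A = np.array(
            [
                [a00, a01, a02, a03, a04, a05],
                [a01, a11, a12, a13, a14, a15],
                [a02, a12, a22, a23, a24, a25],
                [a03, a13, a23, a33, a34, a35],
                [a04, a14, a24, a34, a44, a45],
                [a05, a15, a25, a35, a45, a55],
            ]
        )
        return grad, A

except ImportError:  # pragma: no cover
    _accum_kernel = None
    _accum_kernel6 = None


def _score_info(Xs, resid, w):
    if _accum_kernel is not None:
        if Xs.shape[1] == 6:
            return _accum_kernel6(Xs, resid, w)
        return _accum_kernel(Xs, resid, w)
    return Xs.T @ resid, (Xs * w[:, None]).T @ Xs


def _subset_gradient(w_full, Xs_full, mask, m):
    """mean over masked rows of w * x without materializing the slice."""
    ww = np.where(mask, w_full, 0.0)
    return (ww @ Xs_full) / m


@dataclass
class ModelFit:
    """Logistic MLE with family-clustered sandwich covariance.

    ``beta`` and ``V`` are on the original covariate scale. The standardized
    internals (``_transform``, ``bread``, ``cluster_scores``) support average
    adjusted predictions and influence-function calculations.
    """

    beta: np.ndarray
    V: np.ndarray  # cluster-robust covariance of beta, original scale
    n_obs: int
    converged: bool
    names: list[str] = field(default_factory=list)
    bread: np.ndarray | None = None  # inverse observed information (standardized scale)
    cluster_scores: np.ndarray | None = None  # (n_clusters, k) score sums (standardized scale)
    cluster_index: np.ndarray | None = None  # per-row cluster position
    cluster_labels: np.ndarray | None = None  # unique cluster ids, sorted
    _beta_std: np.ndarray | None = None
    _center: np.ndarray | None = None
    _scale: np.ndarray | None = None
    _V_std: np.ndarray | None = None
    _Xs: np.ndarray | None = None  # standardized design of the fit
    _p: np.ndarray | None = None  # fitted probabilities at the design

    def __post_init__(self):
        if self.V.shape != (len(self.beta), len(self.beta)):
            raise ValueError("covariance dimension does not match coefficients")
        if not np.allclose(self.V, self.V.T, atol=1e-8 * (1 + np.abs(self.V).max())):
            raise ValueError("covariance not symmetric")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self._center) / self._scale

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.standardize(X) @ self._beta_std


@dataclass
class PrevalenceEstimate:
    """Marginalized prevalence (AAP) with delta-method standard error."""

    K_hat: float
    se: float
    subset: str  # "population" or "exposed"
    n: int
    influence: np.ndarray | None = None  # per-cluster influence contributions

    def __post_init__(self):
        if not (0.0 < self.K_hat < 1.0):
            raise ValueError(f"prevalence {self.K_hat} outside (0,1)")
        if self.se < 0:
            raise ValueError("standard error cannot be negative")


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def fit_prevalence_model(
    outcome: np.ndarray,
    covariates: np.ndarray,
    family_ids: np.ndarray,
    names: list[str] | None = None,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
    standardization: tuple[np.ndarray, np.ndarray] | None = None,
    clusters: tuple[np.ndarray, np.ndarray] | None = None,
    prestandardized: bool = False,
) -> ModelFit:
    """Maximum-likelihood logistic fit with family-clustered sandwich variance.

    ``covariates`` must include the intercept column (detected as the column
    with zero variance and value 1). Rows with missing values must have been
    dropped upstream. Raises :class:`FitError` on degenerate outcomes,
    perfect separation, or non-convergence, naming the offending covariate
    where identifiable. ``beta0`` (original scale) warm-starts Newton.

    Fast paths for repeated fitting: ``standardization`` supplies the column
    (center, scale) instead of recomputing them; with ``prestandardized=True``
    the matrix passed is already the standardized design (column 0 must then
    be the intercept, with center 0 and scale 1); ``clusters`` supplies
    precomputed ``(labels, per-row index)`` from ``np.unique``.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(covariates, dtype=float)
    n, k = X.shape
    names = names or [f"x{j}" for j in range(k)]
    if len(names) != k:
        raise ValueError("names length mismatch")
    if y.shape[0] != n:
        raise ValueError("outcome/covariate length mismatch")
    ymin, ymax = y.min(), y.max()
    if ymin < 0 or ymax > 1 or not set(np.unique(y)) <= {0.0, 1.0}:
        raise FitError("outcome must be binary 0/1")
    if ymin == ymax:
        raise FitError("outcome has a single class; prevalence model undefined")

    # standardize non-constant columns; keep the intercept as-is
    if prestandardized:
        if standardization is None:
            raise ValueError("prestandardized fits require the (center, scale) used")
        center, scale = (np.asarray(a, dtype=float) for a in standardization)
        bad = np.flatnonzero(scale[1:] < 1e-12)
        if len(bad):
            raise FitError(f"covariate {names[1 + bad[0]]!r} is constant; model singular")
        Xs = X
        const = np.zeros(k, dtype=bool)
        const[0] = True
    else:
        if standardization is not None:
            center, scale = (np.array(a, dtype=float) for a in standardization)
        else:
            center = X.mean(axis=0)
            scale = X.std(axis=0)
        const = scale < 1e-12
        center[const] = 0.0
        scale[const] = np.where(np.abs(X[0, const]) > 1e-12, X[0, const], 1.0)
        Xs = (X - center) / scale

    if beta0 is None:
        b = np.zeros(k)
        b[const] = np.log((y.mean() + 1e-6) / (1.0 - y.mean() + 1e-6)) * scale[const] / np.where(X[0, const] == 0, 1.0, X[0, const])
    else:
        # map original-scale start into standardized space
        b0 = np.asarray(beta0, dtype=float) * scale
        b0[const] += center @ beta0
        b = b0

    tol_eff = tol * max(1.0, n / 100.0)
    Xs = np.ascontiguousarray(Xs)
    converged = False
    prev_gnorm = np.inf
    for _ in range(max_iter):
        p = _sigmoid(Xs @ b)
        resid = y - p
        w = p * (1.0 - p)
        grad, A = _score_info(Xs, resid, w)
        gnorm = np.max(np.abs(grad))
        if gnorm < tol_eff:
            converged = True
            break
        try:
            step = np.linalg.solve(A, grad)
        except np.linalg.LinAlgError:
            worst = names[int(np.argmax(np.abs(b)))]
            raise FitError(f"singular information matrix (possible separation involving {worst!r})")
        if gnorm > 2.0 * prev_gnorm:  # divergence guard; rare
            step *= 0.5
        b = b + step
        prev_gnorm = gnorm
        if np.max(np.abs(b)) > 60.0:
            worst = names[int(np.argmax(np.abs(b)))]
            raise FitError(f"perfect separation suspected on covariate {worst!r}")
    if not converged:
        raise FitError("logistic fit did not converge")
    if np.max(np.abs(b)) > 20.0:
        # a standardized log-odds coefficient beyond +-20 means some covariate
        # pattern predicts the outcome perfectly
        worst = names[int(np.argmax(np.abs(b)))]
        raise FitError(f"perfect separation suspected on covariate {worst!r}")
    bread = np.linalg.inv(A)

    starts = None
    if clusters is not None:
        fam, cluster_index, *rest = clusters
        if rest:
            starts = rest[0]
    else:
        fam, cluster_index = np.unique(np.asarray(family_ids), return_inverse=True)
    if len(fam) == 1:
        warnings.warn("single cluster: sandwich variance is degenerate", stacklevel=2)
    G = len(fam)
    scores = Xs * resid[:, None]
    if starts is None and G > 1 and cluster_index[0] == 0 and cluster_index[-1] == G - 1 and np.all(np.diff(cluster_index) >= 0):
        starts = np.searchsorted(cluster_index, np.arange(G))
    if starts is not None:
        S = np.add.reduceat(scores, starts, axis=0)
    else:
        S = np.column_stack(
            [np.bincount(cluster_index, weights=scores[:, j], minlength=G) for j in range(k)]
        )
    V_std = bread @ (S.T @ S) @ bread

    # map back to the original covariate scale: eta = Xs b = X (T b)
    T = np.diag(1.0 / scale)
    for j in np.flatnonzero(const):
        T[j, :] = -center / (scale * X[0, j])
        T[j, j] = 1.0 / X[0, j]
    beta = T @ b
    V = T @ V_std @ T.T
    V = 0.5 * (V + V.T)
    return ModelFit(
        beta=beta,
        V=V,
        n_obs=n,
        converged=converged,
        names=list(names),
        bread=bread,
        cluster_scores=S,
        cluster_index=cluster_index,
        cluster_labels=fam,
        _beta_std=b,
        _center=center,
        _scale=scale,
        _V_std=0.5 * (V_std + V_std.T),
        _Xs=Xs,
        _p=p,
    )


def average_adjusted_prediction(
    fit: ModelFit,
    covariates: np.ndarray | None = None,
    subset_mask: np.ndarray | None = None,
    subset: str = "population",
    counterfactual_exposure: int | None = None,
    exposure_col: int | None = None,
) -> PrevalenceEstimate:
    """Average adjusted prediction over a subset, with delta-method SE.

    Default mode averages fitted probabilities at observed covariates within
    the subset ("subgroup-observed"); ``covariates=None`` reuses the design
    the model was fitted on. If ``counterfactual_exposure`` is given, the
    exposure column is set to that value for every row before averaging
    (counterfactual standardization).

    The returned estimate carries per-cluster influence contributions, used
    downstream to combine correlated estimates from the same families.
    """
    if covariates is None and counterfactual_exposure is None:
        Xs_full, p_full = fit._Xs, fit._p
    else:
        X = np.asarray(covariates if covariates is not None else fit._Xs * fit._scale + fit._center, dtype=float)
        if counterfactual_exposure is not None:
            if exposure_col is None:
                raise ValueError("exposure_col required for counterfactual mode")
            X = X.copy()
            X[:, exposure_col] = counterfactual_exposure
        Xs_full = fit.standardize(X)
        p_full = _sigmoid(Xs_full @ fit._beta_std)
    if subset_mask is None:
        p, m = p_full, Xs_full.shape[0]
        K = float(p.mean())
        gbar = ((p * (1.0 - p)) @ Xs_full) / m  # gradient of K wrt standardized beta
    else:
        m = int(subset_mask.sum())
        if m == 0:
            raise ValueError("empty subset for average adjusted prediction")
        p = p_full[subset_mask]
        K = float(p.mean())
        gbar = _subset_gradient(p_full * (1.0 - p_full), Xs_full, subset_mask, m)
    var = float(gbar @ fit._V_std @ gbar)
    se = float(np.sqrt(max(var, 0.0)))

    influence = None
    if fit.cluster_scores is not None and fit.cluster_index is not None:
        # asymptotically linear representation: coefficient part through the
        # sandwich scores plus the direct part from averaging over the subset
        influence = fit.cluster_scores @ (fit.bread @ gbar)
        G = len(fit.cluster_scores)
        cidx = fit.cluster_index if subset_mask is None else fit.cluster_index[subset_mask]
        direct = np.bincount(cidx, weights=(p - K) / m, minlength=G)
        influence = influence + direct
    return PrevalenceEstimate(K_hat=K, se=se, subset=subset, n=m, influence=influence)
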