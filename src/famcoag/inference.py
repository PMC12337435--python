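"""Multiple-testing control and results assembly.

All one-sided tests of a study grid — two recurrence-risk-ratio tests per
(focal, disease) ordered pair plus one familial correlation per unordered
pair (for 5 focal x 7 diseases: 70 + 35 = 105 tests) — form a single
Benjamini-Hochberg family at false discovery rate q. Tests that could not be
computed (e.g. no exposed cases) carry a missing p-value and do not count
toward the family size m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def bh_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up Benjamini-Hochberg over the non-missing p-values.

    Returns (adjusted p-values, rejection flags) in the input order; missing
    entries stay NaN / unrejected and are excluded from the family size m.
    Adjusted p(i) = min_{j >= i} m * p(j) / j over the ascending order,
    capped at 1; reject where adjusted <= q.
    """
    p = np.asarray(pvalues, dtype=float)
    adj = np.full_like(p, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return adj, reject
    psub = p[ok]
    order = np.argsort(psub, kind="stable")
    ranked = psub[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    adj_sub = np.empty(m)
    adj_sub[order] = ranked
    adj[ok] = adj_sub
    reject[ok] = adj_sub <= q
    return adj, reject


@dataclass
class ResultsTable:
    """Assembled study results: lambda rows, r_f rows, and the pooled table
    with BH-adjusted p-values and significance flags."""

    table: pd.DataFrame
    q: float
    n_lambda: int
    n_rf: int

    @property
    def n_tests(self) -> int:
        return int(self.table["p_one_sided"].notna().sum())


def assemble_results(
    lambda_rows: pd.DataFrame,
    rf_rows: pd.DataFrame,
    q: float = 0.05,
    family: str = "pooled",
) -> ResultsTable:
    """Concatenate lambda and r_f rows and BH-adjust.

    ``family='pooled'`` (default) applies one BH family across every test;
    ``family='per-type'`` adjusts lambda and r_f tests separately.
    """
    lam = lambda_rows.copy()
    rf = rf_rows.copy()
    key_lam = lam[["outcome", "relative_phenotype", "degree"]].astype(str).agg("|".join, axis=1) if len(lam) else pd.Series(dtype=str)
    if key_lam.duplicated().any():
        raise ValueError(f"duplicate lambda rows: {key_lam[key_lam.duplicated()].tolist()}")
    if len(rf):
        key_rf = rf[["phenotype_A", "phenotype_B"]].astype(str).agg("|".join, axis=1)
        if key_rf.duplicated().any():
            raise ValueError(f"duplicate r_f rows: {key_rf[key_rf.duplicated()].tolist()}")
    lam["statistic"] = "lambda"
    rf["statistic"] = "rf"
    table = pd.concat([lam, rf], ignore_index=True, sort=False)
    if family == "pooled":
        adj, rej = bh_adjust(table["p_one_sided"].to_numpy(), q)
    elif family == "per-type":
        adj = np.full(len(table), np.nan)
        rej = np.zeros(len(table), dtype=bool)
        for stat in ("lambda", "rf"):
            mask = (table["statistic"] == stat).to_numpy()
            adj[mask], rej[mask] = bh_adjust(table.loc[mask, "p_one_sided"].to_numpy(), q)
    else:
        raise ValueError(f"unknown BH family mode {family!r}")
    table["p_adjusted"] = adj
    table["significant"] = rej
    n_lambda = int((table["statistic"] == "lambda").sum())
    n_rf = int((table["statistic"] == "rf").sum())
    logger.info("assembled %d lambda + %d r_f tests (%d with p-values)", n_lambda, n_rf, int(np.isfinite(adj).sum()))
    return ResultsTable(table=table, q=q, n_lambda=n_lambda, n_rf=n_rf)
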