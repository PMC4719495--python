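"""Statistical toolkit: Pearson correlation, partial correlation of
biomarkers against parameters, and the Mann-Whitney U test.

Partial correlation follows the residual-on-residual definition: each
parameter and the biomarker are regressed (OLS) on all remaining
parameters, and the Pearson correlation of the residuals is reported.  A
rank-based (Spearman-flavoured) variant is available since the linear
choice is a convention.

The Mann-Whitney exact two-sided p-value is computed by enumeration over
all group assignments with midranks (so ties, including identical samples,
are handled; identical samples give p = 1).  Larger samples use the
tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "pearson",
    "partial_correlation",
    "mann_whitney",
    "significance_stars",
    "CorrelationReport",
    "correlation_report",
]

EXACT_MAX_N = 20  # exact enumeration up to this total sample size


def pearson(x, y) -> float:
    """Product-moment correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


def _residuals(target, design):
    """OLS residuals of target on design (with intercept)."""
    X = np.column_stack([np.ones(design.shape[0]), design])
    beta, *_ = np.linalg.lstsq(X, target, rcond=None)
    return target - X @ beta


def partial_correlation(params, biomarker, method: str = "linear"):
    """Partial correlation of each parameter column with the biomarker,
    controlling for all other parameters.

    Returns ``(pcc, pvalues)`` arrays of length n_params.  ``method`` is
    "linear" (default) or "rank" (ranks taken before residualization).
    Raises on rank-deficient designs, naming the collinear columns.
    """
    X = np.asarray(params, dtype=float)
    y = np.asarray(biomarker, dtype=float)
    if X.ndim != 2:
        raise ValueError("params must be a 2-D matrix")
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("biomarker length must match params rows")
    if n < k + 2:
        raise ValueError(f"need >= n_params + 2 = {k + 2} observations, got {n}")
    if method == "rank":
        X = np.apply_along_axis(sps.rankdata, 0, X)
        y = sps.rankdata(y)
    elif method != "linear":
        raise ValueError("method must be 'linear' or 'rank'")

    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
    if rank < k + 1:
        # identify offending columns by leave-one-in rank increase
        bad = []
        base = np.ones((n, 1))
        cur = base
        for j in range(k):
            trial = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(trial) == np.linalg.matrix_rank(cur):
                bad.append(j)
            else:
                cur = trial
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear columns: {bad}")

    pcc = np.empty(k)
    pval = np.empty(k)
    dof = n - k - 1  # n - (k-1 controls) - 2
    for j in range(k):
        others = np.delete(X, j, axis=1)
        rx = _residuals(X[:, j], others)
        ry = _residuals(y, others)
        r = float(np.corrcoef(rx, ry)[0, 1])
        pcc[j] = r
        if abs(r) >= 1.0:
            pval[j] = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r * r))
            pval[j] = 2.0 * sps.t.sf(abs(t), dof)
    return pcc, pval


def _u_statistic(ranks_a, n_a, n_b):
    return float(np.sum(ranks_a)) - n_a * (n_a + 1) / 2.0


def mann_whitney(a, b) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact enumeration (midranks) for total n <= 20, else the tie-corrected
    normal approximation.  Returns ``{"U": ..., "p": ..., "stars": ...}``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a, n_b)
    if n_a + n_b <= EXACT_MAX_N:
        mu = n_a * n_b / 2.0
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = float(np.sum(ranks[list(idx)])) - n_a * (n_a + 1) / 2.0
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        p = float(res.pvalue)
    return {"U": u_obs, "p": float(min(p, 1.0)),
            "stars": significance_stars(p)}


def significance_stars(p: float) -> str:
    """Star mapping used in the figures: *, **, *** at 0.05/0.01/0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationReport:
    """Partial-correlation matrix of biomarkers x parameters with p-values."""

    pcc: pd.DataFrame
    pvalues: pd.DataFrame

    def to_csv(self, path_pcc, path_p=None):
        self.pcc.to_csv(path_pcc)
        if path_p is not None:
            self.pvalues.to_csv(path_p)


def correlation_report(param_table: pd.DataFrame,
                       biomarker_table: pd.DataFrame,
                       method: str = "linear") -> CorrelationReport:
    """Partial correlation of every biomarker column against every parameter."""
    X = param_table.to_numpy(dtype=float)
    pcc_rows, p_rows = {}, {}
    for col in biomarker_table.columns:
        y = biomarker_table[col].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        pcc, pv = partial_correlation(X[ok], y[ok], method=method)
        pcc_rows[col] = pcc
        p_rows[col] = pv
    idx = list(param_table.columns)
    return CorrelationReport(
        pcc=pd.DataFrame(pcc_rows, index=idx).T,
        pvalues=pd.DataFrame(p_rows, index=idx).T,
    )
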