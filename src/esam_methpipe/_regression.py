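"""Shared least-squares machinery for the per-probe and per-pair models.

All differential and meQTL models in this package are ordinary least
squares with a common design matrix across many responses, so fits are
vectorised: one ``(X'X)^{-1}X'`` is computed per design and applied to the
whole response matrix, with per-response residual variances feeding the
Wald/t statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def encode_column(values: pd.Series) -> np.ndarray:
    """Encode one covariate column as a numeric vector.

    Numeric columns pass through; two-level categoricals (e.g. sex M/F)
    become 0/1 indicators with levels taken in sorted order.
    """
    if pd.api.types.is_numeric_dtype(values):
        v = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"covariate {values.name!r} has missing/non-finite values")
        return v
    levels = sorted(pd.unique(values.astype(str)))
    if len(levels) > 2:
        raise ValueError(
            f"categorical covariate {values.name!r} has >2 levels; encode it upstream"
        )
    return (values.astype(str) == levels[-1]).to_numpy(dtype=float)


def build_design(
    samples: pd.DataFrame,
    covariates,
    group_col: str | None = "group",
    group_levels=("NESAM", "ESAM"),
):
    """Build an OLS design matrix [intercept | covariates | group indicator].

    Returns ``(X, names, group_ix)`` where ``group_ix`` indexes the group
    column (None when ``group_col`` is None).  Collinear covariates are
    dropped with a warning; a rank-deficient design after dropping raises.
    """
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate {cov!r} not in sample sheet")
        cols.append(encode_column(samples[cov]))
        names.append(cov)
    group_ix = None
    if group_col is not None:
        g = samples[group_col].astype(str)
        levels = [l for l in group_levels if l in set(g)]
        if len(set(g)) < 2:
            raise ValueError(f"group column {group_col!r} is constant in this subset")
        ref = levels[0] if levels else sorted(set(g))[0]
        cols.append((g != ref).to_numpy(dtype=float))
        names.append(group_col)
        group_ix = len(names) - 1
    X = np.column_stack(cols)
    # drop collinear covariate columns (never intercept or group)
    while np.linalg.matrix_rank(X) < X.shape[1]:
        dropped = False
        for j in range(1, X.shape[1]):
            if group_ix is not None and j == group_ix:
                continue
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == Xr.shape[1] or np.linalg.matrix_rank(
                Xr
            ) == np.linalg.matrix_rank(X):
                logger.warning("dropping collinear covariate %r from design", names[j])
                X = Xr
                if group_ix is not None and j < group_ix:
                    group_ix -= 1
                del names[j]
                dropped = True
                break
        if not dropped:
            raise ValueError("design matrix is rank deficient (group collinear?)")
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError(
            f"too few samples ({X.shape[0]}) for design with {X.shape[1]} columns"
        )
    return X, names, group_ix


def ols_many(X: np.ndarray, Y: np.ndarray, coef_ix: int):
    """OLS of each column of ``Y`` on the shared design ``X``.

    Returns ``(coef, t, p, df)`` for the column ``coef_ix`` of the design:
    estimates, two-sided t statistics and p-values with ``n - k`` residual
    degrees of freedom.
    """
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ (X.T @ Y)
    resid = Y - X @ B
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[coef_ix, coef_ix])
    coef = B[coef_ix]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.where(coef == 0, 0.0, np.inf * np.sign(coef)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return coef, t, p, df
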