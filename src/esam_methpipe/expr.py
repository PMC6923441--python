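"""Methylation-expression correlation and exact correlation-test power.

Per CpG inside a significant cluster, Spearman correlations are computed
against the expression of every *expressed* gene within 10 kb, on both the
beta and the M scale.  A gene counts as expressed when its summarised
expression is at least twofold above the mean of the antigenomic control
probes (array probes matching no genomic sequence).  Context-level sign
tests (two-sided Wilcoxon signed rank on the correlation coefficients)
ask whether, e.g., promoter-proximal (TSS200) methylation is
systematically inversely related to expression.

:func:`correlation_power_exact` reproduces the exact post-hoc power of
the two-sided test of ``rho = 0`` for a bivariate normal sample: the
critical sample correlation comes from the null t transform with ``n - 2``
degrees of freedom, and power integrates the exact non-null density of
the sample correlation coefficient (the Gaussian hypergeometric form)
over the rejection region.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .study import MethylationStudy

logger = logging.getLogger(__name__)


def expressed_filter(
    expr: pd.DataFrame, antigenomic: pd.DataFrame | pd.Series, fold: float = 2.0
) -> set:
    """Genes whose mean expression is >= ``fold`` x the antigenomic mean.

    ``expr`` is genes x samples (one summarised value per gene per
    sample; multi-transcript genes must be collapsed upstream, e.g. by
    mean).  ``antigenomic`` holds the control-probe intensities (frame or
    flat values); their grand mean defines the background.  The boundary
    is inclusive: a gene exactly at ``fold x background`` is expressed.
    """
    bg = np.asarray(antigenomic, dtype=float)
    if bg.size == 0:
        raise ValueError("no antigenomic control probes provided")
    threshold = fold * float(np.nanmean(bg))
    means = expr.mean(axis=1)
    return set(means.index[means >= threshold])


def correlate(
    study: MethylationStudy,
    expr: pd.DataFrame,
    gene_map: Mapping[str, Sequence[str]],
    expressed: set,
    contexts: pd.Series | None = None,
) -> pd.DataFrame:
    """Spearman correlation per (CpG, expressed gene within 10 kb) pair.

    ``gene_map`` maps probe id -> candidate genes (already restricted to
    the cis window, e.g. via the cluster gene map).  Correlations are
    computed across the samples shared by the methylation and expression
    matrices, on the beta scale (``rho``) and the M scale (``rho_m``);
    the p-value is the standard t approximation for Spearman's statistic.
    """
    shared = study.beta.columns.intersection(expr.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    rows = []
    for cpg, genes in gene_map.items():
        if cpg not in study.beta.index:
            continue
        b = study.beta.loc[cpg, shared].to_numpy(dtype=float)
        m = study.m.loc[cpg, shared].to_numpy(dtype=float)
        for gene in genes:
            if gene not in expressed or gene not in expr.index:
                continue
            e = expr.loc[gene, shared].to_numpy(dtype=float)
            rho, p = stats.spearmanr(b, e)
            rho_m, _ = stats.spearmanr(m, e)
            rows.append(
                {
                    "cpg_id": cpg,
                    "gene": gene,
                    "context": contexts.get(cpg) if contexts is not None else None,
                    "rho": float(rho),
                    "rho_m": float(rho_m),
                    "p": float(p),
                    "n": len(shared),
                }
            )
    return pd.DataFrame(rows)


def context_sign_test(records: pd.DataFrame, context: str, value: str = "rho") -> dict:
    """Two-sided Wilcoxon signed-rank test of median rho = 0 in a context.

    Exact null distribution for n <= 25 (no ties/zeros), normal
    approximation with continuity correction otherwise.  Returns a dict
    with ``n``, ``statistic``, ``p`` and ``testable``.
    """
    vals = records.loc[records["context"] == context, value].dropna().to_numpy()
    n = len(vals)
    if n < 2:
        return {"context": context, "n": n, "statistic": None, "p": None, "testable": False}
    zeros = np.any(vals == 0)
    ties = len(np.unique(np.abs(vals[vals != 0]))) < np.count_nonzero(vals)
    method = "exact" if (n <= 25 and not zeros and not ties) else "approx"
    res = stats.wilcoxon(vals, correction=(method == "approx"), method=method)
    return {
        "context": context,
        "n": n,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "testable": True,
    }


def _r_density(r, rho, n):
    """Exact density of the sample correlation coefficient of a size-``n``
    bivariate normal sample with population correlation ``rho``."""
    lg = special.gammaln(n - 1) - special.gammaln(n - 0.5)
    c = (n - 2) / np.sqrt(2.0 * np.pi) * np.exp(lg)
    return (
        c
        * (1.0 - rho**2) ** ((n - 1) / 2.0)
        * (1.0 - r**2) ** ((n - 4) / 2.0)
        * (1.0 - rho * r) ** ((3.0 - 2.0 * n) / 2.0)
        * special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    )


def correlation_critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical sample correlation for the exact test of rho = 0."""
    t_crit = stats.t.isf(alpha / 2.0, n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def correlation_power_exact(n: int, rho: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided bivariate-normal correlation test.

    Probability, under the exact non-null distribution of the sample
    correlation for population correlation ``rho`` and sample size ``n``,
    that ``|r|`` exceeds the two-sided critical value at level ``alpha``.
    Numerical integration to ~1e-8 absolute tolerance; at ``rho = 0`` the
    power equals ``alpha`` (size of the test).
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    rc = correlation_critical_r(n, alpha)
    lo, err_lo = integrate.quad(_r_density, -1.0, -rc, args=(rho, n), epsabs=1e-10, limit=200)
    hi, err_hi = integrate.quad(_r_density, rc, 1.0, args=(rho, n), epsabs=1e-10, limit=200)
    if err_lo + err_hi > 1e-6:
        logger.warning("power integration error %.2e above tolerance", err_lo + err_hi)
    return float(min(1.0, max(0.0, lo + hi)))


def power_percent(n: int, rho: float, alpha: float = 0.05) -> int:
    """Power as a whole percentage (conventional reporting)."""
    return int(round(100.0 * correlation_power_exact(n, rho, alpha)))
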