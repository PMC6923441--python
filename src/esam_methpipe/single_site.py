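"""Per-probe covariate-adjusted differential methylation testing.

The per-probe model is ``M_i = C a + Y b + e``: the (inverse-normal
transformed) M value at probe *i* regressed on a covariate matrix ``C``
(age, sex, principal/MDS components) and a case/control indicator ``Y``
(ESAM = 1, NESAM = 0).  Inference on the group coefficient uses a
two-sided t test.  A second, identically designed OLS on the untransformed
beta scale yields the reported effect size ``beta_slope`` (covariate
adjusted ESAM - NESAM methylation difference in beta units).

Multiple-testing control is Benjamini-Hochberg for FDR and ``alpha / m``
for the Bonferroni threshold.  The genomic inflation factor lambda (median
association chi-square over its null median) is both a QC metric and, via
:func:`lambda_adjust`, a deflation device for cohort-specific statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._regression import build_design, ols_many
from .study import MethylationStudy, rank_inverse_normal

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

RESULT_COLUMNS = [
    "b_m",
    "beta_slope",
    "t_stat",
    "p",
    "fdr_q",
    "bonferroni_sig",
    "direction",
]


def fit_single_sites(
    study: MethylationStudy,
    covariates: Sequence[str] = ("age", "sex", "PC1"),
    group_col: str = "group",
    alpha: float = 0.05,
    transform: bool = True,
) -> pd.DataFrame:
    """Fit the single-probe differential methylation model at every probe.

    Returns a data frame indexed by probe id with columns ``b_m`` (group
    coefficient on the transformed-M scale), ``beta_slope`` (group effect
    in beta units from a parallel OLS on the beta scale), ``t_stat``, ``p``
    (two-sided t), ``fdr_q`` (Benjamini-Hochberg), ``bonferroni_sig``
    (``p < alpha / n_probes``) and ``direction`` (sign of ``beta_slope``).
    """
    if study.n_samples < len(covariates) + 3:
        raise ValueError(
            f"{study.n_samples} samples too few for {len(covariates)} covariates"
        )
    X, _, gix = build_design(study.samples, covariates, group_col)
    M = study.m.to_numpy().T  # samples x probes
    Z = rank_inverse_normal(M, axis=0) if transform else M
    b_m, t, p, _ = ols_many(X, Z, gix)
    beta_slope, _, _, _ = ols_many(X, study.beta.to_numpy().T, gix)
    q = multipletests(p, method="fdr_bh")[1]
    res = pd.DataFrame(
        {
            "b_m": b_m,
            "beta_slope": beta_slope,
            "t_stat": t,
            "p": p,
            "fdr_q": q,
            "bonferroni_sig": p < alpha / len(p),
            "direction": np.sign(beta_slope).astype(int),
        },
        index=study.beta.index,
    )
    return res


def compute_pcs(study: MethylationStudy, n_components: int = 1, transform: bool = True) -> pd.DataFrame:
    """Principal components of the (transformed) M matrix, samples as
    observations; returned as columns ``PC1..PCn`` indexed by sample id.

    The leading component typically absorbs broad technical and sampling
    structure (e.g. geographic origin) and is used as a covariate.
    """
    M = study.m.to_numpy().T
    Z = rank_inverse_normal(M, axis=0) if transform else M
    Zc = Z - Z.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Zc, full_matrices=False)
    pcs = U[:, :n_components] * s[:n_components]
    return pd.DataFrame(
        pcs, index=study.samples.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )


class BonferroniThreshold(NamedTuple):
    raw: float
    rounded: float  # 2 significant digits, as conventionally printed


def adjust_pvalues(p, method: str = "BH", alpha: float = 0.05):
    """Multiple-testing adjustment.

    ``method="BH"`` returns the Benjamini-Hochberg step-up q-values;
    ``method="bonferroni"`` returns the family-wise threshold ``alpha / m``
    as a :class:`BonferroniThreshold` (raw and rounded to two significant
    digits).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method.upper() == "BH":
        return multipletests(p, method="fdr_bh")[1]
    if method.lower() == "bonferroni":
        raw = alpha / p.size
        return BonferroniThreshold(raw=raw, rounded=float(f"{raw:.1e}"))
    raise ValueError(f"unknown method {method!r}")


def genomic_inflation(p=None, chi2=None) -> float:
    """Genomic inflation factor: median association chi-square (1 df)
    divided by the null chi-square median (0.4549)."""
    if chi2 is None:
        if p is None:
            raise ValueError("provide p or chi2")
        p = np.asarray(p, dtype=float)
        chi2 = stats.chi2.isf(p, 1)
    chi2 = np.asarray(chi2, dtype=float)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def lambda_adjust(p, lam: float):
    """Deflate p-values by the genomic inflation factor.

    Each p is converted to its 1-df chi-square deviate, divided by
    ``lam``, and converted back.  ``lam = 1`` is the identity; ``lam > 1``
    can only make p-values larger.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    p = np.asarray(p, dtype=float)
    return stats.chi2.sf(stats.chi2.isf(p, 1) / lam, 1)


@dataclass
class ConcordanceReport:
    """Cross-cohort direction/magnitude agreement at a probe subset."""

    n_probes_compared: int
    n_same_direction: int
    binomial_p: float
    lambda_a: float
    lambda_b: float
    n_lambda_adjusted_sig_both: int
    excluded_age_probes: int

    @property
    def concordance(self) -> float:
        return self.n_same_direction / self.n_probes_compared


def cohort_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    probe_subset,
    age_probe_list=(),
    alpha: float = 0.05,
) -> ConcordanceReport:
    """Compare effect direction and deflated significance across cohorts.

    ``results_a``/``results_b`` are full per-cohort single-site tables
    (their complete p distributions define the per-cohort lambdas).
    Probes in ``age_probe_list`` (e.g. loci known to track age in buccal
    epithelium, when age could not be used as a covariate) are removed
    from ``probe_subset`` before comparison.  Direction agreement is
    tested against 0.5 with a two-sided exact binomial test; probes with
    lambda-adjusted p < ``alpha`` in both cohorts are counted.
    """
    subset = pd.Index(probe_subset)
    age = subset.intersection(pd.Index(age_probe_list))
    subset = subset.difference(age)
    subset = subset.intersection(results_a.index).intersection(results_b.index)
    if len(subset) == 0:
        raise ValueError("no probes left to compare after filtering")
    lam_a = genomic_inflation(results_a["p"])
    lam_b = genomic_inflation(results_b["p"])
    da = results_a.loc[subset, "direction"]
    db = results_b.loc[subset, "direction"]
    same = int(((da == db) & (da != 0)).sum())
    n = len(subset)
    binom_p = stats.binomtest(same, n, 0.5).pvalue
    pa = lambda_adjust(results_a.loc[subset, "p"], max(lam_a, 1.0))
    pb = lambda_adjust(results_b.loc[subset, "p"], max(lam_b, 1.0))
    both = int(((pa < alpha) & (pb < alpha)).sum())
    return ConcordanceReport(
        n_probes_compared=n,
        n_same_direction=same,
        binomial_p=float(binom_p),
        lambda_a=lam_a,
        lambda_b=lam_b,
        n_lambda_adjusted_sig_both=both,
        excluded_age_probes=len(age),
    )
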