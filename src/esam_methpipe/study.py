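"""Core data model and value transforms for array methylation studies.

The central container is :class:`MethylationStudy`, which joins a beta-value
matrix (methylation fraction per probe per sample), a sample sheet (disease
group, timepoint, demographic covariates), and a probe annotation table
(genomic position, gene links with gene-context labels, QC flags).

Beta values live in (0, 1); the analysis scale is the M value,
``M = log2(beta / (1 - beta))``.  Differential testing is performed on
rank-based inverse-normal transformed M values (the classical
``(r - 3/8) / (n + 1/4)`` Blom quantile mapping), which robustifies the
per-probe t tests against the heavy-tailed, bimodal distributions typical
of array methylation data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Gene-context vocabulary used by the 450K-style annotation.  IGR
#: (intergenic region) is reserved for probes with no gene link.
GENE_CONTEXTS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "IGR")

#: Probe-level QC exclusion flags.
PROBE_FLAGS = frozenset(
    {
        "control",
        "high_detection_fail",
        "low_bead",
        "sex_chrom",
        "cross_reactive",
        "snp_at_sbe",
        "snp_near_sbe",
        "age_sensitive",
    }
)

#: Clamp applied when a beta value sits exactly on {0, 1}.
BETA_EPS = 1e-6


def beta_to_m(beta):
    """Convert methylation beta values to M values (log2 odds).

    Values exactly on the closed boundary {0, 1} are clamped to
    ``[BETA_EPS, 1 - BETA_EPS]`` with a warning; values outside [0, 1]
    raise.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0) or np.any(beta > 1):
        raise ValueError("beta values must lie in [0, 1]")
    if np.any(beta <= 0) or np.any(beta >= 1):
        warnings.warn(
            "beta values on the {0,1} boundary clamped to "
            f"[{BETA_EPS}, {1 - BETA_EPS}]",
            stacklevel=2,
        )
        beta = np.clip(beta, BETA_EPS, 1 - BETA_EPS)
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``beta = 2**m / (1 + 2**m)``."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("M values must be finite")
    # logaddexp2 keeps the tails accurate for |m| large
    return np.exp2(m - np.logaddexp2(0.0, m))


def rank_inverse_normal(values, axis=-1):
    """Rank-based inverse normal (Blom) transform along ``axis``.

    Ranks (average rank on ties) are mapped to standard normal quantiles at
    ``(r - 3/8) / (n + 1/4)``.  The output is rank-preserving with mean
    approximately zero.  A constant vector maps to all zeros (a warning is
    emitted, since it carries no information for downstream regression).
    """
    a = np.asarray(values, dtype=float)
    n = a.shape[axis]
    if n < 3:
        raise ValueError("rank_inverse_normal requires at least 3 values")
    if not np.all(np.isfinite(a)):
        raise ValueError("missing/non-finite values are not supported")
    ranks = stats.rankdata(a, axis=axis)
    out = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    const = np.ptp(a, axis=axis) == 0
    if np.any(const):
        warnings.warn("constant vector(s) transformed to all zeros", stacklevel=2)
    return out


@dataclass
class MethylationStudy:
    """Beta matrix + sample sheet + probe annotation, axis-consistent.

    Parameters
    ----------
    beta
        Probes x samples data frame of methylation fractions in (0, 1).
    samples
        Sample sheet indexed by sample id.  Required columns: ``group``
        (ESAM/NESAM), ``timepoint`` (DC/DL).  Covariates (age, sex, PCs or
        MDS components) are additional numeric/categorical columns.
    probes
        Probe annotation indexed by probe id.  Required columns:
        ``chromosome``, ``position`` (1-based bp), ``gene_links`` (tuple of
        ``(gene, context)`` pairs, empty for intergenic probes) and
        ``flags`` (frozenset drawn from :data:`PROBE_FLAGS`).

    Probes are kept sorted by (chromosome, position); the beta matrix is
    reordered to match on construction.
    """

    beta: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self):
        if not self.beta.index.equals(self.probes.index):
            if set(self.beta.index) != set(self.probes.index):
                raise ValueError("beta matrix and probe annotation disagree on probe ids")
            self.probes = self.probes.loc[self.beta.index]
        if not self.beta.columns.equals(self.samples.index):
            if set(self.beta.columns) != set(self.samples.index):
                raise ValueError("beta matrix and sample sheet disagree on sample ids")
            self.samples = self.samples.loc[self.beta.columns]
        for col in ("group", "timepoint"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet misses required column {col!r}")
            if self.samples[col].isna().any():
                raise ValueError(f"sample sheet column {col!r} has missing values")
        for col in ("chromosome", "position"):
            if col not in self.probes.columns:
                raise ValueError(f"probe annotation misses required column {col!r}")
        if (self.probes["position"] <= 0).any():
            raise ValueError("probe positions must be positive (1-based)")
        vals = self.beta.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("beta matrix must be complete and finite")
        if vals.size and (vals.min() <= 0 or vals.max() >= 1):
            raise ValueError("beta values must lie strictly in (0, 1)")
        order = self.probes.sort_values(["chromosome", "position"]).index
        if not order.equals(self.probes.index):
            self.probes = self.probes.loc[order]
            self.beta = self.beta.loc[order]

    @cached_property
    def m(self) -> pd.DataFrame:
        """M-value matrix, ``log2(beta / (1 - beta))`` elementwise."""
        return pd.DataFrame(
            beta_to_m(self.beta.to_numpy()),
            index=self.beta.index,
            columns=self.beta.columns,
        )

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    def subset_samples(self, sample_ids) -> "MethylationStudy":
        sample_ids = pd.Index(sample_ids)
        return MethylationStudy(
            beta=self.beta[sample_ids], samples=self.samples.loc[sample_ids], probes=self.probes
        )

    def subset_probes(self, probe_ids) -> "MethylationStudy":
        probe_ids = pd.Index(probe_ids)
        return MethylationStudy(
            beta=self.beta.loc[probe_ids],
            samples=self.samples,
            probes=self.probes.loc[probe_ids],
        )

    def select_samples(self, **criteria) -> "MethylationStudy":
        """Subset samples by sample-sheet column equality, e.g.
        ``study.select_samples(timepoint="DC")``."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            mask &= self.samples[col] == val
        return self.subset_samples(self.samples.index[mask])


@dataclass
class FilterReport:
    """Per-flag removal counts from :func:`filter_probes`."""

    n_before: int
    n_after: int
    removed_by_flag: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_before - self.n_after


def filter_probes(study: MethylationStudy, exclude_flags: Iterable[str]):
    """Drop probes carrying any of ``exclude_flags``.

    Returns ``(filtered_study, FilterReport)``.  The report counts, per
    flag, how many removed probes carried it (a probe with several flags is
    counted under each).  Unknown flag names raise.  The operation is
    idempotent and order-independent over flags.
    """
    exclude = set(exclude_flags)
    unknown = exclude - PROBE_FLAGS
    if unknown:
        raise ValueError(f"unknown probe flag(s): {sorted(unknown)}")
    flags = study.probes["flags"] if "flags" in study.probes.columns else pd.Series(
        [frozenset()] * study.n_probes, index=study.probes.index
    )
    hit = flags.map(lambda f: bool(set(f) & exclude))
    removed = flags[hit]
    counts = {
        fl: int(removed.map(lambda f: fl in f).sum())
        for fl in sorted(exclude)
        if any(fl in f for f in removed)
    }
    keep = study.probes.index[~hit]
    report = FilterReport(n_before=study.n_probes, n_after=len(keep), removed_by_flag=counts)
    logger.info(
        "filter_probes: removed %d of %d probes (%s)",
        report.n_removed,
        report.n_before,
        counts or "no flags matched",
    )
    if len(keep) == 0:
        return (
            MethylationStudy(
                beta=study.beta.loc[keep], samples=study.samples, probes=study.probes.loc[keep]
            ),
            report,
        )
    return study.subset_probes(keep), report
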