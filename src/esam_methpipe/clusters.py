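"""Direction-consistent CpG clustering (DMC calling) and cluster tests.

Methylation at neighbouring CpGs is spatially correlated, so single-probe
hits are consolidated into differentially methylated clusters (DMCs):

1. probes whose covariate-adjusted beta-scale effect lies strictly inside
   the open interval (-0.05, +0.05) are removed (ambiguous direction at
   the margin of association);
2. the retained probes are scanned left-to-right per chromosome and
   chained into maximal non-overlapping runs in which consecutive probes
   are at most 10 kb apart and share the effect sign; singletons are
   allowed;
3. the single-site regression is repeated with the per-sample mean of the
   member probes' transformed M values as the dependent variable, with a
   Bonferroni threshold of ``alpha / n_clusters``.

The gap rule is applied between consecutive *retained* probes: filtered
probes neither bridge nor break a chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._regression import build_design, ols_many
from .study import MethylationStudy, rank_inverse_normal

logger = logging.getLogger(__name__)

DEFAULT_EFFECT_WINDOW = (-0.05, 0.05)
DEFAULT_MAX_GAP = 10_000


@dataclass
class ClusterSet:
    """A partition of the retained probes into maximal same-direction runs.

    ``clusters`` is indexed by cluster id with columns ``chromosome``,
    ``start``, ``end`` (min/max member position, bp), ``direction`` (+/-1),
    ``n_probes``, ``n_marginal_nearby`` (filtered probes falling within
    the span extended by the gap) and ``marginal_flag``
    (``n_marginal_nearby > 2``).  ``members`` maps probe id -> cluster id.
    """

    clusters: pd.DataFrame
    members: pd.Series
    dropped_probes: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_ids(self, cluster_id) -> pd.Index:
        return self.members.index[self.members == cluster_id]


def build_clusters(
    single_site_results: pd.DataFrame,
    annotation: pd.DataFrame,
    effect_window=DEFAULT_EFFECT_WINDOW,
    max_gap: int = DEFAULT_MAX_GAP,
) -> ClusterSet:
    """Chain retained probes into maximal <=``max_gap`` same-direction runs.

    ``single_site_results`` must carry ``beta_slope``; ``annotation``
    supplies ``chromosome`` and ``position``.  Probes with
    ``lo < beta_slope < hi`` (open interval) are dropped first; a slope on
    the boundary is retained.  A new cluster starts on chromosome change,
    on a gap above ``max_gap`` between consecutive retained probes, or on
    a sign flip.
    """
    lo, hi = effect_window
    df = single_site_results.join(annotation[["chromosome", "position"]], how="inner")
    if len(df) != len(single_site_results):
        raise ValueError("annotation does not cover all result probes")
    ordered = df.sort_values(["chromosome", "position"])
    if not ordered.index.equals(df.index):
        logger.info("build_clusters: input not position-sorted; sorting internally")
        df = ordered
    slope = df["beta_slope"].to_numpy()
    dropped = (slope > lo) & (slope < hi)
    kept = df[~dropped]
    chrom = kept["chromosome"].to_numpy()
    pos = kept["position"].to_numpy()
    sign = np.sign(kept["beta_slope"].to_numpy()).astype(int)
    n = len(kept)
    new_cluster = np.ones(n, dtype=bool)
    if n > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        close = (pos[1:] - pos[:-1]) <= max_gap
        same_sign = sign[1:] == sign[:-1]
        new_cluster[1:] = ~(same_chrom & close & same_sign)
    cluster_num = np.cumsum(new_cluster)
    width = len(str(max(cluster_num.max(), 1))) if n else 1
    ids = np.array([f"DMC{c:0{width}d}" for c in cluster_num])
    members = pd.Series(ids, index=kept.index, name="cluster_id")
    grp = kept.groupby(members)
    clusters = pd.DataFrame(
        {
            "chromosome": grp["chromosome"].first(),
            "start": grp["position"].min(),
            "end": grp["position"].max(),
            "direction": grp["beta_slope"].first().pipe(np.sign).astype(int),
            "n_probes": grp.size(),
        }
    )
    clusters.index.name = "cluster_id"
    # retrospective annotation of filtered "marginal" probes near each span
    marg = df[dropped]
    counts = np.zeros(len(clusters), dtype=int)
    for i, (_, row) in enumerate(clusters.iterrows()):
        m = (
            (marg["chromosome"] == row["chromosome"])
            & (marg["position"] >= row["start"] - max_gap)
            & (marg["position"] <= row["end"] + max_gap)
        )
        counts[i] = int(m.sum())
    clusters["n_marginal_nearby"] = counts
    clusters["marginal_flag"] = clusters["n_marginal_nearby"] > 2
    return ClusterSet(
        clusters=clusters, members=members, dropped_probes=list(df.index[dropped])
    )


def fit_clusters(
    study: MethylationStudy,
    cluster_set: ClusterSet,
    covariates: Sequence[str] = ("age", "sex", "PC1"),
    group_col: str = "group",
    alpha: float = 0.05,
    transform: bool = True,
) -> pd.DataFrame:
    """Cluster-level regression on the mean transformed M of member probes.

    Uses the same design matrix as the single-site analysis; the response
    for a cluster is the per-sample mean of its members' (transformed) M
    values.  Returns a frame indexed by cluster id with ``n_probes``,
    ``span_bp``, ``mean_m_slope``, ``t_stat``, ``p``, ``fdr_q`` and
    ``bonferroni_sig`` (threshold ``alpha / n_clusters``).
    """
    if cluster_set.n_clusters == 0:
        return pd.DataFrame(
            columns=[
                "n_probes",
                "span_bp",
                "mean_m_slope",
                "t_stat",
                "p",
                "fdr_q",
                "bonferroni_sig",
            ]
        )
    missing = cluster_set.members.index.difference(study.m.index)
    if len(missing):
        raise ValueError(f"{len(missing)} cluster member probes absent from study")
    X, _, gix = build_design(study.samples, covariates, group_col)
    M = study.m.loc[cluster_set.members.index].to_numpy().T
    Z = rank_inverse_normal(M, axis=0) if transform else M
    zdf = pd.DataFrame(Z.T, index=cluster_set.members.index, columns=study.samples.index)
    means = zdf.groupby(cluster_set.members).mean()  # clusters x samples
    means = means.loc[cluster_set.clusters.index]
    slope, t, p, _ = ols_many(X, means.to_numpy().T, gix)
    q = multipletests(p, method="fdr_bh")[1]
    res = pd.DataFrame(
        {
            "n_probes": cluster_set.clusters["n_probes"],
            "span_bp": cluster_set.clusters["end"] - cluster_set.clusters["start"],
            "mean_m_slope": slope,
            "t_stat": t,
            "p": p,
            "fdr_q": q,
            "bonferroni_sig": p < alpha / len(p),
        },
        index=cluster_set.clusters.index,
    )
    return res


def cluster_overlap_report(
    cluster_results: pd.DataFrame,
    single_results: pd.DataFrame,
    cluster_set: ClusterSet,
    fdr: float = 0.01,
) -> dict:
    """Cross-tabulate Bonferroni-significant single sites against clusters.

    Reports how many Bonferroni single sites fall inside Bonferroni- or
    FDR-significant clusters, how many fall outside both, and how many
    Bonferroni clusters contain no Bonferroni single site.
    """
    single_sig = single_results.index[single_results["bonferroni_sig"]]
    bonf_clusters = set(cluster_results.index[cluster_results["bonferroni_sig"]])
    fdr_clusters = set(cluster_results.index[cluster_results["fdr_q"] < fdr])
    assigned = cluster_set.members.reindex(single_sig)
    in_bonf = assigned.isin(bonf_clusters)
    in_fdr = assigned.isin(fdr_clusters)
    clusters_with_sig = set(assigned[in_bonf].unique())
    report = {
        "n_single_bonferroni": int(len(single_sig)),
        "n_single_in_bonferroni_clusters": int(in_bonf.sum()),
        "n_single_in_fdr_clusters": int((~in_bonf & in_fdr).sum()),
        "n_single_unclustered_or_nonsig": int((~in_bonf & ~in_fdr).sum()),
        "n_bonferroni_clusters": int(len(bonf_clusters)),
        "n_bonferroni_clusters_without_single_hit": int(
            len(bonf_clusters - clusters_with_sig)
        ),
        "overlap_fraction": float(in_bonf.sum() / len(single_sig)) if len(single_sig) else float("nan"),
    }
    return report
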