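"""Gene mapping, hypergeometric and permutation-based enrichment scores.

Covers the candidate-gene machinery downstream of DMC calling:

* :func:`map_genes` — RefSeq-style genes overlapping or within 10 kb of a
  cluster span (or probe) become candidate genes.
* :func:`context_enrichment` — per gene-context hypergeometric tests of
  enrichment and depletion of DMC probes against the tested background.
* :func:`ontology_enrichment` — generic hypergeometric over-representation
  of a gene list in user-supplied ontology gene sets.
* :func:`efo_score` / :func:`efo_permutation` — GWAS-catalog disease-trait
  (EFO) projection of candidate genes scored by genome-wide-significant
  SNP counts, with a resampling null for the joint (#genes, #EFO terms)
  statistic.
* :func:`hpo_overlap_z` — Z-score of candidate overlap with a phenotype
  (HPO) gene set against size-matched random draws.
* :func:`sgo_kgo_score` — the quartile-weighted score combining study
  gene-ontology (SGO) ranks with phenotype gene-ontology (KGO) ranks.
* :func:`effect_by_context` — Kruskal-Wallis omnibus plus pairwise Dunn
  tests of effect sizes across gene-context categories.

All permutation procedures take an explicit seed and report empirical
p-values both as the raw exceedance fraction ``b/n`` and in the
positively biased but valid ``(b+1)/(n+1)`` convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import ClusterSet

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000


@dataclass
class GeneMap:
    """cluster/probe id -> candidate genes within the cis window."""

    mapping: Mapping[str, tuple]
    background: tuple = ()

    @property
    def all_genes(self) -> list:
        out = set()
        for genes in self.mapping.values():
            out.update(genes)
        return sorted(out)


def map_genes(
    targets,
    genes: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    window: int = DEFAULT_WINDOW,
) -> GeneMap:
    """Link genes overlapping or within ``window`` bp of each target.

    ``targets`` is a :class:`ClusterSet` (spans) or a sequence of probe ids
    (points, requires ``annotation``).  ``genes`` is a table with columns
    ``gene``, ``chromosome``, ``start``, ``end`` (1-based, inclusive).
    When gene coordinates are unavailable the probe-level ``gene_links``
    annotation is used as a fallback (with a warning).  Distance is
    ``|pos_a - pos_b|`` in bp; "within 10 kb" means <= 10,000.
    """
    if isinstance(targets, ClusterSet):
        spans = targets.clusters[["chromosome", "start", "end"]]
    else:
        if annotation is None:
            raise ValueError("probe-id targets require an annotation table")
        ann = annotation.loc[pd.Index(targets)]
        spans = pd.DataFrame(
            {
                "chromosome": ann["chromosome"],
                "start": ann["position"],
                "end": ann["position"],
            }
        )
    if genes is None:
        if annotation is None or "gene_links" not in getattr(annotation, "columns", ()):
            raise ValueError("need a gene coordinate table or probe gene_links")
        warnings.warn(
            "no gene coordinates; falling back to probe-level gene_links",
            stacklevel=2,
        )
        mapping = {}
        if isinstance(targets, ClusterSet):
            for cid in targets.clusters.index:
                links = annotation.loc[targets.member_ids(cid), "gene_links"]
                mapping[cid] = tuple(sorted({g for l in links for g, _ in l}))
        else:
            for pid in spans.index:
                mapping[pid] = tuple(
                    sorted({g for g, _ in annotation.loc[pid, "gene_links"]})
                )
        return GeneMap(mapping=mapping)
    mapping = {}
    for tid, row in spans.iterrows():
        sel = genes[
            (genes["chromosome"] == row["chromosome"])
            & (genes["end"] >= row["start"] - window)
            & (genes["start"] <= row["end"] + window)
        ]
        mapping[tid] = tuple(sorted(sel["gene"].unique()))
    return GeneMap(mapping=mapping, background=tuple(sorted(genes["gene"].unique())))


def hypergeom_tails(k: int, N: int, K: int, n: int) -> tuple[float, float]:
    """(enrichment, depletion) tail probabilities for drawing ``k`` marked
    items in ``n`` draws from ``N`` items of which ``K`` are marked."""
    p_enrich = float(stats.hypergeom.sf(k - 1, N, K, n))
    p_deplete = float(stats.hypergeom.cdf(k, N, K, n))
    return p_enrich, p_deplete


def context_enrichment(
    selected_contexts: Sequence[str], background_contexts: Sequence[str]
) -> pd.DataFrame:
    """Hypergeometric enrichment/depletion of gene contexts in a probe subset.

    ``selected_contexts``/``background_contexts`` are the per-probe context
    labels of the subset (e.g. probes inside significant DMCs) and of all
    tested probes.  Both tails are reported per category.
    """
    bg = pd.Series(list(background_contexts))
    sel = pd.Series(list(selected_contexts))
    if len(sel) == 0 or len(bg) == 0:
        return pd.DataFrame(
            columns=["k_hits", "K_set", "n_drawn", "N_universe", "p_enrich", "p_deplete"]
        )
    N, n = len(bg), len(sel)
    rows = {}
    for ctx in sorted(bg.unique()):
        K = int((bg == ctx).sum())
        k = int((sel == ctx).sum())
        pe, pdep = hypergeom_tails(k, N, K, n)
        rows[ctx] = {
            "k_hits": k,
            "K_set": K,
            "n_drawn": n,
            "N_universe": N,
            "p_enrich": pe,
            "p_deplete": pdep,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def ontology_enrichment(
    candidate_genes: Sequence[str],
    ontology_map: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation p per ontology gene set.

    Candidates and sets are intersected with ``universe`` first.  Returns
    a frame indexed by ontology id with ``k``, ``K``, ``p`` (enrichment
    tail), sorted ascending by p.
    """
    uni = set(universe)
    cand = set(candidate_genes) & uni
    N, n = len(uni), len(cand)
    rows = {}
    for oid, genes in ontology_map.items():
        gs = set(genes) & uni
        k = len(cand & gs)
        rows[oid] = {"k": k, "K": len(gs), "p": hypergeom_tails(k, N, len(gs), n)[0]}
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out.sort_values("p") if len(out) else out


def efo_score(
    candidate_genes: Sequence[str], efo_catalog: pd.DataFrame, min_genes: int = 2
) -> pd.DataFrame:
    """Project candidate genes onto GWAS-catalog EFO disease traits.

    ``efo_catalog`` has columns ``efo_id``, ``efo_label``, ``gene``,
    ``snp_count`` (genome-wide-significant SNPs mapped to the gene under
    that trait) and optionally ``parent_efo``.  Only EFO terms hit by at
    least ``min_genes`` distinct candidate genes are retained; the score of
    each (EFO, gene) cell is the catalog SNP count.
    """
    cand = set(candidate_genes)
    hits = efo_catalog[efo_catalog["gene"].isin(cand)]
    if hits.empty:
        return hits.copy()
    counts = hits.groupby("efo_id")["gene"].nunique()
    keep = counts.index[counts >= min_genes]
    return hits[hits["efo_id"].isin(keep)].reset_index(drop=True)


@dataclass
class EfoPermutationResult:
    g_obs: int
    e_obs: int
    empirical_p: float  # raw exceedance fraction, as conventionally printed
    empirical_p_adjusted: float  # (b+1)/(n+1)
    efo_recurrence: pd.Series = field(repr=False, default=None)
    n_perms: int = 0
    seed: int | None = None


def efo_permutation(
    candidate_genes: Sequence[str],
    universe: Sequence[str],
    efo_catalog: pd.DataFrame,
    n_perms: int = 10_000,
    seed: int | None = None,
    min_genes: int = 2,
) -> EfoPermutationResult:
    """Joint-tail resampling null for the EFO projection.

    Each permutation draws ``len(candidate_genes)`` genes without
    replacement from ``universe`` and records ``G`` (drawn genes with any
    catalog entry) and ``E`` (EFO terms hit by >= ``min_genes`` drawn
    genes).  The empirical probability is the fraction of permutations
    with ``G >= g_obs`` and ``E >= e_obs``.  Per-EFO recurrence (fraction
    of permutations in which the term was hit >= ``min_genes`` times) is
    also reported.
    """
    universe = pd.Index(pd.unique(pd.Series(list(universe))))
    cand = set(candidate_genes)
    if len(cand) > len(universe):
        raise ValueError("more candidates requested than genes in the universe")
    cat = efo_catalog[efo_catalog["gene"].isin(universe)]
    efos = pd.Index(sorted(cat["efo_id"].unique()))
    gene_pos = {g: i for i, g in enumerate(universe)}
    efo_pos = {e: i for i, e in enumerate(efos)}
    # CSR-style gene -> EFO adjacency over the universe
    adj = [[] for _ in range(len(universe))]
    for g, e in zip(cat["gene"], cat["efo_id"]):
        adj[gene_pos[g]].append(efo_pos[e])
    adj = [np.asarray(a, dtype=np.intp) for a in adj]
    in_catalog = np.array([len(a) > 0 for a in adj])

    def joint_stat(idx):
        g = int(in_catalog[idx].sum())
        if len(efos) == 0:
            return g, 0, np.zeros(0, dtype=bool)
        lists = [adj[i] for i in idx if len(adj[i])]
        if lists:
            counts = np.bincount(np.concatenate(lists), minlength=len(efos))
        else:
            counts = np.zeros(len(efos), dtype=int)
        hit = counts >= min_genes
        return g, int(hit.sum()), hit

    cand_idx = np.array([gene_pos[g] for g in cand if g in gene_pos], dtype=np.intp)
    g_obs, e_obs, _ = joint_stat(cand_idx)
    rng = np.random.default_rng(seed)
    size = len(cand)
    exceed = 0
    recurrence = np.zeros(len(efos))
    for _ in range(n_perms):
        idx = rng.choice(len(universe), size=size, replace=False)
        g, e, hit = joint_stat(idx)
        if g >= g_obs and e >= e_obs:
            exceed += 1
        recurrence += hit
    return EfoPermutationResult(
        g_obs=g_obs,
        e_obs=e_obs,
        empirical_p=exceed / n_perms,
        empirical_p_adjusted=(exceed + 1) / (n_perms + 1),
        efo_recurrence=pd.Series(recurrence / n_perms, index=efos),
        n_perms=n_perms,
        seed=seed,
    )


@dataclass
class OverlapZScore:
    observed: int
    null_mean: float
    null_sd: float
    z: float  # NaN when the null is degenerate (sd == 0)
    empirical_p: float
    empirical_p_adjusted: float
    degenerate: bool
    n_perms: int
    seed: int | None = None


def hpo_overlap_z(
    candidate_genes: Sequence[str],
    hpo_gene_set: Sequence[str],
    universe: Sequence[str],
    n_perms: int = 10_000,
    seed: int | None = None,
) -> OverlapZScore:
    """Overlap of candidates with a phenotype gene set vs random draws.

    The null resamples size-matched gene sets from ``universe`` and counts
    their overlap with ``hpo_gene_set`` (the overlap count of a uniform
    without-replacement draw, i.e. a hypergeometric variate, sampled
    ``n_perms`` times).  Reports ``Z = (obs - mean) / sd`` plus the
    one-sided empirical p of seeing at least the observed overlap.
    """
    uni = set(universe)
    cand = set(candidate_genes) & uni
    hpo = set(hpo_gene_set) & uni
    obs = len(cand & hpo)
    rng = np.random.default_rng(seed)
    null = rng.hypergeometric(len(hpo), len(uni) - len(hpo), len(cand), size=n_perms)
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    degenerate = sd == 0
    if degenerate:
        warnings.warn("degenerate permutation null (sd = 0); Z undefined", stacklevel=2)
    b = int((null >= obs).sum())
    return OverlapZScore(
        observed=obs,
        null_mean=mean,
        null_sd=sd,
        z=float("nan") if degenerate else (obs - mean) / sd,
        empirical_p=b / n_perms,
        empirical_p_adjusted=(b + 1) / (n_perms + 1),
        degenerate=degenerate,
        n_perms=n_perms,
        seed=seed,
    )


def _quartile_values(pvals: pd.Series) -> pd.Series:
    """Map p-values to quartile scores {1, 0.75, 0.5, 0.25}, best first.

    Ranking is ascending by p with average ranks on ties; the quartile
    bucket is ``ceil(4 * rank / n)``.
    """
    p = pd.Series(pvals, dtype=float)
    ranks = stats.rankdata(p.to_numpy(), method="average")
    bucket = np.clip(np.ceil(4.0 * ranks / len(p)), 1, 4)
    return pd.Series((5.0 - bucket) / 4.0, index=p.index)


def sgo_kgo_score(
    sgo_pvals: pd.Series,
    kgo_pvals: pd.Series,
    phenotype_gene_map: Mapping[str, Sequence[str]],
    sgo_gene_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Quartile-weighted SGO-KGO score per (study ontology, phenotype).

    ``quartile_score = q_SGO * q_KGO`` where each ``q`` is the term's
    significance quartile value (1 for the top quartile, then 0.75, 0.5,
    0.25) in its own ranked list; an SGO absent from the KGO list scores 0.
    ``proportion_score(phenotype, SGO)`` is the fraction of the
    phenotype's genes that map to the SGO's gene set.  The final score is
    the arithmetic mean of the two and lies in [0, 1]; the maximum 1 is
    reached by an SGO in the top quartile of both lists whose gene set
    covers all of the phenotype's genes.  Phenotypes with an empty gene
    set are flagged (proportion undefined).
    """
    q_sgo = _quartile_values(sgo_pvals)
    q_kgo = _quartile_values(kgo_pvals)
    rows = []
    for sgo in q_sgo.index:
        qs = q_sgo[sgo] * q_kgo[sgo] if sgo in q_kgo.index else 0.0
        sgo_genes = set(sgo_gene_map.get(sgo, ()))
        for pheno, pgenes in phenotype_gene_map.items():
            pgenes = set(pgenes)
            if not pgenes:
                rows.append(
                    {
                        "sgo_id": sgo,
                        "phenotype_id": pheno,
                        "quartile_score": qs,
                        "proportion_score": float("nan"),
                        "final": float("nan"),
                        "flagged": True,
                    }
                )
                continue
            prop = len(pgenes & sgo_genes) / len(pgenes)
            rows.append(
                {
                    "sgo_id": sgo,
                    "phenotype_id": pheno,
                    "quartile_score": qs,
                    "proportion_score": prop,
                    "final": (qs + prop) / 2.0,
                    "flagged": False,
                }
            )
    return pd.DataFrame(rows)


def dunn_pairwise(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's rank-sum z tests for all group pairs (unadjusted p).

    Uses joint ranks with the tie correction
    ``sum(t^3 - t) / (12 (N - 1))`` subtracted from ``N (N + 1) / 12``.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    all_vals = np.concatenate(values)
    N = len(all_vals)
    ranks = stats.rankdata(all_vals)
    sizes = [len(v) for v in values]
    mean_ranks, start = [], 0
    for s in sizes:
        mean_ranks.append(ranks[start : start + s].mean())
        start += s
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {"group_a": a, "group_b": b, "z": z, "p": 2.0 * stats.norm.sf(abs(z))}
        )
    return pd.DataFrame(rows)


def effect_by_context(
    single_site_results: pd.DataFrame,
    contexts: pd.Series,
    signed: bool = False,
    min_group_size: int = 2,
) -> dict:
    """Kruskal-Wallis omnibus + Dunn pairwise tests of effect sizes by
    gene-context category.

    ``contexts`` maps probe id -> context label.  The tested value is
    ``|beta_slope|`` (or the signed slope with ``signed=True``).
    """
    vals = single_site_results["beta_slope"]
    if not signed:
        vals = vals.abs()
    df = pd.DataFrame({"value": vals, "context": contexts.reindex(vals.index)}).dropna()
    groups = {
        ctx: sub["value"].to_numpy()
        for ctx, sub in df.groupby("context")
        if len(sub) >= min_group_size
    }
    if len(groups) < 2:
        raise ValueError("need at least two context groups for the omnibus test")
    h, p = stats.kruskal(*groups.values())
    return {
        "kruskal_h": float(h),
        "kruskal_p": float(p),
        "dunn": dunn_pairwise(groups),
        "group_sizes": {k: len(v) for k, v in groups.items()},
    }
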