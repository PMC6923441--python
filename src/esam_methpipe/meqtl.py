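"""Genotype QC and condition-dependent cis-meQTL analysis.

A cis-meQTL is a SNP whose minor-allele dosage (0/1/2) is linearly
associated with methylation at a CpG within 10 kb.  Two models are fit
per SNP-CpG pair within a sample subset:

* additive:    ``probe value = covariates + dosage``
* interaction: ``probe value = covariates + dosage + group + dosage x group``

where the probe value is the inverse-normal transformed M value (same
preprocessing as the differential analysis) and group is the ESAM/NESAM
disease state.  A pair is classified *nutrition sensitive* when it is a
nominal meQTL among acute (DC) samples, shows a significant dosage-by-group
interaction in DC, and shows no such interaction among recovered (DL)
samples — the signature of a genotype effect on methylation that only
manifests under acute nutritional stress.

Genotype QC mirrors standard array practice: per-SNP missingness,
Hardy-Weinberg exact test (conditional on allele counts), and minor allele
frequency; per-sample missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats, special

from ._regression import build_design, encode_column
from .clusters import ClusterSet
from .study import MethylationStudy, rank_inverse_normal

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000


@dataclass
class GenotypeMatrix:
    """Dosage matrix (SNPs x samples, minor-allele counts, NaN = missing)
    plus per-SNP chromosome/position."""

    dosages: pd.DataFrame
    snps: pd.DataFrame  # index snp_id; columns chromosome, position

    def __post_init__(self):
        if not self.dosages.index.equals(self.snps.index):
            if set(self.dosages.index) != set(self.snps.index):
                raise ValueError("dosage matrix and SNP table disagree on snp ids")
            self.snps = self.snps.loc[self.dosages.index]
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    def maf(self) -> pd.Series:
        f = self.dosages.mean(axis=1, skipna=True) / 2.0
        return np.minimum(f, 1.0 - f)

    def missingness(self) -> pd.Series:
        return self.dosages.isna().mean(axis=1)

    def hwe_p(self) -> pd.Series:
        out = {}
        for snp, row in self.dosages.iterrows():
            v = row.dropna().to_numpy()
            out[snp] = hwe_exact_test(
                int((v == 1).sum()), int((v == 2).sum()), int((v == 0).sum())
            )
        return pd.Series(out)


def hwe_exact_test(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Hardy-Weinberg exact test conditional on allele counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities not exceeding that of the observed
    configuration (the standard exact test of Wigginton, Cutler & Abecasis).
    Returns 1.0 for monomorphic data.
    """
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_rare + n_hom_common
    rare = 2 * min(n_hom_rare, n_hom_common) + n_het
    if n == 0 or rare == 0:
        return 1.0

    def log_prob(h):  # P(n_het = h | allele counts), up to the shared constant
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            h * np.log(2.0)
            - special.gammaln(h + 1)
            - special.gammaln(hom_r + 1)
            - special.gammaln(hom_c + 1)
        )

    hets = np.arange(rare % 2, rare + 1, 2)
    logs = np.array([log_prob(int(h)) for h in hets])
    probs = np.exp(logs - special.logsumexp(logs))
    obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


@dataclass
class QcReport:
    n_snps_before: int
    n_snps_after: int
    n_removed_missing: int
    n_removed_hwe: int
    n_removed_maf: int
    n_samples_before: int
    n_samples_after: int


def genotype_qc(
    geno: GenotypeMatrix,
    max_missing: float = 0.02,
    hwe_alpha: float = 1e-3,
    min_maf: float = 0.05,
    excluded_samples: Sequence[str] = (),
):
    """Apply standard SNP and sample filters; returns (geno, QcReport).

    Removes samples listed in ``excluded_samples`` (e.g. a precomputed
    relatedness/inbreeding exclusion list) and samples with dosage
    missingness above ``max_missing``; then drops SNPs with missingness
    above ``max_missing``, Hardy-Weinberg exact p < ``hwe_alpha``, or
    MAF < ``min_maf`` (monomorphic SNPs have MAF 0 and are removed).
    """
    d = geno.dosages.drop(columns=list(excluded_samples), errors="ignore")
    samp_miss = d.isna().mean(axis=0)
    keep_samples = samp_miss.index[samp_miss <= max_missing]
    d = d[keep_samples]
    g = GenotypeMatrix(dosages=d, snps=geno.snps)
    miss = g.missingness()
    maf = g.maf()
    hwe = g.hwe_p()
    bad_miss = miss > max_missing
    bad_hwe = ~bad_miss & (hwe < hwe_alpha)
    bad_maf = ~bad_miss & ~bad_hwe & (maf < min_maf)
    keep = ~(bad_miss | bad_hwe | bad_maf)
    report = QcReport(
        n_snps_before=len(d),
        n_snps_after=int(keep.sum()),
        n_removed_missing=int(bad_miss.sum()),
        n_removed_hwe=int(bad_hwe.sum()),
        n_removed_maf=int(bad_maf.sum()),
        n_samples_before=geno.dosages.shape[1],
        n_samples_after=len(keep_samples),
    )
    logger.info("genotype_qc: %s", report)
    return GenotypeMatrix(dosages=d[keep], snps=geno.snps[keep]), report


def cis_pairs(geno: GenotypeMatrix, targets, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """All same-chromosome SNP-target pairs within ``window`` bp.

    ``targets`` is a probe annotation frame (``chromosome``/``position``;
    point distance) or a :class:`ClusterSet` (distance to the cluster
    span, zero inside).  Returns a frame with ``snp_id``, ``cpg_id`` and
    ``distance``; the boundary ``distance == window`` is included.
    """
    if isinstance(targets, ClusterSet):
        tgt = targets.clusters[["chromosome", "start", "end"]]
    else:
        tgt = pd.DataFrame(
            {
                "chromosome": targets["chromosome"],
                "start": targets["position"],
                "end": targets["position"],
            }
        )
    rows = []
    for chrom, snps in geno.snps.groupby("chromosome"):
        t = tgt[tgt["chromosome"] == chrom]
        if t.empty:
            continue
        spos = snps["position"].to_numpy()[:, None]
        dist = np.maximum(
            0, np.maximum(t["start"].to_numpy()[None, :] - spos, spos - t["end"].to_numpy()[None, :])
        )
        si, ti = np.nonzero(dist <= window)
        for a, b in zip(si, ti):
            rows.append((snps.index[a], t.index[b], int(dist[a, b])))
    return pd.DataFrame(rows, columns=["snp_id", "cpg_id", "distance"])


def _subset_ids(study: MethylationStudy, subset: Mapping[str, str] | None):
    if not subset:
        return study.samples.index
    mask = pd.Series(True, index=study.samples.index)
    for col, val in subset.items():
        mask &= study.samples[col] == val
    return study.samples.index[mask]


def _pair_ols(y, covar_cols, extra_cols, coef_ix):
    X = np.column_stack([np.ones(len(y))] + covar_cols + extra_cols)
    n, k = X.shape
    df = n - k
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return None
    b = xtx_inv @ (X.T @ y)
    resid = y - X @ b
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.maximum(max(sigma2, 0.0) * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return b, se, t, np.clip(p, np.finfo(float).tiny, 1.0), df


def fit_meqtl(
    study: MethylationStudy,
    geno: GenotypeMatrix,
    pairs: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "PC1"),
    subset: Mapping[str, str] | None = None,
    transform: bool = True,
) -> pd.DataFrame:
    """Additive model per pair: probe value ~ covariates + dosage.

    Fits within the sample ``subset`` (e.g. ``{"timepoint": "DC"}``).
    Pairs with fewer than two distinct observed dosages, or with too few
    samples for the design, are flagged ``untested`` rather than fit.
    Returns one row per pair with ``beta1`` (M change per minor allele on
    the transformed scale), ``p_main``, ``n`` and ``status``.
    """
    ids = _subset_ids(study, subset)
    samples = study.samples.loc[ids]
    M = study.m[ids].to_numpy().T
    Z = rank_inverse_normal(M, axis=0) if transform else M
    zdf = pd.DataFrame(Z.T, index=study.m.index, columns=ids)
    covar_cols = [encode_column(samples[c]) for c in covariates]
    n_params = 2 + len(covar_cols)
    dos = geno.dosages[ids]
    rows = []
    for snp, cpg in zip(pairs["snp_id"], pairs["cpg_id"]):
        d = dos.loc[snp].to_numpy(dtype=float)
        obs = ~np.isnan(d)
        n_used = int(obs.sum())
        record = {"snp_id": snp, "cpg_id": cpg, "n": n_used}
        if len(np.unique(d[obs])) < 2 or n_used < n_params + 1:
            record.update({"beta1": np.nan, "se": np.nan, "t": np.nan, "p_main": np.nan, "status": "untested"})
            rows.append(record)
            continue
        y = zdf.loc[cpg].to_numpy()[obs]
        cc = [c[obs] for c in covar_cols]
        fit = _pair_ols(y, cc, [d[obs]], coef_ix=-1)
        if fit is None:
            record.update({"beta1": np.nan, "se": np.nan, "t": np.nan, "p_main": np.nan, "status": "untested"})
        else:
            b, se, t, p, _ = fit
            record.update(
                {"beta1": b[-1], "se": se[-1], "t": t[-1], "p_main": p[-1], "status": "ok"}
            )
        rows.append(record)
    return pd.DataFrame(rows)


def fit_interaction(
    study: MethylationStudy,
    geno: GenotypeMatrix,
    pairs: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "PC1"),
    group_col: str = "group",
    group_levels=("NESAM", "ESAM"),
    subset: Mapping[str, str] | None = None,
    transform: bool = True,
) -> pd.DataFrame:
    """Interaction model per pair: ~ covariates + dosage + group + dosage:group.

    ``p_interaction`` is the two-sided t (Wald) p on the product term.
    Per-group dosage slopes are also reported (reference group slope and
    reference + interaction for the alternate group).  Raises when the
    group indicator is constant within the subset.
    """
    ids = _subset_ids(study, subset)
    samples = study.samples.loc[ids]
    g = samples[group_col].astype(str)
    if g.nunique() < 2:
        raise ValueError("interaction inestimable: group constant in subset")
    ref = group_levels[0] if group_levels[0] in set(g) else sorted(set(g))[0]
    gind = (g != ref).to_numpy(dtype=float)
    M = study.m[ids].to_numpy().T
    Z = rank_inverse_normal(M, axis=0) if transform else M
    zdf = pd.DataFrame(Z.T, index=study.m.index, columns=ids)
    covar_cols = [encode_column(samples[c]) for c in covariates]
    n_params = 4 + len(covar_cols)
    dos = geno.dosages[ids]
    rows = []
    for snp, cpg in zip(pairs["snp_id"], pairs["cpg_id"]):
        d = dos.loc[snp].to_numpy(dtype=float)
        obs = ~np.isnan(d)
        n_used = int(obs.sum())
        record = {"snp_id": snp, "cpg_id": cpg, "n": n_used}
        untested = {
            "slope_ref": np.nan,
            "slope_alt": np.nan,
            "beta_interaction": np.nan,
            "p_interaction": np.nan,
            "status": "untested",
        }
        if (
            len(np.unique(d[obs])) < 2
            or n_used < n_params + 1
            or len(np.unique(gind[obs])) < 2
        ):
            record.update(untested)
            rows.append(record)
            continue
        y = zdf.loc[cpg].to_numpy()[obs]
        cc = [c[obs] for c in covar_cols]
        dd, gg = d[obs], gind[obs]
        fit = _pair_ols(y, cc, [dd, gg, dd * gg], coef_ix=-1)
        if fit is None:
            record.update(untested)
        else:
            b, se, t, p, _ = fit
            record.update(
                {
                    "slope_ref": b[-3],
                    "slope_alt": b[-3] + b[-1],
                    "beta_interaction": b[-1],
                    "p_interaction": p[-1],
                    "status": "ok",
                }
            )
        rows.append(record)
    return pd.DataFrame(rows)


def merge_meqtl_fits(additive: pd.DataFrame, interaction: pd.DataFrame) -> pd.DataFrame:
    """Join additive (p_main) and interaction (p_interaction) fits on pair."""
    keys = ["snp_id", "cpg_id"]
    a = additive.set_index(keys)[["n", "beta1", "p_main", "status"]]
    b = interaction.set_index(keys)[
        ["slope_ref", "slope_alt", "beta_interaction", "p_interaction", "status"]
    ].rename(columns={"status": "status_interaction"})
    return a.join(b, how="inner").reset_index()


def classify_nutrition_sensitive(
    dc_records: pd.DataFrame,
    dl_records: pd.DataFrame,
    p_main_cut: float = 0.05,
    p_int_cut: float = 0.05,
    stringent_p: float = 1e-4,
) -> pd.DataFrame:
    """Classify each SNP-CpG pair as nutrition sensitive / insensitive.

    ``dc_records`` carries ``p_main`` and ``p_interaction`` from the acute
    (DC) fits (see :func:`merge_meqtl_fits`); ``dl_records`` carries
    ``p_interaction`` from the recovered (DL) fits.  A pair is

    * ``untested`` if either fit is missing/failed or the DC additive
      screen ``p_main <= p_main_cut`` is not passed (it is not a DC meQTL);
    * ``nutrition_sensitive`` if, in addition, DC
      ``p_interaction <= p_int_cut`` and DL ``p_interaction > p_int_cut``;
    * ``insensitive`` otherwise.

    ``stringent`` marks sensitive pairs whose DC interaction also passes
    ``p_interaction < stringent_p``.
    """
    keys = ["snp_id", "cpg_id"]
    dc = dc_records.set_index(keys)
    dl = dl_records.set_index(keys)[["p_interaction"]].rename(
        columns={"p_interaction": "p_interaction_dl"}
    )
    out = dc.join(dl, how="left").reset_index()
    screened = (out["p_main"] <= p_main_cut) & out["p_main"].notna()
    complete = out["p_interaction"].notna() & out["p_interaction_dl"].notna()
    sensitive = (
        screened
        & complete
        & (out["p_interaction"] <= p_int_cut)
        & (out["p_interaction_dl"] > p_int_cut)
    )
    out["classification"] = "untested"
    out.loc[screened & complete, "classification"] = "insensitive"
    out.loc[sensitive, "classification"] = "nutrition_sensitive"
    out["stringent"] = sensitive & (out["p_interaction"] < stringent_p)
    return out.sort_values(keys).reset_index(drop=True)


def reference_overlap_fisher(
    n_sensitive: int,
    k_sensitive_in_ref: int,
    n_insensitive: int,
    k_insensitive_in_ref: int,
    method: str = "minlike",
):
    """Two-sided Fisher exact test of reference-catalog overlap.

    Tests the 2x2 table ``[[k_s, n_s - k_s], [k_i, n_i - k_i]]``.  The
    default two-sided rule sums all tables with point probability not
    exceeding the observed one (the convention of mainstream
    implementations); ``method="doubling"`` doubles the smaller one-sided
    tail (capped at 1).  Returns ``(odds_ratio, p)``.
    """
    table = [
        [k_sensitive_in_ref, n_sensitive - k_sensitive_in_ref],
        [k_insensitive_in_ref, n_insensitive - k_insensitive_in_ref],
    ]
    if min(min(r) for r in table) < 0:
        raise ValueError("counts must be non-negative and k <= n")
    if method == "minlike":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    if method == "doubling":
        odds, p_less = stats.fisher_exact(table, alternative="less")
        _, p_greater = stats.fisher_exact(table, alternative="greater")
        return float(odds), float(min(1.0, 2.0 * min(p_less, p_greater)))
    raise ValueError(f"unknown method {method!r}")
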