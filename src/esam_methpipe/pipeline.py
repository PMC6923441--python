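"""End-to-end orchestration of the simulated analysis.

``run_pipeline`` executes the stages in dependency order on a synthetic
study: simulate -> probe filter -> single-site differential methylation
(acute/DC) -> DMC clustering and cluster tests (DC and DL) -> gene
mapping and enrichment scores -> cis-meQTL classification -> expression
correlation.  Every stage's headline counts land in one JSON report;
given the same config the report is byte identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters, enrichment, expr, meqtl, simulate, single_site
from .study import filter_probes

logger = logging.getLogger(__name__)

_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Validated top-level run configuration.

    Unknown keys in a config file are rejected before any computation.
    The single ``seed`` fans out deterministically to per-stage seeds.
    """

    seed: int = 0
    out_dir: str | None = None
    covariates: tuple = ("age", "sex", "PC1")
    group_col: str = "group"
    alpha: float = 0.05
    fdr: float = 0.01
    cis_window: int = 10_000
    effect_window: tuple = (-0.05, 0.05)
    max_gap: int = 10_000
    n_perms: int = 1_000
    exclude_flags: tuple = (
        "control",
        "high_detection_fail",
        "low_bead",
        "sex_chrom",
        "cross_reactive",
        "snp_at_sbe",
        "snp_near_sbe",
    )
    simulation: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for tup_key in ("covariates", "effect_window", "exclude_flags"):
            if tup_key in d and isinstance(d[tup_key], list):
                d[tup_key] = tuple(d[tup_key])
        cfg = cls(**d)
        sim_known = {f.name for f in dataclasses.fields(simulate.SimulationConfig)}
        sim_unknown = set(cfg.simulation) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation key(s): {sorted(sim_unknown)}")
        return cfg

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and optionally writes) the report."""
    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", config.stage_seed("simulate"))
    sim_cfg = simulate.SimulationConfig(**sim_kwargs)
    study, truth = simulate.simulate_study(sim_cfg)
    geno, study = simulate.simulate_genotypes(sim_cfg, study, truth)
    gene_table = study.probes.attrs.get("genes")

    study_f, filt_report = filter_probes(study, config.exclude_flags)
    if study_f.n_probes == 0:
        raise RuntimeError("no probes remain after QC filtering")

    dc = study_f.select_samples(timepoint="DC")
    dl = study_f.select_samples(timepoint="DL")
    single_dc = single_site.fit_single_sites(
        dc, config.covariates, config.group_col, alpha=config.alpha
    )
    single_dl = single_site.fit_single_sites(
        dl, config.covariates, config.group_col, alpha=config.alpha
    )
    lam_dc = single_site.genomic_inflation(single_dc["p"])
    bonf = single_site.adjust_pvalues(single_dc["p"], "bonferroni", config.alpha)

    cs_dc = clusters.build_clusters(
        single_dc, study_f.probes, config.effect_window, config.max_gap
    )
    cres_dc = clusters.fit_clusters(
        dc, cs_dc, config.covariates, config.group_col, alpha=config.alpha
    )
    cs_dl = clusters.build_clusters(
        single_dl, study_f.probes, config.effect_window, config.max_gap
    )
    cres_dl = clusters.fit_clusters(
        dl, cs_dl, config.covariates, config.group_col, alpha=config.alpha
    )
    overlap = clusters.cluster_overlap_report(cres_dc, single_dc, cs_dc, fdr=config.fdr)

    # recovery vs truth
    true_probes = truth.true_probe_ids.intersection(single_dc.index)
    fdr_hits = single_dc.index[single_dc["fdr_q"] < config.fdr]
    recovered = len(fdr_hits.intersection(true_probes))
    false_pos = len(fdr_hits.difference(true_probes))
    sig = single_dc.loc[fdr_hits]

    # enrichment on Bonferroni-significant clusters
    bonf_clusters = cres_dc.index[cres_dc["bonferroni_sig"]]
    cs_sig = clusters.ClusterSet(
        clusters=cs_dc.clusters.loc[bonf_clusters],
        members=cs_dc.members[cs_dc.members.isin(bonf_clusters)],
        dropped_probes=cs_dc.dropped_probes,
    )
    gmap = enrichment.map_genes(cs_sig, genes=gene_table, window=config.cis_window)
    candidates = gmap.all_genes
    ctx_lookup = study_f.probes["gene_links"].map(lambda l: l[0][1] if l else "IGR")
    ctx = enrichment.context_enrichment(
        ctx_lookup.loc[cs_sig.members.index], ctx_lookup
    )
    bundle = simulate.simulate_genesets(sim_cfg)
    efo_perm = enrichment.efo_permutation(
        candidates,
        bundle.universe,
        bundle.efo_catalog,
        n_perms=config.n_perms,
        seed=config.stage_seed("efo"),
    ) if candidates else None
    first_hpo = next(iter(bundle.hpo_map))
    hpo_z = enrichment.hpo_overlap_z(
        candidates,
        bundle.hpo_map[first_hpo],
        bundle.universe,
        n_perms=config.n_perms,
        seed=config.stage_seed("hpo"),
    )
    try:
        ebc = enrichment.effect_by_context(single_dc, ctx_lookup)
        effect_ctx = {"kruskal_h": ebc["kruskal_h"], "kruskal_p": ebc["kruskal_p"]}
    except ValueError:
        effect_ctx = None

    # meQTLs
    geno_qc, qc_report = meqtl.genotype_qc(geno)
    pairs = meqtl.cis_pairs(geno_qc, study_f.probes, window=config.cis_window)
    dc_add = meqtl.fit_meqtl(
        study_f, geno_qc, pairs, config.covariates, subset={"timepoint": "DC"}
    )
    dc_int = meqtl.fit_interaction(
        study_f, geno_qc, pairs, config.covariates, config.group_col,
        subset={"timepoint": "DC"},
    )
    dl_int = meqtl.fit_interaction(
        study_f, geno_qc, pairs, config.covariates, config.group_col,
        subset={"timepoint": "DL"},
    )
    classified = meqtl.classify_nutrition_sensitive(
        meqtl.merge_meqtl_fits(dc_add, dc_int), dl_int
    )
    class_counts = classified["classification"].value_counts().to_dict()
    truth_pairs = truth.meqtl_pairs
    planted_int = set(
        map(tuple, truth_pairs.loc[truth_pairs["kind"] == "interaction", ["snp_id", "cpg_id"]].to_numpy())
    )
    called = set(
        map(
            tuple,
            classified.loc[
                classified["classification"] == "nutrition_sensitive", ["snp_id", "cpg_id"]
            ].to_numpy(),
        )
    )
    meqtl_sensitivity = (
        len(called & planted_int) / len(planted_int) if planted_int else float("nan")
    )

    # expression correlation at probes within significant clusters
    expr_mat, controls = simulate.simulate_expression(
        study_f, truth, seed=config.stage_seed("expr")
    )
    expressed = expr.expressed_filter(expr_mat, controls)
    probe_genes = {
        pid: [g for g, _ in study_f.probes.loc[pid, "gene_links"]]
        for pid in cs_sig.members.index
    }
    corr = expr.correlate(
        study_f.select_samples(timepoint="DC"), expr_mat, probe_genes, expressed,
        contexts=ctx_lookup,
    )
    sign_tests = [
        expr.context_sign_test(corr, c)
        for c in (corr["context"].dropna().unique() if len(corr) else [])
    ]

    report = {
        "provenance": {
            "version": _VERSION,
            "seed": config.seed,
            "config_hash": hashlib.sha256(
                json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
        },
        "filter": {
            "n_before": filt_report.n_before,
            "n_after": filt_report.n_after,
            "removed_by_flag": dict(filt_report.removed_by_flag),
        },
        "single_site": {
            "n_probes": int(len(single_dc)),
            "n_fdr_significant": int(len(fdr_hits)),
            "n_bonferroni_significant": int(single_dc["bonferroni_sig"].sum()),
            "bonferroni_threshold": bonf.rounded,
            "lambda": round(lam_dc, 2),
            "mean_abs_beta_slope_significant": (
                float(sig["beta_slope"].abs().mean()) if len(sig) else None
            ),
            "frac_hypomethylated_significant": (
                float((sig["direction"] < 0).mean()) if len(sig) else None
            ),
            "n_true_recovered_fdr": recovered,
            "n_true_planted": int(len(true_probes)),
            "n_false_positive_fdr": false_pos,
            "n_dl_fdr_significant": int((single_dl["fdr_q"] < config.fdr).sum()),
        },
        "clusters": {
            "n_clusters_dc": int(cs_dc.n_clusters),
            "n_clusters_dl": int(cs_dl.n_clusters),
            "n_bonferroni_dmcs": int(cres_dc["bonferroni_sig"].sum()),
            "n_fdr_dmcs": int((cres_dc["fdr_q"] < config.fdr).sum()),
            "n_bonferroni_dmcs_dl": int(cres_dl["bonferroni_sig"].sum()),
            "overlap": overlap,
        },
        "enrichment": {
            "n_candidate_genes": len(candidates),
            "context_table": ctx.to_dict(orient="index") if len(ctx) else {},
            "efo": (
                {
                    "g_obs": efo_perm.g_obs,
                    "e_obs": efo_perm.e_obs,
                    "empirical_p": efo_perm.empirical_p,
                }
                if efo_perm
                else None
            ),
            "hpo_z": None if hpo_z.degenerate else round(hpo_z.z, 3),
            "effect_by_context": effect_ctx,
        },
        "meqtl": {
            "qc": dataclasses.asdict(qc_report),
            "n_cis_pairs": int(len(pairs)),
            "classification_counts": {k: int(v) for k, v in class_counts.items()},
            "interaction_sensitivity": meqtl_sensitivity,
        },
        "expression": {
            "n_expressed_genes": len(expressed),
            "n_correlations": int(len(corr)),
            "sign_tests": sign_tests,
        },
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, default=_jsonify))
        single_dc.to_csv(out / "single_site_dc.tsv", sep="\t")
        cres_dc.to_csv(out / "clusters_dc.tsv", sep="\t")
        classified.to_csv(out / "meqtl_classified.tsv", sep="\t", index=False)
        if len(corr):
            corr.to_csv(out / "expr_corr.tsv", sep="\t", index=False)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
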