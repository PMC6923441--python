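"""Synthetic methylation studies with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-probe baseline methylation is logit-normal — a baseline M value is
  drawn per probe and sample-level M values scatter around it with
  homoscedastic Gaussian noise (``noise_sd_m``);
* probe positions are laid down cluster-first: blocks of 2-10 probes with
  intra-block gaps of 50-2,000 bp, separated by inter-block gaps above
  10 kb, so that genuinely co-methylated runs are chainable by the 10 kb
  rule and distinct blocks are not;
* group effects (ESAM vs NESAM, acute samples only) are injected on the
  beta scale — a shift of ``true_effect_beta`` with a shared sign across
  all probes of each affected block — and then transformed, because
  effect sizes are reported in beta units while testing happens on the M
  scale;
* covariates (age, sex, PC1) act additively on the M scale with
  configured slopes;
* meQTL SNPs dose methylation additively (``meqtl_slope_m`` per minor
  allele, all samples) or in an interaction-only fashion (effect confined
  to acute ESAM samples); SNP positions fall within 10 kb of their target
  CpG;
* gene-set universes (EFO catalog, HPO term -> genes, plain ontologies)
  are drawn uniformly under the null, with optional planting of hit
  genes.

Randomness comes from a single seed; per-component generators are derived
deterministically from it (NumPy ``SeedSequence`` spawning, PCG64
streams), so equal seeds give bit-identical outputs on all platforms.
Every simulation returns a truth ledger for recovery tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .meqtl import GenotypeMatrix
from .study import GENE_CONTEXTS, MethylationStudy, beta_to_m, m_to_beta

logger = logging.getLogger(__name__)

_BETA_CLAMP = (0.001, 0.999)


@dataclass
class GeneSetConfig:
    """Sizes of the simulated gene-set universes.

    Defaults mirror the scale of a 450K-style study: a ~20,622-gene
    probe-linked universe and a ~24,094-gene cluster-linked universe.
    """

    n_genes: int = 20_622
    n_genes_cluster_universe: int = 24_094
    n_efos: int = 40
    efo_genes_range: tuple = (2, 30)
    snp_count_mean: float = 3.0
    n_hpo_terms: int = 10
    hpo_genes_range: tuple = (20, 200)
    n_ontologies: int = 60
    ontology_genes_range: tuple = (10, 100)


@dataclass
class SimulationConfig:
    """Study-scale parameters of the synthetic generator.

    The defaults are the conditions of the emulated study design: 150
    acutely ill (DC) children per disease group, ~10,000 probes in 2-10
    probe blocks across 10 chromosomes, a handful of truly differential
    blocks shifted by 0.05 beta units (hypomethylated in ESAM with
    probability ``prob_hypo``), M-scale residual noise, and additive plus
    interaction-only cis-meQTLs at 0.4 M per minor allele.
    """

    n_samples_per_group: int = 150
    n_dl_samples_per_group: int = 25
    n_probes: int = 10_000
    n_chromosomes: int = 10
    intra_cluster_gap_bp: tuple = (50, 2_000)
    inter_cluster_gap_mean_bp: float = 50_000.0
    block_size_range: tuple = (2, 10)
    n_true_dmcs: int = 10
    true_effect_beta: float = 0.05
    prob_hypo: float = 0.9
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.02, "sex": 0.1, "PC1": 0.2}
    )
    noise_sd_m: float = 0.3
    baseline_m_sd: float = 2.0
    flagged_fraction: float = 0.02
    n_snps: int = 200
    maf_range: tuple = (0.05, 0.5)
    n_additive_meqtls: int = 5
    n_interaction_meqtls: int = 5
    meqtl_slope_m: float = 0.4
    genesets: GeneSetConfig = field(default_factory=GeneSetConfig)
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_samples_per_group",
            "n_probes",
            "n_chromosomes",
            "n_snps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.true_effect_beta < 0.5:
            raise ValueError("true_effect_beta must lie in (0, 0.5)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_true_dmcs < 0:
            raise ValueError("n_true_dmcs must be non-negative")


@dataclass
class TruthTable:
    """Ground-truth ledger: which probes/pairs carry real effects.

    ``probes`` is indexed by probe id with ``is_differential``,
    ``true_direction`` (+/-1, 0 for nulls) and ``cluster_id`` (the
    generating block; every differential probe belongs to exactly one).
    ``meqtl_pairs`` lists planted SNP-CpG pairs with their kind
    (``additive``/``interaction``) and true slope; interaction-only pairs
    have additive slope 0 in the reference (NESAM) group.
    """

    probes: pd.DataFrame
    meqtl_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["snp_id", "cpg_id", "kind", "true_slope"]
        )
    )

    @property
    def true_probe_ids(self) -> pd.Index:
        return self.probes.index[self.probes["is_differential"]]


def _rng(config: SimulationConfig, component: int) -> np.random.Generator:
    # deterministic per-component stream derived from the single seed
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(component,)))


def _layout_probes(config: SimulationConfig, rng) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster-first probe layout: returns (annotation, block ids)."""
    lo_b, hi_b = config.block_size_range
    lo_g, hi_g = config.intra_cluster_gap_bp
    sizes = []
    total = 0
    while total < config.n_probes:
        s = int(rng.integers(lo_b, hi_b + 1))
        s = min(s, config.n_probes - total)
        sizes.append(s)
        total += s
    n_blocks = len(sizes)
    block_chrom = np.sort(rng.integers(1, config.n_chromosomes + 1, size=n_blocks))
    chroms, positions, blocks = [], [], []
    cursor: dict[int, int] = {}
    for b, (size, ch) in enumerate(zip(sizes, block_chrom)):
        start = cursor.get(ch, 0) + 10_001 + int(rng.exponential(config.inter_cluster_gap_mean_bp))
        pos = start
        for _ in range(size):
            chroms.append(f"chr{ch}")
            positions.append(pos)
            blocks.append(b)
            pos += int(rng.integers(lo_g, hi_g + 1))
        cursor[ch] = positions[-1]
    ids = [f"cg{i:08d}" for i in range(config.n_probes)]
    ann = pd.DataFrame(
        {"chromosome": chroms, "position": positions}, index=pd.Index(ids, name="probe_id")
    )
    return ann, np.asarray(blocks)


def _assign_genes(ann: pd.DataFrame, blocks: np.ndarray, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One synthetic gene per block (80% of blocks); returns updated
    annotation (gene_links, flags placeholder) and a gene coordinate table."""
    gene_rows = []
    links = []
    contexts = [c for c in GENE_CONTEXTS if c != "IGR"]
    block_gene: dict[int, tuple] = {}
    for b in np.unique(blocks):
        if rng.random() < 0.8:
            sel = ann[blocks == b]
            gname = f"G{b:05d}"
            start = int(sel["position"].min()) - int(rng.integers(0, 5_000))
            end = int(sel["position"].max()) + int(rng.integers(0, 5_000))
            gene_rows.append(
                {
                    "gene": gname,
                    "chromosome": sel["chromosome"].iloc[0],
                    "start": max(1, start),
                    "end": end,
                }
            )
            block_gene[b] = gname
    for pid, b in zip(ann.index, blocks):
        if b in block_gene:
            ctx = contexts[int(rng.integers(0, len(contexts)))]
            links.append(((block_gene[b], ctx),))
        else:
            links.append(())
    ann = ann.copy()
    ann["gene_links"] = links
    return ann, pd.DataFrame(gene_rows)


def _sample_sheet(config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    i = 0
    for timepoint, n_per in (
        ("DC", config.n_samples_per_group),
        ("DL", config.n_dl_samples_per_group),
    ):
        for group in ("ESAM", "NESAM"):
            for _ in range(n_per):
                age = (
                    float(rng.uniform(0.5, 5.0))
                    if timepoint == "DC"
                    else float(rng.uniform(18.0, 40.0))
                )
                rows.append(
                    {
                        "sample_id": f"S{i:04d}",
                        "group": group,
                        "timepoint": timepoint,
                        "age": age,
                        "sex": "M" if rng.random() < 0.5 else "F",
                        "cohort": "Jamaica" if rng.random() < 0.5 else "Malawi",
                        "PC1": float(rng.normal()),
                    }
                )
                i += 1
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_study(config: SimulationConfig) -> tuple[MethylationStudy, TruthTable]:
    """Generate a complete methylation study plus its truth ledger.

    Deterministic given ``config.seed``: the same config yields
    bit-identical matrices.  Beta values are strictly inside (0, 1) and
    satisfy ``M = log2(beta / (1 - beta))`` exactly.  Group effects (beta
    scale, clamped to (0.001, 0.999) with a logged warning if clamping
    occurs) are confined to the probes of ``n_true_dmcs`` randomly chosen
    multi-probe blocks and to acute (DC) samples, with one shared sign
    per block.
    """
    rng = _rng(config, 0)
    ann, blocks = _layout_probes(config, rng)
    ann, genes = _assign_genes(ann, blocks, rng)
    samples = _sample_sheet(config, rng)

    block_sizes = pd.Series(blocks).value_counts()
    eligible = block_sizes.index[block_sizes >= 2].to_numpy()
    if config.n_true_dmcs > len(eligible):
        raise ValueError("not enough multi-probe blocks for the requested true DMCs")
    true_blocks = rng.choice(eligible, size=config.n_true_dmcs, replace=False)
    directions = np.where(rng.random(config.n_true_dmcs) < config.prob_hypo, -1, 1)
    block_dir = dict(zip(true_blocks.tolist(), directions.tolist()))

    is_diff = np.isin(blocks, true_blocks)
    true_dir = np.array([block_dir.get(b, 0) for b in blocks])

    # probe QC flags on a small fraction of null probes only
    flags = [frozenset()] * config.n_probes
    flaggable = np.flatnonzero(~is_diff)
    n_flag = int(round(config.flagged_fraction * config.n_probes))
    flag_vocab = ("cross_reactive", "sex_chrom", "snp_at_sbe", "low_bead")
    for ix in rng.choice(flaggable, size=min(n_flag, len(flaggable)), replace=False):
        flags[ix] = frozenset({flag_vocab[int(rng.integers(0, len(flag_vocab)))]})
    ann["flags"] = flags

    n_samples = len(samples)
    m0 = rng.normal(0.0, config.baseline_m_sd, size=config.n_probes)
    base_beta = m_to_beta(m0)
    is_dc = (samples["timepoint"] == "DC").to_numpy()
    is_esam = (samples["group"] == "ESAM").to_numpy()
    effect_on = (is_dc & is_esam)[None, :] * is_diff[:, None]  # probes x samples
    target_beta = base_beta[:, None] + effect_on * true_dir[:, None] * config.true_effect_beta
    clamped = (target_beta < _BETA_CLAMP[0]) | (target_beta > _BETA_CLAMP[1])
    if clamped.any():
        logger.warning(
            "group effect pushed %d probe/sample betas outside %s; clamped",
            int(clamped.sum()),
            _BETA_CLAMP,
        )
        target_beta = np.clip(target_beta, *_BETA_CLAMP)
    mu = beta_to_m(target_beta)
    cov_effects = dict(config.covariate_effects)
    for cov, slope in cov_effects.items():
        if cov == "sex":
            x = (samples["sex"] == "M").to_numpy(dtype=float)
        else:
            x = samples[cov].to_numpy(dtype=float)
        mu = mu + slope * x[None, :]
    M = mu + rng.normal(0.0, config.noise_sd_m, size=(config.n_probes, n_samples))
    beta = pd.DataFrame(m_to_beta(M), index=ann.index, columns=samples.index)

    truth_probes = pd.DataFrame(
        {
            "is_differential": is_diff,
            "true_direction": true_dir,
            "cluster_id": np.where(is_diff, blocks, -1),
        },
        index=ann.index,
    )
    study = MethylationStudy(beta=beta, samples=samples, probes=ann)
    truth = TruthTable(probes=truth_probes.loc[study.probes.index])
    study.probes.attrs["genes"] = genes
    return study, truth


def simulate_genotypes(
    config: SimulationConfig, study: MethylationStudy, truth: TruthTable
) -> tuple[GenotypeMatrix, MethylationStudy]:
    """Generate genotypes and dose methylation at planted meQTL pairs.

    Dosages are Binomial(2, MAF) per SNP with MAF uniform on
    ``config.maf_range``.  The first ``n_additive_meqtls`` SNPs add
    ``meqtl_slope_m x dosage`` to their target CpG's M value in all
    samples; the next ``n_interaction_meqtls`` add it only in acute ESAM
    samples (interaction-only: additive slope 0 in the reference group).
    Each designated SNP sits within 10 kb of its target CpG.  Returns the
    genotype matrix and a new study with the doped methylation; the pair
    truth is appended to ``truth.meqtl_pairs``.
    """
    rng = _rng(config, 1)
    n_pairs = config.n_additive_meqtls + config.n_interaction_meqtls
    if n_pairs > config.n_snps:
        raise ValueError("more meQTL pairs requested than SNPs")
    probe_ids = study.probes.index.to_numpy()
    if n_pairs > len(probe_ids):
        raise ValueError("more meQTL pairs requested than available cis probes")
    targets = rng.choice(probe_ids, size=n_pairs, replace=False)

    snp_ids = [f"rs{i:06d}" for i in range(config.n_snps)]
    chroms, positions = [], []
    for i in range(config.n_snps):
        if i < n_pairs:
            p = study.probes.loc[targets[i]]
            off = int(rng.integers(-10_000, 10_001))
            chroms.append(p["chromosome"])
            positions.append(max(1, int(p["position"]) + off))
        else:
            anchor = study.probes.iloc[int(rng.integers(0, len(probe_ids)))]
            chroms.append(anchor["chromosome"])
            positions.append(max(1, int(anchor["position"]) + int(rng.integers(-30_000, 30_001))))
    mafs = rng.uniform(*config.maf_range, size=config.n_snps)
    dos = rng.binomial(2, mafs[:, None], size=(config.n_snps, study.n_samples)).astype(float)
    geno = GenotypeMatrix(
        dosages=pd.DataFrame(dos, index=pd.Index(snp_ids, name="snp_id"), columns=study.beta.columns),
        snps=pd.DataFrame(
            {"chromosome": chroms, "position": positions}, index=pd.Index(snp_ids, name="snp_id")
        ),
    )

    M = study.m.to_numpy().copy()
    probe_pos = {pid: i for i, pid in enumerate(study.beta.index)}
    is_esam_dc = (
        (study.samples["group"] == "ESAM") & (study.samples["timepoint"] == "DC")
    ).to_numpy(dtype=float)
    pair_rows = []
    for i in range(n_pairs):
        kind = "additive" if i < config.n_additive_meqtls else "interaction"
        row = dos[i]
        j = probe_pos[targets[i]]
        if kind == "additive":
            M[j] += config.meqtl_slope_m * row
        else:
            M[j] += config.meqtl_slope_m * row * is_esam_dc
        pair_rows.append(
            {
                "snp_id": snp_ids[i],
                "cpg_id": targets[i],
                "kind": kind,
                "true_slope": config.meqtl_slope_m,
            }
        )
    new_pairs = pd.DataFrame(pair_rows)
    truth.meqtl_pairs = (
        new_pairs
        if truth.meqtl_pairs.empty
        else pd.concat([truth.meqtl_pairs, new_pairs], ignore_index=True)
    )
    beta = pd.DataFrame(m_to_beta(M), index=study.beta.index, columns=study.beta.columns)
    doped = MethylationStudy(beta=beta, samples=study.samples, probes=study.probes)
    doped.probes.attrs = dict(study.probes.attrs)
    return geno, doped


@dataclass
class GeneSetBundle:
    efo_catalog: pd.DataFrame
    hpo_map: dict
    ontology_map: dict
    universe: list


def simulate_genesets(
    config: SimulationConfig | GeneSetConfig,
    hit_genes=(),
    enrichment: float = 0.0,
    seed: int | None = None,
) -> GeneSetBundle:
    """Draw EFO catalog, HPO term and plain ontology gene sets.

    Under the null (``enrichment = 0``) every set is a uniform draw from
    the universe.  With ``enrichment > 0`` each set additionally includes
    that fraction of ``hit_genes``, planting real signal.  Duplicate set
    names raise.
    """
    gcfg = config.genesets if isinstance(config, SimulationConfig) else config
    if seed is None and isinstance(config, SimulationConfig):
        rng = _rng(config, 2)
    else:
        rng = np.random.default_rng(seed)
    universe = [f"G{i:05d}" for i in range(gcfg.n_genes)]
    hit = [g for g in hit_genes if g in set(universe)] if len(hit_genes) else []

    def draw_set(size):
        base = rng.choice(gcfg.n_genes, size=size, replace=False)
        genes = {universe[i] for i in base}
        if enrichment > 0 and hit:
            extra = [g for g in hit if rng.random() < enrichment]
            genes.update(extra)
        return sorted(genes)

    efo_rows = []
    for e in range(gcfg.n_efos):
        size = int(rng.integers(*gcfg.efo_genes_range))
        for g in draw_set(size):
            efo_rows.append(
                {
                    "efo_id": f"EFO:{e:07d}",
                    "efo_label": f"trait_{e}",
                    "gene": g,
                    "snp_count": 1 + int(rng.poisson(gcfg.snp_count_mean)),
                    "parent_efo": f"parent_{e % 5}",
                }
            )
    efo_catalog = pd.DataFrame(efo_rows)

    def named_sets(prefix, n, size_range):
        out = {}
        for i in range(n):
            name = f"{prefix}:{i:05d}"
            if name in out:
                raise ValueError(f"duplicate set name {name}")
            out[name] = draw_set(int(rng.integers(*size_range)))
        return out

    hpo_map = named_sets("HP", gcfg.n_hpo_terms, gcfg.hpo_genes_range)
    ontology_map = named_sets("GO", gcfg.n_ontologies, gcfg.ontology_genes_range)
    return GeneSetBundle(
        efo_catalog=efo_catalog, hpo_map=hpo_map, ontology_map=ontology_map, universe=universe
    )


def simulate_expression(
    study: MethylationStudy,
    truth: TruthTable,
    n_control_probes: int = 20,
    corr_strength: float = 0.8,
    expressed_fraction: float = 0.7,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix for the probe-linked genes plus antigenomic controls.

    Each gene linked to study probes receives per-sample expression
    ``base + sign * corr_strength * scale * mean_beta + noise``, with the
    correlation sign random per gene (the regulatory effect of
    methylation is context dependent and bidirectional).  A fraction of
    genes is given low baseline expression (below the twofold-antigenomic
    threshold) to exercise the expressed-gene filter.  Antigenomic
    control probes are background-level draws.
    """
    rng = np.random.default_rng(seed)
    gene_probes: dict[str, list] = {}
    for pid, links in zip(study.probes.index, study.probes["gene_links"]):
        for gene, _ in links:
            gene_probes.setdefault(gene, []).append(pid)
    bg_level = 50.0
    controls = pd.DataFrame(
        rng.normal(bg_level, 5.0, size=(n_control_probes, study.n_samples)),
        index=[f"AG{i:03d}" for i in range(n_control_probes)],
        columns=study.beta.columns,
    )
    rows, index = [], []
    for gene, pids in sorted(gene_probes.items()):
        meanb = study.beta.loc[pids].mean(axis=0).to_numpy()
        expressed = rng.random() < expressed_fraction
        base = rng.uniform(200.0, 2_000.0) if expressed else rng.uniform(10.0, 60.0)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        scale = 0.5 * base
        noise = rng.normal(0.0, (1.0 - corr_strength) * scale + 1e-3, size=study.n_samples)
        centred = meanb - meanb.mean()
        rows.append(base + sign * corr_strength * scale * centred + noise)
        index.append(gene)
    expr = pd.DataFrame(rows, index=pd.Index(index, name="gene"), columns=study.beta.columns)
    return expr, controls
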