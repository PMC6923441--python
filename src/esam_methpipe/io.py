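"""Readers and writers for the package's plain-text interchange formats.

Matrices travel as TSV (probes/genes as rows, sample ids as header),
probe annotation as a BED-compatible TSV (chromosome + 1-based position),
gene sets as GMT, genotypes as a dosage TSV or minimal VCF 4.2, truth
tables as JSON, configs as YAML/JSON.  Writes print floats at full
round-trip precision so read(write(x)) is bit exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .meqtl import GenotypeMatrix
from .simulate import TruthTable
from .study import MethylationStudy

_FLOAT_FMT = "%.17g"


def write_matrix(df: pd.DataFrame, path, index_label="probe_id"):
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def read_matrix(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_sample_sheet(samples: pd.DataFrame, path):
    samples.to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def _links_to_str(links) -> str:
    return ";".join(f"{g}:{c}" for g, c in links)


def _str_to_links(s) -> tuple:
    if not isinstance(s, str) or not s:
        return ()
    return tuple(tuple(part.split(":", 1)) for part in s.split(";"))


def write_probe_annotation(probes: pd.DataFrame, path):
    out = probes.copy()
    if "gene_links" in out.columns:
        out["gene_links"] = out["gene_links"].map(_links_to_str)
    if "flags" in out.columns:
        out["flags"] = out["flags"].map(lambda f: ";".join(sorted(f)))
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_probe_annotation(path) -> pd.DataFrame:
    probes = pd.read_csv(path, sep="\t", index_col="probe_id")
    if "gene_links" in probes.columns:
        probes["gene_links"] = probes["gene_links"].map(_str_to_links)
    else:
        probes["gene_links"] = [()] * len(probes)
    if "flags" in probes.columns:
        probes["flags"] = probes["flags"].map(
            lambda s: frozenset(s.split(";")) if isinstance(s, str) and s else frozenset()
        )
    else:
        probes["flags"] = [frozenset()] * len(probes)
    return probes


def write_study(study: MethylationStudy, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(study.beta, outdir / "beta.tsv")
    write_sample_sheet(study.samples, outdir / "samples.tsv")
    write_probe_annotation(study.probes, outdir / "probes.tsv")


def read_study(outdir) -> MethylationStudy:
    outdir = Path(outdir)
    return MethylationStudy(
        beta=read_matrix(outdir / "beta.tsv"),
        samples=read_sample_sheet(outdir / "samples.tsv"),
        probes=read_probe_annotation(outdir / "probes.tsv"),
    )


def write_genotypes(geno: GenotypeMatrix, path):
    out = geno.snps.join(geno.dosages)
    out.to_csv(path, sep="\t", index_label="snp_id", float_format="%g")


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    snp_cols = ["chromosome", "position"]
    return GenotypeMatrix(dosages=df.drop(columns=snp_cols), snps=df[snp_cols])


def write_vcf(geno: GenotypeMatrix, path):
    """Minimal VCF 4.2 with GT-only genotype fields (dosage = ALT count)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.dosages.columns)
            + "\n"
        )
        for snp, meta in geno.snps.iterrows():
            row = geno.dosages.loc[snp]
            gts = "\t".join(gt_map.get(v, "./.") for v in row)
            fh.write(
                f"{meta['chromosome']}\t{int(meta['position'])}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (ALT allele count from GT)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 extra") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, positions, rows = [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        types = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        rows.append(
            [{0: 0.0, 1: 1.0, 3: 2.0}.get(int(t), np.nan) for t in types]
        )
    dos = pd.DataFrame(rows, index=pd.Index(ids, name="snp_id"), columns=samples)
    snps = pd.DataFrame(
        {"chromosome": chroms, "position": positions}, index=dos.index
    )
    return GenotypeMatrix(dosages=dos, snps=snps)


def write_gmt(sets: dict, path, description="na"):
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            if parts[0] in out:
                raise ValueError(f"duplicate gene-set name {parts[0]!r}")
            out[parts[0]] = parts[2:]
    return out


def write_truth(truth: TruthTable, path):
    payload = {
        "probes": {
            pid: {
                "is_differential": bool(row.is_differential),
                "true_direction": int(row.true_direction),
                "cluster_id": int(row.cluster_id),
            }
            for pid, row in truth.probes.iterrows()
        },
        "meqtl_pairs": truth.meqtl_pairs.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> TruthTable:
    payload = json.loads(Path(path).read_text())
    probes = pd.DataFrame.from_dict(payload["probes"], orient="index")
    probes.index.name = "probe_id"
    return TruthTable(probes=probes, meqtl_pairs=pd.DataFrame(payload["meqtl_pairs"]))


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_cluster_bed(cluster_set, path):
    """ClusterSet spans as BED-like TSV (0-based start, 1-based end)."""
    df = cluster_set.clusters
    out = pd.DataFrame(
        {
            "chrom": df["chromosome"],
            "start": df["start"] - 1,
            "end": df["end"],
            "cluster_id": df.index,
            "direction": df["direction"],
            "n_probes": df["n_probes"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
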