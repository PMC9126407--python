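"""Readers and writers for the tabular interchange formats.

Everything flows through plain TSV: dosage matrices, phenotype and
covariate tables, summary statistics (GWAS-SSF-like columns), gene
regions (BED-like, converted to 1-based inclusive internally) and
weight models.  Genotypes can additionally be written as an
uncompressed VCF with a per-sample dosage (DS) FORMAT field and read
back with cyvcf2 when that optional dependency is installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qtlscan import CisRegion
from .simdata import GenotypeMatrix


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    """Variants as rows (metadata columns first), samples as s0..sN."""
    frame = geno.variants.copy()
    dose = pd.DataFrame(
        geno.dosages.T, columns=[f"s{i}" for i in range(geno.n_samples)]
    )
    pd.concat([frame.reset_index(drop=True), dose], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_genotypes_tsv(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t")
    meta_cols = ["variant_id", "chrom", "pos", "region", "effect_allele", "other_allele", "maf"]
    meta = frame[[c for c in meta_cols if c in frame.columns]]
    sample_cols = [c for c in frame.columns if c.startswith("s") and c[1:].isdigit()]
    dosages = frame[sample_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, meta.reset_index(drop=True))


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Uncompressed VCF with genotype dosages in the DS FORMAT field."""
    n = geno.n_samples
    samples = "\t".join(f"s{i}" for i in range(n))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        chroms = geno.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, row in geno.variants.iterrows():
            ds = "\t".join(f"{d:g}" for d in geno.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t.\tDS\t{ds}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a dosage VCF via cyvcf2 (optional dependency)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, doses = [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(f"{var.ID}: no DS field")
        doses.append(np.asarray(ds, dtype=float).ravel())
        rows.append(
            {
                "variant_id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS,
                "region": 0,
                "effect_allele": var.ALT[0],
                "other_allele": var.REF,
                "maf": np.nan,
            }
        )
    dosages = np.vstack(doses).T
    meta = pd.DataFrame(rows)
    eaf = dosages.mean(axis=0) / 2
    meta["maf"] = np.minimum(eaf, 1 - eaf)
    return GenotypeMatrix(dosages, meta)


def write_stats(stats_df: pd.DataFrame, path) -> None:
    stats_df.to_csv(path, sep="\t", index=False)


def read_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_regions_bed(path, flank: int = 500_000) -> list[CisRegion]:
    """BED-like region file (chrom, start, end, gene_id), 0-based
    half-open on disk, converted to 1-based inclusive."""
    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"],
        comment="#",
    )
    return [
        CisRegion(
            gene_id=str(r["gene_id"]),
            chrom=str(r["chrom"]),
            gene_start=int(r["start"]) + 1,
            gene_stop=int(r["end"]),
            flank=flank,
        )
        for _, r in frame.iterrows()
    ]


def write_weights(models, path) -> None:
    rows = []
    for m in models:
        for _, r in m.weights.iterrows():
            rows.append(
                {
                    "gene_id": m.gene_id,
                    "tissue": m.tissue,
                    "variant_id": r["variant_id"],
                    "effect_allele": r["effect_allele"],
                    "weight": r["weight"],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_weights(path) -> list:
    from .twas import WeightModel

    frame = pd.read_csv(path, sep="\t")
    models = []
    for (gene, tissue), grp in frame.groupby(["gene_id", "tissue"], sort=True):
        models.append(
            WeightModel(
                gene_id=str(gene),
                tissue=str(tissue),
                weights=grp[["variant_id", "effect_allele", "weight"]].reset_index(drop=True),
            )
        )
    return models


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
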