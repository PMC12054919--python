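"""Readers and writers for the plain-text formats the pipeline exchanges.

Genotypes travel as TSV dosage tables (variant metadata columns followed by
one column per sample) or minimal VCF v4.2 with GT fields; functional
classes as BED3+name; phenotypes, expression panels, target lists and read
fixtures as TSV.  Internal coordinates are 0-based half-open; VCF positions
are converted on the way in and out.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grm import GenotypeMatrix
from .varcomp import PhenotypeTable

META_COLS = ["chrom", "pos", "id", "ref", "alt"]

__all__ = [
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_bed",
    "write_bed",
    "read_expression",
    "write_expression",
    "read_reads_tsv",
    "write_reads_tsv",
]


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = [c for c in df.columns if c not in META_COLS]
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, df[META_COLS], np.asarray(samples))


def write_genotype_tsv(geno: GenotypeMatrix, path) -> None:
    dosage_cols = pd.DataFrame(
        geno.dosages.T, columns=list(geno.samples), index=geno.variants.index
    )
    out = pd.concat([geno.variants, dosage_cols], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_vcf(path) -> GenotypeMatrix:
    """Minimal VCF v4.2 reader (GT field only), via pysam."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, dosage_cols = [], []
    for rec in vf:
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos - 1,  # VCF is 1-based
                "id": rec.id or f"{rec.chrom}:{rec.pos}",
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
            }
        )
        col = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                col.append(np.nan)
            else:
                col.append(float(sum(gt)))
        dosage_cols.append(col)
    vf.close()
    dosages = np.asarray(dosage_cols, dtype=float).T
    return GenotypeMatrix(dosages, pd.DataFrame(rows), np.asarray(samples))


def write_vcf(geno: GenotypeMatrix, path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Minimal diploid VCF v4.2 with GT genotypes."""
    chroms = geno.variants["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            length = (chrom_lengths or {}).get(
                c, int(geno.variants.loc[geno.variants["chrom"] == c, "pos"].max()) + 1
            )
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.samples))
            + "\n"
        )
        gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in geno.variants.iterrows():
            calls = []
            for i in range(geno.n_individuals):
                d = geno.dosages[i, j]
                calls.append("./." if np.isnan(d) else gt_of[int(round(d))])
            fh.write(
                f"{row['chrom']}\t{row['pos'] + 1}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t"))


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"][: 4],
        dtype={0: str},
    )
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_expression(values_path, meta_path=None):
    """Expression TSV (genes x samples, first column gene IDs) and optional
    sample-metadata TSV indexed by sample ID."""
    from .specificity import ExpressionMatrix

    values = pd.read_csv(values_path, sep="\t", index_col=0)
    if meta_path is None:
        return values
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta)


def write_expression(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t")


def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "mapped" in df:
        df["mapped"] = df["mapped"].astype(bool)
    return df


def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)
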