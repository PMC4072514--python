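"""Plain-text readers and writers for the pipeline's tables.

Genotypes travel as VCF (GT hard calls) or as a dosage TSV (individuals x
SNPs); expression, covariates, phenotypes and truth tables as TSV with a
header row; flow and CFSE events as CSV (one row per event); H3K4me3
peaks as BED6+ with height in the score column and an optional summit
offset in column 7.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix
from .peaks import validate_peaks

__all__ = [
    "write_dosage_tsv", "read_dosage_tsv",
    "write_vcf", "read_vcf",
    "write_expression_tsv", "read_expression_tsv",
    "write_table", "read_table",
    "write_flow_csv", "read_flow_csv",
    "read_bed_peaks",
]


def write_dosage_tsv(genotypes: GenotypeMatrix, dosage_path, meta_path) -> None:
    genotypes.dosages.to_csv(dosage_path, sep="\t")
    genotypes.snps.to_csv(meta_path, sep="\t")


def read_dosage_tsv(dosage_path, meta_path) -> GenotypeMatrix:
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"chrom": str})
    return GenotypeMatrix(dos, meta)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Hard-call GT VCF; fractional dosages are rounded to the nearest call."""
    ids = list(genotypes.individuals)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        D = genotypes.dosages.to_numpy()
        for j, (snp, row) in enumerate(genotypes.snps.iterrows()):
            calls = "\t".join(gt_of[int(round(v))] for v in D[:, j])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Minimal GT-field VCF reader (text VCF, bi-allelic rows)."""
    rows, meta = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                ids = line.rstrip("\n").split("\t")[9:]
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, snp, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            gt_idx = f[8].split(":").index("GT")
            dos = [sum(int(a) for a in s.split(":")[gt_idx].replace("|", "/").split("/"))
                   for s in f[9:]]
            rows.append(dos)
            meta.append((snp, chrom, pos, ref, alt))
    snps = pd.DataFrame(meta, columns=["snp", "chrom", "pos", "ref", "alt"]) \
        .set_index("snp")
    D = pd.DataFrame(np.array(rows, dtype=float).T, index=pd.Index(ids, name="individual"),
                     columns=snps.index)
    freq = D.mean(axis=0) / 2
    snps["maf"] = np.minimum(freq, 1 - freq)
    return GenotypeMatrix(D, snps)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_expression_tsv(path, state: str = "rest") -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0), state=state)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_flow_csv(events: np.ndarray, path, columns=("CD45RA", "CD45RO", "CD62L")) -> None:
    pd.DataFrame(np.atleast_2d(events), columns=list(columns)[: np.atleast_2d(events).shape[1]]) \
        .to_csv(path, index=False)


def read_flow_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)


def read_bed_peaks(path) -> pd.DataFrame:
    """BED6+ peaks: chrom, start, end, name, height(score), strand[, summit]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "height", "strand", "summit"]
    df.columns = names[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    return validate_peaks(df)
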