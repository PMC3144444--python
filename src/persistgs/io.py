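"""Plain-text readers and writers for pedigree, phenotype and genotype data.

Pedigree and phenotype tables are CSV; genotypes travel either as a TSV
dosage matrix (rows = individuals, columns = SNP, cells 0/1/2/NA) or as a
minimal single-allele VCF with one sample column per individual.
Relationship matrices are TSV with an id header row and column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .relationships import RelationshipMatrix
from .simulate import GenotypeMatrix

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_phenotypes",
    "read_phenotypes",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "write_relmat",
    "read_relmat",
]

PED_COLS = ["id", "sire", "dam", "generation", "sex", "hatch"]
PHEN_COLS = ["id", "trait", "value", "hatch", "generation"]


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree[PED_COLS].to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PED_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file lacks columns: {sorted(missing)}")
    df["sire"] = df["sire"].fillna(0).astype(int)
    df["dam"] = df["dam"].fillna(0).astype(int)
    df["hatch"] = df["hatch"].fillna("")  # founders carry no hatch label
    return df[PED_COLS]


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes[PHEN_COLS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHEN_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing)}")
    return df[PHEN_COLS]


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        genotypes.calls, index=genotypes.ids, columns=genotypes.snps.index
    )
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_genotypes_tsv(path, snps: "pd.DataFrame | None" = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    if snps is None:
        snps = pd.DataFrame(
            {"chrom": 1, "pos": np.arange(1, df.shape[1] + 1, dtype=float)},
            index=pd.Index(df.columns, name="snp_id"),
        )
    return GenotypeMatrix(
        ids=df.index.to_numpy(), snps=snps, calls=df.to_numpy(float)
    )


def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal biallelic VCF (GT only); missing call written as ./."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in genotypes.snps["chrom"].unique():
            fh.write(f"##contig=<ID={int(chrom)}>\n")
        samples = "\t".join(str(i) for i in genotypes.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for k, (snp_id, row) in enumerate(genotypes.snps.iterrows()):
            # map position in Morgans -> integer bp-like coordinate
            pos_bp = int(round(row["pos"] * 1_000_000)) + 1
            calls = genotypes.calls[:, k]
            gts = "\t".join(
                "./." if np.isnan(c) else gt_map[float(c)] for c in calls
            )
            fh.write(
                f"{int(row['chrom'])}\t{pos_bp}\t{snp_id}\tA\tB\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    # cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    dosage = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}
    vcf = VCF(str(path))
    snp_ids, chroms, pos, rows = [], [], [], []
    for var in vcf:
        chroms.append(int(var.CHROM))
        pos.append((var.POS - 1) / 1_000_000)
        snp_ids.append(var.ID)
        rows.append([dosage[int(t)] for t in var.gt_types])
    samples = vcf.samples
    vcf.close()
    snps = pd.DataFrame(
        {"chrom": chroms, "pos": pos}, index=pd.Index(snp_ids, name="snp_id")
    )
    calls = np.array(rows, dtype=float).T  # SNP-major in file, individual-major here
    ids = np.array(samples, dtype=object)
    try:
        ids = ids.astype(int)
    except (TypeError, ValueError):
        pass
    return GenotypeMatrix(ids=ids, snps=snps, calls=calls)


def write_relmat(rm: RelationshipMatrix, path) -> None:
    rm.to_frame().to_csv(path, sep="\t", index_label="id")


def read_relmat(path, kind: str = "pedigree") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = df.index.to_numpy()
    return RelationshipMatrix(ids=ids, values=df.to_numpy(float), kind=kind)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
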