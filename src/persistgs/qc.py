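"""SNP-panel and phenotype editing rules.

Three per-SNP filters (all strict inequalities): minor allele frequency
above 0.025, missing-call proportion below 0.05, and parent-offspring
opposing-homozygote (Mendelian mismatch) rate below 0.05.  Phenotype
records deviating from their within-hatch-within-generation mean by more
than three standard deviations are removed as outliers.  Missing genotypes
are mean-imputed (2 * allele frequency) before any matrix algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "apply_snp_qc",
    "filter_outlier_phenotypes",
    "impute_missing",
]


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.025
    missing_max: float = 0.05
    mendel_mismatch_max: float = 0.05
    outlier_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "mendel_mismatch_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")


def mendel_mismatch_rate(
    genotypes: GenotypeMatrix, pedigree: pd.DataFrame
) -> tuple[np.ndarray, int]:
    """Per-SNP opposing-homozygote rate over genotyped parent-offspring pairs.

    A pair mismatches at a SNP when one member is 0 and the other 2 (an
    offspring cannot be an opposing homozygote of a true parent).  The
    statistic is symmetric in parent and offspring.  Returns the per-SNP
    rate (NaN where no pair has both calls) and the number of pairs found.
    """
    pos = {int(i): k for k, i in enumerate(genotypes.ids)}
    pairs: list[tuple[int, int]] = []
    for _, row in pedigree.iterrows():
        child = int(row["id"])
        if child not in pos:
            continue
        for parent in (int(row["sire"]), int(row["dam"])):
            if parent != 0 and parent in pos:
                pairs.append((pos[child], pos[parent]))
    m = genotypes.n_snp
    if not pairs:
        return np.full(m, np.nan), 0
    mism = np.zeros(m)
    informative = np.zeros(m)
    calls = genotypes.calls
    for ci, pi in pairs:
        a, b = calls[ci], calls[pi]
        both = ~np.isnan(a) & ~np.isnan(b)
        informative += both
        mism += both & (np.abs(a - b) == 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(informative > 0, mism / np.maximum(informative, 1), np.nan)
    return rate, len(pairs)


def apply_snp_qc(
    genotypes: GenotypeMatrix,
    pedigree: "pd.DataFrame | None",
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter the SNP panel; returns the filtered matrix and a per-SNP report.

    Report columns: maf, missing_rate, mendel_rate, pass_maf, pass_missing,
    pass_mendel, pass.  SNP with no informative parent-offspring pair (or
    when no pedigree is supplied) pass the Mendel rule vacuously; the
    report's ``mendel_checked`` attribute flags whether the rule was active.
    """
    if genotypes.n_individuals == 0 or genotypes.n_snp == 0:
        raise ValueError("empty genotype matrix")
    freqs = genotypes.allele_freq()
    maf = np.minimum(freqs, 1.0 - freqs)
    missing = genotypes.missing_rate()
    if pedigree is not None:
        mendel, n_pairs = mendel_mismatch_rate(genotypes, pedigree)
    else:
        mendel, n_pairs = np.full(genotypes.n_snp, np.nan), 0
    pass_maf = maf > thresholds.maf_min
    pass_missing = missing < thresholds.missing_max
    pass_mendel = np.isnan(mendel) | (mendel < thresholds.mendel_mismatch_max)
    ok = pass_maf & pass_missing & pass_mendel
    report = pd.DataFrame(
        {
            "maf": maf,
            "missing_rate": missing,
            "mendel_rate": mendel,
            "pass_maf": pass_maf,
            "pass_missing": pass_missing,
            "pass_mendel": pass_mendel,
            "pass": ok,
        },
        index=genotypes.snps.index,
    )
    report.attrs["mendel_checked"] = n_pairs > 0
    return genotypes.subset_snps(ok), report


def filter_outlier_phenotypes(
    phenotypes: pd.DataFrame, outlier_sd: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records more than ``outlier_sd`` SD from their within-hatch
    (within-generation, within-trait) mean.  Groups with fewer than two
    records, or zero SD, are left untouched.
    """
    if outlier_sd <= 0:
        raise ValueError("outlier_sd must be positive")
    df = phenotypes.copy()
    grp = df.groupby(["trait", "generation", "hatch"])["value"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1; NaN for singleton groups
    dev = (df["value"] - mean).abs()
    with np.errstate(invalid="ignore"):
        is_outlier = (dev > outlier_sd * sd) & sd.notna() & (sd > 0)
    return df[~is_outlier].reset_index(drop=True), df[is_outlier].reset_index(drop=True)


def impute_missing(
    genotypes: GenotypeMatrix, freqs: "np.ndarray | None" = None
) -> GenotypeMatrix:
    """Replace missing calls at SNP k by twice the allele frequency.

    ``freqs`` defaults to observed frequencies in ``genotypes`` itself.
    The result is no longer restricted to {0,1,2}, so it is returned as a
    plain dosage matrix inside a GenotypeMatrix-shaped object.
    """
    if freqs is None:
        freqs = genotypes.allele_freq()
    freqs = np.asarray(freqs, dtype=float)
    if np.isnan(freqs).any():
        bad = genotypes.snps.index[np.isnan(freqs)].tolist()
        raise ValueError(f"SNP with no observed calls cannot be imputed: {bad[:5]}")
    calls = genotypes.calls.copy()
    miss = np.isnan(calls)
    if miss.any():
        fill = np.broadcast_to(2.0 * freqs, calls.shape)
        calls[miss] = fill[miss]
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.ids = genotypes.ids
    out.snps = genotypes.snps
    out.calls = calls
    return out
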