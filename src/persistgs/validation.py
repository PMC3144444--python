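"""Cross-generation training/validation designs and the accuracy statistic.

Two designs are supported.  In the *accumulate* design, training uses all
data up to generation g and validation uses genotyped progeny with own
phenotypes in generation g + 1 (retraining every generation).  In the
*persist* design, training is done once on data through a fixed generation
(default 1) and validation moves forward through every later generation,
measuring how accuracy decays as validation animals become more remote
from training.

Accuracy is the Pearson correlation between (G)EBV and hatch-corrected
phenotype in the validation set, divided by the square root of the trait
heritability estimated by pedigree BLUP REML on all available data.  Under
pedigree information alone, relationships halve at each meiosis, so this
accuracy is expected to shrink by sqrt(0.5) per generation of separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blup import (
    FitResult,
    VarianceComponents,
    em_reml,
    family_means,
    fit_gblup_reduced,
    fit_pblup,
    precorrect_phenotypes,
)
from .bayes import McmcConfig
from .qc import QCThresholds, apply_snp_qc, filter_outlier_phenotypes, impute_missing
from .simulate import GenotypeMatrix, Population

__all__ = [
    "AccuracyRecord",
    "compute_accuracy",
    "expected_decay",
    "run_design",
]

METHODS = ("PBLUP", "GBLUP", "BayesA", "BayesCpi")


@dataclass
class AccuracyRecord:
    method: str
    trait: str
    training_upto: int
    validation_generation: int
    n_validation: int
    correlation: float
    accuracy: float
    h2_used: float
    reason: str = ""


def compute_accuracy(
    ebv: pd.Series, corrected: pd.DataFrame, h2: float
) -> tuple[float, float, int, str]:
    """Correlation of EBV with hatch-corrected phenotype over the id
    intersection, and accuracy = correlation / sqrt(h2)."""
    if h2 <= 0:
        raise ValueError("h2 must be positive for the accuracy denominator")
    merged = corrected.set_index("id")["value"]
    common = ebv.index.intersection(merged.index)
    if len(common) < 2:
        return np.nan, np.nan, len(common), "fewer than 2 validation individuals"
    a = ebv.loc[common].to_numpy(float)
    b = merged.loc[common].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan, np.nan, len(common), "zero variance"
    r = float(np.corrcoef(a, b)[0, 1])
    return r, r / math.sqrt(h2), len(common), ""


def expected_decay(base_accuracy: float, lag: float) -> float:
    """Expected accuracy after ``lag`` generations of pedigree-only decay:
    base * sqrt(0.5)^lag (relationships halve per meiosis)."""
    if lag < 0:
        raise ValueError("lag must be non-negative")
    return base_accuracy * 0.5 ** (lag / 2.0)


def _bayes_training_records(
    train_phen: pd.DataFrame,
    pedigree: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pblup_fit: FitResult,
    vc: VarianceComponents,
) -> pd.DataFrame:
    """Pre-corrected own records of genotyped animals plus weighted
    full-sib family means of non-genotyped progeny of genotyped parents."""
    corrected = precorrect_phenotypes(train_phen, pblup_fit)
    gset = set(int(i) for i in genotypes.ids)
    own = corrected[corrected["id"].astype(int).isin(gset)][["id", "value"]].copy()
    own["weight"] = 1.0
    fams = family_means(corrected, pedigree, gset)
    rows = [own]
    if not fams.empty:
        # a family-mean record stands at the parent-average genotype; the
        # design row is 0.5 (z_sire + z_dam), encoded as a pseudo-genotype
        var_mean = (0.5 * vc.sigma2_a + vc.sigma2_e) / fams["n"].to_numpy(float)
        rows.append(
            pd.DataFrame(
                {
                    "id": list(zip(fams["sire"].astype(int), fams["dam"].astype(int))),
                    "value": fams["mean"].to_numpy(float),
                    "weight": vc.sigma2_e / var_mean,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _bayes_design(
    records: pd.DataFrame, genotypes: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand id column (ints or (sire, dam) tuples) into dosage rows."""
    pos = {int(i): k for k, i in enumerate(genotypes.ids)}
    X = np.empty((len(records), genotypes.n_snp))
    for r, rid in enumerate(records["id"]):
        if isinstance(rid, tuple):
            X[r] = 0.5 * (genotypes.calls[pos[rid[0]]] + genotypes.calls[pos[rid[1]]])
        else:
            X[r] = genotypes.calls[pos[int(rid)]]
    return X, records["value"].to_numpy(float), records["weight"].to_numpy(float)


def run_design(
    dataset: Population,
    methods=("PBLUP",),
    mode: str = "accumulate",
    trait: str = "trait",
    train_upto: int = 1,
    h2_policy="reml_full",
    varcomp_policy="reml",
    mcmc: "McmcConfig | None" = None,
    qc_thresholds: QCThresholds = QCThresholds(),
    run_qc: bool = True,
) -> pd.DataFrame:
    """Run one training/validation design over a dataset.

    ``h2_policy`` is either 'reml_full' (heritability for the accuracy
    denominator re-estimated by PBLUP REML on all data, as are the
    hatch-correction solutions) or a numeric heritability to use directly.
    ``varcomp_policy`` is 'reml' (re-estimate per training window) or a
    VarianceComponents to hold fixed.  Validation phenotypes never enter
    any training fit; this is asserted on the records.
    """
    if mode not in ("accumulate", "persist"):
        raise ValueError(f"unknown design mode {mode!r}")
    methods = [_canon_method(m) for m in methods]
    pedigree = dataset.pedigree
    phen = dataset.phenotypes[dataset.phenotypes["trait"] == trait].copy()
    genotypes = dataset.genotypes
    if run_qc:
        genotypes, _ = apply_snp_qc(genotypes, pedigree, qc_thresholds)
        phen, _ = filter_outlier_phenotypes(phen, qc_thresholds.outlier_sd)
    genotypes = impute_missing(genotypes)
    pooled_freqs = genotypes.calls.mean(axis=0) / 2.0

    generations = sorted(phen["generation"].unique())
    last_gen = generations[-1]
    gset = set(int(i) for i in genotypes.ids)

    # full-data PBLUP: heritability denominator and hatch correction
    if h2_policy == "reml_full":
        vc_full = em_reml(phen, pedigree)
    else:
        h2 = float(h2_policy)
        vc_full = VarianceComponents(sigma2_a=h2, sigma2_e=1.0 - h2)
    full_fit = fit_pblup(phen, pedigree, vc_full)
    corrected_all = precorrect_phenotypes(phen, full_fit)
    h2_used = vc_full.h2

    if mode == "accumulate":
        windows = [(g, g + 1) for g in generations if g + 1 <= last_gen]
    else:
        windows = [(train_upto, v) for v in generations if v > train_upto]

    rows: list[AccuracyRecord] = []
    fits_cache: dict[int, dict[str, pd.Series]] = {}
    for g_train, g_val in windows:
        if g_train not in fits_cache:
            fits_cache[g_train] = _train_all(
                methods,
                phen[phen["generation"] <= g_train],
                pedigree,
                genotypes,
                pooled_freqs,
                varcomp_policy,
                mcmc,
            )
        ebv_by_method = fits_cache[g_train]
        val_phen = corrected_all[corrected_all["generation"] == g_val]
        val_ids = [int(i) for i in val_phen["id"] if int(i) in gset]
        val_phen = val_phen[val_phen["id"].astype(int).isin(val_ids)]
        train_ids = set(
            phen.loc[phen["generation"] <= g_train, "id"].astype(int)
        )
        assert not train_ids & set(val_ids), "validation ids leaked into training"
        for method in methods:
            ebv = ebv_by_method[method]
            ebv_val = ebv[ebv.index.isin(val_ids)]
            r, acc, n, reason = compute_accuracy(ebv_val, val_phen, h2_used)
            rows.append(
                AccuracyRecord(
                    method=method,
                    trait=trait,
                    training_upto=g_train,
                    validation_generation=g_val,
                    n_validation=n,
                    correlation=r,
                    accuracy=acc,
                    h2_used=h2_used,
                    reason=reason,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def _canon_method(m: str) -> str:
    for cand in METHODS:
        if m.lower().replace("_", "") == cand.lower():
            return cand
    raise ValueError(f"unknown method {m!r}; choose from {METHODS}")


def _train_all(
    methods,
    train_phen: pd.DataFrame,
    pedigree: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pooled_freqs: np.ndarray,
    varcomp_policy,
    mcmc: "McmcConfig | None",
) -> dict[str, pd.Series]:
    """Fit each requested method on one training window; EBV by id."""
    from .bayes import BayesA as _BA, BayesCPi as _BC

    if isinstance(varcomp_policy, VarianceComponents):
        vc = varcomp_policy
    elif varcomp_policy == "reml":
        vc = em_reml(train_phen, pedigree)
    else:
        raise ValueError("varcomp_policy must be 'reml' or a VarianceComponents")
    out: dict[str, pd.Series] = {}
    pblup_fit = None
    if {"PBLUP", "BayesA", "BayesCpi"} & set(methods):
        pblup_fit = fit_pblup(train_phen, pedigree, vc)
    if "PBLUP" in methods:
        out["PBLUP"] = pblup_fit.ebv
    if "GBLUP" in methods:
        fit = fit_gblup_reduced(
            train_phen, genotypes, pedigree, vc, freqs=pooled_freqs
        )
        out["GBLUP"] = fit.ebv
    if {"BayesA", "BayesCpi"} & set(methods):
        if mcmc is None:
            mcmc = McmcConfig()
        records = _bayes_training_records(
            train_phen, pedigree, genotypes, pblup_fit, vc
        )
        X, y, w = _bayes_design(records, genotypes)
        common = dict(
            chain_length=mcmc.chain_length,
            burn_in=mcmc.burn_in,
            thin=mcmc.thin,
            nu_a=mcmc.nu_a,
            sigma2_a=vc.sigma2_a,
            sigma2_e=vc.sigma2_e,
            scale_override=mcmc.scale_override,
            random_state=mcmc.seed,
        )
        if "BayesA" in methods:
            est = _BA(**common).fit(X, y, sample_weight=w, freqs=pooled_freqs)
            out["BayesA"] = pd.Series(
                est.predict(genotypes.calls), index=genotypes.ids
            )
        if "BayesCpi" in methods:
            est = _BC(pi_fixed=mcmc.pi_fixed, pi0=mcmc.pi0, **common).fit(
                X, y, sample_weight=w, freqs=pooled_freqs
            )
            out["BayesCpi"] = pd.Series(
                est.predict(genotypes.calls), index=genotypes.ids
            )
    return out
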