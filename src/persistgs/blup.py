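"""Animal-model BLUP machinery.

PBLUP: single-trait animal model with hatch-within-generation fixed
effects, solved from Henderson's mixed-model equations with the sparse
pedigree A-inverse; variance components by EM-REML.

GBLUP: reduced animal model on the genomic relationship matrix.  Only
genotyped animals carry breeding-value unknowns; a record on a
non-genotyped progeny of two genotyped parents is linked to the parent
average, its residual inflated by the Mendelian-sampling variance
0.5 * sigma2_a (non-inbred parents).

Also: fixed-effect pre-correction of phenotypes and full-sib family means
of non-genotyped progeny, the record types consumed by the Bayesian
whole-genome regression module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator, RegressorMixin

from .relationships import RelationshipMatrix, build_A_inverse, build_G
from .simulate import GenotypeMatrix

__all__ = [
    "VarianceComponents",
    "FitResult",
    "em_reml",
    "fit_pblup",
    "fit_gblup_reduced",
    "precorrect_phenotypes",
    "family_means",
    "PedigreeBLUP",
    "ReducedGBLUP",
    "RRBlup",
]


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    converged: bool = True
    n_iter: int = 0
    history: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0

    @property
    def ratio(self) -> float:
        """lambda = sigma2_e / sigma2_a used in the mixed-model equations."""
        if self.sigma2_a <= 0:
            raise ZeroDivisionError("sigma2_a = 0: variance ratio undefined")
        return self.sigma2_e / self.sigma2_a


@dataclass
class FitResult:
    method: str
    ebv: pd.Series  # indexed by individual id
    fixed_solutions: pd.Series  # indexed by hatch label
    varcomp: VarianceComponents
    posterior: "dict | None" = None


def _hatch_design(phenotypes: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    levels = pd.Index(sorted(phenotypes["hatch"].unique()))
    X = pd.get_dummies(
        pd.Categorical(phenotypes["hatch"], categories=levels)
    ).to_numpy(float)
    return X, levels


def _animal_incidence(
    record_ids: np.ndarray, animal_ids: np.ndarray
) -> sp.csr_matrix:
    pos = {int(a): k for k, a in enumerate(animal_ids)}
    rows = np.arange(len(record_ids))
    cols = np.array([pos[int(i)] for i in record_ids])
    data = np.ones(len(record_ids))
    return sp.csr_matrix((data, (rows, cols)), shape=(len(record_ids), len(animal_ids)))


def em_reml(
    phenotypes: pd.DataFrame,
    pedigree: "pd.DataFrame | None" = None,
    relmat_inverse: "RelationshipMatrix | None" = None,
    init: tuple[float, float] = (0.5, 0.5),
    tol: float = 1e-8,
    max_iter: int = 500,
) -> VarianceComponents:
    """EM-REML for the single-trait animal model y = X h + Z a + e.

    The fixed design is hatch-within-generation.  One generalized
    eigendecomposition of (Z'SZ, A-inverse), with S the projection
    orthogonal to X, makes each EM step O(n^2); iteration stops when the
    relative change of both components falls below ``tol``.
    """
    if relmat_inverse is None:
        if pedigree is None:
            raise ValueError("either a pedigree or a relationship inverse is required")
        relmat_inverse = build_A_inverse(pedigree)
    animal_ids = relmat_inverse.ids
    Ainv = relmat_inverse.dense()
    y = phenotypes["value"].to_numpy(float)
    X, _ = _hatch_design(phenotypes)
    Z = _animal_incidence(phenotypes["id"].to_numpy(), animal_ids).toarray()
    n, p = X.shape
    q = len(animal_ids)
    if n <= p:
        raise ValueError("more fixed-effect levels than records")

    XtX = X.T @ X
    rank_X = np.linalg.matrix_rank(XtX)
    XtX_inv = np.linalg.pinv(XtX)
    SZ = Z - X @ (XtX_inv @ (X.T @ Z))
    ZtSZ = Z.T @ SZ
    ZtSy = SZ.T @ y
    # generalized eigenproblem Z'SZ v = mu Ainv v with V' Ainv V = I
    mu, V = scipy.linalg.eigh(ZtSZ, Ainv)
    mu = np.clip(mu, 0.0, None)
    c = V.T @ ZtSy
    Zty = Z.T @ y
    Xty = X.T @ y
    yty = y @ y

    s2a, s2e = float(init[0]), float(init[1])
    history = [(s2a, s2e)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = s2e / s2a
        d = mu + lam
        a_hat = V @ (c / d)
        b_hat = XtX_inv @ (Xty - X.T @ (Z @ a_hat))
        aAinva = float(np.sum((c / d) ** 2))  # a' Ainv a since V'AinvV = I
        tr_term = s2e * float(np.sum(1.0 / d))  # tr(Ainv Caa)
        s2a_new = (aAinva + tr_term) / q
        s2e_new = float(yty - b_hat @ Xty - a_hat @ Zty) / (n - rank_X)
        rel = max(
            abs(s2a_new - s2a) / max(s2a, 1e-12),
            abs(s2e_new - s2e) / max(s2e, 1e-12),
        )
        s2a, s2e = s2a_new, s2e_new
        history.append((s2a, s2e))
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM-REML did not converge within max_iter", RuntimeWarning)
    return VarianceComponents(
        sigma2_a=s2a, sigma2_e=s2e, converged=converged, n_iter=it, history=history
    )


def fit_pblup(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    varcomp: VarianceComponents,
) -> FitResult:
    """Pedigree BLUP: sparse mixed-model equations with A-inverse * lambda.

    EBV are returned for every pedigree member, phenotyped or not.
    """
    Ainv_rm = build_A_inverse(pedigree)
    animal_ids = Ainv_rm.ids
    missing = set(phenotypes["id"].astype(int)) - set(int(i) for i in animal_ids)
    if missing:
        raise KeyError(f"phenotyped ids missing from pedigree: {sorted(missing)[:5]}")
    y = phenotypes["value"].to_numpy(float)
    X_dense, levels = _hatch_design(phenotypes)
    X = sp.csr_matrix(X_dense)
    Z = _animal_incidence(phenotypes["id"].to_numpy(), animal_ids)
    lam = varcomp.ratio
    C = sp.bmat(
        [
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam * Ainv_rm.values],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = spla.spsolve(C, rhs)
    p = X.shape[1]
    return FitResult(
        method="PBLUP",
        ebv=pd.Series(sol[p:], index=pd.Index(animal_ids, name="id"), name="ebv"),
        fixed_solutions=pd.Series(sol[:p], index=levels, name="hatch_effect"),
        varcomp=varcomp,
    )


def fit_gblup_reduced(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    varcomp: VarianceComponents,
    freqs: "np.ndarray | None" = None,
    blend: float = 0.99,
) -> FitResult:
    """Reduced animal model on G: breeding values only for genotyped animals.

    Non-genotyped phenotyped progeny of two genotyped parents enter through
    the parent-average row (0.5, 0.5) with residual variance inflated by the
    Mendelian-sampling term 0.5 * sigma2_a; records whose parents are not
    both genotyped are dropped with a warning.  ``blend`` mixes G with the
    identity (G* = blend * G + (1 - blend) * I) to guarantee invertibility.
    """
    if np.isnan(genotypes.calls).any():
        raise ValueError("genotypes contain missing calls; impute first")
    G = build_G(genotypes, freqs).dense()
    if blend < 1.0:
        G = blend * G + (1.0 - blend) * np.eye(len(G))
    g_ids = genotypes.ids
    gset = set(int(i) for i in g_ids)
    parents = pedigree.set_index("id")[["sire", "dam"]]

    s2a, s2e = varcomp.sigma2_a, varcomp.sigma2_e
    if s2a <= 0:
        raise ZeroDivisionError("sigma2_a = 0: variance ratio undefined")
    pos = {int(i): k for k, i in enumerate(g_ids)}
    rows_T, cols_T, vals_T = [], [], []
    res_var, keep_idx = [], []
    for r, (rid, _) in enumerate(zip(phenotypes["id"].astype(int), phenotypes.index)):
        if rid in gset:
            rows_T.append(len(keep_idx))
            cols_T.append(pos[rid])
            vals_T.append(1.0)
            res_var.append(s2e)
            keep_idx.append(r)
        else:
            if rid not in parents.index:
                warnings.warn(f"record {rid} not in pedigree; dropped", RuntimeWarning)
                continue
            s, d = int(parents.loc[rid, "sire"]), int(parents.loc[rid, "dam"])
            if s in gset and d in gset:
                k = len(keep_idx)
                rows_T += [k, k]
                cols_T += [pos[s], pos[d]]
                vals_T += [0.5, 0.5]
                res_var.append(s2e + 0.5 * s2a)
                keep_idx.append(r)
            else:
                warnings.warn(
                    f"record {rid} has a non-genotyped parent; dropped",
                    RuntimeWarning,
                )
    if not keep_idx:
        raise ValueError("no usable records for the reduced animal model")
    sub = phenotypes.iloc[keep_idx]
    y = sub["value"].to_numpy(float)
    X, levels = _hatch_design(sub)
    T = sp.csr_matrix(
        (vals_T, (rows_T, cols_T)), shape=(len(keep_idx), len(g_ids))
    ).toarray()
    W = 1.0 / np.asarray(res_var)
    Ginv = np.linalg.inv(G)
    XtW = X.T * W
    TtW = T.T * W
    C = np.block(
        [
            [XtW @ X, XtW @ T],
            [TtW @ X, TtW @ T + Ginv / s2a],
        ]
    )
    rhs = np.concatenate([XtW @ y, TtW @ y])
    sol = np.linalg.solve(C, rhs)
    p = X.shape[1]
    return FitResult(
        method="GBLUP",
        ebv=pd.Series(sol[p:], index=pd.Index(g_ids, name="id"), name="gebv"),
        fixed_solutions=pd.Series(sol[:p], index=levels, name="hatch_effect"),
        varcomp=varcomp,
    )


def precorrect_phenotypes(
    phenotypes: pd.DataFrame, fit: FitResult
) -> pd.DataFrame:
    """Subtract the fitted hatch-within-generation solution from each record."""
    unseen = set(phenotypes["hatch"]) - set(fit.fixed_solutions.index)
    if unseen:
        raise KeyError(f"no fixed-effect solution for hatches {sorted(unseen)[:5]}")
    out = phenotypes.copy()
    out["value"] = out["value"].to_numpy(float) - fit.fixed_solutions.loc[
        out["hatch"]
    ].to_numpy(float)
    return out


def family_means(
    corrected: pd.DataFrame,
    pedigree: pd.DataFrame,
    genotyped: "set[int] | np.ndarray",
) -> pd.DataFrame:
    """Full-sib family means of non-genotyped progeny with genotyped parents.

    Returns one row per (sire, dam) family: mean pre-corrected phenotype and
    family size n.  The residual variance attached to such a mean record is
    (0.5 * sigma2_a + sigma2_e) / n: each sib deviates from the parent
    average by an independent Mendelian-sampling term (variance
    0.5 * sigma2_a, non-inbred parents) plus its residual, and both average
    down with family size.
    """
    gset = set(int(i) for i in np.asarray(list(genotyped)).ravel())
    ped = pedigree.set_index("id")
    rec = corrected[~corrected["id"].astype(int).isin(gset)].copy()
    if rec.empty:
        return pd.DataFrame(columns=["sire", "dam", "mean", "n"])
    rec["sire"] = ped.loc[rec["id"], "sire"].to_numpy()
    rec["dam"] = ped.loc[rec["id"], "dam"].to_numpy()
    rec = rec[
        rec["sire"].astype(int).isin(gset) & rec["dam"].astype(int).isin(gset)
    ]
    if rec.empty:
        return pd.DataFrame(columns=["sire", "dam", "mean", "n"])
    out = (
        rec.groupby(["sire", "dam"])["value"]
        .agg(mean="mean", n="size")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


# ---------------------------------------------------------------------------
# estimator-style wrappers


class PedigreeBLUP:
    """Animal-model pedigree BLUP with estimator conventions.

    Parameters are set at construction; ``fit`` solves the mixed-model
    equations (estimating variance components by EM-REML unless fixed ones
    are supplied) and exposes ``ebv_``, ``fixed_solutions_`` and
    ``varcomp_``.
    """

    def __init__(self, varcomp: "VarianceComponents | None" = None,
                 reml_tol: float = 1e-8, reml_max_iter: int = 500):
        self.varcomp = varcomp
        self.reml_tol = reml_tol
        self.reml_max_iter = reml_max_iter

    def get_params(self, deep=True):
        return {
            "varcomp": self.varcomp,
            "reml_tol": self.reml_tol,
            "reml_max_iter": self.reml_max_iter,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, phenotypes: pd.DataFrame, pedigree: pd.DataFrame):
        vc = self.varcomp
        if vc is None:
            vc = em_reml(
                phenotypes, pedigree, tol=self.reml_tol, max_iter=self.reml_max_iter
            )
        res = fit_pblup(phenotypes, pedigree, vc)
        self.ebv_ = res.ebv
        self.fixed_solutions_ = res.fixed_solutions
        self.varcomp_ = vc
        return self

    def predict(self, ids) -> np.ndarray:
        return self.ebv_.loc[np.asarray(ids)].to_numpy()


class ReducedGBLUP:
    """Reduced-animal-model GBLUP with estimator conventions (see
    :func:`fit_gblup_reduced`)."""

    def __init__(self, varcomp: "VarianceComponents | None" = None,
                 freqs=None, blend: float = 0.99):
        self.varcomp = varcomp
        self.freqs = freqs
        self.blend = blend

    def get_params(self, deep=True):
        return {"varcomp": self.varcomp, "freqs": self.freqs, "blend": self.blend}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, phenotypes, genotypes: GenotypeMatrix, pedigree):
        vc = self.varcomp
        if vc is None:
            vc = em_reml(phenotypes, pedigree)
        res = fit_gblup_reduced(
            phenotypes, genotypes, pedigree, vc, freqs=self.freqs, blend=self.blend
        )
        self.ebv_ = res.ebv
        self.fixed_solutions_ = res.fixed_solutions
        self.varcomp_ = vc
        return self

    def predict(self, ids) -> np.ndarray:
        return self.ebv_.loc[np.asarray(ids)].to_numpy()


class RRBlup(RegressorMixin, BaseEstimator):
    """Closed-form ridge regression on centered SNP dosages (SNP-BLUP).

    The marker-effect view of GBLUP: effects shrunk with ridge parameter
    lambda = sigma2_e / sigma2_alpha, sigma2_alpha = sigma2_a / (2 sum p(1-p)).
    """

    def __init__(self, sigma2_a: float = 1.0, sigma2_e: float = 1.0,
                 fit_intercept: bool = True):
        self.sigma2_a = sigma2_a
        self.sigma2_e = sigma2_e
        self.fit_intercept = fit_intercept

    def fit(self, X, y, sample_weight=None, freqs=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if freqs is None:
            freqs = X.mean(axis=0) / 2.0
        freqs = np.asarray(freqs, dtype=float)
        Z = X - 2.0 * freqs
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight)
        sum2pq = float(np.sum(2.0 * freqs * (1.0 - freqs)))
        if sum2pq <= 0:
            raise ValueError("no segregating SNP at the centering frequencies")
        lam = self.sigma2_e / (self.sigma2_a / sum2pq)
        m = Z.shape[1]
        ZtW = Z.T * w
        if self.fit_intercept:
            # intercept estimated jointly (unpenalized)
            ones = np.ones((len(y), 1))
            C = np.block(
                [
                    [(ones.T * w) @ ones, (ones.T * w) @ Z],
                    [ZtW @ ones, ZtW @ Z + lam * np.eye(m)],
                ]
            )
            rhs = np.concatenate([(ones.T * w) @ y, ZtW @ y])
            sol = np.linalg.solve(C, rhs)
            self.intercept_ = float(sol[0])
            self.alpha_ = sol[1:]
        else:
            self.intercept_ = 0.0
            self.alpha_ = np.linalg.solve(ZtW @ Z + lam * np.eye(m), ZtW @ y)
        self.freqs_ = freqs
        self.gebv_ = Z @ self.alpha_
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted = getattr(self, "alpha_", None)
        if check_is_fitted is None:
            raise RuntimeError("RRBlup is not fitted")
        X = np.asarray(X, dtype=float)
        return (X - 2.0 * self.freqs_) @ self.alpha_
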