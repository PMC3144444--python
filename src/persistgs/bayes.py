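"""Gibbs samplers for BayesA and BayesCpi marker-effect models.

Both models regress pre-corrected records (individual phenotypes and
weighted full-sib family means) on centered SNP dosages with an intercept:

    y_j = mu + sum_k z_jk alpha_k + e_j,   e_j ~ N(0, sigma2_e / w_j).

BayesA gives every SNP its own effect variance with a scaled-inverse-chi^2
prior (nu_a degrees of freedom).  BayesCpi gives each SNP an inclusion
indicator, a variance common to all included SNP (scaled-inverse-chi^2,
nu_a = 4.2), and treats the exclusion probability pi as unknown with a
uniform prior, so its full conditional is Beta on the inclusion counts.

The per-locus updates run in numba kernels (residual-update trick, O(nm)
per sweep); all randomness flows from a single seeded generator so chains
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .simulate import GenotypeMatrix

__all__ = [
    "McmcConfig",
    "WgrPosterior",
    "BayesA",
    "BayesCPi",
    "fit_bayesA",
    "fit_bayesCpi",
    "gebv_from_effects",
]


@dataclass
class McmcConfig:
    chain_length: int = 160_000
    burn_in: int = 50_000
    thin: int = 10
    seed: int = 0
    nu_a: float = 4.2
    pi_fixed: "float | None" = None
    scale_override: "float | None" = None
    pi0: float = 0.95  # assumed initial pi for the BayesCpi prior scale

    def __post_init__(self) -> None:
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be shorter than chain_length")
        if self.nu_a <= 2:
            raise ValueError("nu_a must exceed 2 for a finite prior mean")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class WgrPosterior:
    snp_ids: pd.Index
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    sigma2_e_mean: float
    gebv: pd.Series  # training individuals
    freqs: np.ndarray  # centering frequencies
    pi_mean: "float | None" = None
    inclusion_prob: "np.ndarray | None" = None
    monomorphic: "np.ndarray | None" = None


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _bayesA_sweep(Z, w, e, alpha, sigma2_k, sigma2_e, c, norm):  # pragma: no cover
    n, m = Z.shape
    for k in range(m):
        if c[k] == 0.0:
            continue
        rhs = c[k] * alpha[k]
        for i in range(n):
            rhs += w[i] * Z[i, k] * e[i]
        lhs = c[k] + sigma2_e / sigma2_k[k]
        new = rhs / lhs + norm[k] * np.sqrt(sigma2_e / lhs)
        diff = new - alpha[k]
        if diff != 0.0:
            for i in range(n):
                e[i] -= Z[i, k] * diff
        alpha[k] = new


@njit(cache=True)
def _bayesC_sweep(
    Z, w, e, alpha, delta, sigma2_alpha, sigma2_e, pi, c, norm, unif
):  # pragma: no cover
    n, m = Z.shape
    m_plus = 0
    for k in range(m):
        if c[k] == 0.0:
            delta[k] = 0
            continue
        r = c[k] * alpha[k]
        for i in range(n):
            r += w[i] * Z[i, k] * e[i]
        if pi >= 1.0:
            include = False
        elif pi <= 0.0:
            include = True
        else:
            v0 = c[k] * sigma2_e
            v1 = v0 + c[k] * c[k] * sigma2_alpha
            log_odds = (
                np.log((1.0 - pi) / pi)
                + 0.5 * np.log(v0 / v1)
                + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
            )
            if log_odds > 35.0:
                include = True
            elif log_odds < -35.0:
                include = False
            else:
                include = unif[k] < 1.0 / (1.0 + np.exp(-log_odds))
        if include:
            lhs = c[k] + sigma2_e / sigma2_alpha
            new = r / lhs + norm[k] * np.sqrt(sigma2_e / lhs)
            delta[k] = 1
            m_plus += 1
        else:
            new = 0.0
            delta[k] = 0
        diff = new - alpha[k]
        if diff != 0.0:
            for i in range(n):
                e[i] -= Z[i, k] * diff
        alpha[k] = new
    return m_plus


# ---------------------------------------------------------------------------
# shared sampler scaffolding


def _prepare(X, y, sample_weight, freqs):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per record")
    if freqs is None:
        freqs = X.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=np.float64)
    Z = np.asfortranarray(X - 2.0 * freqs)
    w = (
        np.ones(len(y))
        if sample_weight is None
        else np.asarray(sample_weight, dtype=np.float64)
    )
    if (w <= 0).any():
        raise ValueError("sample weights must be positive")
    c = np.einsum("i,ij,ij->j", w, Z, Z)
    return Z, y, w, c, freqs


def _update_intercept(mu, e, w, sigma2_e, rng):
    sw = w.sum()
    rhs = float(np.dot(w, e)) + mu * sw
    new = rhs / sw + rng.standard_normal() * np.sqrt(sigma2_e / sw)
    e -= new - mu
    return new


def _sample_sigma2_e(e, w, n, rng):
    ss = float(np.dot(w, e * e))
    return ss / rng.chisquare(n)


def _run_bayesA(X, y, sample_weight, freqs, sigma2_a, sigma2_e0, mcmc, rng):
    Z, y, w, c, freqs = _prepare(X, y, sample_weight, freqs)
    n, m = Z.shape
    sum2pq = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if sum2pq <= 0:
        raise ValueError("no segregating SNP at the centering frequencies")
    nu = mcmc.nu_a
    if mcmc.scale_override is not None:
        S = mcmc.scale_override
    else:
        S = (sigma2_a / sum2pq) * (nu - 2.0) / nu
    alpha = np.zeros(m)
    sigma2_k = np.full(m, S * nu / (nu - 2.0))
    sigma2_e = sigma2_e0
    mu = float(np.average(y, weights=w))
    e = y - mu
    keep_a = []
    keep_se = []
    gebv_sum = np.zeros(n)
    kept = 0
    for it in range(mcmc.chain_length):
        # per-locus variances given effects (vectorized), then effects
        sigma2_k = (nu * S + alpha**2) / rng.chisquare(nu + 1.0, size=m)
        _bayesA_sweep(Z, w, e, alpha, sigma2_k, sigma2_e, c, rng.standard_normal(m))
        mu = _update_intercept(mu, e, w, sigma2_e, rng)
        sigma2_e = _sample_sigma2_e(e, w, n, rng)
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            keep_a.append(alpha.copy())
            keep_se.append(sigma2_e)
            gebv_sum += Z @ alpha
            kept += 1
    A = np.array(keep_a)
    return {
        "alpha_mean": A.mean(axis=0),
        "alpha_sd": A.std(axis=0, ddof=1) if len(A) > 1 else np.zeros(m),
        "sigma2_e_mean": float(np.mean(keep_se)),
        "gebv": gebv_sum / kept,
        "freqs": freqs,
        "monomorphic": c == 0.0,
    }


def _run_bayesC(X, y, sample_weight, freqs, sigma2_a, sigma2_e0, mcmc, rng):
    Z, y, w, c, freqs = _prepare(X, y, sample_weight, freqs)
    n, m = Z.shape
    sum2pq = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if sum2pq <= 0:
        raise ValueError("no segregating SNP at the centering frequencies")
    nu = mcmc.nu_a
    pi0 = mcmc.pi_fixed if mcmc.pi_fixed is not None else mcmc.pi0
    frac = max(1.0 - pi0, 1.0 / m)  # expected fraction of SNP with effects
    if mcmc.scale_override is not None:
        S = mcmc.scale_override
    else:
        S = (sigma2_a / (frac * sum2pq)) * (nu - 2.0) / nu
    alpha = np.zeros(m)
    delta = np.zeros(m, dtype=np.int64)
    sigma2_alpha = S * nu / (nu - 2.0)
    sigma2_e = sigma2_e0
    pi = mcmc.pi_fixed if mcmc.pi_fixed is not None else 0.5
    mu = float(np.average(y, weights=w))
    e = y - mu
    keep_a, keep_se, keep_pi = [], [], []
    incl_sum = np.zeros(m)
    gebv_sum = np.zeros(n)
    kept = 0
    for it in range(mcmc.chain_length):
        m_plus = _bayesC_sweep(
            Z,
            w,
            e,
            alpha,
            delta,
            sigma2_alpha,
            sigma2_e,
            pi,
            c,
            rng.standard_normal(m),
            rng.uniform(size=m),
        )
        ss_alpha = float(np.sum(alpha[delta == 1] ** 2))
        sigma2_alpha = (nu * S + ss_alpha) / rng.chisquare(nu + m_plus)
        if mcmc.pi_fixed is None:
            pi = rng.beta(m - m_plus + 1.0, m_plus + 1.0)
        mu = _update_intercept(mu, e, w, sigma2_e, rng)
        sigma2_e = _sample_sigma2_e(e, w, n, rng)
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            keep_a.append(alpha.copy())
            keep_se.append(sigma2_e)
            keep_pi.append(pi)
            incl_sum += delta
            gebv_sum += Z @ alpha
            kept += 1
    A = np.array(keep_a)
    return {
        "alpha_mean": A.mean(axis=0),
        "alpha_sd": A.std(axis=0, ddof=1) if len(A) > 1 else np.zeros(m),
        "sigma2_e_mean": float(np.mean(keep_se)),
        "gebv": gebv_sum / kept,
        "freqs": freqs,
        "pi_mean": float(np.mean(keep_pi)),
        "inclusion_prob": incl_sum / kept,
        "monomorphic": c == 0.0,
    }


# ---------------------------------------------------------------------------
# scikit-learn estimators


class _BayesBase(RegressorMixin, BaseEstimator):
    def __init__(
        self,
        chain_length=160_000,
        burn_in=50_000,
        thin=10,
        nu_a=4.2,
        sigma2_a=1.0,
        sigma2_e=1.0,
        scale_override=None,
        random_state=0,
    ):
        self.chain_length = chain_length
        self.burn_in = burn_in
        self.thin = thin
        self.nu_a = nu_a
        self.sigma2_a = sigma2_a
        self.sigma2_e = sigma2_e
        self.scale_override = scale_override
        self.random_state = random_state

    def _mcmc(self, **extra) -> McmcConfig:
        return McmcConfig(
            chain_length=self.chain_length,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
            nu_a=self.nu_a,
            scale_override=self.scale_override,
            **extra,
        )

    def predict(self, X) -> np.ndarray:
        """GEBV for new genotype dosages using the training centering."""
        check_is_fitted(self, "alpha_mean_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.alpha_mean_):
            raise ValueError(
                f"X has {X.shape[1]} SNP, model was trained on {len(self.alpha_mean_)}"
            )
        return (X - 2.0 * self.freqs_) @ self.alpha_mean_


class BayesA(_BayesBase):
    """Marker-effect model with a locus-specific effect variance per SNP.

    Every SNP keeps a nonzero effect each iteration; heavy-tailed shrinkage
    comes from the scaled-inverse-chi^2 prior on each locus variance.
    """

    def fit(self, X, y, sample_weight=None, freqs=None):
        rng = np.random.default_rng(self.random_state)
        out = _run_bayesA(
            X, y, sample_weight, freqs, self.sigma2_a, self.sigma2_e, self._mcmc(), rng
        )
        self.alpha_mean_ = out["alpha_mean"]
        self.alpha_sd_ = out["alpha_sd"]
        self.sigma2_e_mean_ = out["sigma2_e_mean"]
        self.gebv_ = out["gebv"]
        self.freqs_ = out["freqs"]
        self.monomorphic_ = out["monomorphic"]
        return self


class BayesCPi(_BayesBase):
    """Marker-effect model with per-SNP inclusion indicators, a common
    effect variance, and an estimated proportion pi of excluded SNP."""

    def __init__(
        self,
        chain_length=160_000,
        burn_in=50_000,
        thin=10,
        nu_a=4.2,
        sigma2_a=1.0,
        sigma2_e=1.0,
        scale_override=None,
        pi_fixed=None,
        pi0=0.95,
        random_state=0,
    ):
        super().__init__(
            chain_length, burn_in, thin, nu_a, sigma2_a, sigma2_e, scale_override,
            random_state,
        )
        self.pi_fixed = pi_fixed
        self.pi0 = pi0

    def fit(self, X, y, sample_weight=None, freqs=None):
        rng = np.random.default_rng(self.random_state)
        mcmc = self._mcmc(pi_fixed=self.pi_fixed, pi0=self.pi0)
        out = _run_bayesC(
            X, y, sample_weight, freqs, self.sigma2_a, self.sigma2_e, mcmc, rng
        )
        self.alpha_mean_ = out["alpha_mean"]
        self.alpha_sd_ = out["alpha_sd"]
        self.sigma2_e_mean_ = out["sigma2_e_mean"]
        self.gebv_ = out["gebv"]
        self.freqs_ = out["freqs"]
        self.pi_mean_ = out["pi_mean"]
        self.inclusion_prob_ = out["inclusion_prob"]
        self.monomorphic_ = out["monomorphic"]
        return self


# ---------------------------------------------------------------------------
# functional wrappers on GenotypeMatrix records


def _records_to_xy(records: pd.DataFrame, genotypes: GenotypeMatrix):
    """records: columns id, value and optional weight; rows aligned on ids."""
    sub = genotypes.subset_individuals(records["id"].to_numpy())
    w = records["weight"].to_numpy(float) if "weight" in records else None
    return sub.calls, records["value"].to_numpy(float), w


def fit_bayesA(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    varcomp,
    mcmc: McmcConfig = McmcConfig(),
    freqs: "np.ndarray | None" = None,
) -> WgrPosterior:
    X, y, w = _records_to_xy(records, genotypes)
    est = BayesA(
        chain_length=mcmc.chain_length,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
        nu_a=mcmc.nu_a,
        sigma2_a=varcomp.sigma2_a,
        sigma2_e=varcomp.sigma2_e,
        scale_override=mcmc.scale_override,
        random_state=mcmc.seed,
    ).fit(X, y, sample_weight=w, freqs=freqs)
    return WgrPosterior(
        snp_ids=genotypes.snps.index,
        alpha_mean=est.alpha_mean_,
        alpha_sd=est.alpha_sd_,
        sigma2_e_mean=est.sigma2_e_mean_,
        gebv=pd.Series(est.gebv_, index=records["id"].to_numpy(), name="gebv"),
        freqs=est.freqs_,
        monomorphic=est.monomorphic_,
    )


def fit_bayesCpi(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    varcomp,
    mcmc: McmcConfig = McmcConfig(),
    freqs: "np.ndarray | None" = None,
) -> WgrPosterior:
    X, y, w = _records_to_xy(records, genotypes)
    est = BayesCPi(
        chain_length=mcmc.chain_length,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
        nu_a=mcmc.nu_a,
        sigma2_a=varcomp.sigma2_a,
        sigma2_e=varcomp.sigma2_e,
        scale_override=mcmc.scale_override,
        pi_fixed=mcmc.pi_fixed,
        pi0=mcmc.pi0,
        random_state=mcmc.seed,
    ).fit(X, y, sample_weight=w, freqs=freqs)
    return WgrPosterior(
        snp_ids=genotypes.snps.index,
        alpha_mean=est.alpha_mean_,
        alpha_sd=est.alpha_sd_,
        sigma2_e_mean=est.sigma2_e_mean_,
        gebv=pd.Series(est.gebv_, index=records["id"].to_numpy(), name="gebv"),
        freqs=est.freqs_,
        pi_mean=est.pi_mean_,
        inclusion_prob=est.inclusion_prob_,
        monomorphic=est.monomorphic_,
    )


def gebv_from_effects(
    genotypes: GenotypeMatrix,
    posterior: WgrPosterior,
    freqs: "np.ndarray | None" = None,
) -> pd.Series:
    """GEBV_i = sum_k (g_ik - 2 p_k) alpha_k for any genotyped individuals.

    The SNP set must match the training panel; centering frequencies
    default to those used in training.
    """
    if not genotypes.snps.index.equals(posterior.snp_ids):
        missing = posterior.snp_ids.difference(genotypes.snps.index).tolist()
        extra = genotypes.snps.index.difference(posterior.snp_ids).tolist()
        raise KeyError(
            f"SNP set mismatch: missing {missing[:5]}, unexpected {extra[:5]}"
        )
    if freqs is None:
        freqs = posterior.freqs
    Z = genotypes.calls - 2.0 * np.asarray(freqs)
    return pd.Series(
        Z @ posterior.alpha_mean, index=genotypes.ids, name="gebv"
    )
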