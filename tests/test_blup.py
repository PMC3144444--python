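import warnings

import numpy as np
import pandas as pd
import pytest

from persistgs import (
    SimConfig,
    VarianceComponents,
    build_A,
    build_G,
    em_reml,
    family_means,
    fit_gblup_reduced,
    fit_pblup,
    impute_missing,
    precorrect_phenotypes,
    simulate_population,
)
from persistgs.blup import RRBlup
from persistgs.simulate import GenotypeMatrix, snp_map

from conftest import make_pedigree


def phen_frame(ids, values, hatches=None, generation=0):
    return pd.DataFrame(
        {
            "id": ids,
            "trait": "t",
            "value": values,
            "hatch": hatches if hatches is not None else ["h1"] * len(ids),
            "generation": generation,
        }
    )


def gls_animal_model(y, X, Z, A, s2a, s2e):
    """Dense GLS oracle: fixed effects by GLS on V, EBV by conditional mean."""
    V = s2a * (Z @ A @ Z.T) + s2e * np.eye(len(y))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    a = s2a * A @ Z.T @ Vi @ (y - X @ b)
    return b, a


class TestPblup:
    def toy(self):
        rng = np.random.default_rng(3)
        rows = [(i, 0, 0, 0, "M" if i % 2 else "F", "h") for i in range(1, 5)]
        rows += [
            (5, 1, 2, 1, "M", "h"),
            (6, 1, 2, 1, "F", "h"),
            (7, 3, 4, 1, "M", "h"),
            (8, 5, 6, 2, "F", "h"),
            (9, 5, 4, 2, "M", "h"),
            (10, 7, 8, 3, "F", "h"),
        ]
        ped = make_pedigree(rows)
        ids = ped["id"].to_numpy()
        hatches = np.where(ids % 2 == 0, "h1", "h2")
        phen = phen_frame(ids, rng.normal(0, 1, 10), hatches)
        return ped, phen

    def test_mme_equals_dense_gls_oracle(self):
        ped, phen = self.toy()
        vc = VarianceComponents(sigma2_a=0.8, sigma2_e=1.2)
        fit = fit_pblup(phen, ped, vc)
        A = build_A(ped)
        order = {int(i): k for k, i in enumerate(A.ids)}
        y = phen["value"].to_numpy()
        X = pd.get_dummies(phen["hatch"]).to_numpy(float)
        Z = np.zeros((len(y), len(A.ids)))
        for r, i in enumerate(phen["id"]):
            Z[r, order[int(i)]] = 1.0
        b, a = gls_animal_model(y, X, Z, A.dense(), 0.8, 1.2)
        np.testing.assert_allclose(
            fit.ebv.loc[A.ids].to_numpy(), a, atol=1e-8
        )
        np.testing.assert_allclose(
            fit.fixed_solutions.to_numpy(), b, atol=1e-8
        )

    def test_ebv_vanish_in_infinite_shrinkage_limit(self):
        ped, phen = self.toy()
        fit = fit_pblup(phen, ped, VarianceComponents(1e-10, 1.0))
        assert np.abs(fit.ebv).max() < 1e-6

    def test_zero_additive_variance_rejected(self):
        ped, phen = self.toy()
        with pytest.raises(ZeroDivisionError):
            fit_pblup(phen, ped, VarianceComponents(0.0, 1.0))

    def test_unrelated_unphenotyped_animal_gets_zero_ebv(self):
        ped, phen = self.toy()
        ped = pd.concat(
            [ped, make_pedigree([(99, 0, 0, 0, "M", "h")])], ignore_index=True
        )
        fit = fit_pblup(phen, ped, VarianceComponents(1.0, 1.0))
        assert fit.ebv.loc[99] == pytest.approx(0.0, abs=1e-12)

    def test_unphenotyped_progeny_ebv_is_parent_average(self):
        ped, phen = self.toy()
        ped = pd.concat(
            [ped, make_pedigree([(11, 9, 10, 4, "M", "h")])], ignore_index=True
        )
        fit = fit_pblup(phen, ped, VarianceComponents(1.0, 1.0))
        assert fit.ebv.loc[11] == pytest.approx(
            0.5 * (fit.ebv.loc[9] + fit.ebv.loc[10]), abs=1e-10
        )

    def test_ebv_invariant_to_constant_shift_within_hatch(self):
        ped, phen = self.toy()
        vc = VarianceComponents(1.0, 1.0)
        base = fit_pblup(phen, ped, vc)
        shifted = phen.copy()
        shifted.loc[shifted["hatch"] == "h1", "value"] += 7.0
        fit = fit_pblup(shifted, ped, vc)
        np.testing.assert_allclose(fit.ebv, base.ebv, atol=1e-10)


class TestEmReml:
    def sim(self, seed, pi=0.5, h2=0.4, n=500):
        return simulate_population(
            SimConfig(
                n_founders=100, n_generations=1, n_sires=20, n_dams=40,
                n_progeny_per_generation=n, n_snp=100, burn_in_generations=5,
                burn_in_ne=60, pi=pi, h2=h2, seed=seed,
            )
        )

    def test_loglik_nondecreasing_over_em_iterations(self):
        pop = self.sim(seed=1, n=150)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = em_reml(pop.phenotypes, pop.pedigree, max_iter=40)
        # dense REML log-likelihood oracle on the history of iterates
        A = build_A(pop.pedigree)
        order = {int(i): k for k, i in enumerate(A.ids)}
        phen = pop.phenotypes
        y = phen["value"].to_numpy()
        X = pd.get_dummies(phen["hatch"]).to_numpy(float)
        Z = np.zeros((len(y), len(A.ids)))
        for r, i in enumerate(phen["id"]):
            Z[r, order[int(i)]] = 1.0
        ZAZ = Z @ A.dense() @ Z.T

        def rell(s2a, s2e):
            V = s2a * ZAZ + s2e * np.eye(len(y))
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
            sign, ld_v = np.linalg.slogdet(V)
            sign2, ld_x = np.linalg.slogdet(XtViX)
            return -0.5 * (ld_v + ld_x + y @ P @ y)

        lls = [rell(a, e) for a, e in vc.history]
        assert all(b - a > -1e-6 for a, b in zip(lls, lls[1:]))

    def test_null_additive_variance_estimated_near_boundary(self):
        hits = 0
        for seed in range(6):
            pop = self.sim(seed=seed, pi=1.0)  # no QTL: sigma2_a = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vc = em_reml(pop.phenotypes, pop.pedigree)
            hits += vc.sigma2_a < 0.05 * vc.sigma2_e
        assert hits >= 5

    def test_h2_recovery_single_replicate_sanity(self):
        pop = self.sim(seed=9, n=800)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = em_reml(pop.phenotypes, pop.pedigree)
        assert abs(vc.h2 - 0.4) < 0.15


class TestGblupReduced:
    def genotyped_toy(self, n=24, m=120, seed=0):
        # external centering frequencies keep G full-rank (centering at the
        # observed column means would put the ones vector in G's null space)
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.2, 0.8, m)
        calls = rng.binomial(2, p, (n, m)).astype(float)
        gm = GenotypeMatrix(
            ids=np.arange(1, n + 1), snps=snp_map(m, 2, 1.0), calls=calls
        )
        ped = make_pedigree(
            [(i, 0, 0, 0, "M" if i % 2 else "F", "h") for i in range(1, n + 1)]
        )
        g = (calls - calls.mean(0)) @ rng.normal(0, 0.1, m)
        y = g + rng.normal(0, 1, n)
        return gm, ped, phen_frame(np.arange(1, n + 1), y), p

    def test_all_genotyped_equals_plain_G_animal_model(self):
        gm, ped, phen, p = self.genotyped_toy()
        vc = VarianceComponents(1.0, 1.0)
        fit = fit_gblup_reduced(phen, gm, ped, vc, freqs=p, blend=1.0)
        G = build_G(gm, freqs=p).dense()
        y = phen["value"].to_numpy()
        X = np.ones((len(y), 1))
        Z = np.eye(len(y))
        _, a = gls_animal_model(y, X, Z, G, 1.0, 1.0)
        np.testing.assert_allclose(fit.ebv.to_numpy(), a, atol=1e-10)

    def test_reduced_model_matches_full_model_with_progeny_fitted(self):
        rng = np.random.default_rng(7)
        m = 60
        p = rng.uniform(0.2, 0.8, m)
        parents = rng.binomial(2, p, (4, m)).astype(float)
        gm = GenotypeMatrix(
            ids=np.arange(1, 5), snps=snp_map(m, 2, 1.0), calls=parents
        )
        rows = [(1, 0, 0, 0, "M", "h"), (2, 0, 0, 0, "F", "h"),
                (3, 0, 0, 0, "M", "h"), (4, 0, 0, 0, "F", "h")]
        prog_ids = np.arange(5, 17)
        pairings = [(1, 2)] * 6 + [(3, 4)] * 6
        for i, (s, d) in zip(prog_ids, pairings):
            rows.append((int(i), s, d, 1, "M", "h"))
        ped = make_pedigree(rows)
        y = rng.normal(0, 1, 12)
        phen = phen_frame(prog_ids, y)
        s2a, s2e = 0.7, 1.3
        vc = VarianceComponents(s2a, s2e)
        fit = fit_gblup_reduced(phen, gm, ped, vc, freqs=p, blend=1.0)
        # full-model oracle: progeny carry their own breeding values with
        # covariance T G T' + 0.5 I around the genotyped parents
        G = build_G(gm, freqs=p).dense()
        T = np.zeros((12, 4))
        for r, (s, d) in enumerate(pairings):
            T[r, s - 1] = T[r, d - 1] = 0.5
        H = np.block(
            [[G, G @ T.T], [T @ G, T @ G @ T.T + 0.5 * np.eye(12)]]
        )
        X = np.ones((12, 1))
        Z = np.hstack([np.zeros((12, 4)), np.eye(12)])
        _, a_full = gls_animal_model(y, X, Z, H, s2a, s2e)
        np.testing.assert_allclose(
            fit.ebv.to_numpy(), a_full[:4], atol=1e-6
        )

    def test_gebv_equal_rrblup_marker_effects(self):
        gm, ped, phen, p = self.genotyped_toy(n=30, m=200, seed=4)
        vc = VarianceComponents(0.9, 1.1)
        fit = fit_gblup_reduced(phen, gm, ped, vc, freqs=p, blend=1.0)
        # independent ridge oracle with matched variance parameterization
        calls = gm.calls
        freqs = p
        Z = calls - 2 * freqs
        sum2pq = float(np.sum(2 * freqs * (1 - freqs)))
        lam = vc.sigma2_e / (vc.sigma2_a / sum2pq)
        n, m = Z.shape
        ones = np.ones((n, 1))
        C = np.block(
            [
                [ones.T @ ones, ones.T @ Z],
                [Z.T @ ones, Z.T @ Z + lam * np.eye(m)],
            ]
        )
        rhs = np.concatenate([ones.T @ phen["value"], Z.T @ phen["value"]])
        sol = np.linalg.solve(C, rhs)
        gebv_rr = Z @ sol[1:]
        np.testing.assert_allclose(fit.ebv.to_numpy(), gebv_rr, atol=1e-6)
        # and the packaged closed-form SNP-BLUP agrees too
        est = RRBlup(sigma2_a=0.9, sigma2_e=1.1).fit(calls, phen["value"], freqs=p)
        np.testing.assert_allclose(est.gebv_, gebv_rr, atol=1e-6)

    def test_record_with_non_genotyped_parent_dropped_with_warning(self):
        gm, ped, phen, _ = self.genotyped_toy(n=6)
        ped = pd.concat(
            [ped, make_pedigree([(50, 0, 0, 0, "M", "h"), (51, 0, 0, 0, "F", "h"),
                                 (52, 50, 51, 1, "M", "h")])],
            ignore_index=True,
        )
        phen = pd.concat(
            [phen, phen_frame([52], [1.0], generation=1)], ignore_index=True
        )
        with pytest.warns(RuntimeWarning):
            fit = fit_gblup_reduced(phen, gm, ped, VarianceComponents(1, 1))
        assert 52 not in fit.ebv.index


class TestPrecorrection:
    def test_two_hatch_arithmetic_oracle(self):
        from persistgs.blup import FitResult

        phen = phen_frame(
            [1, 2, 3, 4], [5.0, 7.0, 1.0, 3.0], ["a", "a", "b", "b"]
        )
        fit = FitResult(
            method="PBLUP",
            ebv=pd.Series(dtype=float),
            fixed_solutions=pd.Series({"a": 2.0, "b": -1.0}),
            varcomp=VarianceComponents(1, 1),
        )
        out = precorrect_phenotypes(phen, fit)
        # independent arithmetic: group means shift by minus the solution
        assert out.loc[out["hatch"] == "a", "value"].mean() == pytest.approx(
            6.0 - 2.0
        )
        assert out.loc[out["hatch"] == "b", "value"].mean() == pytest.approx(
            2.0 + 1.0
        )

    def test_zero_solutions_idempotent(self):
        from persistgs.blup import FitResult

        phen = phen_frame([1, 2], [1.0, 2.0], ["a", "a"])
        fit = FitResult(
            "PBLUP", pd.Series(dtype=float), pd.Series({"a": 0.0}),
            VarianceComponents(1, 1),
        )
        once = precorrect_phenotypes(phen, fit)
        twice = precorrect_phenotypes(once, fit)
        pd.testing.assert_frame_equal(once, twice)

    def test_unseen_hatch_rejected(self):
        from persistgs.blup import FitResult

        phen = phen_frame([1], [1.0], ["new"])
        fit = FitResult(
            "PBLUP", pd.Series(dtype=float), pd.Series({"a": 0.0}),
            VarianceComponents(1, 1),
        )
        with pytest.raises(KeyError):
            precorrect_phenotypes(phen, fit)


class TestFamilyMeans:
    def setup_family(self):
        rows = [(1, 0, 0, 0, "M", "h"), (2, 0, 0, 0, "F", "h"),
                (3, 0, 0, 0, "M", "h"), (4, 0, 0, 0, "F", "h")]
        for i in range(5, 10):
            rows.append((i, 1, 2, 1, "M", "h"))
        rows.append((10, 3, 4, 1, "F", "h"))
        return make_pedigree(rows)

    def test_family_of_one_and_of_five(self):
        ped = self.setup_family()
        phen = phen_frame(np.arange(5, 11), [1.0, 2.0, 3.0, 4.0, 5.0, 9.0],
                          generation=1)
        fams = family_means(phen, ped, genotyped={1, 2, 3, 4})
        fams = fams.set_index(["sire", "dam"])
        assert fams.loc[(1, 2), "mean"] == pytest.approx(3.0)  # brute-force avg
        assert fams.loc[(1, 2), "n"] == 5
        assert fams.loc[(3, 4), "mean"] == pytest.approx(9.0)
        assert fams.loc[(3, 4), "n"] == 1

    def test_genotyped_progeny_excluded(self):
        ped = self.setup_family()
        phen = phen_frame(np.arange(5, 11), np.ones(6), generation=1)
        fams = family_means(phen, ped, genotyped={1, 2, 3, 4, 5, 6, 7, 8, 9, 10})
        assert fams.empty

    def test_monte_carlo_variance_matches_weighting_formula(self):
        """var(family mean - parent-average BV) = (0.5 s2a + s2e)/n."""
        devs = []
        for seed in (1, 2):
            cfg = SimConfig(
                n_founders=320, n_generations=1, n_sires=40, n_dams=150,
                n_progeny_per_generation=600, n_snp=400,
                burn_in_generations=10, burn_in_ne=100, pi=0.9, h2=0.4,
                n_hatches_per_generation=1, hatch_effect_sd_factor=0.0,
                seed=seed,
            )
            pop = simulate_population(cfg)
            ped = pop.pedigree.set_index("id")
            ph = pop.phenotypes.copy()
            ph["value"] -= list(pop.architecture.hatch_effects.values())[0]
            fams = family_means(ph, pop.pedigree, genotyped=set(
                pop.pedigree.loc[pop.pedigree["generation"] == -1, "id"]
            ))
            for _, row in fams.iterrows():
                pa = 0.5 * (pop.tbv.loc[row["sire"]] + pop.tbv.loc[row["dam"]])
                devs.append((row["mean"] - pa, row["n"]))
        arr = np.array(devs)
        n4 = arr[arr[:, 1] == 4, 0]
        s2a, s2e = 1.0, 1.0 * (1 - 0.4) / 0.4
        expected = (0.5 * s2a + s2e) / 4
        assert abs(n4.var(ddof=1) - expected) / expected < 0.10
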