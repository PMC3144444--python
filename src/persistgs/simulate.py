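"""Gene-dropping simulator for a closed breeding population with discrete generations.

Emulates the data structure of a commercial layer line under genomic
selection: a burn-in phase of random mating generates founder linkage
disequilibrium, after which each generation is bred from a limited set of
selected sires and dams (default 60 and 310), progeny are phenotyped within
hatches, and parents plus a fraction of progeny are genotyped on a SNP
panel.  A single additive trait is controlled by a subset of the panel SNP
(the proportion ``pi`` of SNP carries no effect), so both polygenic and
oligogenic architectures can be simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "TraitArchitecture",
    "Population",
    "simulate_population",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "select_parents",
]


@dataclass
class SimConfig:
    """Parameters of one simulated closed breeding line.

    Counts refer to a single (discrete) generation.  ``pi`` is the
    proportion of panel SNP with zero effect on the trait and ``h2`` the
    narrow-sense heritability realised in the founders.
    """

    n_founders: int = 370
    n_generations: int = 6
    n_sires: int = 60
    n_dams: int = 310
    n_progeny_per_generation: int = 2400
    n_hatches_per_generation: int = 2
    n_chromosomes: int = 10
    chromosome_length: float = 1.0  # Morgans
    n_snp: int = 2000
    pi: float = 0.95
    h2: float = 0.4
    sigma2_a: float = 1.0
    selection_mode: str = "random"  # random | phenotype | ebv
    progeny_genotyped_fraction: float = 0.13
    burn_in_generations: int = 100
    burn_in_ne: int = 100
    missing_rate: float = 0.01
    hatch_effect_sd_factor: float = 0.5  # hatch SD = factor * sigma2_e**0.5 / 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        for name in (
            "n_founders",
            "n_sires",
            "n_dams",
            "n_progeny_per_generation",
            "n_hatches_per_generation",
            "n_chromosomes",
            "n_snp",
            "burn_in_ne",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_generations < 0 or self.burn_in_generations < 0:
            raise ValueError("generation counts must be non-negative")
        if self.selection_mode not in ("random", "phenotype", "ebv"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.n_sires + self.n_dams > self.n_founders:
            raise ValueError(
                "infeasible config: n_sires + n_dams exceeds the number of founders"
            )
        if self.n_generations > 1 and (
            self.n_sires + self.n_dams > self.n_progeny_per_generation
        ):
            raise ValueError(
                "infeasible config: n_sires + n_dams exceeds the number of "
                "candidates per generation"
            )


@dataclass
class GenotypeMatrix:
    """Allele-count genotypes (0/1/2, NaN = missing) for genotyped individuals.

    ``snps`` carries one row per SNP with columns ``chrom`` and ``pos``
    (map position in Morgans, non-decreasing within chromosome).
    """

    ids: np.ndarray  # (n,) int individual ids
    snps: pd.DataFrame  # index snp_id (str), columns chrom (int), pos (float)
    calls: np.ndarray  # (n, m) float, values {0,1,2,nan}

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.ids), len(self.snps)):
            raise ValueError("calls shape inconsistent with ids/snps")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype calls must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snp(self) -> int:
        return len(self.snps)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP allele frequency over observed (non-missing) calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        ids = np.asarray(ids)
        pos = {int(i): k for k, i in enumerate(self.ids)}
        missing = [int(i) for i in ids if int(i) not in pos]
        if missing:
            raise KeyError(f"individuals not genotyped: {missing[:5]}")
        rows = [pos[int(i)] for i in ids]
        return GenotypeMatrix(ids=ids, snps=self.snps, calls=self.calls[rows])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Column subset; ``keep`` is a boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            ids=self.ids, snps=self.snps.iloc[keep], calls=self.calls[:, keep]
        )


@dataclass
class TraitArchitecture:
    """Ground truth of the simulated trait: QTL, effects and variances."""

    qtl_idx: np.ndarray  # indices into the SNP panel
    alpha: np.ndarray  # additive effect per QTL (trait units / allele copy)
    sigma2_a: float
    sigma2_e: float
    hatch_effects: dict = field(default_factory=dict)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_idx)

    @property
    def h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0


class Population(NamedTuple):
    pedigree: pd.DataFrame  # id, sire, dam, generation, sex, hatch
    genotypes: GenotypeMatrix
    architecture: TraitArchitecture
    phenotypes: pd.DataFrame  # id, trait, value, hatch, generation
    tbv: pd.Series  # true breeding value indexed by id


# ---------------------------------------------------------------------------
# meiosis machinery


def snp_map(n_snp: int, n_chrom: int, length: float) -> pd.DataFrame:
    """Equally spaced SNP positions over ``n_chrom`` chromosomes."""
    base = n_snp // n_chrom
    extra = n_snp % n_chrom
    chroms, pos = [], []
    for c in range(n_chrom):
        m_c = base + (1 if c < extra else 0)
        chroms.append(np.full(m_c, c + 1))
        pos.append((np.arange(1, m_c + 1) / (m_c + 1)) * length)
    df = pd.DataFrame(
        {"chrom": np.concatenate(chroms).astype(int), "pos": np.concatenate(pos)}
    )
    df.index = pd.Index([f"snp{i + 1}" for i in range(n_snp)], name="snp_id")
    return df


def _chrom_slices(snps: pd.DataFrame) -> list[tuple[slice, np.ndarray]]:
    out = []
    chrom = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        out.append((slice(idx[0], idx[-1] + 1), pos[idx]))
    return out


def _gamete(
    hap: np.ndarray,
    chrom_slices: list[tuple[slice, np.ndarray]],
    length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiosis under the Haldane map (Poisson crossovers, no interference)."""
    m = hap.shape[1]
    out = np.empty(m, dtype=np.int8)
    for sl, pos in chrom_slices:
        n_xo = rng.poisson(length)
        start = rng.integers(2)
        if n_xo == 0:
            out[sl] = hap[start, sl]
        else:
            xo = np.sort(rng.uniform(0.0, length, n_xo))
            phase = (start + np.searchsorted(xo, pos)) % 2
            seg = hap[:, sl]
            out[sl] = np.where(phase == 0, seg[0], seg[1])
    return out


def _random_mating_generation(
    haps: np.ndarray,
    sex: np.ndarray,
    n_offspring: int,
    chrom_slices,
    length: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One burn-in generation of random mating at constant size."""
    males = np.flatnonzero(sex == 0)
    females = np.flatnonzero(sex == 1)
    new = np.empty((n_offspring, 2, haps.shape[2]), dtype=np.int8)
    sires = rng.choice(males, n_offspring)
    dams = rng.choice(females, n_offspring)
    for i in range(n_offspring):
        new[i, 0] = _gamete(haps[sires[i]], chrom_slices, length, rng)
        new[i, 1] = _gamete(haps[dams[i]], chrom_slices, length, rng)
    new_sex = _balanced_sexes(n_offspring, rng)
    return new, new_sex


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Half male (0) half female (1), randomly ordered."""
    sex = np.zeros(n, dtype=int)
    sex[n // 2 :] = 1
    rng.shuffle(sex)
    return sex


# ---------------------------------------------------------------------------
# trait architecture and phenotypes


def assign_qtl_effects(
    genotypes: GenotypeMatrix,
    pi: float,
    sigma2_a: float,
    seed: int,
) -> TraitArchitecture:
    """Pick ``round((1 - pi) * m)`` SNP as QTL and scale their normal effects
    so that the additive variance at the supplied (founder) allele
    frequencies equals ``sigma2_a``: sum_k 2 p_k (1 - p_k) alpha_k^2 = sigma2_a.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must be in [0, 1], got {pi}")
    rng = np.random.default_rng(seed)
    m = genotypes.n_snp
    n_qtl = int(round((1.0 - pi) * m))
    if n_qtl == 0:
        return TraitArchitecture(
            qtl_idx=np.array([], dtype=int),
            alpha=np.array([]),
            sigma2_a=0.0,
            sigma2_e=np.nan,
        )
    freqs = genotypes.allele_freq()
    seg = np.flatnonzero((freqs > 0.0) & (freqs < 1.0))
    if len(seg) == 0:
        raise ValueError("no segregating SNP available for QTL assignment")
    pool = seg if len(seg) >= n_qtl else np.arange(m)
    qtl = np.sort(rng.choice(pool, size=n_qtl, replace=False))
    alpha = rng.standard_normal(n_qtl)
    p = freqs[qtl]
    raw = np.sum(2.0 * p * (1.0 - p) * alpha**2)
    if raw <= 0:
        raise ValueError("selected QTL carry no genetic variance at founder frequencies")
    alpha *= np.sqrt(sigma2_a / raw)
    return TraitArchitecture(
        qtl_idx=qtl, alpha=alpha, sigma2_a=float(sigma2_a), sigma2_e=np.nan
    )


def simulate_phenotypes(
    arch: TraitArchitecture,
    pedigree: pd.DataFrame,
    tbv: pd.Series,
    config: SimConfig,
    seed: int,
    trait: str = "trait",
) -> pd.DataFrame:
    """Phenotype = hatch effect + true breeding value + N(0, sigma2_e) residual.

    sigma2_e = sigma2_a (1 - h2) / h2, so founders realise heritability h2.
    Individuals of generation >= 0 are phenotyped; founders are the
    (unphenotyped) pedigree base.
    """
    if config.h2 <= 0:
        raise ValueError("h2 = 0 leaves the residual variance undefined")
    rng = np.random.default_rng(seed)
    sigma2_e = config.sigma2_a * (1.0 - config.h2) / config.h2
    rows = pedigree[pedigree["generation"] >= 0]
    missing_hatch = set(rows["hatch"]) - set(arch.hatch_effects)
    if missing_hatch:
        raise KeyError(f"no hatch effect for hatches {sorted(missing_hatch)[:5]}")
    hatch_vals = rows["hatch"].map(arch.hatch_effects).to_numpy(float)
    g = tbv.loc[rows["id"]].to_numpy(float)
    resid = (
        rng.normal(0.0, np.sqrt(sigma2_e), len(rows)) if sigma2_e > 0 else np.zeros(len(rows))
    )
    return pd.DataFrame(
        {
            "id": rows["id"].to_numpy(),
            "trait": trait,
            "value": hatch_vals + g + resid,
            "hatch": rows["hatch"].to_numpy(),
            "generation": rows["generation"].to_numpy(),
        }
    )


def select_parents(
    candidates: pd.DataFrame,
    criterion: "pd.Series | dict | None",
    n_sires: int,
    n_dams: int,
    mode: str,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Choose sires and dams from a candidate frame (columns id, sex).

    mode='random' samples uniformly within sex; 'phenotype' or 'ebv' apply
    truncation selection on the supplied per-id criterion, ties broken by id.
    """
    if mode not in ("random", "phenotype", "ebv"):
        raise ValueError(f"unknown selection mode {mode!r}")
    rng = np.random.default_rng(seed)
    males = candidates.loc[candidates["sex"] == "M", "id"].to_numpy()
    females = candidates.loc[candidates["sex"] == "F", "id"].to_numpy()
    if len(males) < n_sires or len(females) < n_dams:
        raise ValueError(
            f"not enough candidates: {len(males)} males for {n_sires} sires, "
            f"{len(females)} females for {n_dams} dams"
        )
    if mode == "random":
        sires = rng.choice(males, n_sires, replace=False)
        dams = rng.choice(females, n_dams, replace=False)
        return np.sort(sires), np.sort(dams)
    if criterion is None:
        raise ValueError(f"selection mode {mode!r} requires a criterion")
    crit = pd.Series(criterion)

    def top_k(ids: np.ndarray, k: int) -> np.ndarray:
        scores = crit.loc[ids].to_numpy(float)
        # descending score, ascending id on ties
        order = np.lexsort((ids, -scores))
        return np.sort(ids[order[:k]])

    return top_k(males, n_sires), top_k(females, n_dams)


# ---------------------------------------------------------------------------
# full population simulation


def simulate_population(config: SimConfig) -> Population:
    """Simulate the closed line: burn-in founders, then ``n_generations``
    discrete generations bred from selected parents.

    Founders carry generation -1.  Returns pedigree, genotypes of the
    genotyped set (all parents plus a random fraction of progeny, with
    missing calls at ``missing_rate``), the trait architecture, phenotypes
    of all generation >= 0 individuals, and true breeding values.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    snps = snp_map(cfg.n_snp, cfg.n_chromosomes, cfg.chromosome_length)
    slices = _chrom_slices(snps)
    L = cfg.chromosome_length

    # burn-in at constant size to build LD, then expand to the founder set
    p0 = rng.uniform(0.1, 0.9, cfg.n_snp)
    haps = (rng.uniform(size=(cfg.burn_in_ne, 2, cfg.n_snp)) < p0).astype(np.int8)
    sex = _balanced_sexes(cfg.burn_in_ne, rng)
    for _ in range(cfg.burn_in_generations):
        haps, sex = _random_mating_generation(haps, sex, cfg.burn_in_ne, slices, L, rng)
    founder_haps, founder_sex = _random_mating_generation(
        haps, sex, cfg.n_founders, slices, L, rng
    )

    sigma2_e = cfg.sigma2_a * (1.0 - cfg.h2) / cfg.h2
    hatch_sd = cfg.hatch_effect_sd_factor * np.sqrt(sigma2_e) / 2.0

    founder_geno = founder_haps.sum(axis=1)
    founder_ids = np.arange(1, cfg.n_founders + 1)
    founder_gm = GenotypeMatrix(
        ids=founder_ids, snps=snps, calls=founder_geno.astype(float)
    )
    arch = assign_qtl_effects(
        founder_gm, cfg.pi, cfg.sigma2_a, seed=int(rng.integers(2**31))
    )

    def tbv_of(geno: np.ndarray) -> np.ndarray:
        if arch.n_qtl == 0:
            return np.zeros(geno.shape[0])
        return geno[:, arch.qtl_idx] @ arch.alpha

    ped_rows: list[tuple] = []
    tbv_list: list[np.ndarray] = []
    sexes = np.array(["M", "F"])
    for i, ind in enumerate(founder_ids):
        ped_rows.append((ind, 0, 0, -1, sexes[founder_sex[i]], ""))
    tbv_list.append(tbv_of(founder_geno))

    genotyped: dict[int, np.ndarray] = {}
    pheno_rows: list[pd.DataFrame] = []
    hatch_effects: dict[str, float] = {}

    cur_ids = founder_ids
    cur_haps = founder_haps
    cur_sex = founder_sex
    cur_pheno: "pd.Series | None" = None  # phenotypes of current candidates
    next_id = cfg.n_founders + 1

    for g in range(cfg.n_generations):
        cand = pd.DataFrame({"id": cur_ids, "sex": sexes[cur_sex]})
        criterion = None
        if cfg.selection_mode == "phenotype" and cur_pheno is not None:
            criterion = cur_pheno
        elif cfg.selection_mode == "ebv" and pheno_rows:
            criterion = _pblup_criterion(
                ped_rows, pheno_rows, cfg, hatch_effects, cur_ids
            )
        mode = cfg.selection_mode if criterion is not None else "random"
        sires, dams = select_parents(
            cand, criterion, cfg.n_sires, cfg.n_dams, mode, int(rng.integers(2**31))
        )
        for pid in np.concatenate([sires, dams]):
            if pid not in genotyped:
                row = np.flatnonzero(cur_ids == pid)[0]
                genotyped[int(pid)] = cur_haps[row].sum(axis=0)

        # random mating design: each dam assigned one sire, litters as equal
        # as possible so full-sib families exist for the family-mean machinery
        dam_sires = rng.choice(sires, len(dams))
        n_prog = cfg.n_progeny_per_generation
        prog_dam_idx = np.repeat(np.arange(len(dams)), -(-n_prog // len(dams)))[:n_prog]
        id_by_pos = {int(pid): k for k, pid in enumerate(cur_ids)}

        new_haps = np.empty((n_prog, 2, cfg.n_snp), dtype=np.int8)
        new_ids = np.arange(next_id, next_id + n_prog)
        next_id += n_prog
        new_sex = _balanced_sexes(n_prog, rng)
        hatches = rng.integers(cfg.n_hatches_per_generation, size=n_prog)
        for h in range(cfg.n_hatches_per_generation):
            label = f"g{g}h{h}"
            if label not in hatch_effects:
                hatch_effects[label] = float(rng.normal(0.0, hatch_sd))
        for i in range(n_prog):
            d = dams[prog_dam_idx[i]]
            s = dam_sires[prog_dam_idx[i]]
            new_haps[i, 0] = _gamete(cur_haps[id_by_pos[int(s)]], slices, L, rng)
            new_haps[i, 1] = _gamete(cur_haps[id_by_pos[int(d)]], slices, L, rng)
            ped_rows.append(
                (
                    int(new_ids[i]),
                    int(s),
                    int(d),
                    g,
                    sexes[new_sex[i]],
                    f"g{g}h{hatches[i]}",
                )
            )
        new_geno = new_haps.sum(axis=1)
        new_tbv = tbv_of(new_geno)
        tbv_list.append(new_tbv)

        # phenotype this generation
        resid = rng.normal(0.0, np.sqrt(sigma2_e), n_prog)
        hatch_labels = np.array([f"g{g}h{h}" for h in hatches])
        pheno_rows.append(
            pd.DataFrame(
                {
                    "id": new_ids,
                    "trait": "trait",
                    "value": np.array([hatch_effects[h] for h in hatch_labels])
                    + new_tbv
                    + resid,
                    "hatch": hatch_labels,
                    "generation": g,
                }
            )
        )
        # genotype a fraction of progeny at birth
        n_extra = int(round(cfg.progeny_genotyped_fraction * n_prog))
        if n_extra > 0:
            extra = rng.choice(n_prog, n_extra, replace=False)
            for i in extra:
                genotyped[int(new_ids[i])] = new_geno[i]

        cur_ids, cur_haps, cur_sex = new_ids, new_haps, new_sex
        cur_pheno = pheno_rows[-1].set_index("id")["value"]

    pedigree = pd.DataFrame(
        ped_rows, columns=["id", "sire", "dam", "generation", "sex", "hatch"]
    )
    tbv = pd.Series(np.concatenate(tbv_list), index=pedigree["id"], name="tbv")
    phenotypes = (
        pd.concat(pheno_rows, ignore_index=True)
        if pheno_rows
        else pd.DataFrame(columns=["id", "trait", "value", "hatch", "generation"])
    )

    g_ids = np.array(sorted(genotyped))
    calls = (
        np.array([genotyped[i] for i in g_ids], dtype=float)
        if len(g_ids)
        else np.empty((0, cfg.n_snp))
    )
    if cfg.missing_rate > 0 and calls.size:
        mask = rng.uniform(size=calls.shape) < cfg.missing_rate
        calls[mask] = np.nan
    gm = GenotypeMatrix(ids=g_ids, snps=snps, calls=calls)

    arch = dataclasses.replace(arch, sigma2_e=sigma2_e, hatch_effects=hatch_effects)
    return Population(pedigree, gm, arch, phenotypes, tbv)


def _pblup_criterion(ped_rows, pheno_rows, cfg, hatch_effects, cur_ids) -> pd.Series:
    """EBV of current candidates from a quick pedigree BLUP at the true
    variance ratio (used only when selection_mode='ebv')."""
    from .blup import VarianceComponents, fit_pblup

    pedigree = pd.DataFrame(
        ped_rows, columns=["id", "sire", "dam", "generation", "sex", "hatch"]
    )
    phenos = pd.concat(pheno_rows, ignore_index=True)
    sigma2_e = cfg.sigma2_a * (1.0 - cfg.h2) / cfg.h2
    vc = VarianceComponents(sigma2_a=cfg.sigma2_a, sigma2_e=max(sigma2_e, 1e-8))
    fit = fit_pblup(phenos, pedigree, vc)
    return fit.ebv.loc[cur_ids]
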