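"""Reference experiments: pedigree-decay simulation and relationship halving.

These are the package's two self-contained benchmark quantities.  The
decay experiment simulates replicate closed populations under random
selection, trains pedigree BLUP once on the first two phenotyped
generations, validates in each later generation, and summarises how fast
accuracy decays: with information flowing only through pedigree
relationships, which halve at each meiosis, the squared ratio of
accuracies in consecutive validation generations is expected to be 0.5.

The halving experiment verifies the 50%-per-meiosis reduction of the
numerator relationship itself on a single-lineage chain pedigree.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .blup import VarianceComponents
from .relationships import build_A
from .simulate import SimConfig, simulate_population
from .validation import run_design

__all__ = ["pedigree_decay_experiment", "relationship_halving_experiment"]


def decay_config(seed: int) -> SimConfig:
    """Study conditions of the decay experiment: 20 sires x 100 dams,
    400 phenotyped (and genotyped) offspring per generation, h2 = 0.4,
    random parent selection, 6 discrete generations."""
    return SimConfig(
        n_founders=400,
        n_generations=6,
        n_sires=20,
        n_dams=100,
        n_progeny_per_generation=400,
        n_snp=600,
        burn_in_generations=100,
        burn_in_ne=100,
        pi=0.95,
        h2=0.4,
        progeny_genotyped_fraction=1.0,
        selection_mode="random",
        seed=seed,
    )


def pedigree_decay_experiment(
    n_replicates: int = 30, seed: int = 1
) -> dict:
    """Mean squared ratio of consecutive-generation PBLUP accuracies.

    Training is fixed at generations 0-1; validation covers generations
    2-5.  Accuracies are averaged over replicates per validation
    generation before taking consecutive ratios (per-replicate ratios are
    unstable once the denominator accuracy is small), then the squared
    ratios are averaged over the three lags.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(2**31, size=n_replicates)
    h2 = 0.4
    acc = []
    for s in rep_seeds:
        pop = simulate_population(decay_config(int(s)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = run_design(
                pop,
                methods=("pblup",),
                mode="persist",
                train_upto=1,
                h2_policy=h2,
                varcomp_policy=VarianceComponents(
                    sigma2_a=1.0, sigma2_e=(1.0 - h2) / h2
                ),
            )
        acc.append(
            tab.sort_values("validation_generation")["accuracy"].to_numpy()
        )
    acc = np.array(acc)
    mean_acc = acc.mean(axis=0)
    sq_ratios = (mean_acc[1:] / mean_acc[:-1]) ** 2
    return {
        "mean_accuracy_by_generation": pd.Series(
            mean_acc, index=[2, 3, 4, 5], name="accuracy"
        ),
        "squared_ratios": sq_ratios,
        "mean_squared_ratio": float(sq_ratios.mean()),
        "n_replicates": n_replicates,
    }


def relationship_halving_experiment(n_generations: int = 5) -> dict:
    """Percent reduction per meiosis of a(founder, descendant) on a chain
    pedigree with unrelated, non-inbred mates (tabular method, exact)."""
    rows = [(1, 0, 0, 0, "M", "h0"), (2, 0, 0, 0, "F", "h0")]
    for g in range(1, n_generations + 1):
        rows.append((2 * g + 1, 2 * g - 1, 2 * g, g, "M", f"h{g}"))
        rows.append((2 * g + 2, 0, 0, g, "F", f"h{g}"))
    ped = pd.DataFrame(
        rows, columns=["id", "sire", "dam", "generation", "sex", "hatch"]
    )
    A = build_A(ped).to_frame()
    rel = np.array([A.loc[1, 2 * g + 1] for g in range(n_generations + 1)])
    reductions = 100.0 * (1.0 - rel[1:] / rel[:-1])
    return {
        "relationships": rel,
        "percent_reduction_per_meiosis": reductions,
        "mean_percent_reduction": float(reductions.mean()),
        "n_meioses": n_generations,
    }
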