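import numpy as np
import pandas as pd
import pytest

from persistgs import SimConfig, simulate_population


def make_pedigree(rows):
    """rows: (id, sire, dam, generation, sex, hatch) tuples."""
    return pd.DataFrame(
        rows, columns=["id", "sire", "dam", "generation", "sex", "hatch"]
    )


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_founders=60,
        n_generations=3,
        n_sires=8,
        n_dams=20,
        n_progeny_per_generation=120,
        n_snp=300,
        burn_in_generations=20,
        burn_in_ne=40,
        pi=0.9,
        h2=0.4,
        progeny_genotyped_fraction=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_pop(small_cfg):
    return simulate_population(small_cfg)


@pytest.fixture()
def chain_pedigree():
    """Founder 1 mated down a single lineage with unrelated mates.

    Individual 2k+1 is the generation-k direct-line descendant; 2k+2 the
    unrelated mate introduced at generation k.
    """

    def build(n_gen: int) -> pd.DataFrame:
        rows = [(1, 0, 0, 0, "M", "h0"), (2, 0, 0, 0, "F", "h0")]
        for g in range(1, n_gen + 1):
            child = 2 * g + 1
            mate = 2 * g + 2
            sire, dam = 2 * g - 1, 2 * g
            rows.append((child, sire, dam, g, "M", f"h{g}"))
            rows.append((mate, 0, 0, g, "F", f"h{g}"))
        return make_pedigree(rows)

    return build


def pearson(a, b):
    """Brute-force Pearson correlation from the defining sums."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))
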