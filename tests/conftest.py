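import numpy as np
import pandas as pd
import pytest

from nanoliver import simulate


@pytest.fixture(scope="session")
def small_genome():
    return simulate.make_genome(20_000, gc_fraction=0.45, n_promoters=4, seed=5)


@pytest.fixture(scope="session")
def small_methylome(small_genome):
    return simulate.simulate_methylome(
        small_genome,
        promoter_open_prob=0.85,
        background_open_prob=0.15,
        cpg_meth_prob=0.7,
        seed=6,
    )


@pytest.fixture(scope="session")
def bulk_counts():
    cfg = simulate.SimulationConfig(seed=12, n_genes=2000, de_fraction=0.1, lfc_scale=3.0)
    counts, truth, sf = simulate.simulate_counts_bulk(cfg)
    return counts, truth, sf


@pytest.fixture(scope="session")
def sc_dataset():
    cfg = simulate.SimulationConfig(seed=9, n_cells=400, lowq_fraction=0.1)
    markers = simulate.default_phase_markers()
    counts, truth = simulate.simulate_counts_sc(cfg, markers)
    return counts, truth, markers


def random_stats_table(rng: np.random.Generator, n: int = 200) -> pd.DataFrame:
    """A random GeneStats-like table for ranking/signature tests."""
    p = rng.uniform(0, 1, size=n)
    return pd.DataFrame(
        {
            "baseMean": rng.uniform(1, 500, size=n),
            "log2fc": rng.normal(0, 2.5, size=n),
            "se": rng.uniform(0.1, 1.0, size=n),
            "p": p,
            "padj": np.clip(p * 1.5, 0, 1),
        },
        index=[f"g{i:04d}" for i in range(n)],
    )
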