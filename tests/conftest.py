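import numpy as np
import pandas as pd
import pytest

from kheterosis.de import CountMatrix, TrioDesign, normalize
from kheterosis.simulate import SimulationConfig, simulate_trio_counts


@pytest.fixture(scope="session")
def small_trio():
    """One simulated trio at default study conditions, small gene count."""
    cfg = SimulationConfig(n_genes=3000, seed=42)
    cm, design, truth = simulate_trio_counts(cfg)
    return cm, design, truth


@pytest.fixture(scope="session")
def null_trio():
    """All-null trio (no planted differences) for type-I checks."""
    cfg = SimulationConfig(n_genes=4000, pattern_proportions={"null": 1.0}, seed=7)
    cm, design, truth = simulate_trio_counts(cfg)
    return cm, design, truth


@pytest.fixture()
def toy_matrix():
    """3-gene x 2-sample matrix whose median-of-ratios factors are known in
    closed form: (2^-1/2, 2^1/2)."""
    counts = pd.DataFrame(
        {"s1": [100, 200, 400], "s2": [50, 400, 1600]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return CountMatrix(counts)


def make_two_group_matrix(mu_a, mu_b, n=3, dispersion=0.05, seed=0, prefix="g"):
    """NB counts for two groups with per-gene means mu_a / mu_b (arrays)."""
    rng = np.random.default_rng(seed)
    mu_a = np.asarray(mu_a, dtype=float)
    mu_b = np.asarray(mu_b, dtype=float)
    size = 1.0 / dispersion

    def draw(mu):
        p = size / (size + mu[:, None] * np.ones(n))
        return rng.negative_binomial(size, p)

    mat = np.hstack([draw(mu_a), draw(mu_b)])
    ids = [f"{prefix}{i}" for i in range(len(mu_a))]
    cols = [f"a{j}" for j in range(n)] + [f"b{j}" for j in range(n)]
    cm = CountMatrix(pd.DataFrame(mat, index=pd.Index(ids, name="gene_id"), columns=cols))
    return normalize(cm), cols[:n], cols[n:]
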