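import numpy as np
import pandas as pd
import pytest

from codep import ModuleSpec, SynthConfig, cor_targets, make_pathway_sets, simulate

RECOVERY_SEED = 20240
RECOVERY_CONFIG = SynthConfig(
    n_cells=200,
    modules=(
        ModuleSpec(size=20, rho=0.6, neg_frac=0.25),
        ModuleSpec(size=20, rho=0.6, neg_frac=0.25),
        ModuleSpec(size=20, rho=0.6, neg_frac=0.25),
    ),
    n_noise=400,
    missing_rate=0.05,
    seed=RECOVERY_SEED,
)


@pytest.fixture(scope="session")
def recovery_screen():
    """One fixed draw of the planted-module recovery study."""
    matrix, meta, truth = simulate(RECOVERY_CONFIG)
    return matrix, meta, truth


@pytest.fixture(scope="session")
def recovery_table(recovery_screen):
    """Correlation table for the first member of module M1, all genes."""
    matrix, _, truth = recovery_screen
    target = truth.loc[truth["module"] == "M1", "gene"].iloc[0]
    return cor_targets(matrix, target), target, truth


@pytest.fixture(scope="session")
def recovery_sets(recovery_screen):
    _, _, truth = recovery_screen
    return make_pathway_sets(truth)


@pytest.fixture
def tiny_matrix():
    """5 samples x 4 genes, one missing entry, one constant column."""
    rng = np.random.default_rng(11)
    vals = rng.standard_normal((5, 4))
    vals[:, 2] = 2.0 * vals[:, 0] + 0.1 * rng.standard_normal(5)
    vals[:, 3] = 1.5
    vals[1, 1] = np.nan
    return pd.DataFrame(
        vals,
        index=pd.Index([f"S{i}" for i in range(5)], name="sample_id"),
        columns=["GA", "GB", "GC", "GD"],
    )


def make_table(rows):
    """Build a correlation table from (target, gene, r, p, q, n) tuples."""
    return pd.DataFrame(rows, columns=["target", "gene", "r", "p", "q", "n"])
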