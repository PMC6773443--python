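import numpy as np
import pandas as pd
import pytest

from sexdiet import synthdata
from sexdiet.tables_io import CountMatrix


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-truth dataset reused across read-only tests."""
    params = synthdata.SimCountParams(
        n_genes=800, n_D=80, n_DxS=20, n_DplusDxS=30,
        n_sexlim_male=25, n_sexlim_female=10, seed=42,
    )
    return synthdata.simulate_counts(params)


@pytest.fixture()
def tiny_counts():
    """Hand-written 3-gene x 4-sample matrix (one sample per sex x diet)."""
    counts = pd.DataFrame(
        [[10, 20, 30, 40], [5, 5, 5, 5], [0, 1, 2, 3]],
        index=["gA", "gB", "gC"],
        columns=["FC1", "FP1", "MC1", "MP1"],
    )
    meta = pd.DataFrame(
        {"sex": ["F", "F", "M", "M"], "diet": ["C", "P", "C", "P"],
         "replicate": [1, 1, 1, 1]},
        index=pd.Index(["FC1", "FP1", "MC1", "MP1"], name="sample"),
    )
    return CountMatrix(counts, meta)


def make_two_group_counts(rng, n_genes, n_per_group, mu, phi, logfc=0.0):
    """Counts for a one-factor two-group layout inside the 2x2 metadata frame
    is NOT needed here: plain arrays for the GLM-level tests."""
    mu_a = np.full(n_genes, mu)
    mu_b = mu_a * 2.0 ** logfc
    def draw(m):
        if phi <= 0:
            return rng.poisson(m, size=(n_genes, n_per_group)).astype(float)
        lam = rng.gamma(1.0 / phi, m[:, None] * phi, size=(n_genes, n_per_group))
        return rng.poisson(lam).astype(float)
    return np.hstack([draw(mu_a), draw(mu_b)])
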