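"""Shared fixtures: small simulated gene datasets and fast MCMC schedules."""

import numpy as np
import pytest

from maat import GeneDataset, MaatConfig, standardize


def make_gene_dataset(
    n=120,
    p=15,
    m=5,
    seed=0,
    h_e2=0.3,
    causal=(0, 1, 2),
    annotation_sep=0.0,
):
    """Standardized GeneDataset with a few causal SNPs.

    ``annotation_sep`` > 0 makes the last two annotation columns informative
    (mean shifted on the causal set).
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    causal = np.asarray(causal, dtype=int)
    beta[causal] = rng.standard_normal(causal.size)
    genetic = X @ beta
    if h_e2 > 0:
        beta *= np.sqrt(h_e2 / genetic.var(ddof=1))
    else:
        beta[:] = 0
    E = X @ beta + np.sqrt(1 - h_e2) * rng.standard_normal(n)
    W = rng.standard_normal((p, m))
    if annotation_sep:
        W[causal, -2:] += annotation_sep
    ds = GeneDataset(
        gene_id="simgene",
        snp_ids=[f"rs{i}" for i in range(p)],
        effect_alleles=["A"] * p,
        X=X,
        E=E,
        W=W,
    )
    return standardize(ds), beta


@pytest.fixture
def small_dataset():
    ds, _ = make_gene_dataset(seed=3)
    return ds


@pytest.fixture
def short_config():
    """Fast MCMC schedule for unit tests."""
    return MaatConfig(n_iter=300, n_burnin=150, thin=1, seed=7)
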