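"""Sampler correctness: GRM, determinism, shrinkage under the null,
importance ranking, sparsification and prediction."""

import numpy as np
import pytest

from maat import (
    GeneDataset,
    MaatConfig,
    compute_grm,
    fit_maat,
    imputation_r2,
    predict_expression,
    snp_importance,
    sparsify_weights,
    standardize,
)
from conftest import make_gene_dataset


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def test_grm_matches_outer_product_oracle():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((8, 4))
    K = compute_grm(X)
    oracle = sum(np.outer(X[:, j], X[:, j]) for j in range(4)) / 4
    np.testing.assert_allclose(K, oracle, atol=1e-12)
    assert np.linalg.eigvalsh(K).min() >= -1e-10
    with pytest.raises(ValueError):
        compute_grm(np.empty((5, 0)))


def test_grm_trace_single_column():
    col = np.array([[-1.0], [1.0]])
    K = compute_grm(col)
    assert np.trace(K) == pytest.approx(2.0)  # sum of squared entries / p=1


# ---------------------------------------------------------------------------
# fit_maat behaviour
# ---------------------------------------------------------------------------

def test_fit_deterministic_given_seed(small_dataset, short_config):
    f1 = fit_maat(small_dataset, short_config)
    f2 = fit_maat(small_dataset, short_config)
    np.testing.assert_array_equal(f1.weights_full, f2.weights_full)
    np.testing.assert_array_equal(f1.importance, f2.importance)
    np.testing.assert_array_equal(f1.traces["log_posterior"],
                                  f2.traces["log_posterior"])


def test_fit_requires_standardized_and_valid_schedule(small_dataset):
    raw = GeneDataset("g", small_dataset.snp_ids, small_dataset.effect_alleles,
                      small_dataset.X, small_dataset.E, small_dataset.W,
                      standardized=False)
    with pytest.raises(ValueError, match="standardized"):
        fit_maat(raw, MaatConfig(n_iter=20, n_burnin=10))
    with pytest.raises(ValueError, match="n_burnin"):
        MaatConfig(n_iter=10, n_burnin=10)


def test_fit_invariants(small_dataset, short_config):
    fit = fit_maat(small_dataset, short_config)
    p = small_dataset.p
    C = fit.coclustering
    np.testing.assert_allclose(C, C.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(C), 1.0)
    assert C.min() >= 0 and C.max() <= 1
    assert np.all(fit.importance >= 0) and np.all(np.isfinite(fit.importance))
    for q, w in fit.weights_by_sparsity.items():
        assert int((w != 0).sum()) == int(np.ceil(q * p))
    assert np.all(fit.traces["k_p"] >= 1)


def test_null_expression_gives_small_heldout_r2():
    """With expression independent of genotype the fitted model must have
    no predictive signal: held-out R^2 stays below 0.05 (n=300 train,
    p=50) and the weights are shrunk well below the OLS fit.  (Training
    squared correlation is scale-free and sits near p/n for *any*
    noise-aligned direction, so the held-out set is where shrinkage
    shows.)"""
    ds, _ = make_gene_dataset(n=300, p=50, seed=10, h_e2=0.0)
    fit = fit_maat(ds, MaatConfig(n_iter=600, n_burnin=300, thin=1, seed=1))
    rng = np.random.default_rng(77)
    X_new = rng.standard_normal((400, 50))
    E_new = rng.standard_normal(400)  # null: expression independent of X
    grex = predict_expression(X_new, fit.weights_full)
    assert imputation_r2(E_new, grex) <= 0.05
    ols = np.linalg.lstsq(ds.X, ds.E, rcond=None)[0]
    assert np.linalg.norm(fit.weights_full) < np.linalg.norm(ols)


def test_single_strong_causal_snp_tops_importance():
    """A SNP explaining half the expression variance should receive the top
    importance score in at least 95% of seeds."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        ds, _ = make_gene_dataset(n=300, p=50, seed=100 + seed, h_e2=0.5,
                                  causal=(7,), annotation_sep=3.0)
        fit = fit_maat(ds, MaatConfig(n_iter=400, n_burnin=200, thin=1,
                                      seed=seed))
        hits += int(np.argmax(fit.importance) == 7)
    assert hits >= int(0.95 * n_seeds)


def test_two_cluster_importance_separation():
    """With two annotation-defined clusters of very different effect-size
    variance, every high-variance member should outrank every low-variance
    member in >= 90% of seeds."""
    hits = 0
    n_seeds = 10
    n, p = 400, 20
    big = np.arange(6)
    small = np.arange(6, p)
    for seed in range(n_seeds):
        rng = np.random.default_rng(500 + seed)
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[big] = rng.standard_normal(big.size) * 1.0
        beta[small] = rng.standard_normal(small.size) * 0.02
        genetic = X @ beta
        beta *= np.sqrt(0.5 / genetic.var(ddof=1))
        E = X @ beta + np.sqrt(0.5) * rng.standard_normal(n)
        W = rng.standard_normal((p, 2)) * 0.3
        W[big] += 3.0
        ds = standardize(GeneDataset(
            "g", [f"rs{i}" for i in range(p)], ["A"] * p, X, E, W))
        fit = fit_maat(ds, MaatConfig(n_iter=400, n_burnin=200, thin=1,
                                      seed=seed))
        hits += int(fit.importance[big].min() > fit.importance[small].max())
    assert hits >= int(0.9 * n_seeds)


def test_coclustering_recovers_annotation_groups():
    """Mean within-group co-clustering exceeds mean between-group
    co-clustering on a two-group annotation design."""
    ds, _ = make_gene_dataset(n=300, p=30, seed=42, h_e2=0.4,
                              causal=tuple(range(8)), annotation_sep=3.0)
    fit = fit_maat(ds, MaatConfig(n_iter=500, n_burnin=250, thin=1, seed=3))
    C = fit.coclustering
    group = np.zeros(30, dtype=bool)
    group[:8] = True
    within = np.concatenate([
        C[np.ix_(group, group)][np.triu_indices(8, 1)],
        C[np.ix_(~group, ~group)][np.triu_indices(22, 1)],
    ])
    between = C[np.ix_(group, ~group)].ravel()
    assert within.mean() > between.mean()


# ---------------------------------------------------------------------------
# importance / sparsification / prediction helpers
# ---------------------------------------------------------------------------

def test_snp_importance_degenerate_and_permutation():
    draws = np.array([[0.5, 2.0, 0.1]])
    np.testing.assert_allclose(snp_importance(draws), draws[0])
    multi = np.abs(np.random.default_rng(0).standard_normal((7, 5)))
    perm = np.array([3, 0, 4, 1, 2])
    np.testing.assert_allclose(
        snp_importance(multi[:, perm]), snp_importance(multi)[perm])


def test_sparsify_weights():
    w = np.array([1.0, -2.0, 0.5, 3.0, -0.1])
    imp = np.array([5.0, 1.0, 4.0, 2.0, 3.0])
    np.testing.assert_array_equal(sparsify_weights(w, imp, 1.0), w)
    out = sparsify_weights(np.arange(10.0), np.arange(10.0), 0.2)
    assert int((out != 0).sum()) == 2
    # retained set equals brute-force top-k of importance
    out = sparsify_weights(w, imp, 0.4)
    topk = set(np.argsort(-imp)[:2])
    assert set(np.flatnonzero(out != 0)) == topk
    with pytest.raises(ValueError):
        sparsify_weights(w, imp, 0.0)


def test_sparsify_tie_break_deterministic():
    w = np.array([0.1, -0.5, 0.5, 0.2])
    imp = np.ones(4)
    out = sparsify_weights(w, imp, 0.5)
    # equal importance: larger |weight| wins, then lower index
    assert set(np.flatnonzero(out != 0)) == {1, 2}


def test_predict_expression():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((6, 3))
    np.testing.assert_array_equal(predict_expression(X, np.zeros(3)), np.zeros(6))
    w = np.array([0.0, 1.0, 0.0])
    np.testing.assert_array_equal(predict_expression(X, w), X[:, 1])
    w = rng.standard_normal(3)
    oracle = np.array([sum(X[i, j] * w[j] for j in range(3)) for i in range(6)])
    np.testing.assert_allclose(predict_expression(X, w), oracle, atol=1e-12)


def test_imputation_r2():
    e = np.array([1.0, 2.0, 3.0, 4.0, 2.5])
    assert imputation_r2(e, e) == pytest.approx(1.0)
    assert imputation_r2(e, -e) == pytest.approx(1.0)
    g = np.array([0.9, 2.2, 2.7, 4.4, 2.0])
    r = np.corrcoef(e, g)[0, 1]
    assert imputation_r2(e, g) == pytest.approx(r * r)
    with pytest.warns(UserWarning, match="constant"):
        assert imputation_r2(e, np.ones(5)) == 0.0


# ---------------------------------------------------------------------------
# conjugacy: ridge equivalence with clustering disabled
# ---------------------------------------------------------------------------

def test_ridge_equivalence_with_fixed_single_cluster():
    """With one forced cluster and frozen variances, the posterior mean of
    beta_tilde + xi equals the ridge posterior mean under the equivalent
    Gaussian prior, within Monte Carlo error."""
    ds, _ = make_gene_dataset(n=200, p=20, seed=8, h_e2=0.4,
                              causal=(0, 1, 2, 3))
    se2, s02, s12 = 0.7, 0.5, 0.3
    c = s12 + s02 / ds.p
    ridge = np.linalg.solve(ds.X.T @ ds.X + np.eye(ds.p) / c, ds.X.T @ ds.E)
    means = []
    for seed in range(5):
        fit = fit_maat(
            ds, MaatConfig(n_iter=1500, n_burnin=300, thin=1, seed=seed),
            update_partition=False, fixed_variances=(se2, s02, s12),
        )
        means.append(fit.weights_full)
    avg = np.mean(means, axis=0)
    assert np.abs(avg - ridge).max() < 0.02
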