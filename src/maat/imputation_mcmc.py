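"""Gibbs sampler for the annotation-guided expression imputation model.

The model for one gene with standardized genotypes ``X`` (n x p) and
standardized expression ``E`` is

    E = X beta_tilde + X xi + eps,           eps  ~ N(0, sigma_e^2 I_n)
    beta_tilde_k | z_k = j                   ~ N(0, sigma_e^2 sigma_j^2)
    xi                                       ~ N(0, sigma_e^2 sigma_0^2 I_p / p)
    sigma_e^2 ~ IG(a_e, b_e);  sigma_0^2, sigma_j^2 ~ IG(a, b)
    P(Z | W)  — the PPMx partition prior of :mod:`maat.ppmx_prior`

so the total SNP weight is ``beta = beta_tilde + xi``: a sparse,
cluster-structured component whose prior variance is shared within
annotation-defined clusters, plus a dense polygenic background whose
marginal covariance is ``sigma_e^2 sigma_0^2 XX'/p`` (the GRM).

The sampler is a systematic Gibbs sweep:

1. each ``z_k`` in turn, from the conditional over occupied clusters plus
   one auxiliary new cluster whose variance is a fresh IG(a, b) draw
   (the standard auxiliary-variable device for non-conjugate DP-style
   priors);
2. ``beta_tilde`` coordinate-wise from its exact Gaussian conditional;
3. ``xi`` block-wise from its Gaussian conditional, solved in the
   eigenbasis of X'X (computed once per fit);
4-6. the variance components from their conjugate inverse-gamma
   conditionals.

All randomness flows through a single seeded Generator, so identical seed
and input give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import gammaln

from .data_model import GeneDataset, MaatConfig
from .ppmx_prior import (
    annotation_variance_floors,
    cluster_log_similarity,
    log_partition_prior,
)

_LOG_2PI = float(np.log(2.0 * np.pi))
_TINY_GAMMA = 1e-300


@dataclass
class ImputationFit:
    """Posterior summaries of one fitted gene model."""

    gene_id: str
    snp_ids: List[str]
    effect_alleles: List[str]
    weights_full: np.ndarray                    # posterior mean of beta_tilde + xi
    weights_by_sparsity: Dict[float, np.ndarray]
    importance: np.ndarray                      # per-SNP cluster-scale scores
    coclustering: np.ndarray                    # p x p co-assignment frequency
    traces: Dict[str, np.ndarray]
    config: MaatConfig
    seed: int


def compute_grm(X: np.ndarray) -> np.ndarray:
    """Genetic relatedness matrix K = X X' / p from standardized genotypes."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    return X @ X.T / X.shape[1]


def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    """Draw from IG(shape, rate) via the reciprocal gamma."""
    g = rng.standard_gamma(shape)
    return rate / max(g, _TINY_GAMMA)


def _log_ig_pdf(x: float, a: float, b: float) -> float:
    return a * math.log(b) - float(gammaln(a)) - (a + 1.0) * math.log(x) - b / x


class _SamplerState:
    """Mutable sweep state with per-cluster sufficient statistics."""

    def __init__(self, p: int, m: int, init_labels: np.ndarray, W: Optional[np.ndarray]):
        self.z = init_labels.astype(np.int64).copy()
        k = int(self.z.max()) + 1
        self.nclus = k
        self.csize = np.zeros(p + 1, dtype=np.int64)
        self.csum = np.zeros((p + 1, m))
        self.csumsq = np.zeros((p + 1, m))
        self.sigma2 = np.ones(p + 1)
        np.add.at(self.csize, self.z, 1)
        if W is not None:
            np.add.at(self.csum, self.z, W)
            np.add.at(self.csumsq, self.z, W ** 2)

    def relabel_first_occurrence(self) -> None:
        """Compact labels so clusters are numbered by first SNP occurrence."""
        p = self.z.shape[0]
        k = self.nclus
        first = np.full(k, p, dtype=np.int64)
        np.minimum.at(first, self.z, np.arange(p))
        order = np.argsort(first, kind="stable")
        newlab = np.empty(k, dtype=np.int64)
        newlab[order] = np.arange(k)
        self.z = newlab[self.z]
        self.csize[:k] = self.csize[:k][order]
        self.csum[:k] = self.csum[:k][order]
        self.csumsq[:k] = self.csumsq[:k][order]
        self.sigma2[:k] = self.sigma2[:k][order]


def fit_maat(
    dataset: GeneDataset,
    config: MaatConfig,
    *,
    use_annotations: bool = True,
    update_partition: bool = True,
    init_labels: Optional[np.ndarray] = None,
    fixed_variances: Optional[Tuple[float, float, float]] = None,
) -> ImputationFit:
    """Fit the imputation model by Gibbs sampling.

    Parameters
    ----------
    dataset:
        A standardized :class:`GeneDataset`.
    config:
        Hyperparameters and MCMC schedule.
    use_annotations:
        With ``False`` the similarity term is dropped and the partition prior
        reduces to the unit-mass Dirichlet-process (Ewens) weight — the
        annotation-agnostic special case.
    update_partition:
        With ``False`` the cluster labels stay at ``init_labels`` (default a
        single cluster); used for diagnostics such as the ridge-equivalence
        check.
    fixed_variances:
        Optional ``(sigma_e^2, sigma_0^2, sigma_cluster^2)`` to freeze all
        variance components (diagnostics only).

    Returns
    -------
    ImputationFit with posterior-mean weights, per-sparsity weight vectors,
    SNP importance scores, co-clustering frequencies and traces.
    """
    if not dataset.standardized:
        raise ValueError("fit_maat requires a standardized dataset")
    n, p = dataset.X.shape
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    if p < 2:
        raise ValueError(f"need at least 2 SNPs, got {p}")

    rng = np.random.default_rng(config.seed)
    X = np.ascontiguousarray(dataset.X)
    Xf = np.asfortranarray(X)
    E = dataset.E
    W = np.ascontiguousarray(dataset.W) if use_annotations else None
    m = dataset.W.shape[1]
    floors = (
        annotation_variance_floors(dataset.W, config.variance_floor_frac)
        if use_annotations
        else None
    )
    log_floor_singleton = (
        float(-0.5 * np.sum(_LOG_2PI + np.log(floors))) if use_annotations else 0.0
    )

    xtx = np.einsum("ij,ij->j", X, X)
    XtX = X.T @ X
    evals, Q = np.linalg.eigh(XtX)
    evals = np.clip(evals, 0.0, None)

    if init_labels is None:
        init_labels = np.zeros(p, dtype=np.int64)
    state = _SamplerState(p, m, np.asarray(init_labels), W)

    beta = np.zeros(p)
    xi = np.zeros(p)
    if fixed_variances is not None:
        sigma_e2, sigma2_0, sig_fixed = (float(v) for v in fixed_variances)
        state.sigma2[:] = sig_fixed
    else:
        sigma_e2, sigma2_0 = 1.0, 1.0
    r = E - X @ (beta + xi)

    n_retained = 0
    sum_w = np.zeros(p)
    var_draws: List[np.ndarray] = []
    cocl = np.zeros((p, p))
    tr_sigma_e2: List[float] = []
    tr_sigma2_0: List[float] = []
    tr_kp: List[int] = []
    tr_logpost: List[float] = []

    a_ig, b_ig = config.a, config.b
    idx = np.arange(p)

    for it in range(config.n_iter):
        # --- (1) cluster assignments -------------------------------------
        if update_partition:
            for k in range(p):
                b_k = beta[k]
                j = state.z[k]
                state.csize[j] -= 1
                if W is not None:
                    wk = W[k]
                    state.csum[j] -= wk
                    state.csumsq[j] -= wk * wk
                if state.csize[j] == 0:
                    last = state.nclus - 1
                    if j != last:
                        state.csize[j] = state.csize[last]
                        state.csum[j] = state.csum[last]
                        state.csumsq[j] = state.csumsq[last]
                        state.sigma2[j] = state.sigma2[last]
                        state.z[state.z == last] = j
                    state.csize[last] = 0
                    state.nclus = last
                K = state.nclus
                sizes = state.csize[:K]
                if W is not None:
                    logg0 = cluster_log_similarity(
                        sizes, state.csum[:K], state.csumsq[:K], floors
                    )
                    logg1 = cluster_log_similarity(
                        sizes + 1,
                        state.csum[:K] + wk,
                        state.csumsq[:K] + wk * wk,
                        floors,
                    )
                    dprior = logg1 - logg0 + np.log(sizes)
                    d_new = log_floor_singleton
                else:
                    dprior = np.log(sizes)
                    d_new = 0.0
                if fixed_variances is not None:
                    sig_new = state.sigma2[K]  # constant, pre-filled
                else:
                    sig_new = _inv_gamma(rng, a_ig, b_ig)
                cand_sig = np.append(state.sigma2[:K], sig_new)
                loglik = -0.5 * (
                    _LOG_2PI + np.log(sigma_e2 * cand_sig)
                ) - b_k * b_k / (2.0 * sigma_e2 * cand_sig)
                lw = np.append(dprior, d_new) + loglik
                lw -= lw.max()
                pr = np.exp(lw)
                cum = np.cumsum(pr)
                jnew = int(np.searchsorted(cum, rng.random() * cum[-1]))
                jnew = min(jnew, K)
                if jnew == K:
                    state.sigma2[K] = sig_new
                    state.csize[K] = 0
                    state.csum[K] = 0.0
                    state.csumsq[K] = 0.0
                    state.nclus += 1
                state.z[k] = jnew
                state.csize[jnew] += 1
                if W is not None:
                    state.csum[jnew] += wk
                    state.csumsq[jnew] += wk * wk
            state.relabel_first_occurrence()

        # --- (2) beta_tilde, coordinate-wise ------------------------------
        sig_by_snp = state.sigma2[state.z]
        for k in range(p):
            xk = Xf[:, k]
            r += xk * beta[k]
            mk = xk @ r
            denom = xtx[k] + 1.0 / sig_by_snp[k]
            mean = mk / denom
            beta[k] = mean + math.sqrt(sigma_e2 / denom) * rng.standard_normal()
            r -= xk * beta[k]

        # --- (3) xi, block-wise in the eigenbasis of X'X ------------------
        t = X.T @ r + XtX @ xi               # = X'(E - X beta_tilde)
        dvec = evals + p / sigma2_0
        tq = Q.T @ t
        xi = Q @ (tq / dvec + np.sqrt(sigma_e2 / dvec) * rng.standard_normal(p))
        r = E - X @ (beta + xi)

        # --- (4-6) variance components ------------------------------------
        if fixed_variances is None:
            K = state.nclus
            ssq = np.bincount(state.z, weights=beta * beta, minlength=K)[:K]
            shape_j = a_ig + state.csize[:K] / 2.0
            rate_j = b_ig + ssq / (2.0 * sigma_e2)
            g = np.maximum(rng.standard_gamma(shape_j), _TINY_GAMMA)
            state.sigma2[:K] = rate_j / g
            xi2 = float(xi @ xi)
            sigma2_0 = _inv_gamma(
                rng, a_ig + p / 2.0, b_ig + p * xi2 / (2.0 * sigma_e2)
            )
            quad = (
                float(r @ r)
                + float(np.sum(beta * beta / state.sigma2[state.z]))
                + p * xi2 / sigma2_0
            )
            sigma_e2 = _inv_gamma(
                rng, config.a_e + (n + 2 * p) / 2.0, config.b_e + quad / 2.0
            )

        # --- retention ----------------------------------------------------
        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            n_retained += 1
            total_w = beta + xi
            sum_w += total_w
            var_draws.append(sigma_e2 * state.sigma2[state.z])
            for j in range(state.nclus):
                members = idx[state.z == j]
                cocl[np.ix_(members, members)] += 1.0
            lp = _log_joint(
                dataset, config, use_annotations, floors,
                r, beta, xi, state, sigma_e2, sigma2_0,
            )
            if not np.isfinite(lp):
                raise RuntimeError(
                    f"non-finite log posterior at iteration {it}: "
                    f"sigma_e2={sigma_e2:.3g}, sigma2_0={sigma2_0:.3g}, "
                    f"k_p={state.nclus}"
                )
            tr_sigma_e2.append(sigma_e2)
            tr_sigma2_0.append(sigma2_0)
            tr_kp.append(state.nclus)
            tr_logpost.append(lp)

    weights_full = sum_w / n_retained
    importance = snp_importance(np.asarray(var_draws), weights_full)
    cocl /= n_retained
    weights_by_sparsity = {
        q: sparsify_weights(weights_full, importance, q)
        for q in config.sparsity_levels
    }
    return ImputationFit(
        gene_id=dataset.gene_id,
        snp_ids=list(dataset.snp_ids),
        effect_alleles=list(dataset.effect_alleles),
        weights_full=weights_full,
        weights_by_sparsity=weights_by_sparsity,
        importance=importance,
        coclustering=cocl,
        traces={
            "sigma2_e": np.asarray(tr_sigma_e2),
            "sigma2_0": np.asarray(tr_sigma2_0),
            "k_p": np.asarray(tr_kp),
            "log_posterior": np.asarray(tr_logpost),
        },
        config=config,
        seed=config.seed,
    )


def _log_joint(
    dataset: GeneDataset,
    config: MaatConfig,
    use_annotations: bool,
    floors: Optional[np.ndarray],
    r: np.ndarray,
    beta: np.ndarray,
    xi: np.ndarray,
    state: _SamplerState,
    sigma_e2: float,
    sigma2_0: float,
) -> float:
    n, p = dataset.X.shape
    sig_by_snp = state.sigma2[state.z]
    ll = -0.5 * n * (_LOG_2PI + math.log(sigma_e2)) - float(r @ r) / (2 * sigma_e2)
    lb = float(
        np.sum(
            -0.5 * (_LOG_2PI + np.log(sigma_e2 * sig_by_snp))
            - beta * beta / (2.0 * sigma_e2 * sig_by_snp)
        )
    )
    xi2 = float(xi @ xi)
    lxi = (
        -0.5 * p * (_LOG_2PI + math.log(sigma_e2 * sigma2_0 / p))
        - p * xi2 / (2.0 * sigma_e2 * sigma2_0)
    )
    lpv = _log_ig_pdf(sigma_e2, config.a_e, config.b_e)
    lpv += _log_ig_pdf(sigma2_0, config.a, config.b)
    for j in range(state.nclus):
        lpv += _log_ig_pdf(float(state.sigma2[j]), config.a, config.b)
    lz = log_partition_prior(
        state.z,
        dataset.W if use_annotations else None,
        floors=floors,
    )
    return ll + lb + lxi + lpv + lz


def snp_importance(
    cluster_var_draws: np.ndarray,
    tie_break_weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-SNP importance: geometric posterior mean of
    ``sigma_e^2 sigma_{z_k}^2`` over retained draws.

    ``cluster_var_draws`` is a (T, p) matrix whose row t holds, for each SNP,
    the draw-t product of the residual variance and the SNP's cluster-level
    effect variance — the model's per-cluster effect-size scale.  The summary
    is ``exp(mean(log draws))`` rather than the arithmetic mean: the
    inverse-gamma full conditional of a singleton cluster has shape
    ``a + 1/2 < 1`` and therefore infinite mean, so an arithmetic average is
    dominated by rare enormous draws from transient singletons; the geometric
    mean is a finite, scale-equivariant location summary of the same draw
    sequence (and coincides with the draw itself when all draws are equal).
    The scores are what the sparsification step ranks; ties are broken by
    absolute posterior-mean weight and then SNP index inside
    :func:`sparsify_weights`.
    """
    draws = np.atleast_2d(np.asarray(cluster_var_draws, dtype=float))
    if draws.size == 0:
        raise ValueError("no retained draws")
    if np.any(draws <= 0) or not np.all(np.isfinite(draws)):
        raise ValueError("cluster variance draws must be finite and positive")
    return np.exp(np.log(draws).mean(axis=0))


def sparsify_weights(
    weights_full: np.ndarray, importance: np.ndarray, q: float
) -> np.ndarray:
    """Keep the ceil(q * p) highest-importance SNPs, zero the rest.

    Retained weights are the unmodified posterior means (no refit).  Ties on
    importance are broken by larger absolute weight, then lower SNP index.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"sparsity fraction must lie in (0, 1], got {q}")
    weights_full = np.asarray(weights_full, dtype=float)
    importance = np.asarray(importance, dtype=float)
    p = weights_full.shape[0]
    if importance.shape[0] != p:
        raise ValueError("weights and importance lengths differ")
    k = int(math.ceil(q * p))
    order = np.lexsort((-np.abs(weights_full), -importance))
    out = np.zeros(p)
    keep = order[:k]
    out[keep] = weights_full[keep]
    return out


def predict_expression(X_new: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Impute genetically regulated expression: GReX = X_new @ weights."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    weights = np.asarray(weights, dtype=float).ravel()
    if X_new.shape[1] != weights.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns but weights length is "
            f"{weights.shape[0]}"
        )
    return X_new @ weights


def imputation_r2(E_obs: np.ndarray, grex: np.ndarray) -> float:
    """Squared Pearson correlation between observed expression and GReX.

    Defined as 0 (with a warning) when either input is constant.
    """
    import warnings

    E_obs = np.asarray(E_obs, dtype=float).ravel()
    grex = np.asarray(grex, dtype=float).ravel()
    if E_obs.shape[0] != grex.shape[0]:
        raise ValueError("length mismatch between expression and GReX")
    if E_obs.std() == 0 or grex.std() == 0:
        warnings.warn("constant input to imputation_r2; returning 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(E_obs, grex)[0, 1]
    return float(r * r)
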