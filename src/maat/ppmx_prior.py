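"""Product partition model with covariates (PPMx) prior over cis-SNP clusters.

The imputation model groups the ``p`` cis-SNPs of a gene into latent clusters
that share an effect-size variance.  The prior over cluster assignments
``Z = (z_1, ..., z_p)`` is

    P(Z | W)  propto  prod_j  g(W*_j) C(S_j)

where ``S_j`` is the set of SNPs in cluster ``j``, the cohesion
``C(S) = (|S| - 1)!`` rewards larger clusters (it is exactly the partition
weight induced by a Dirichlet process with total mass 1), and the similarity
``g`` rewards within-cluster homogeneity of the ``m`` annotation scores.
The similarity is a "double dipping" plug-in: per annotation ``l`` the
cluster's own sample mean and sample variance are plugged into a normal
density evaluated at each member's score,

    g(W*_jl) = prod_{t in S_j} phi(W_tl | mu_hat_jl, max(s2_hat_jl, floor_l)).

The variance is floored at a small fraction of the annotation's global
variance so that a cluster with identical scores does not produce an
infinite density; a singleton cluster (whose sample variance is undefined)
contributes the density at its own mean with the floor variance.

With the similarity disabled (``W=None``), the prior reduces to the Ewens
partition distribution of a unit-mass Dirichlet process — the
annotation-agnostic special case of the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PartitionState:
    """One MCMC state: cluster labels plus the variance components."""

    z: np.ndarray                # length-p labels in 0..k_p-1
    cluster_sizes: np.ndarray    # |S_j| per label
    sigma2_j: np.ndarray         # per-cluster effect variance scale
    sigma2_e: float              # residual variance
    sigma2_0: float              # polygenic background scale
    beta_tilde: np.ndarray       # sparse-prior effect component
    xi: np.ndarray               # random-effect component

    def validate(self) -> None:
        k = len(self.cluster_sizes)
        if sorted(np.unique(self.z)) != list(range(k)):
            raise ValueError("labels must be 0..k-1 with every label occupied")
        if int(self.cluster_sizes.sum()) != self.z.shape[0]:
            raise ValueError("cluster sizes must sum to p")
        if self.sigma2_e <= 0 or self.sigma2_0 <= 0 or np.any(self.sigma2_j <= 0):
            raise ValueError("variance components must be strictly positive")


def log_cohesion(size: int) -> float:
    """log C(S) = log((|S| - 1)!) for a cluster of the given size."""
    if size < 1:
        raise ValueError(f"cluster size must be >= 1, got {size}")
    return float(gammaln(size))


def annotation_variance_floors(W: np.ndarray, frac: float = 0.01) -> np.ndarray:
    """Per-annotation variance floors: ``frac`` times the global sample
    variance of each annotation column (with a tiny absolute floor for
    constant columns)."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] > 1:
        gvar = W.var(axis=0, ddof=1)
    else:
        gvar = np.ones(W.shape[1])
    return np.maximum(frac * gvar, 1e-12)


def cluster_log_similarity(
    sizes: np.ndarray,
    sums: np.ndarray,
    sumsqs: np.ndarray,
    floors: np.ndarray,
) -> np.ndarray:
    """Vectorized log-similarity for K clusters from sufficient statistics.

    ``sizes`` is (K,), ``sums`` and ``sumsqs`` are (K, m) per-annotation
    sums and sums of squares.  Uses the sample variance (divisor |S|-1);
    a singleton's variance is 0 and falls back to the floor.
    """
    s = np.asarray(sizes, dtype=float).reshape(-1, 1)
    ss_num = np.clip(sumsqs - sums * sums / s, 0.0, None)
    denom = np.maximum(s - 1.0, 1.0)
    s2 = ss_num / denom                       # 0 exactly for singletons
    v = np.maximum(s2, floors)
    out = -0.5 * (s * (_LOG_2PI + np.log(v)) + (s - 1.0) * s2 / v)
    return out.sum(axis=1)


def log_similarity(W_cluster: np.ndarray, variance_floor: np.ndarray) -> float:
    """log g(W*_j) for one cluster's annotation block (|S_j| x m)."""
    W_cluster = np.atleast_2d(np.asarray(W_cluster, dtype=float))
    if not np.all(np.isfinite(W_cluster)):
        raise ValueError("non-finite annotation score in cluster")
    floors = np.asarray(variance_floor, dtype=float).ravel()
    if floors.shape[0] != W_cluster.shape[1]:
        raise ValueError("variance floor length must equal annotation count")
    if np.any(floors <= 0):
        raise ValueError("variance floors must be positive")
    s = np.array([W_cluster.shape[0]])
    return float(
        cluster_log_similarity(
            s, W_cluster.sum(axis=0)[None, :],
            (W_cluster ** 2).sum(axis=0)[None, :], floors
        )[0]
    )


def log_partition_prior(
    z: np.ndarray,
    W: Optional[np.ndarray] = None,
    floors: Optional[np.ndarray] = None,
    variance_floor_frac: float = 0.01,
) -> float:
    """Unnormalized log P(Z | W): sum over clusters of similarity + cohesion.

    ``W=None`` disables the similarity term, leaving the Ewens / unit-mass
    Dirichlet-process partition weight ``sum_j log (|S_j| - 1)!``.
    Invariant under relabeling of clusters.
    """
    z = np.asarray(z)
    if z.ndim != 1 or z.shape[0] == 0:
        raise ValueError("z must be a non-empty 1-D labeling")
    labels, compact = np.unique(z, return_inverse=True)
    k = labels.shape[0]
    # every label between 0 and max must be occupied (compact labeling)
    if np.issubdtype(z.dtype, np.integer) and (z.min() < 0 or z.max() >= z.shape[0]):
        raise ValueError("labels out of range for a valid partition")
    sizes = np.bincount(compact, minlength=k)
    total = float(gammaln(sizes).sum())
    if W is not None:
        W = np.atleast_2d(np.asarray(W, dtype=float))
        if W.shape[0] != z.shape[0]:
            raise ValueError("W rows must match labeling length")
        if floors is None:
            floors = annotation_variance_floors(W, variance_floor_frac)
        m = W.shape[1]
        sums = np.zeros((k, m))
        sumsqs = np.zeros((k, m))
        np.add.at(sums, compact, W)
        np.add.at(sumsqs, compact, W ** 2)
        total += float(cluster_log_similarity(sizes, sums, sumsqs, floors).sum())
    return total
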