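"""Second-stage gene-trait association testing.

Given per-gene SNP weights from the imputation stage and GWAS summary
statistics, the gene-level test statistic is the FUSION-style burden Z-score

    Z = Z_SG' beta_hat / sqrt(beta_hat' V beta_hat)

where ``Z_SG`` are the per-SNP marginal GWAS Z-scores and ``V`` the cis-SNP
LD (correlation) matrix from a reference panel.  One such test is run per
weight-sparsity level and the resulting p-values are combined with the
aggregated Cauchy association test (ACAT):

    T = sum_i tan{(0.5 - p_i) pi} / d,     p_combined = 0.5 - arctan(T) / pi

which is well calibrated under arbitrary dependence between the component
p-values.  When individual-level GWAS data are available instead, a GLM of
the phenotype on imputed GReX (identity or logit link) provides the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, NamedTuple, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GwasSummary, LdMatrix, harmonize

logger = logging.getLogger(__name__)

_P_CLAMP = 1e-15


class BurdenResult(NamedTuple):
    z: float
    p: Optional[float]
    degenerate: bool


class GlmResult(NamedTuple):
    omega: float
    p: Optional[float]
    converged: bool


@dataclass
class AssociationResult:
    gene_id: str
    per_sparsity: Dict[float, Tuple[float, Optional[float]]]
    p_acat: Optional[float]
    n_snps_used: int
    flags: List[str] = field(default_factory=list)


def estimate_ld(X_ref: np.ndarray, regularization: float = 0.1) -> LdMatrix:
    """LD matrix from a standardized reference panel.

    ``V = X'X / (n_ref - 1)`` followed by shrinkage toward the identity,
    ``V <- (1 - lambda) V + lambda I``, which preserves the unit diagonal
    and guarantees positive-definiteness for ``lambda > 0``.
    """
    X_ref = np.atleast_2d(np.asarray(X_ref, dtype=float))
    n_ref = X_ref.shape[0]
    if n_ref < 2:
        raise ValueError("reference panel needs at least 2 samples")
    if not 0.0 <= regularization < 1.0:
        raise ValueError("regularization must lie in [0, 1)")
    V = X_ref.T @ X_ref / (n_ref - 1)
    if regularization > 0:
        V = (1.0 - regularization) * V
        V[np.diag_indices_from(V)] += regularization
    return LdMatrix(V=V, regularization=regularization)


def burden_z(
    weights: np.ndarray,
    z_gwas: np.ndarray,
    V: Union[LdMatrix, np.ndarray],
    denom_tol: float = 1e-12,
) -> BurdenResult:
    """FUSION burden Z-score and its two-sided normal p-value.

    All-zero weights or a quadratic form at or below ``denom_tol`` flag the
    test as degenerate (no p-value); the statistic is invariant to positive
    rescaling of the weights.
    """
    w = np.asarray(weights, dtype=float).ravel()
    z = np.asarray(z_gwas, dtype=float).ravel()
    Vm = V.V if isinstance(V, LdMatrix) else np.asarray(V, dtype=float)
    if w.shape[0] != z.shape[0] or Vm.shape[0] != w.shape[0]:
        raise ValueError("weights, z and V dimensions must agree")
    quad = float(w @ Vm @ w)
    if not np.any(w) or quad <= denom_tol:
        return BurdenResult(z=float("nan"), p=None, degenerate=True)
    zscore = float(z @ w) / np.sqrt(quad)
    p = float(2.0 * stats.norm.sf(abs(zscore)))
    return BurdenResult(z=zscore, p=p, degenerate=False)


def glm_association(
    grex: np.ndarray,
    Y: np.ndarray,
    C_new: Optional[np.ndarray] = None,
    family: str = "identity",
) -> GlmResult:
    """GLM Wald test of the phenotype on imputed GReX.

    ``family="identity"`` fits ordinary least squares for a quantitative
    phenotype; ``family="logit"`` fits logistic regression for a binary
    phenotype (both classes must be present).  Separation or non-convergence
    is flagged rather than raised.
    """
    import statsmodels.api as sm

    grex = np.asarray(grex, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float).ravel()
    if grex.shape[0] != Y.shape[0]:
        raise ValueError("GReX and phenotype lengths differ")
    cols = [grex]
    if C_new is not None and np.asarray(C_new).size:
        C_new = np.atleast_2d(np.asarray(C_new, dtype=float))
        if C_new.shape[0] != Y.shape[0]:
            C_new = C_new.T
        cols.append(C_new)
    exog = sm.add_constant(np.column_stack(cols))
    if family == "identity":
        res = sm.OLS(Y, exog).fit()
        return GlmResult(float(res.params[1]), float(res.pvalues[1]), True)
    if family == "logit":
        classes = np.unique(Y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ValueError("logit family needs Y in {0,1} with both classes")
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(Y, exog).fit(disp=0, maxiter=200)
        except Exception as exc:  # perfect separation, singular Hessian, ...
            logger.warning("logit fit failed: %s", exc)
            return GlmResult(float("nan"), None, False)
        converged = bool(res.mle_retvals.get("converged", False))
        return GlmResult(float(res.params[1]), float(res.pvalues[1]), converged)
    raise ValueError(f"unknown GLM family {family!r}")


def acat_combine(p_list: Iterable[float]) -> float:
    """Combine p-values with the aggregated Cauchy association test.

    Inputs are clamped to ``[1e-15, 1 - 1e-15]`` before the tangent
    transform.  A single p-value is returned unchanged (tan/arctan are
    inverse); all-0.5 inputs give exactly 0.5.
    """
    arr = np.asarray(list(p_list), dtype=float)
    if arr.size == 0:
        raise ValueError("acat_combine needs at least one p-value")
    arr = np.clip(arr, _P_CLAMP, 1.0 - _P_CLAMP)
    T = float(np.mean(np.tan((0.5 - arr) * np.pi)))
    p = 0.5 - np.arctan(T) / np.pi
    return float(np.clip(p, 1e-300, 1.0 - 1e-16))


def bonferroni_threshold(alpha: float, n_genes: int) -> float:
    """Family-wise significance threshold alpha / n_genes."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


LdSource = Union[
    LdMatrix,
    Mapping[str, LdMatrix],
    Callable[[str, List[str]], LdMatrix],
]


def _resolve_ld(ld_source: LdSource, gene_id: str, snp_ids: List[str]) -> LdMatrix:
    if isinstance(ld_source, LdMatrix):
        return ld_source
    if callable(ld_source):
        return ld_source(gene_id, snp_ids)
    return ld_source[gene_id]


def run_twas(
    models: Iterable,
    gwas: GwasSummary,
    ld_source: LdSource,
) -> Tuple[pd.DataFrame, List[dict]]:
    """Run the per-gene association pipeline over a set of fitted models.

    For each gene (processed in gene-id order): harmonize the GWAS Z-scores
    to the model's SNPs and effect alleles, subset weights and LD to the
    overlapping SNPs, compute one burden Z per sparsity level, and
    ACAT-combine the valid p-values.  Genes with zero overlapping SNPs are
    skipped with a logged reason.

    ``ld_source`` supplies the LD matrix for a gene's *full* SNP list: a
    single :class:`LdMatrix`, a mapping ``gene_id -> LdMatrix``, or a
    callable ``(gene_id, snp_ids) -> LdMatrix``.

    Returns the results table (one row per gene, wide per-sparsity columns)
    and a list of skip records.
    """
    models = sorted(models, key=lambda f: f.gene_id)
    if not models:
        raise ValueError("run_twas needs at least one gene model")
    rows: List[dict] = []
    skipped: List[dict] = []
    for fit in models:
        try:
            h = harmonize(
                fit.snp_ids, fit.effect_alleles,
                gwas.snp_ids, gwas.effect_alleles, gwas.z,
            )
        except ValueError as exc:
            logger.info("skipping gene %s: %s", fit.gene_id, exc)
            skipped.append({"gene_id": fit.gene_id, "reason": str(exc)})
            continue
        ld = _resolve_ld(ld_source, fit.gene_id, fit.snp_ids)
        if ld.p != len(fit.snp_ids):
            raise ValueError(
                f"LD matrix for gene {fit.gene_id} has {ld.p} SNPs, "
                f"model has {len(fit.snp_ids)}"
            )
        sub = np.ix_(h.kept_idx, h.kept_idx)
        V_sub = ld.V[sub]
        flags: List[str] = []
        per_sparsity: Dict[float, Tuple[float, Optional[float]]] = {}
        valid_p: List[float] = []
        for q in sorted(fit.weights_by_sparsity):
            w = fit.weights_by_sparsity[q][h.kept_idx]
            res = burden_z(w, h.values, V_sub)
            per_sparsity[q] = (res.z, res.p)
            if res.degenerate:
                flags.append(f"degenerate_denominator_q={q:g}")
            else:
                valid_p.append(res.p)
        p_acat = acat_combine(valid_p) if valid_p else None
        result = AssociationResult(
            gene_id=fit.gene_id,
            per_sparsity=per_sparsity,
            p_acat=p_acat,
            n_snps_used=len(h.kept_idx),
            flags=flags,
        )
        row = {"gene_id": result.gene_id, "n_snps": result.n_snps_used}
        for q, (zq, pq) in per_sparsity.items():
            row[f"z_{q:g}"] = zq
            row[f"p_{q:g}"] = pq
        row["p_acat"] = p_acat
        row["flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows), skipped
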