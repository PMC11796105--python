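"""Assign the most influential annotation to a gene-trait association.

The mean of the gene-level TWAS statistic is governed by the angle between
two LD-rotated effect-size vectors: the cis-SNP effects on expression
(``beta``) and on the phenotype (``alpha``, approximated by marginal GWAS
Z-scores when joint effects are unavailable).  With the LD eigendecomposition
``V = U Lambda U'`` the rotation is ``v_r = Lambda^{1/2} U' v``, which maps
the LD-weighted quadratic form onto an ordinary Euclidean norm:
``||v_r||^2 = v' V v``.

Each annotation column is scored by how well its rotated profile aligns with
both rotated effect vectors,

    score_l = | cos(W_l_rot, beta_r) + cos(W_l_rot, alpha_r) |,

and the gene is assigned the annotation maximizing the score.  Cosines are
scale-free, so any positive rescaling of ``beta``, ``alpha`` or an
annotation column leaves the assignment unchanged; annotation columns are
centered before rotation by default (the cosine is location-sensitive
otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np

from .data_model import LdMatrix


@dataclass
class RotationBasis:
    """Retained-rank eigenbasis of an LD matrix.

    Eigenvalues are sorted descending; components below
    ``eigen_tol_rel * max_eigenvalue`` are dropped (rank reduction) rather
    than floored, since ``Lambda^{1/2}`` of near-null directions only
    amplifies noise.
    """

    U: np.ndarray        # p x r eigenvectors
    Lambda: np.ndarray   # r eigenvalues, descending
    r: int

    @classmethod
    def from_ld(
        cls, V: Union[LdMatrix, np.ndarray], eigen_tol_rel: float = 1e-8
    ) -> "RotationBasis":
        Vm = V.V if isinstance(V, LdMatrix) else np.atleast_2d(np.asarray(V, float))
        evals, U = np.linalg.eigh(Vm)
        order = np.argsort(evals)[::-1]
        evals, U = evals[order], U[:, order]
        if evals[0] <= 0:
            raise ValueError("LD matrix has no positive eigenvalues")
        keep = evals >= eigen_tol_rel * evals[0]
        if not keep.any():
            raise ValueError("all eigenvalues below tolerance")
        return cls(U=U[:, keep], Lambda=evals[keep], r=int(keep.sum()))


@dataclass
class AnnotationAssignment:
    gene_id: str
    scores: np.ndarray
    l_star: int
    annotation_names: List[str]
    tied: bool = False


def rotate(
    V: Union[LdMatrix, np.ndarray, RotationBasis],
    v: np.ndarray,
    eigen_tol_rel: float = 1e-8,
) -> np.ndarray:
    """Rotate a length-p vector into LD eigenspace: ``Lambda^{1/2} U' v``.

    Satisfies ``||v_r||^2 = v' V v`` up to the dropped-eigenvalue error.
    """
    basis = V if isinstance(V, RotationBasis) else RotationBasis.from_ld(V, eigen_tol_rel)
    v = np.asarray(v, dtype=float).ravel()
    if v.shape[0] != basis.U.shape[0]:
        raise ValueError(
            f"vector length {v.shape[0]} does not match LD dimension "
            f"{basis.U.shape[0]}"
        )
    return np.sqrt(basis.Lambda) * (basis.U.T @ v)


def marginal_alpha(gwas_z: np.ndarray) -> np.ndarray:
    """Proxy for the SNP-on-phenotype effect vector: the harmonized marginal
    GWAS Z-scores.  The downstream cosine is invariant to positive rescaling,
    so the unit scale is immaterial."""
    return np.asarray(gwas_z, dtype=float).ravel().copy()


def _cosine(a: np.ndarray, b: np.ndarray, tol: float) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= tol or nb <= tol:
        return 0.0
    return float(a @ b / (na * nb))


def assign_annotation(
    W: np.ndarray,
    weights: np.ndarray,
    alpha: np.ndarray,
    V: Union[LdMatrix, np.ndarray, RotationBasis],
    annotation_names: Optional[List[str]] = None,
    gene_id: str = "",
    center: bool = True,
    eigen_tol_rel: float = 1e-8,
    norm_tol: float = 1e-12,
) -> AnnotationAssignment:
    """Score every annotation and pick the argmax.

    ``score_l = |cos(W_l_rot, beta_r) + cos(W_l_rot, alpha_r)|`` lies in
    [0, 2]; ties go to the lowest index with the ``tied`` flag set.
    Degenerate (near-zero-norm) rotated effect vectors raise, naming the
    offending vector; an annotation orthogonal to both vectors scores 0.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    basis = V if isinstance(V, RotationBasis) else RotationBasis.from_ld(V, eigen_tol_rel)
    beta_r = rotate(basis, weights)
    alpha_r = rotate(basis, marginal_alpha(alpha))
    if np.linalg.norm(beta_r) <= norm_tol:
        raise ValueError("degenerate rotated expression-effect vector (beta)")
    if np.linalg.norm(alpha_r) <= norm_tol:
        raise ValueError("degenerate rotated phenotype-effect vector (alpha)")
    m = W.shape[1]
    if annotation_names is None:
        annotation_names = [f"annotation_{l}" for l in range(m)]
    scores = np.empty(m)
    for l in range(m):
        col = W[:, l] - W[:, l].mean() if center else W[:, l]
        col_r = rotate(basis, col)
        scores[l] = min(
            abs(_cosine(col_r, beta_r, norm_tol)
                + _cosine(col_r, alpha_r, norm_tol)),
            2.0,
        )
    l_star = int(np.argmax(scores))
    tied = bool(np.sum(np.isclose(scores, scores[l_star], rtol=0, atol=1e-12)) > 1)
    return AnnotationAssignment(
        gene_id=gene_id,
        scores=scores,
        l_star=l_star,
        annotation_names=list(annotation_names),
        tied=tied,
    )
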