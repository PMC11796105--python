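"""Synthetic data generators and the simulation study harnesses.

The real reference data behind the method (cohort genotypes for 1000
cis-SNPs of a single gene, FAVOR annotation scores, biobank GWAS panels)
are access-controlled, so the study conditions are emulated:

* **Genotypes** — a Gaussian-copula stand-in: latent block-AR(1) Gaussian
  vectors are dichotomized twice per individual (two haplotypes) at the
  MAF quantile and summed to dosages {0, 1, 2}.  This preserves the local
  LD regime the method exploits while satisfying MAF >= 5% and
  Hardy-Weinberg equilibrium by construction.
* **Annotations** — five scores per SNP: three non-informative columns
  drawn from one normal for every SNP, and two informative columns whose
  normal means differ by ``annotation_separation`` between causal and
  non-causal SNPs.
* **Expression** — ``E = X beta + eps`` with ``eps ~ N(0, 1 - h_e2)``;
  non-causal effects are zero, causal effects come from two mean-zero
  normals (variance ratio ``causal_var_ratio``) indexed by a two-way split
  of the causal set, then the whole ``beta`` is rescaled so the sample
  expression heritability equals ``h_e2``.
* **Phenotype** — ``Y = omega E + eps1`` with ``omega = sqrt(h_p2)`` on
  unit-variance expression and ``eps1 ~ N(0, 1 - h_p2)``; the null
  phenotype is i.i.d. standard normal, independent of the genotypes.

The harnesses run the full pipeline: fit the imputation model on the
training split, sparsify the weights at the configured levels, synthesize
GWAS summary statistics on the testing split (marginal regression Z-scores
of the phenotype on each standardized SNP), run the burden-Z test per
sparsity level with LD estimated from the same panel, and ACAT-combine.
Every generator is a pure function of (config, seed): per-replicate
Generators are forked from the experiment seed by a fixed integer scheme
``default_rng([seed, stream, replicate])``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GeneDataset, LdMatrix, MaatConfig, standardize_matrix
from .imputation_mcmc import fit_maat, imputation_r2, predict_expression
from .association import estimate_ld

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_annotations",
    "simulate_causal_structure",
    "simulate_effects_and_expression",
    "simulate_phenotype",
    "simulate_null_phenotype",
    "marginal_summary_z",
    "run_power_experiment",
    "run_type1_experiment",
]


@dataclass
class SimConfig:
    """Study conditions for the simulation experiments.

    Defaults mirror the reference study design: 500 training and 125
    testing samples (4:1), 1000 cis-SNPs with MAF in [0.05, 0.5], five
    annotations (two informative), 50 expression replicates, 100 phenotype
    replicates per power cell and 100,000 per type-I cell at nominal level
    0.05.  ``ld_rho`` / ``block_size`` set the stand-in LD regime.
    ``ld_regularization`` applies to the harness LD matrix; it defaults to
    0 because inside the simulation the LD panel coincides with the sample
    generating the summary statistics, making the burden-Z denominator
    exact without shrinkage.
    """

    n_train: int = 500
    n_test: int = 125
    p: int = 1000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.7
    block_size: int = 50
    p_cs: float = 0.1
    h_e2: float = 0.2
    h_p2: float = 0.25
    n_expr_reps: int = 50
    n_pheno_reps_power: int = 100
    n_pheno_reps_null: int = 100_000
    alpha_sim: float = 0.05
    seed: int = 0
    annotation_separation: float = 2.0
    causal_var_ratio: float = 4.0
    ld_regularization: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cs < 1.0:
            raise ValueError("p_cs must lie in (0, 1)")
        for name in ("h_e2", "h_p2"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.block_size > self.p:
            raise ValueError("block_size must not exceed p")
        if not 0.0 < self.alpha_sim < 1.0:
            raise ValueError("alpha_sim must lie in (0, 1)")

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_test

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth of one expression replicate."""

    causal_index: np.ndarray       # sorted positions of causal SNPs
    beta_true: np.ndarray          # length-p, zero off the causal set
    omega_true: float
    annotation_groups: np.ndarray  # length-p: 0 non-causal, 1/2 causal groups


@dataclass
class GenotypeSim:
    """Simulated dosages plus split-standardized views."""

    dosages: np.ndarray    # (n_train + n_test) x p raw dosages in {0,1,2}
    X_train: np.ndarray    # standardized training block
    X_test: np.ndarray     # standardized testing block
    X_all: np.ndarray      # jointly standardized full matrix
    maf: np.ndarray        # realized minor allele frequencies


def _stream(seed: int, *path: int) -> np.random.Generator:
    """Deterministic per-replicate stream: default_rng([seed, *path])."""
    return np.random.default_rng([int(seed)] + [int(x) for x in path])


def simulate_genotypes(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> GenotypeSim:
    """Block-AR(1) Gaussian-copula dosages for train + test samples.

    Within each block of ``block_size`` SNPs the latent haplotype vectors
    follow an AR(1) with correlation ``ld_rho``; blocks are independent.
    Each haplotype allele is the indicator of the latent value falling
    below the MAF quantile, so Hardy-Weinberg holds by construction.
    Blocks whose realized MAF leaves [0.04, 0.51] (or with a monomorphic
    column in either split) are redrawn.
    """
    rng = rng if rng is not None else _stream(config.seed, 0)
    n, p = config.n_total, config.p
    lo, hi = config.maf_range
    rho = config.ld_rho
    blocks = [
        (start, min(start + config.block_size, p))
        for start in range(0, p, config.block_size)
    ]
    dos = np.empty((n, p))
    maf_target = np.empty(p)
    sqrt1m = np.sqrt(1.0 - rho * rho)
    for start, stop in blocks:
        width = stop - start
        for attempt in range(50):
            maf = rng.uniform(lo, hi, size=width)
            thresh = stats.norm.ppf(maf)
            hap_sum = np.zeros((n, width))
            for _hap in range(2):
                lat = np.empty((n, width))
                lat[:, 0] = rng.standard_normal(n)
                for j in range(1, width):
                    lat[:, j] = rho * lat[:, j - 1] + sqrt1m * rng.standard_normal(n)
                hap_sum += lat < thresh
            realized = hap_sum.mean(axis=0) / 2.0
            realized = np.minimum(realized, 1.0 - realized)
            ok = np.all((realized >= 0.04) & (realized <= 0.51))
            ok = ok and np.all(hap_sum[: config.n_train].std(axis=0) > 0)
            ok = ok and np.all(hap_sum[config.n_train:].std(axis=0) > 0)
            if ok:
                dos[:, start:stop] = hap_sum
                maf_target[start:stop] = realized
                break
        else:
            raise RuntimeError(
                f"could not realize MAF in [0.04, 0.51] for block "
                f"[{start}, {stop}) after 50 attempts"
            )
    return GenotypeSim(
        dosages=dos,
        X_train=standardize_matrix(dos[: config.n_train]),
        X_test=standardize_matrix(dos[config.n_train:]),
        X_all=standardize_matrix(dos),
        maf=maf_target,
    )


def simulate_causal_structure(
    p: int, p_cs: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Choose round(p_cs * p) causal SNPs and split them into two
    effect-size groups.

    Returns (causal_index sorted, groups) where ``groups`` is length-p with
    0 for non-causal SNPs and 1/2 for the two causal groups.
    """
    n_causal = int(round(p_cs * p))
    if n_causal < 1 or n_causal >= p:
        raise ValueError(f"causal count {n_causal} must lie in [1, p)")
    causal = np.sort(rng.choice(p, size=n_causal, replace=False))
    groups = np.zeros(p, dtype=int)
    half = rng.permutation(n_causal) < n_causal // 2
    groups[causal] = np.where(half, 1, 2)
    return causal, groups


def simulate_annotations(
    p: int,
    causal_index: np.ndarray,
    rng: Union[int, np.random.Generator],
    separation: float = 2.0,
    n_informative: int = 2,
    n_noninformative: int = 3,
) -> np.ndarray:
    """Five annotation scores per SNP (two informative, three not).

    Non-informative columns are i.i.d. N(0, 1) for every SNP; informative
    columns are N(separation, 1) on the causal set and N(0, 1) elsewhere.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    causal_index = np.asarray(causal_index, dtype=int)
    if causal_index.size == 0 or causal_index.size >= p:
        raise ValueError("causal set must be a nonempty proper subset")
    m = n_noninformative + n_informative
    W = rng.standard_normal((p, m))
    for col in range(n_noninformative, m):
        W[causal_index, col] += separation
    return W


def simulate_effects_and_expression(
    X: np.ndarray,
    causal_index: np.ndarray,
    annotation_groups: np.ndarray,
    h_e2: float,
    rng: Union[int, np.random.Generator],
    var_ratio: float = 4.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """True effect sizes and one expression draw at heritability ``h_e2``.

    Causal effects come from N(0, 1) (group 1) and N(0, 1/var_ratio)
    (group 2), then the whole vector is rescaled so the sample variance of
    the genetic component satisfies
    ``Var(X beta) / (Var(X beta) + (1 - h_e2)) = h_e2``;
    the residual is N(0, 1 - h_e2).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    causal_index = np.asarray(causal_index, dtype=int)
    if causal_index.size == 0:
        raise ValueError("causal set must be nonempty")
    beta = np.zeros(p)
    groups = np.asarray(annotation_groups)
    sd = np.where(groups[causal_index] == 1, 1.0, 1.0 / np.sqrt(var_ratio))
    beta[causal_index] = rng.standard_normal(causal_index.size) * sd
    genetic = X @ beta
    v = float(genetic.var(ddof=1))
    if v <= 0:
        raise ValueError("Var(X beta) is zero; cannot set heritability")
    if h_e2 > 0:
        # c^2 v / (c^2 v + (1 - h)) = h  =>  c^2 = h / v
        beta *= np.sqrt(h_e2 / v)
    else:
        beta[:] = 0.0
    eps = rng.standard_normal(X.shape[0]) * np.sqrt(1.0 - h_e2)
    E = X @ beta + eps
    return beta, E


def simulate_phenotype(
    E: np.ndarray, h_p2: float, rng: Union[int, np.random.Generator]
) -> np.ndarray:
    """Phenotype ``Y = sqrt(h_p2) E_std + eps1`` with ``eps1 ~ N(0, 1-h_p2)``."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    E = np.asarray(E, dtype=float).ravel()
    sd = E.std(ddof=1)
    if sd <= 0:
        raise ValueError("expression vector is constant")
    E_std = (E - E.mean()) / sd
    return np.sqrt(h_p2) * E_std + np.sqrt(1.0 - h_p2) * rng.standard_normal(E.size)


def simulate_null_phenotype(
    n: int, rng: Union[int, np.random.Generator]
) -> np.ndarray:
    """i.i.d. standard-normal phenotype, independent of all genotypes."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return rng.standard_normal(n)


def marginal_summary_z(X_std: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Synthetic GWAS summary statistics: per-SNP marginal regression
    Z-scores, ``z_k = sqrt(n-1) * corr(x_k, y)``.

    ``X_std`` must be column-standardized.  ``Y`` may be a vector or an
    ``n x R`` matrix of phenotype replicates (returns ``p x R``).
    """
    X_std = np.asarray(X_std, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    Y = Y.reshape(Y.shape[0], -1)
    if Y.shape[0] != X_std.shape[0]:
        raise ValueError("phenotype length must match genotype rows")
    n = X_std.shape[0]
    Yc = Y - Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    Z = (X_std.T @ Yc) / (np.sqrt(n - 1) * sd)
    return Z[:, 0] if squeeze else Z


def _acat_matrix(P: np.ndarray) -> np.ndarray:
    """Vectorized ACAT over axis 0 of a (d, R) p-value matrix."""
    P = np.clip(P, 1e-15, 1.0 - 1e-15)
    T = np.tan((0.5 - P) * np.pi).mean(axis=0)
    return 0.5 - np.arctan(T) / np.pi


def _fit_one_replicate(
    config: SimConfig,
    maat_config: MaatConfig,
    geno: GenotypeSim,
    truth_rng: np.random.Generator,
    struct: Tuple[np.ndarray, np.ndarray],
    W: np.ndarray,
    fit_seed: int,
):
    """One expression replicate: draw effects/expression, fit the model."""
    causal, groups = struct
    beta_true, E_all = simulate_effects_and_expression(
        geno.X_all, causal, groups, config.h_e2, truth_rng,
        var_ratio=config.causal_var_ratio,
    )
    E_train = E_all[: config.n_train]
    E_test = E_all[config.n_train:]
    ds = GeneDataset(
        gene_id="simulated",
        snp_ids=[f"snp{i}" for i in range(config.p)],
        effect_alleles=["A"] * config.p,
        X=geno.X_train,
        E=(E_train - E_train.mean()) / E_train.std(ddof=1),
        W=W,
        standardized=True,
    )
    fit = fit_maat(ds, maat_config.replace(seed=fit_seed))
    truth = SimTruth(
        causal_index=causal,
        beta_true=beta_true,
        omega_true=float(np.sqrt(config.h_p2)),
        annotation_groups=groups,
    )
    return fit, truth, E_test


def _association_pvalues(
    fit, V: LdMatrix, X_test: np.ndarray, Y: np.ndarray
) -> np.ndarray:
    """ACAT-combined p-value for each phenotype replicate (column of Y)."""
    Z = marginal_summary_z(X_test, Y)
    Z = Z.reshape(Z.shape[0], -1)
    levels = sorted(fit.weights_by_sparsity)
    P = np.empty((len(levels), Z.shape[1]))
    for i, q in enumerate(levels):
        w = fit.weights_by_sparsity[q]
        quad = float(w @ V.V @ w)
        if quad <= 1e-12:
            P[i] = np.nan
            continue
        zb = (w @ Z) / np.sqrt(quad)
        P[i] = 2.0 * stats.norm.sf(np.abs(zb))
    valid = ~np.isnan(P).all(axis=1)
    return _acat_matrix(P[valid])


def _derive_fit_seed(seed: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(seed)] + [int(x) for x in path])
    return int(ss.generate_state(1)[0] % (2**31))


def run_power_experiment(
    config: SimConfig,
    maat_config: Optional[MaatConfig] = None,
    h_p2_values: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Association power of the full pipeline per (p_cs, h_e2, h_p2).

    Genotypes, the causal set and the annotation matrix are fixed for the
    experiment; each of ``n_expr_reps`` expression replicates redraws effect
    sizes and expression, fits the imputation model on the training split,
    and evaluates ``n_pheno_reps_power`` phenotype replicates per ``h_p2``
    on the testing split through the summary-statistic burden-Z / ACAT
    path.  Power is the fraction of combined p-values below ``alpha_sim``.

    Returns a long table with one row per (replicate, h_p2) carrying the
    power, the test-set imputation R² of the full and per-sparsity weights,
    and a config echo in ``DataFrame.attrs``.
    """
    maat_config = maat_config if maat_config is not None else MaatConfig()
    h_grid = list(h_p2_values) if h_p2_values is not None else [config.h_p2]
    geno = simulate_genotypes(config, _stream(config.seed, 0))
    struct = simulate_causal_structure(config.p, config.p_cs, _stream(config.seed, 1))
    W = simulate_annotations(
        config.p, struct[0], _stream(config.seed, 2),
        separation=config.annotation_separation,
    )
    V = estimate_ld(geno.X_test, config.ld_regularization)
    rows = []
    for rep in range(config.n_expr_reps):
        fit, truth, E_test = _fit_one_replicate(
            config, maat_config, geno, _stream(config.seed, 3, rep), struct, W,
            _derive_fit_seed(config.seed, 4, rep),
        )
        r2_cols = {
            "r2_full": imputation_r2(
                E_test, predict_expression(geno.X_test, fit.weights_full)
            )
        }
        for q, w in fit.weights_by_sparsity.items():
            r2_cols[f"r2_{q:g}"] = imputation_r2(
                E_test, predict_expression(geno.X_test, w)
            )
        pheno_rng = _stream(config.seed, 5, rep)
        for h_p2 in h_grid:
            R = config.n_pheno_reps_power
            Y = np.column_stack([
                simulate_phenotype(E_test, h_p2, pheno_rng) for _ in range(R)
            ])
            p_acat = _association_pvalues(fit, V, geno.X_test, Y)
            rows.append({
                "p_cs": config.p_cs,
                "h_e2": config.h_e2,
                "h_p2": h_p2,
                "replicate": rep,
                "power": float(np.mean(p_acat < config.alpha_sim)),
                "n_pheno_reps": R,
                **r2_cols,
            })
    df = pd.DataFrame(rows)
    df.attrs["config"] = config
    return df


def run_type1_experiment(
    config: SimConfig,
    maat_config: Optional[MaatConfig] = None,
    return_pvalues: bool = False,
):
    """Type-I error of the full pipeline under null phenotypes.

    Identical to the power harness except the phenotype replicates are
    i.i.d. standard normal, independent of the genotypes; the type-I error
    rate is the fraction of ACAT-combined p-values below ``alpha_sim``
    among ``n_pheno_reps_null`` replicates.
    """
    maat_config = maat_config if maat_config is not None else MaatConfig()
    geno = simulate_genotypes(config, _stream(config.seed, 0))
    struct = simulate_causal_structure(config.p, config.p_cs, _stream(config.seed, 1))
    W = simulate_annotations(
        config.p, struct[0], _stream(config.seed, 2),
        separation=config.annotation_separation,
    )
    V = estimate_ld(geno.X_test, config.ld_regularization)
    rows = []
    pvals = []
    for rep in range(config.n_expr_reps):
        fit, _truth, _E_test = _fit_one_replicate(
            config, maat_config, geno, _stream(config.seed, 3, rep), struct, W,
            _derive_fit_seed(config.seed, 4, rep),
        )
        pheno_rng = _stream(config.seed, 6, rep)
        R = config.n_pheno_reps_null
        Y = pheno_rng.standard_normal((config.n_test, R))
        p_acat = _association_pvalues(fit, V, geno.X_test, Y)
        rows.append({
            "p_cs": config.p_cs,
            "h_e2": config.h_e2,
            "replicate": rep,
            "type1_rate": float(np.mean(p_acat < config.alpha_sim)),
            "n_pheno_reps": R,
        })
        if return_pvalues:
            pvals.append(p_acat)
    df = pd.DataFrame(rows)
    df.attrs["config"] = config
    if return_pvalues:
        return df, pvals
    return df
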