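"""Data containers and I/O for gene-level TWAS inputs.

A TWAS analysis of one gene needs four aligned pieces: an ``n x p`` additive
dosage matrix for the gene's cis-SNPs, the length-``n`` expression vector,
a ``p x m`` matrix of per-SNP functional annotation scores, and (for the
association stage) GWAS summary Z-scores harmonized to the same SNPs and
effect alleles.  This module holds those containers plus the surrounding
plumbing: PLINK bed / dosage-TSV readers, allele harmonization,
standardization, covariate adjustment, and a single-file model archive.

Conventions used throughout the package:

* dosages count copies of the *effect allele* on a 0..2 scale;
* "sample variance" always uses divisor ``n - 1``;
* missing genotype entries are filled with the column mean at read time,
  before standardization;
* strand-ambiguous (A/T, C/G) variants are matched by identifier and allele
  letter only — a warning is emitted, no strand flipping is attempted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd

MODEL_FORMAT_VERSION = 1

_AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MaatConfig:
    """Hyperparameters and schedule for the imputation model.

    Parameters
    ----------
    a_e, b_e:
        Inverse-gamma shape/scale for the residual variance ``sigma_e^2``.
        Weakly informative by default.
    a, b:
        Inverse-gamma shape/scale shared by the per-cluster effect variances
        ``sigma_j^2`` and the polygenic background scale ``sigma_0^2``.
    n_iter, n_burnin, thin:
        MCMC schedule: total sweeps, discarded sweeps, retention stride.
    sparsity_levels:
        Fractions of cis-SNPs retained when the weight vector is sparsified;
        each level feeds one association test, later combined with ACAT.
    ld_regularization:
        Shrinkage ``lambda`` applied to reference-panel LD matrices,
        ``V <- (1 - lambda) V + lambda I``.
    eigen_tol:
        Relative eigenvalue floor used when rotating vectors into LD
        eigenspace; components below ``eigen_tol * max_eigenvalue`` are
        dropped.
    variance_floor_frac:
        The annotation-similarity variance floor for annotation ``l`` is
        ``variance_floor_frac`` times the global sample variance of that
        annotation; it keeps plug-in densities finite when a cluster's
        scores coincide.
    """

    a_e: float = 0.01
    b_e: float = 0.01
    a: float = 0.01
    b: float = 0.01
    n_iter: int = 2000
    n_burnin: int = 1000
    thin: int = 2
    seed: int = 0
    sparsity_levels: Tuple[float, ...] = (0.05, 0.10, 0.20, 0.30)
    ld_regularization: float = 0.1
    eigen_tol: float = 1e-8
    variance_floor_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError(
                f"n_burnin ({self.n_burnin}) must be < n_iter ({self.n_iter})"
            )
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        self.sparsity_levels = tuple(float(q) for q in self.sparsity_levels)
        for q in self.sparsity_levels:
            if not 0.0 < q <= 1.0:
                raise ValueError(f"sparsity fraction {q} outside (0, 1]")
        for name in ("a_e", "b_e", "a", "b", "variance_floor_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.ld_regularization < 1.0:
            raise ValueError("ld_regularization must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sparsity_levels"] = list(self.sparsity_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MaatConfig":
        d = dict(d)
        if "sparsity_levels" in d:
            d["sparsity_levels"] = tuple(d["sparsity_levels"])
        return cls(**d)

    def replace(self, **kw) -> "MaatConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneDataset:
    """Aligned genotype / expression / annotation data for one gene."""

    gene_id: str
    snp_ids: List[str]
    effect_alleles: List[str]
    X: np.ndarray  # n x p additive dosages (or standardized values)
    E: np.ndarray  # n expression values
    W: np.ndarray  # p x m annotation scores
    standardized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.E = np.asarray(self.E, dtype=float).ravel()
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.effect_alleles = [str(a).upper() for a in self.effect_alleles]
        n, p = self.X.shape
        if len(self.snp_ids) != p:
            raise ValueError(
                f"{len(self.snp_ids)} SNP ids but X has {p} columns"
            )
        if len(self.effect_alleles) != p:
            raise ValueError("effect_alleles length must match SNP count")
        if self.E.shape[0] != n:
            raise ValueError("expression length must match X rows")
        if self.W.shape[0] != p:
            raise ValueError(
                f"annotation matrix has {self.W.shape[0]} rows, expected {p}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if not np.all(np.isfinite(self.E)):
            raise ValueError("E contains non-finite values")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return self.W.shape[1]


@dataclass
class GwasSummary:
    """Per-SNP marginal GWAS Z-scores with their effect alleles."""

    snp_ids: List[str]
    effect_alleles: List[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.effect_alleles = [str(a).upper() for a in self.effect_alleles]
        self.z = np.asarray(self.z, dtype=float).ravel()
        if len(self.snp_ids) != self.z.shape[0]:
            raise ValueError("snp_ids and z lengths differ")
        if len(self.effect_alleles) != self.z.shape[0]:
            raise ValueError("effect_alleles and z lengths differ")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("GWAS z contains non-finite values")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in GWAS summary")


@dataclass
class LdMatrix:
    """Symmetric SNP-SNP correlation matrix, optionally shrunk to identity."""

    V: np.ndarray
    regularization: float = 0.0

    def __post_init__(self) -> None:
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        if self.V.shape[0] != self.V.shape[1]:
            raise ValueError("LD matrix must be square")
        if not np.allclose(self.V, self.V.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")

    @property
    def p(self) -> int:
        return self.V.shape[0]


@dataclass
class HarmonizeResult:
    """Outcome of aligning an external table to the genotype SNP order."""

    values: np.ndarray          # aligned (possibly sign-flipped) values
    kept_idx: np.ndarray        # positions in the genotype SNP list
    dropped_ids: List[str]      # genotype SNPs absent from the other source


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------

def _fill_missing_by_column_mean(X: np.ndarray, snp_ids: Sequence[str]) -> np.ndarray:
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = ~np.isfinite(col)
        if miss.all():
            raise ValueError(f"SNP {snp_ids[j]}: all genotype values missing")
        if miss.any():
            col[miss] = col[~miss].mean()
    return X


def _read_dosage_tsv(path: Path) -> Tuple[List[str], List[str], np.ndarray]:
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed dosage file {path}: {exc}") from exc
    snp_ids = [str(c) for c in df.columns]
    try:
        X = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed dosage file {path}: non-numeric entry ({exc})") from exc
    X = _fill_missing_by_column_mean(X, snp_ids)

    sidecar = Path(str(path) + ".alleles")
    if sidecar.exists():
        al = pd.read_csv(sidecar, sep="\t", header=None, names=["snp_id", "allele"])
        amap = dict(zip(al["snp_id"].astype(str), al["allele"].astype(str)))
        missing = [s for s in snp_ids if s not in amap]
        if missing:
            raise ValueError(f"allele sidecar {sidecar} missing SNPs: {missing[:5]}")
        alleles = [amap[s] for s in snp_ids]
    else:
        warnings.warn(
            f"no allele sidecar {sidecar}; effect alleles set to 'N'",
            stacklevel=3,
        )
        alleles = ["N"] * len(snp_ids)
    return snp_ids, alleles, X


# 2-bit PLINK codes (SNP-major): 00 -> 2 copies of A1, 01 -> missing,
# 10 -> heterozygous, 11 -> 0 copies of A1.  Lowest bits come first.
_BED_CODE = np.array([2.0, np.nan, 1.0, 0.0])
_BED_LOOKUP = np.empty((256, 4))
for _byte in range(256):
    for _k in range(4):
        _BED_LOOKUP[_byte, _k] = _BED_CODE[(_byte >> (2 * _k)) & 0b11]


def _read_plink_bed(path: Path) -> Tuple[List[str], List[str], np.ndarray]:
    prefix = Path(str(path)[:-4]) if str(path).endswith(".bed") else path
    bed = Path(str(prefix) + ".bed")
    bim = Path(str(prefix) + ".bim")
    fam = Path(str(prefix) + ".fam")
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"PLINK file {f} not found")
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None,
                         names=["chrom", "snp_id", "cm", "pos", "a1", "a2"])
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None)
    snp_ids = bim_df["snp_id"].astype(str).tolist()
    alleles = bim_df["a1"].astype(str).tolist()   # A1 is the counted allele
    n, p = len(fam_df), len(snp_ids)

    raw = bed.read_bytes()
    if raw[:3] != b"\x6c\x1b\x01":
        raise ValueError(f"malformed PLINK bed {bed}: bad magic/SNP-major flag")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != p * bytes_per_snp:
        raise ValueError(
            f"malformed PLINK bed {bed}: expected {p * bytes_per_snp} data "
            f"bytes, found {body.size}"
        )
    geno = _BED_LOOKUP[body.reshape(p, bytes_per_snp)].reshape(p, -1)[:, :n]
    X = np.ascontiguousarray(geno.T)
    X = _fill_missing_by_column_mean(X, snp_ids)
    return snp_ids, alleles, X


def read_genotypes(path, dialect: str = "dosage-tsv"):
    """Read an additive dosage matrix.

    Parameters
    ----------
    path:
        For ``dosage-tsv``: a tab-separated file whose header row lists SNP
        ids and whose rows are samples; an optional sidecar ``<path>.alleles``
        (two tab-separated columns: SNP id, effect allele) supplies alleles.
        For ``plink-bed``: the ``.bed`` path or the triplet prefix.
    dialect:
        ``"dosage-tsv"`` or ``"plink-bed"``.

    Returns
    -------
    (snp_ids, effect_alleles, X) with missing entries filled by column mean.
    """
    path = Path(path)
    if dialect == "dosage-tsv":
        if not path.exists():
            raise FileNotFoundError(f"dosage file {path} not found")
        return _read_dosage_tsv(path)
    if dialect == "plink-bed":
        return _read_plink_bed(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# harmonization and standardization
# ---------------------------------------------------------------------------

def harmonize(
    geno_snp_ids: Sequence[str],
    geno_alleles: Sequence[str],
    other_snp_ids: Sequence[str],
    other_alleles: Sequence[str],
    other_values: Sequence[float],
) -> HarmonizeResult:
    """Align external per-SNP values (e.g. GWAS Z-scores) to genotype order.

    A value whose effect allele differs from the genotype's is sign-flipped
    (the external statistic was computed for the other allele).  Variants
    forming a strand-ambiguous pair (A/T or C/G) are matched by letter only
    and trigger a warning.  Genotype SNPs absent from the external source are
    dropped from the analysis set and reported.
    """
    if len(geno_snp_ids) == 0 or len(other_snp_ids) == 0:
        raise ValueError("empty SNP id list")
    other_values = np.asarray(other_values, dtype=float).ravel()
    table = {
        str(s): (str(a).upper(), v)
        for s, a, v in zip(other_snp_ids, other_alleles, other_values)
    }
    vals, kept, dropped = [], [], []
    for i, (sid, ga) in enumerate(zip(geno_snp_ids, geno_alleles)):
        entry = table.get(str(sid))
        if entry is None:
            dropped.append(str(sid))
            continue
        oa, v = entry
        ga = str(ga).upper()
        if oa != ga:
            if frozenset((ga, oa)) in _AMBIGUOUS_PAIRS:
                warnings.warn(
                    f"SNP {sid}: strand-ambiguous allele pair {ga}/{oa}; "
                    "matched by letter only",
                    stacklevel=2,
                )
            v = -v
        vals.append(v)
        kept.append(i)
    if not kept:
        raise ValueError("no overlapping SNPs between genotypes and summary data")
    return HarmonizeResult(
        values=np.asarray(vals, dtype=float),
        kept_idx=np.asarray(kept, dtype=int),
        dropped_ids=dropped,
    )


def standardize_matrix(X: np.ndarray, names: Optional[Sequence[str]] = None) -> np.ndarray:
    """Center each column and scale to unit sample variance (divisor n-1)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        label = names[bad[0]] if names is not None else f"column {bad[0]}"
        raise ValueError(f"constant column: {label}")
    return (X - mu) / sd


def standardize(dataset: GeneDataset) -> GeneDataset:
    """Return a copy with each genotype column and the expression vector
    centered to mean 0 and scaled to unit sample variance."""
    X = standardize_matrix(dataset.X, dataset.snp_ids)
    e_sd = dataset.E.std(ddof=1)
    if e_sd <= 0:
        raise ValueError("expression vector has zero variance")
    E = (dataset.E - dataset.E.mean()) / e_sd
    return GeneDataset(
        gene_id=dataset.gene_id,
        snp_ids=list(dataset.snp_ids),
        effect_alleles=list(dataset.effect_alleles),
        X=X,
        E=E,
        W=dataset.W.copy(),
        standardized=True,
    )


def adjust_covariates(E: np.ndarray, C: Optional[np.ndarray]) -> np.ndarray:
    """Residualize expression on an intercept plus covariates (OLS).

    With no covariates this is simple mean-centering.  Raises if the design
    (intercept included) is rank-deficient.
    """
    E = np.asarray(E, dtype=float).ravel()
    n = E.shape[0]
    if C is None or (hasattr(C, "size") and np.asarray(C).size == 0):
        return E - E.mean()
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != n:
        if C.shape[1] == n:
            C = C.T
        else:
            raise ValueError("covariate rows must match expression length")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank-deficient (with intercept)")
    coef, *_ = np.linalg.lstsq(design, E, rcond=None)
    return E - design @ coef


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------

def write_model(fit, path) -> None:
    """Serialize an ImputationFit to a single HDF5 archive."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = MODEL_FORMAT_VERSION
        h5.attrs["gene_id"] = fit.gene_id
        h5.attrs["seed"] = int(fit.seed)
        h5.attrs["config_json"] = json.dumps(fit.config.to_dict())
        str_dt = h5py.string_dtype()
        h5.create_dataset("snp_ids", data=np.array(fit.snp_ids, dtype=str_dt))
        h5.create_dataset(
            "effect_alleles", data=np.array(fit.effect_alleles, dtype=str_dt)
        )
        h5.create_dataset("weights_full", data=fit.weights_full)
        h5.create_dataset("importance", data=fit.importance)
        h5.create_dataset("coclustering", data=fit.coclustering)
        grp = h5.create_group("weights_by_sparsity")
        for q, w in fit.weights_by_sparsity.items():
            grp.create_dataset(f"{q:.6g}", data=w)
        tr = h5.create_group("traces")
        for name, arr in fit.traces.items():
            tr.create_dataset(name, data=np.asarray(arr))


def read_model(path):
    """Load an ImputationFit written by :func:`write_model`."""
    from .imputation_mcmc import ImputationFit  # avoid circular import

    path = Path(path)
    with h5py.File(path, "r") as h5:
        version = int(h5.attrs["format_version"])
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model archive {path} has format version {version}; "
                f"this build reads version {MODEL_FORMAT_VERSION}"
            )
        config = MaatConfig.from_dict(json.loads(h5.attrs["config_json"]))
        fit = ImputationFit(
            gene_id=str(h5.attrs["gene_id"]),
            snp_ids=[s.decode() if isinstance(s, bytes) else str(s)
                     for s in h5["snp_ids"][()]],
            effect_alleles=[s.decode() if isinstance(s, bytes) else str(s)
                            for s in h5["effect_alleles"][()]],
            weights_full=h5["weights_full"][()],
            weights_by_sparsity={
                float(k): v[()] for k, v in h5["weights_by_sparsity"].items()
            },
            importance=h5["importance"][()],
            coclustering=h5["coclustering"][()],
            traces={k: v[()] for k, v in h5["traces"].items()},
            config=config,
            seed=int(h5.attrs["seed"]),
        )
    return fit
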