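"""Readers, harmonization, standardization and the model archive."""

import warnings

import numpy as np
import pytest

from maat import (
    GeneDataset,
    MaatConfig,
    adjust_covariates,
    harmonize,
    read_genotypes,
    read_model,
    standardize,
    write_model,
)
from maat.imputation_mcmc import ImputationFit


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------

def _write_dosage(tmp_path, rows, snps=("rs1", "rs2"), alleles=("A", "G")):
    path = tmp_path / "geno.tsv"
    lines = ["\t".join(snps)] + ["\t".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    sidecar = tmp_path / "geno.tsv.alleles"
    sidecar.write_text("".join(f"{s}\t{a}\n" for s, a in zip(snps, alleles)))
    return path


def test_dosage_tsv_identity_readback(tmp_path):
    path = _write_dosage(tmp_path, [(0, 2), (1, 1), (2, 0)])
    snps, alleles, X = read_genotypes(path, "dosage-tsv")
    assert snps == ["rs1", "rs2"]
    assert alleles == ["A", "G"]
    np.testing.assert_array_equal(X, [[0, 2], [1, 1], [2, 0]])


def test_dosage_missing_filled_with_column_mean(tmp_path):
    path = _write_dosage(tmp_path, [(0, 1), ("NA", 1), (2, 1)])
    _, _, X = read_genotypes(path, "dosage-tsv")
    assert X[1, 0] == pytest.approx(1.0)  # mean of 0 and 2


def test_dosage_all_missing_column_names_snp(tmp_path):
    path = _write_dosage(tmp_path, [("NA", 1), ("NA", 0)])
    with pytest.raises(ValueError, match="rs1"):
        read_genotypes(path, "dosage-tsv")


def _write_plink(tmp_path, dosages, snps, alleles, missing=None):
    """Write a bed/bim/fam triplet for an n x p dosage matrix (A1 counts)."""
    n, p = dosages.shape
    prefix = tmp_path / "panel"
    (tmp_path / "panel.bim").write_text("".join(
        f"1\t{s}\t0\t{1000 + j}\t{a}\tT\n"
        for j, (s, a) in enumerate(zip(snps, alleles))
    ))
    (tmp_path / "panel.fam").write_text("".join(
        f"F{i} I{i} 0 0 0 -9\n" for i in range(n)
    ))
    code = {2: 0b00, 1: 0b10, 0: 0b11, None: 0b01}
    body = bytearray()
    for j in range(p):
        for start in range(0, n, 4):
            byte = 0
            for k, i in enumerate(range(start, min(start + 4, n))):
                val = None if (missing and (i, j) in missing) else int(dosages[i, j])
                byte |= code[val] << (2 * k)
            body.append(byte)
    (tmp_path / "panel.bed").write_bytes(b"\x6c\x1b\x01" + bytes(body))
    return prefix


def test_plink_bed_matches_dosage_tsv_twin(tmp_path):
    rng = np.random.default_rng(11)
    dosages = rng.integers(0, 3, size=(7, 5))
    snps = [f"rs{i}" for i in range(5)]
    alleles = ["A", "C", "G", "T", "A"]
    prefix = _write_plink(tmp_path, dosages, snps, alleles)
    tsv = _write_dosage(tmp_path, dosages.tolist(), snps, alleles)
    s1, a1, X1 = read_genotypes(prefix, "plink-bed")
    s2, a2, X2 = read_genotypes(tsv, "dosage-tsv")
    assert s1 == s2 and a1 == a2
    np.testing.assert_allclose(X1, X2)


def test_plink_bed_missing_filled_and_bad_magic(tmp_path):
    dosages = np.array([[0, 2], [2, 2], [2, 0], [0, 1]])
    prefix = _write_plink(tmp_path, dosages, ["rs1", "rs2"], ["A", "G"],
                          missing={(1, 0)})
    _, _, X = read_genotypes(prefix, "plink-bed")
    assert X[1, 0] == pytest.approx(np.mean([0, 2, 0]))
    (tmp_path / "panel.bed").write_bytes(b"\x00\x00\x00")
    with pytest.raises(ValueError, match="magic"):
        read_genotypes(prefix, "plink-bed")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def test_harmonize_identity_and_flip_and_dropout():
    res = harmonize(["rs1", "rs2"], ["A", "C"],
                    ["rs1", "rs2"], ["A", "C"], [1.5, -0.2])
    np.testing.assert_allclose(res.values, [1.5, -0.2])
    assert res.dropped_ids == []

    res = harmonize(["rs1"], ["A"], ["rs1"], ["G"], [1.5])
    np.testing.assert_allclose(res.values, [-1.5])

    res = harmonize(["rs1", "rs2", "rs3"], ["A", "C", "G"],
                    ["rs1", "rs3"], ["A", "G"], [0.5, 0.7])
    np.testing.assert_allclose(res.values, [0.5, 0.7])
    np.testing.assert_array_equal(res.kept_idx, [0, 2])
    assert res.dropped_ids == ["rs2"]


def test_harmonize_self_is_identity():
    snps = ["rs1", "rs2", "rs3"]
    alleles = ["A", "C", "T"]
    vals = np.array([0.3, -1.0, 2.0])
    res = harmonize(snps, alleles, snps, alleles, vals)
    np.testing.assert_array_equal(res.values, vals)
    np.testing.assert_array_equal(res.kept_idx, [0, 1, 2])


def test_harmonize_zero_overlap_raises_and_ambiguous_warns():
    with pytest.raises(ValueError, match="overlap"):
        harmonize(["rs1"], ["A"], ["rs9"], ["A"], [1.0])
    with pytest.warns(UserWarning, match="ambiguous"):
        harmonize(["rs1"], ["A"], ["rs1"], ["T"], [1.0])


# ---------------------------------------------------------------------------
# standardization and covariates
# ---------------------------------------------------------------------------

def _dataset(X, E, p=None):
    p = X.shape[1]
    return GeneDataset("g", [f"rs{i}" for i in range(p)], ["A"] * p,
                       X, E, np.zeros((p, 2)))


def test_standardize_column_and_idempotence():
    X = np.array([[0.0, 5.0], [1.0, 7.0], [2.0, 6.0]])
    ds = standardize(_dataset(X, np.array([1.0, 2.0, 3.0])))
    np.testing.assert_allclose(ds.X[:, 0], [-1, 0, 1], atol=1e-12)
    again = standardize(ds)
    np.testing.assert_allclose(again.X, ds.X, atol=1e-12)
    np.testing.assert_allclose(again.E, ds.E, atol=1e-12)


def test_standardize_makes_correlation_matrix():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 5)) * 3 + 1
    ds = standardize(_dataset(X, rng.standard_normal(50)))
    assert np.abs(ds.X.mean(axis=0)).max() < 1e-12
    assert np.abs(ds.X.var(axis=0, ddof=1) - 1).max() < 1e-12
    C = ds.X.T @ ds.X / 49
    np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)


def test_standardize_constant_column_names_snp():
    X = np.ones((4, 2))
    X[:, 1] = [0, 1, 2, 3]
    with pytest.raises(ValueError, match="rs0"):
        standardize(_dataset(X, np.array([1.0, 2, 3, 4])))


def test_adjust_covariates():
    rng = np.random.default_rng(1)
    E = rng.standard_normal(30)
    np.testing.assert_allclose(adjust_covariates(E, None), E - E.mean())

    C = rng.standard_normal((30, 3))
    gamma = np.array([0.5, -1.0, 2.0])
    exact = C @ gamma + 4.0
    np.testing.assert_allclose(adjust_covariates(exact, C), 0, atol=1e-10)

    E2 = C @ gamma + rng.standard_normal(30)
    resid = adjust_covariates(E2, C)
    for j in range(3):
        assert abs(np.corrcoef(resid, C[:, j])[0, 1]) < 1e-10

    C_def = np.column_stack([C[:, 0], C[:, 0]])
    with pytest.raises(ValueError, match="rank"):
        adjust_covariates(E2, C_def)


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------

def _make_fit(seed):
    rng = np.random.default_rng(seed)
    p = 6
    return ImputationFit(
        gene_id=f"gene{seed}",
        snp_ids=[f"rs{i}" for i in range(p)],
        effect_alleles=["A"] * p,
        weights_full=rng.standard_normal(p),
        weights_by_sparsity={0.5: rng.standard_normal(p)},
        importance=rng.random(p),
        coclustering=np.eye(p),
        traces={"sigma2_e": rng.random(10), "k_p": np.arange(10)},
        config=MaatConfig(n_iter=20, n_burnin=10, seed=seed),
        seed=seed,
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_model_archive_round_trip(tmp_path, seed):
    fit = _make_fit(seed)
    path = tmp_path / "model.h5"
    write_model(fit, path)
    back = read_model(path)
    assert back.gene_id == fit.gene_id
    assert back.snp_ids == fit.snp_ids
    np.testing.assert_array_equal(back.weights_full, fit.weights_full)
    np.testing.assert_array_equal(back.weights_by_sparsity[0.5],
                                  fit.weights_by_sparsity[0.5])
    np.testing.assert_array_equal(back.importance, fit.importance)
    assert back.config == fit.config


def test_model_archive_version_mismatch(tmp_path):
    import h5py

    fit = _make_fit(0)
    path = tmp_path / "model.h5"
    write_model(fit, path)
    with h5py.File(path, "a") as h5:
        h5.attrs["format_version"] = 999
    with pytest.raises(ValueError, match="version"):
        read_model(path)
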