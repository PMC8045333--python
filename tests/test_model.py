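import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from binsplice import (
    SimConfig,
    ValidationError,
    design_from_conditions,
    filter_bins,
    fit_bin_models,
    simulate_utr_counts,
    squeeze_variances,
    tmm_factors,
    voom_weights,
)
from binsplice.counting import BinCountMatrix
from binsplice.model import BinFits, fit_f_dist

from conftest import make_design


def make_matrix(counts, conditions=("a", "a", "a", "b", "b", "b")):
    counts = np.asarray(counts)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    ids = pd.Index([f"g{i}:1" for i in range(counts.shape[0])], name="bin_id")
    info = pd.DataFrame({"gene": [f"g{i}" for i in range(counts.shape[0])]},
                        index=ids)
    return BinCountMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=samples),
        bin_info=info,
        lib_sizes=pd.Series(counts.sum(axis=0), index=samples),
        conditions=pd.Series(list(conditions), index=samples),
    )


# ---------------------------------------------------------------------------
# filtering


def test_filter_drops_all_zero_and_keeps_strong_bins():
    mat = make_matrix([
        [0, 0, 0, 0, 0, 0],
        [500, 520, 480, 510, 530, 490],
        [400, 410, 390, 420, 380, 400],
    ])
    design = design_from_conditions(mat.conditions)
    kept = filter_bins(mat, design)
    assert list(kept.counts.index) == ["g1:1", "g2:1"]


def test_filter_smallest_group_rule():
    # bin present strongly in exactly the 3 samples of one group
    base = np.tile([1000, 1000, 1000, 1000, 1000, 1000], (20, 1))
    target = np.array([[40, 45, 42, 0, 0, 0]])
    mat = make_matrix(np.vstack([base, target]))
    design = design_from_conditions(mat.conditions)
    kept = filter_bins(mat, design)
    assert "g20:1" in kept.counts.index
    # in only 2 samples (fewer than the smallest group): dropped
    target2 = np.array([[40, 45, 0, 0, 0, 0]])
    mat2 = make_matrix(np.vstack([base, target2]))
    kept2 = filter_bins(mat2, design_from_conditions(mat2.conditions))
    assert "g20:1" not in kept2.counts.index


def test_filter_zero_bins_is_error():
    mat = make_matrix(np.ones((3, 6), dtype=int))
    design = design_from_conditions(mat.conditions)
    with pytest.raises(ValidationError, match="threshold"):
        filter_bins(mat, design, min_count=1e6)


# ---------------------------------------------------------------------------
# TMM


def test_tmm_identical_samples_give_unit_factors():
    rng = np.random.default_rng(0)
    col = rng.integers(10, 1000, size=50)
    mat = make_matrix(np.tile(col[:, None], (1, 6)))
    out = tmm_factors(mat)
    assert np.allclose(out.norm_factors, 1.0)


def test_tmm_uniform_scaling_absorbed_by_library_size():
    rng = np.random.default_rng(1)
    col = rng.integers(50, 2000, size=200)
    counts = np.column_stack([col, 2 * col, col, col, 2 * col, col])
    mat = make_matrix(counts)
    out = tmm_factors(mat)
    assert np.allclose(out.norm_factors, 1.0, atol=1e-6)


def test_tmm_factors_multiply_to_one():
    counts, _ = simulate_utr_counts(SimConfig(seed=3, n_genes=100,
                                              n_utr_genes=20,
                                              n_de_utr_genes=5,
                                              n_de_other_genes=5))
    out = tmm_factors(counts)
    assert np.isclose(np.prod(out.norm_factors), 1.0)
    assert not np.allclose(out.norm_factors, 1.0)  # non-trivial factors


def test_tmm_matches_edger(tmp_path):
    """Cross-check against the reference implementation in R."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    counts, _ = simulate_utr_counts(SimConfig(seed=5, n_genes=80,
                                              n_utr_genes=20,
                                              n_de_utr_genes=5,
                                              n_de_other_genes=5))
    ours = tmm_factors(counts).norm_factors
    cpath = tmp_path / "c.tsv"
    counts.counts.to_csv(cpath, sep="\t")
    lib = ",".join(str(int(x)) for x in counts.lib_sizes)
    r = subprocess.run(
        ["Rscript", "-e",
         f'suppressMessages(library(edgeR));'
         f'x <- read.delim("{cpath}", row.names=1);'
         f'f <- calcNormFactors(as.matrix(x), lib.size=c({lib}));'
         f'cat(f, sep="\\n")'],
        capture_output=True, text=True, check=True,
    )
    theirs = np.array([float(v) for v in r.stdout.split()])
    assert np.allclose(ours.to_numpy(), theirs, atol=1e-6)


# ---------------------------------------------------------------------------
# precision weights


def test_voom_equal_counts_give_equal_weights():
    mat = make_matrix(np.full((10, 6), 100))
    design = design_from_conditions(mat.conditions)
    _, w = voom_weights(mat, design)
    assert np.allclose(w.to_numpy(), w.to_numpy()[0, 0])


def test_voom_weights_increase_with_expression():
    """Counts follow the decreasing NB mean-variance trend, so higher
    fitted counts must earn larger weights."""
    rng = np.random.default_rng(11)
    mus = 10 ** rng.uniform(1, 4, size=400)
    phi = 0.1
    r = 1 / phi
    counts = rng.negative_binomial(r, r / (r + mus)[:, None], size=(400, 6))
    mat = make_matrix(counts)
    design = design_from_conditions(mat.conditions)
    logexpr, w = voom_weights(mat, design)
    mean_w = w.mean(axis=1)
    amean = logexpr.mean(axis=1)
    rho = pd.Series(mean_w.to_numpy()).corr(
        pd.Series(amean.to_numpy()), method="spearman"
    )
    assert rho > 0.8


def test_voom_weight_symmetry_under_sample_relabeling():
    rng = np.random.default_rng(2)
    counts = rng.integers(20, 500, size=(50, 6))
    mat = make_matrix(counts)
    design = design_from_conditions(mat.conditions)
    _, w1 = voom_weights(mat, design)
    # swapping two samples within a group permutes weights identically
    perm = [1, 0, 2, 3, 4, 5]
    mat2 = make_matrix(counts[:, perm])
    _, w2 = voom_weights(mat2, design)
    assert np.allclose(w1.to_numpy()[:, perm], w2.to_numpy())


# ---------------------------------------------------------------------------
# weighted least squares


def fits_from_arrays(Y, W, design, genes=None):
    ids = pd.Index([f"b{i}" for i in range(Y.shape[0])], name="bin_id")
    le = pd.DataFrame(Y, index=ids, columns=design.X.index)
    w = pd.DataFrame(W, index=ids, columns=design.X.index)
    info = pd.DataFrame(
        {"gene": genes if genes is not None else [f"g{i}" for i in ids]},
        index=ids,
    )
    return fit_bin_models(le, w, design, info)


def test_unit_weight_two_group_beta_is_mean_difference():
    design = make_design()
    rng = np.random.default_rng(4)
    Y = rng.normal(size=(5, 6))
    fits = fits_from_arrays(Y, np.ones_like(Y), design)
    expect = Y[:, 3:].mean(axis=1) - Y[:, :3].mean(axis=1)
    assert np.allclose(fits.table["coef"], expect, atol=1e-12)


def test_wls_matches_statsmodels():
    import statsmodels.api as sm

    design = make_design()
    rng = np.random.default_rng(5)
    Y = rng.normal(size=(20, 6))
    W = rng.uniform(0.2, 3.0, size=(20, 6))
    fits = fits_from_arrays(Y, W, design)
    X = design.X.to_numpy()
    for i in range(20):
        res = sm.WLS(Y[i], X, weights=W[i]).fit()
        assert np.isclose(fits.table["coef"].iloc[i], res.params[1],
                          atol=1e-10)
        # u = unscaled sd: statsmodels bse = u * sqrt(sigma2)
        sigma2 = res.mse_resid
        assert np.isclose(fits.table["u"].iloc[i],
                          res.bse[1] / np.sqrt(sigma2), atol=1e-10)
        assert np.isclose(fits.table["sigma2"].iloc[i], sigma2, atol=1e-10)


def test_duplicating_samples_halves_u_squared():
    design = make_design()
    # duplicated samples keep the original column order a,a,a,b,b,b,a,...
    cond2 = pd.Series(list("aaabbb") * 2,
                      index=[f"d{i}" for i in range(12)])
    design2 = design_from_conditions(cond2)
    rng = np.random.default_rng(6)
    Y = rng.normal(size=(8, 6))
    W = rng.uniform(0.5, 2.0, size=(8, 6))
    f1 = fits_from_arrays(Y, W, design)
    f2 = fits_from_arrays(np.hstack([Y, Y]), np.hstack([W, W]), design2)
    assert np.allclose(f1.table["coef"], f2.table["coef"], atol=1e-12)
    assert np.allclose(f2.table["u"] ** 2, f1.table["u"] ** 2 / 2,
                       atol=1e-12)


def test_zero_variance_bin_fits_exactly():
    design = make_design()
    Y = np.array([[1.0, 1.0, 1.0, 3.0, 3.0, 3.0]])
    fits = fits_from_arrays(Y, np.ones_like(Y), design)
    assert np.isclose(fits.table["coef"].iloc[0], 2.0)
    assert np.isclose(fits.table["sigma2"].iloc[0], 0.0, atol=1e-20)


def test_rank_deficient_design_rejected():
    X = pd.DataFrame(
        {"a": [1.0] * 4, "b": [2.0] * 4},
        index=[f"s{i}" for i in range(4)],
    )
    from binsplice.model import DesignMatrix

    with pytest.raises(ValidationError, match="rank"):
        DesignMatrix(X=X, coef="b")


# ---------------------------------------------------------------------------
# variance squeezing


def make_fits_table(s2, df, genes):
    ids = pd.Index([f"b{i}" for i in range(len(s2))], name="bin_id")
    table = pd.DataFrame(
        {"gene": genes, "coef": 0.0, "u": 1.0, "sigma2": s2,
         "df": float(df), "amean": 5.0},
        index=ids,
    )
    return BinFits(table=table, design=make_design())


def test_identical_variances_give_degenerate_prior():
    fits = make_fits_table([2.0] * 10, 4, [f"g{i}" for i in range(10)])
    sq = squeeze_variances(fits, per_bin=True)
    assert math.isinf(sq.d0)
    assert np.allclose(sq.post_s2, 2.0)


def test_posterior_is_convex_combination():
    rng = np.random.default_rng(7)
    s2 = np.exp(rng.normal(0.0, 1.5, size=100))  # wide spread: finite d0
    fits = make_fits_table(s2, 4, [f"g{i}" for i in range(100)])
    sq = squeeze_variances(fits, per_bin=True)
    manual = (sq.d0 * sq.s02 + 4 * s2) / (sq.d0 + 4)
    assert np.allclose(sq.post_s2, manual)
    lo = np.minimum(s2, sq.s02)
    hi = np.maximum(s2, sq.s02)
    assert ((sq.post_s2 >= lo - 1e-12) & (sq.post_s2 <= hi + 1e-12)).all()


def test_prior_recovery_from_known_distribution():
    """d0 and s0^2 recovered within 25% from 500 draws (d0=4, s0^2=2)."""
    rng = np.random.default_rng(42)
    d0_true, s0_true, df = 4.0, 2.0, 4.0
    s2_prior = d0_true * s0_true / rng.chisquare(d0_true, size=500)
    s2_obs = s2_prior * rng.chisquare(df, size=500) / df
    d0, s0 = fit_f_dist(s2_obs, np.full(500, df))
    assert abs(d0 - d0_true) / d0_true < 0.25
    assert abs(s0 - s0_true) / s0_true < 0.25


def test_squeeze_matches_limma(tmp_path):
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    rng = np.random.default_rng(42)
    s2_prior = 8.0 / rng.chisquare(4.0, size=500)
    s2 = s2_prior * rng.chisquare(4, size=500) / 4
    np.savetxt(tmp_path / "s2.txt", s2)
    d0, s0 = fit_f_dist(s2, np.full(500, 4.0))
    r = subprocess.run(
        ["Rscript", "-e",
         f'suppressMessages(library(limma));'
         f's2 <- scan("{tmp_path / "s2.txt"}", quiet=TRUE);'
         f'sv <- squeezeVar(s2, df=4);'
         f'cat(sv$df.prior, sv$var.prior, sep="\\n")'],
        capture_output=True, text=True, check=True,
    )
    d0_r, s0_r = (float(v) for v in r.stdout.split())
    assert np.isclose(d0, d0_r, rtol=1e-6)
    assert np.isclose(s0, s0_r, rtol=1e-6)


def test_gene_level_squeeze_averages_within_genes():
    genes = ["gA"] * 3 + ["gB"] * 3
    s2 = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    fits = make_fits_table(s2, 4, genes)
    sq = squeeze_variances(fits, per_bin=False)
    assert not sq.per_bin
    # every bin of a gene shares the gene posterior
    assert sq.post_s2.iloc[0] == sq.post_s2.iloc[1] == sq.post_s2.iloc[2]
    # gene df is the summed residual df
    assert (sq.gene_df == 12.0).all()
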