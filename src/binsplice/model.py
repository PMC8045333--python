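"""Per-bin linear modeling of log counts.

The pre-processing chain mirrors the established count-model workflow:
expression filtering, trimmed-mean-of-M-values (TMM) library
normalization, mean-variance precision weights, weighted least squares
per bin, and empirical-Bayes squeezing of the residual variances toward
a moment-matched scaled inverse-chi-square prior. Everything here is
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .counting import BinCountMatrix
from .errors import ValidationError


# ---------------------------------------------------------------------------
# design


@dataclass
class DesignMatrix:
    """Samples x coefficients design with the tested coefficient named."""

    X: pd.DataFrame  # index sample ids, columns coefficient names
    coef: str  # name of the contrast coefficient tested

    def __post_init__(self):
        if self.coef not in self.X.columns:
            raise ValidationError(f"coefficient {self.coef!r} not in design")
        if np.linalg.matrix_rank(self.X.to_numpy()) < self.X.shape[1]:
            raise ValidationError("design matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def coef_index(self) -> int:
        return list(self.X.columns).index(self.coef)

    def smallest_group_size(self) -> int:
        """Number of samples in the smallest design-distinct group."""
        rows = [tuple(r) for r in self.X.to_numpy()]
        return min(rows.count(r) for r in set(rows))


def design_from_conditions(conditions: pd.Series, reference: str | None = None
                           ) -> DesignMatrix:
    """Two-group intercept + indicator design from condition labels.

    The tested coefficient is the log2 fold change of the non-reference
    condition over the reference (lexicographically first by default).
    """
    conditions = pd.Series(conditions)
    levels = sorted(conditions.unique())
    if len(levels) != 2:
        raise ValidationError(
            f"expected exactly 2 conditions, got {levels}"
        )
    if reference is None:
        reference = levels[0]
    other = [l for l in levels if l != reference][0]
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            f"condition_{other}": (conditions == other).astype(float),
        },
        index=conditions.index,
    )
    return DesignMatrix(X=X, coef=f"condition_{other}")


# ---------------------------------------------------------------------------
# filtering (filterByExpr-style rule)


def filter_bins(
    counts: BinCountMatrix,
    design: DesignMatrix,
    min_count: float = 10,
    min_total_count: float = 15,
    large_n: int = 10,
    min_prop: float = 0.7,
) -> BinCountMatrix:
    """Keep bins with enough reads for stable inference.

    A bin is kept when its CPM (against the median effective library
    size) reaches the CPM equivalent of ``min_count`` in at least as many
    samples as the smallest design group (damped to
    ``large_n + (n-large_n)*min_prop`` for large groups), and its total
    count reaches ``min_total_count``.
    """
    if counts.counts.shape[1] < 2:
        raise ValidationError("filtering requires at least 2 samples")
    lib = counts.effective_lib_sizes().to_numpy(dtype=float)
    n_min = design.smallest_group_size()
    if n_min > large_n:
        n_min = large_n + (n_min - large_n) * min_prop
    median_lib = np.median(lib)
    cpm_cutoff = min_count / median_lib * 1e6
    cpm = counts.counts.to_numpy() / lib * 1e6
    tol = 1e-14
    keep = ((cpm >= cpm_cutoff).sum(axis=1) >= n_min - tol) & (
        counts.counts.sum(axis=1).to_numpy() >= min_total_count - tol
    )
    if not keep.any():
        raise ValidationError(
            "no bins pass the expression filter; review min_count/"
            "min_total_count thresholds"
        )
    out = counts.subset_bins(counts.counts.index[keep])
    out.bin_info = out.bin_info.copy()
    return out


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(obs, ref, lib_obs, lib_ref,
              logratio_trim=0.3, sum_trim=0.05) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logR = np.log2((obs / lib_obs) / (ref / lib_ref))
        absE = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(logR) & np.isfinite(absE) & (absE > -1e10)
    logR, absE, v = logR[fin], absE[fin], v[fin]
    if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    loL = math.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = math.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rankR = pd.Series(logR).rank().to_numpy()
    rankE = pd.Series(absE).rank().to_numpy()
    keep = (rankR >= loL) & (rankR <= hiL) & (rankE >= loS) & (rankE <= hiS)
    if not keep.any():
        return 1.0
    f = np.sum(logR[keep] / v[keep]) / np.sum(1 / v[keep])
    return float(2 ** f)


def tmm_factors(counts: BinCountMatrix) -> BinCountMatrix:
    """Fill normalization factors by trimmed mean of M-values.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the mean of those quantiles. Factors are rescaled to
    have geometric mean 1.
    """
    mat = counts.counts.to_numpy(dtype=float)
    lib = counts.lib_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValidationError("non-positive library size")
    f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75)
                    for j in range(mat.shape[1])])
    if np.median(f75) < 1e-20:
        ref_j = int(np.argmax(mat.sum(axis=0)))
    else:
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if mat[:, j].sum() == 0:
            factors[j] = 1.0  # all-zero sample: leave unscaled
            continue
        factors[j] = _tmm_pair(mat[:, j], mat[:, ref_j], lib[j], lib[ref_j])
    factors = factors / np.exp(np.mean(np.log(factors)))
    out = counts.subset_bins(counts.counts.index)
    out.norm_factors = pd.Series(factors, index=counts.counts.columns)
    return out


# ---------------------------------------------------------------------------
# precision weights (voom-style mean-variance trend)


def _wls_stats(Y: np.ndarray, W: np.ndarray, X: np.ndarray):
    """Batched weighted least squares.

    Y, W: (G, n); X: (n, p). Returns beta (G, p), unscaled covariances
    (G, p, p), residual variances (G,) and residual df.
    """
    G, n = Y.shape
    p = X.shape[1]
    A = np.einsum("ni,gn,nj->gij", X, W, X)
    rhs = np.einsum("ni,gn->gi", X, W * Y)
    cov = np.linalg.inv(A)
    beta = np.einsum("gij,gj->gi", cov, rhs)
    resid = Y - beta @ X.T
    df = n - p
    sigma2 = np.einsum("gn,gn->g", W, resid ** 2) / df
    return beta, cov, sigma2, df


def voom_weights(
    counts: BinCountMatrix,
    design: DesignMatrix,
    span: float = 0.5,
):
    """Log2-CPM matrix and inverse mean-variance-trend precision weights.

    Log2 CPM uses a 0.5 count offset against effective library sizes + 1.
    Residual square-root standard deviations from an unweighted fit are
    regressed on average log2 counts by lowess; weights are the inverse
    fourth power of the trend evaluated at each observation's fitted log2
    count, clamped to the fitted range at the extremes.
    """
    X = design.X.to_numpy(dtype=float)
    n, p = X.shape
    if n - p < 1:
        raise ValidationError("fewer than 1 residual degree of freedom")
    lib = counts.effective_lib_sizes().to_numpy(dtype=float) + 1.0
    mat = counts.counts.to_numpy(dtype=float)
    E = np.log2((mat + 0.5) / lib * 1e6)

    ones = np.ones_like(E)
    beta, _, sigma2, _ = _wls_stats(E, ones, X)
    sqrt_sd = np.sqrt(np.sqrt(np.maximum(sigma2, 0.0)))
    amean = E.mean(axis=1)
    # back to the log-count scale the trend is fitted on
    sx = amean + np.mean(np.log2(lib)) - np.log2(1e6)

    if np.unique(sx).size < 2 or np.allclose(sqrt_sd, sqrt_sd[0]):
        # degenerate trend (e.g. perfectly symmetric toy input): flat weights
        const = max(float(np.mean(sqrt_sd)), 1e-8)
        trend_x = np.array([sx.min(), sx.max()])
        trend_y = np.array([const, const])
    else:
        fit = lowess(sqrt_sd, sx, frac=span, it=3)
        trend_x, trend_y = fit[:, 0], fit[:, 1]

    fitted = beta @ X.T  # fitted log2 CPM
    fitted_logcount = fitted + (np.log2(lib) - np.log2(1e6))
    pred = np.interp(fitted_logcount, trend_x, trend_y)  # clamped at ends
    pred = np.maximum(pred, 1e-8)
    W = 1.0 / pred ** 4
    logexpr = pd.DataFrame(E, index=counts.counts.index,
                           columns=counts.counts.columns)
    weights = pd.DataFrame(W, index=counts.counts.index,
                           columns=counts.counts.columns)
    return logexpr, weights


# ---------------------------------------------------------------------------
# per-bin model fits


@dataclass
class BinFits:
    """Weighted least-squares results for every bin.

    ``table`` has one row per bin: gene, coefficient (log2 fold change of
    the tested contrast), its unscaled standard deviation u (square root
    of the tested diagonal element of (X'VX)^-1), residual variance,
    residual df and average log2 expression.
    """

    table: pd.DataFrame
    design: DesignMatrix
    weights: pd.DataFrame = None

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="bin_id",
                          float_format="%.10g")


def fit_bin_models(
    logexpr: pd.DataFrame,
    weights: pd.DataFrame,
    design: DesignMatrix,
    bin_info: pd.DataFrame,
) -> BinFits:
    """Fit a weighted linear model to every bin's log expression."""
    X = design.X.to_numpy(dtype=float)
    Y = logexpr.to_numpy(dtype=float)
    W = weights.to_numpy(dtype=float)
    if Y.shape != W.shape or Y.shape[1] != X.shape[0]:
        raise ValidationError("dimension mismatch between expression, "
                              "weights and design")
    beta, cov, sigma2, df = _wls_stats(Y, W, X)
    j = design.coef_index
    u = np.sqrt(cov[:, j, j])
    table = pd.DataFrame(
        {
            "gene": bin_info.loc[logexpr.index, "gene"].to_numpy(),
            "coef": beta[:, j],
            "u": u,
            "sigma2": sigma2,
            "df": float(df),
            "amean": Y.mean(axis=1),
        },
        index=logexpr.index,
    )
    for col in ("type", "width"):
        if col in bin_info.columns:
            table[col] = bin_info.loc[logexpr.index, col].to_numpy()
    return BinFits(table=table, design=design, weights=weights)


# ---------------------------------------------------------------------------
# empirical-Bayes variance squeezing


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif) / y) < 1e-8:
            break
    return y


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled F distribution to observed variances.

    Works on log variances: corrects each log variance for the bias of
    log chi-square with its df, then matches the mean and the excess
    variance to the digamma/trigamma moments of the prior. Returns
    (prior df d0, prior variance s0^2); d0 may be infinite when the
    observed spread is no larger than sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValidationError("need at least 2 variances with positive df")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1)
    evar = evar - np.mean(polygamma(1, df / 2))
    if evar > 0:
        d0 = float(2 * _trigamma_inverse(np.array([evar]))[0])
        s0 = float(np.exp(emean + digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        # spread no larger than sampling noise: degenerate point prior
        d0 = math.inf
        s0 = float(np.mean(s2))
    return d0, s0


@dataclass
class SqueezeResult:
    """Prior (d0, s0^2) and posterior variances, indexed like the input."""

    d0: float
    s02: float
    post_s2: pd.Series
    df: pd.Series  # residual df backing each posterior
    per_bin: bool = True
    gene_post_s2: pd.Series = None  # legacy path: per-gene posteriors
    gene_df: pd.Series = None


def squeeze_variances(
    fits: BinFits,
    per_bin: bool = True,
) -> SqueezeResult:
    """Squeeze residual variances toward an empirical-Bayes prior.

    With ``per_bin=True`` each bin's residual variance is squeezed
    directly (the improved statistic's behaviour). With ``per_bin=False``
    variances are first averaged within genes and the gene values are
    squeezed (the legacy behaviour, which assumes a constant residual
    variance across the bins of a gene); the per-bin posterior is then
    the gene posterior of the bin's gene.
    """
    tab = fits.table
    s2 = tab["sigma2"].to_numpy(dtype=float)
    df = tab["df"].to_numpy(dtype=float)
    if per_bin:
        if np.allclose(s2, s2[0]):
            d0, s0 = math.inf, float(s2[0])
        else:
            d0, s0 = fit_f_dist(s2, df)
        post = _posterior(s2, df, d0, s0)
        return SqueezeResult(
            d0=d0, s02=s0,
            post_s2=pd.Series(post, index=tab.index),
            df=pd.Series(df, index=tab.index),
            per_bin=True,
        )
    gene_s2 = tab.groupby("gene")["sigma2"].mean()
    gene_df = tab.groupby("gene")["df"].sum()
    g_s2 = gene_s2.to_numpy(dtype=float)
    g_df = gene_df.to_numpy(dtype=float)
    if np.allclose(g_s2, g_s2[0]):
        d0, s0 = math.inf, float(g_s2[0])
    else:
        d0, s0 = fit_f_dist(g_s2, g_df)
    g_post = _posterior(g_s2, g_df, d0, s0)
    gene_post = pd.Series(g_post, index=gene_s2.index)
    per_bin_post = tab["gene"].map(gene_post)
    per_bin_df = tab["gene"].map(pd.Series(g_df, index=gene_s2.index))
    return SqueezeResult(
        d0=d0, s02=s0,
        post_s2=per_bin_post,
        df=per_bin_df,
        per_bin=False,
        gene_post_s2=gene_post,
        gene_df=pd.Series(g_df, index=gene_s2.index),
    )


def _posterior(s2: np.ndarray, df: np.ndarray, d0: float, s02: float
               ) -> np.ndarray:
    """Convex combination of prior and sample variances."""
    if math.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s02)
    return (d0 * s02 + df * s2) / (d0 + df)
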