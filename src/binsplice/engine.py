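"""Differential bin-usage statistics.

Both tests compare each bin's log2 fold change beta_k with a
precision-weighted average B_k of the other bins of the same gene:

    B_k = sum_{i != k} w_i beta_i / sum_{i != k} w_i,   C_k = beta_k - B_k.

The legacy moderated t (``diffsplice_classic``) uses w_i = 1/u_i^2,
rescales C_k by sqrt(1 - w_k / sum w) into D_k, and divides by the
gene-level posterior residual standard deviation:

    t_k = D_k / (u_k * s_g).

The improved statistic (``diffsplice2``) drops the constant-variance
assumption: each bin's residual variance is squeezed individually, the
weights become w_i = 1/(s_i^2 u_i^2), and C_k is used directly:

    t_k = C_k / (u_k * s_k).

Two-sided p-values come from a t distribution with empirical-Bayes
moderated degrees of freedom; gene-level p-values are Simes-aggregated
and both levels are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .model import BinFits, SqueezeResult, squeeze_variances


@dataclass
class DiffSpliceResult:
    """Bin-level and gene-level differential-usage tables."""

    bins: pd.DataFrame  # index bin_id: gene, coef(C), t, p, df, fdr, ...
    genes: pd.DataFrame  # index gene: p_simes, fdr, n_bins
    method: str  # "diffsplice" | "diffsplice2"
    d0: float = math.nan
    s02: float = math.nan

    def write_tsv(self, bins_path, genes_path) -> None:
        self.bins.to_csv(bins_path, sep="\t", index_label="bin_id",
                         float_format="%.10g")
        self.genes.to_csv(genes_path, sep="\t", index_label="gene",
                          float_format="%.10g")


def simes(p: np.ndarray) -> float:
    """Simes combination: min over i of n * p_(i) / i, capped at 1."""
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValidationError("no finite p-values to aggregate")
    ps = np.sort(p)
    n = ps.size
    return float(min(1.0, np.min(n * ps / np.arange(1, n + 1))))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR over the finite entries; NaN passthrough."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _relative_coefficients(beta, u, w):
    """C_k (and the leave-one-out average B_k) under weights w."""
    sw = w.sum()
    swb = (w * beta).sum()
    B = (swb - w * beta) / (sw - w)
    C = beta - B
    return B, C, sw


def _run(fits: BinFits, squeeze: SqueezeResult, method: str
         ) -> DiffSpliceResult:
    tab = fits.table.copy()
    usable = np.isfinite(tab["u"]) & (tab["u"] > 0) & np.isfinite(tab["coef"])
    if (~usable).any():
        tab = tab.copy()
    tab["usable"] = usable
    n_per_gene = tab.groupby("gene")["usable"].transform("sum")
    tested = usable & (n_per_gene >= 2)

    d0 = squeeze.d0
    total_df = float(np.nansum(fits.table["df"].to_numpy()))

    C = np.full(len(tab), np.nan)
    D = np.full(len(tab), np.nan)
    t = np.full(len(tab), np.nan)
    dfree = np.full(len(tab), np.nan)

    idx_all = np.arange(len(tab))
    for gene, sub in tab[tested].groupby("gene", sort=False):
        rows = idx_all[tab.index.get_indexer(sub.index)]
        beta = sub["coef"].to_numpy(dtype=float)
        u = sub["u"].to_numpy(dtype=float)
        s2 = squeeze.post_s2.loc[sub.index].to_numpy(dtype=float)
        if method == "diffsplice2":
            w = 1.0 / (s2 * u ** 2)
        else:
            w = 1.0 / u ** 2
        _, Cg, sw = _relative_coefficients(beta, u, w)
        C[rows] = Cg
        if method == "diffsplice2":
            t[rows] = Cg / (u * np.sqrt(s2))
            df_g = sub["df"].to_numpy(dtype=float) + (
                0.0 if math.isinf(d0) else d0
            )
        else:
            Dg = Cg * np.sqrt(1.0 - w / sw)
            D[rows] = Dg
            s_g = math.sqrt(float(squeeze.gene_post_s2.loc[gene]))
            t[rows] = Dg / (u * s_g)
            df_g = float(squeeze.gene_df.loc[gene]) + (
                0.0 if math.isinf(d0) else d0
            )
            df_g = np.full(len(rows), df_g)
        if math.isinf(d0):
            dfree[rows] = np.inf
        else:
            dfree[rows] = np.minimum(df_g, total_df)

    with np.errstate(invalid="ignore"):
        p = np.where(
            np.isfinite(t),
            2 * stats.t.sf(np.abs(t), np.where(np.isfinite(dfree), dfree, 1e12)),
            np.nan,
        )
    tab["coef"] = tab["coef"].where(tested, np.nan)  # beta only meaningful raw
    out = pd.DataFrame(
        {
            "gene": tab["gene"],
            "coef": C,
            "D": D,
            "t": t,
            "p": p,
            "df": dfree,
            "fdr": bh_adjust(p),
            "amean": fits.table["amean"],
        },
        index=fits.table.index,
    )
    for col in ("type", "width"):
        if col in fits.table.columns:
            out[col] = fits.table[col]

    genes = _aggregate_genes(out)
    return DiffSpliceResult(bins=out, genes=genes, method=method,
                            d0=d0, s02=squeeze.s02)


def _aggregate_genes(bins: pd.DataFrame, p_col: str = "p") -> pd.DataFrame:
    rows = {}
    for gene, sub in bins.groupby("gene", sort=True):
        p = sub[p_col].to_numpy(dtype=float)
        n = int(np.isfinite(p).sum())
        if n == 0:
            continue
        rows[gene] = (simes(p), n)
    genes = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["p_simes", "n_bins"])
    genes.index.name = "gene"
    genes["fdr"] = bh_adjust(genes["p_simes"].to_numpy())
    return genes[["p_simes", "fdr", "n_bins"]]


def diffsplice_classic(fits: BinFits, squeeze: SqueezeResult | None = None
                       ) -> DiffSpliceResult:
    """Legacy moderated t with gene-level residual variance."""
    if squeeze is None:
        squeeze = squeeze_variances(fits, per_bin=False)
    if squeeze.per_bin:
        raise ValidationError("classic statistic needs a per-gene squeeze")
    return _run(fits, squeeze, "diffsplice")


def diffsplice2(fits: BinFits, squeeze: SqueezeResult | None = None
                ) -> DiffSpliceResult:
    """Improved moderated t with per-bin squeezed variances."""
    if squeeze is None:
        squeeze = squeeze_variances(fits, per_bin=True)
    if not squeeze.per_bin:
        raise ValidationError("diffsplice2 needs a per-bin squeeze")
    return _run(fits, squeeze, "diffsplice2")


def utr_gene_results(
    result: DiffSpliceResult,
    which: str = "both",
) -> DiffSpliceResult:
    """Gene-level results restricted to (3') UTR bins.

    All bins not of the requested type(s) get p := 1 before Simes
    aggregation, so a gene is only called on the strength of its UTR
    bins; genes with no UTR bin at all get gene p = 1. Bin-level C
    values are kept for display.
    """
    allowed = {
        "UTR": {"UTR"},
        "3UTR": {"3UTR"},
        "both": {"UTR", "3UTR"},
    }.get(which)
    if allowed is None:
        raise ValidationError(f"unknown UTR selection {which!r}")
    if "type" not in result.bins.columns:
        raise ValidationError("bin types unavailable; rebuild with a BinSet")
    bins = result.bins.copy()
    is_utr = bins["type"].isin(allowed)
    tested = np.isfinite(bins["p"].to_numpy(dtype=float))
    masked = bins["p"].to_numpy(dtype=float).copy()
    masked[tested & ~is_utr.to_numpy()] = 1.0
    bins["p_masked"] = masked
    genes = _aggregate_genes(bins, p_col="p_masked")
    return DiffSpliceResult(bins=bins, genes=genes,
                            method=result.method + "+utr",
                            d0=result.d0, s02=result.s02)


@dataclass
class GeneScore:
    gene: str
    score: float
    p: float
    fdr: float
    mean_expr: float
    rel_expr_sig: float


def gene_effect_scores(
    result: DiffSpliceResult,
    mode: str = "UTR",
    weight_cap: float = 10.0,
    sig_fdr: float = 0.05,
) -> pd.DataFrame:
    """Gene-level effect sizes for ranking and plotting.

    DEU mode averages absolute bin coefficients weighted by significance
    (omega_k = -log10 p_k, capped); UTR mode averages signed coefficients
    weighted by significance and bin width (reported in kb-weighted log2
    units), so a lengthening gene scores positive. Also reports the gene
    mean expression and the share of gene expression carried by
    significant bins (plot aesthetics).
    """
    if mode not in ("DEU", "UTR"):
        raise ValidationError(f"unknown scoring mode {mode!r}")
    bins = result.bins
    p_col = "p_masked" if (mode == "UTR" and "p_masked" in bins) else "p"
    rows = []
    for gene, sub in bins.groupby("gene", sort=True):
        p = sub[p_col].to_numpy(dtype=float)
        C = sub["coef"].to_numpy(dtype=float)
        ok = np.isfinite(p) & np.isfinite(C)
        if not ok.any():
            continue
        p, C = p[ok], C[ok]
        with np.errstate(divide="ignore"):
            omega = np.minimum(-np.log10(np.maximum(p, 1e-300)), weight_cap)
        if omega.sum() == 0:
            score = 0.0
        elif mode == "DEU":
            score = float(np.sum(np.abs(C) * omega) / np.sum(omega))
        else:
            width_kb = sub["width"].to_numpy(dtype=float)[ok] / 1000.0
            score = float(np.sum(C * width_kb * omega) / np.sum(omega))
        amean = sub["amean"].to_numpy(dtype=float)[ok]
        expr = 2.0 ** amean
        sig = sub["fdr"].to_numpy(dtype=float)[ok] < sig_fdr
        rel_sig = float(expr[sig].sum() / expr.sum()) if expr.sum() > 0 else 0.0
        gp = result.genes["p_simes"].get(gene, np.nan)
        gf = result.genes["fdr"].get(gene, np.nan)
        rows.append((gene, score, gp, gf, float(amean.mean()), rel_sig))
    df = pd.DataFrame(
        rows, columns=["gene", "score", "p_simes", "fdr",
                       "mean_expr", "rel_expr_sig"]
    ).set_index("gene")
    return df.sort_values("p_simes")
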