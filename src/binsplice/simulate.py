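"""Synthetic inputs with known differential 3' UTR usage.

Three generators cover the rest of the package:

* :func:`make_toy_annotation` — tiny deterministic GTF + APA BED text
  exercising every bin-construction edge case (overlapping genes,
  over-long candidate UTRs, gene-start guard, non-coding transcripts).
* :func:`make_read_fixture` — SAM text with interior, junction, spliced
  and off-bin reads whose expected bin counts are computed analytically.
* :func:`simulate_utr_counts` — a count-level emulation of the
  read-simulation benchmark design: genes carry a short/long isoform
  pair differing by inclusion of distal 3' UTR segments (extended to the
  next, second-next or third-next downstream poly(A) site); in affected
  genes one isoform is up- and the other down-regulated by the same
  fold change drawn between 1.3 and 5, shifting usage without
  (necessarily) changing overall gene expression. Counts are negative
  binomial around the isoform-mixture means, two conditions with three
  replicates each by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import BinCountMatrix
from .errors import ValidationError


# ---------------------------------------------------------------------------
# toy annotation + APA fixture


def make_toy_annotation(
    overlapping_genes: bool = False,
    far_apa: bool = False,
    gene_start_guard: bool = False,
    noncoding_gene: bool = True,
) -> tuple[str, str]:
    """Deterministic toy GTF and APA BED texts for the bin builder.

    The base layout on chr1 (+ strand): geneA with two transcripts whose
    exons overlap partially, a CDS ending inside the second exon, and two
    downstream APA sites at 1300 and 1500; geneB on the - strand with a
    mirrored structure. Optional flags add an exon-overlapping gene pair,
    an APA site >15 kb downstream, a gene start between geneA's end and a
    poly(A) site, and a non-coding gene.
    """
    g = []  # gtf lines
    b = []  # bed lines (0-based half-open)

    def feat(chrom, src, ftype, start, end, strand, attrs):
        g.append(
            f"{chrom}\t{src}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
        )

    def attrs(gene, tx=None, biotype="protein_coding"):
        s = f'gene_id "{gene}"; gene_biotype "{biotype}";'
        if tx:
            s += f' transcript_id "{tx}"; transcript_biotype "{biotype}";'
        return s

    # geneA, + strand: exons 100-400 (tx1, tx2) and 500-1200 (tx1: 500-1200,
    # tx2: 500-900); CDS 150-700 on tx1 -> bins past 700 are 3' UTR.
    feat("chr1", "toy", "gene", 100, 1200, "+", attrs("geneA"))
    feat("chr1", "toy", "transcript", 100, 1200, "+", attrs("geneA", "txA1"))
    feat("chr1", "toy", "exon", 100, 400, "+", attrs("geneA", "txA1"))
    feat("chr1", "toy", "exon", 500, 1200, "+", attrs("geneA", "txA1"))
    feat("chr1", "toy", "CDS", 150, 400, "+", attrs("geneA", "txA1"))
    feat("chr1", "toy", "CDS", 500, 700, "+", attrs("geneA", "txA1"))
    feat("chr1", "toy", "transcript", 100, 900, "+", attrs("geneA", "txA2"))
    feat("chr1", "toy", "exon", 100, 400, "+", attrs("geneA", "txA2"))
    feat("chr1", "toy", "exon", 500, 900, "+", attrs("geneA", "txA2"))
    feat("chr1", "toy", "CDS", 150, 400, "+", attrs("geneA", "txA2"))
    feat("chr1", "toy", "CDS", 500, 600, "+", attrs("geneA", "txA2"))
    # APA sites downstream of geneA: 1300 and 1500 (1-based single bases)
    b.append("chr1\t1299\t1300\tapa1\t0\t+")
    b.append("chr1\t1499\t1500\tapa2\t0\t+")

    # geneB, - strand, separate locus: exons 5000-5400, 5600-6000;
    # CDS 5600-5900 -> 3' UTR is the low-coordinate side.
    feat("chr1", "toy", "gene", 5000, 6000, "-", attrs("geneB"))
    feat("chr1", "toy", "transcript", 5000, 6000, "-", attrs("geneB", "txB1"))
    feat("chr1", "toy", "exon", 5000, 5400, "-", attrs("geneB", "txB1"))
    feat("chr1", "toy", "exon", 5600, 6000, "-", attrs("geneB", "txB1"))
    feat("chr1", "toy", "CDS", 5600, 5900, "-", attrs("geneB", "txB1"))
    b.append("chr1\t4799\t4800\tapaB\t0\t-")  # downstream on - strand

    if noncoding_gene:
        feat("chr1", "toy", "gene", 8000, 8500, "+",
             attrs("geneNC", biotype="lincRNA"))
        feat("chr1", "toy", "transcript", 8000, 8500, "+",
             attrs("geneNC", "txNC1", biotype="lincRNA"))
        feat("chr1", "toy", "exon", 8000, 8500, "+",
             attrs("geneNC", "txNC1", biotype="lincRNA"))

    if overlapping_genes:
        # geneC/geneD share 20100-20200 on + strand
        feat("chr2", "toy", "gene", 20000, 20200, "+", attrs("geneC"))
        feat("chr2", "toy", "transcript", 20000, 20200, "+",
             attrs("geneC", "txC1"))
        feat("chr2", "toy", "exon", 20000, 20200, "+", attrs("geneC", "txC1"))
        feat("chr2", "toy", "CDS", 20000, 20150, "+", attrs("geneC", "txC1"))
        feat("chr2", "toy", "gene", 20100, 20400, "+", attrs("geneD"))
        feat("chr2", "toy", "transcript", 20100, 20400, "+",
             attrs("geneD", "txD1"))
        feat("chr2", "toy", "exon", 20100, 20400, "+", attrs("geneD", "txD1"))
        feat("chr2", "toy", "CDS", 20150, 20350, "+", attrs("geneD", "txD1"))

    if far_apa:
        # >15 kb downstream of geneA's last bin: must be dropped by default
        b.append(f"chr1\t{1200 + 20000 - 1}\t{1200 + 20000}\tapaFar\t0\t+")

    if gene_start_guard:
        # geneE starts at 2000 (+) with its first exon at 2200; the APA
        # site at 2100 overlaps no bin and geneE's start lies between
        # geneA's 3' boundary and the site -> candidate discarded
        feat("chr1", "toy", "gene", 2000, 3000, "+", attrs("geneE"))
        feat("chr1", "toy", "transcript", 2200, 3000, "+",
             attrs("geneE", "txE1"))
        feat("chr1", "toy", "exon", 2200, 3000, "+", attrs("geneE", "txE1"))
        feat("chr1", "toy", "CDS", 2200, 2900, "+", attrs("geneE", "txE1"))
        b.append("chr1\t2099\t2100\tapaGuard\t0\t+")

    return "\n".join(g) + "\n", "\n".join(b) + "\n"


# ---------------------------------------------------------------------------
# SAM read fixture


@dataclass
class ReadPlanEntry:
    """One group of identical reads.

    kind: 'interior' (inside one bin), 'junction' (spans two adjacent
    bins), 'spliced' (two blocks skipping everything between two bins),
    'offbin' (overlaps no bin).
    """

    kind: str
    bin_ids: tuple[str, ...]
    count: int = 1


def make_read_fixture(bins, plan: list[ReadPlanEntry]
                      ) -> tuple[str, pd.Series]:
    """SAM text realizing a read plan, plus the analytic expected counts."""
    by_id = dict(zip(bins.bin_ids(), bins))
    chrom_len: dict[str, int] = {}
    for b in bins:
        chrom_len[b.chrom] = max(chrom_len.get(b.chrom, 0), b.end + 1000)
    expected = pd.Series(0, index=pd.Index(bins.bin_ids(), name="bin_id"),
                         dtype=np.int64)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chrom_len):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_len[chrom]}")
    n = 0
    for entry in plan:
        for _ in range(entry.count):
            n += 1
            name = f"r{n:04d}"
            if entry.kind == "interior":
                b = by_id[entry.bin_ids[0]]
                length = min(20, b.width)
                pos = b.start
                cigar = f"{length}M"
                expected[entry.bin_ids[0]] += 1
            elif entry.kind == "junction":
                b1, b2 = (by_id[i] for i in entry.bin_ids[:2])
                if b2.start != b1.end + 1:
                    raise ValidationError(
                        "junction reads need adjacent bins"
                    )
                pos = max(b1.start, b1.end - 9)
                length = (b1.end - pos + 1) + min(10, b2.width)
                cigar = f"{length}M"
                for i in entry.bin_ids[:2]:
                    expected[i] += 1
            elif entry.kind == "spliced":
                b1, b2 = (by_id[i] for i in entry.bin_ids[:2])
                m1 = min(10, b1.width)
                m2 = min(10, b2.width)
                pos = b1.end - m1 + 1
                gap = b2.start - b1.end - 1
                if gap <= 0:
                    raise ValidationError("spliced reads need a gap")
                cigar = f"{m1}M{gap}N{m2}M"
                for i in entry.bin_ids[:2]:
                    expected[i] += 1
            elif entry.kind == "offbin":
                b = by_id[entry.bin_ids[0]]
                pos = b.end + 500
                cigar = "20M"
            else:
                raise ValidationError(f"unknown read kind {entry.kind!r}")
            b0 = by_id[entry.bin_ids[0]]
            flag = 16 if b0.strand == "-" else 0
            seqlen = sum(
                int(x) for x, op in _cigar_ops(cigar) if op in "M=XIS"
            )
            lines.append(
                f"{name}\t{flag}\t{b0.chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t"
                f"{'A' * seqlen}\t*"
            )
    return "\n".join(lines) + "\n", expected


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


# ---------------------------------------------------------------------------
# count-level benchmark simulation


@dataclass
class SimConfig:
    """Design of the count-level differential-UTR benchmark."""

    n_genes: int = 500
    bins_per_gene: tuple[int, int] = (4, 8)
    n_utr_genes: int = 100
    n_de_utr_genes: int = 30  # whole-gene DE among the UTR-change genes
    n_de_other_genes: int = 30  # whole-gene DE among unchanged genes
    fold_range: tuple[float, float] = (1.3, 5.0)
    extension_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    replicates: int = 3
    nb_dispersion: float = 0.1
    # sd of log dispersion across bins: real RNA-seq shows strong
    # bin-to-bin spread of biological variability around the trend
    nb_dispersion_spread: float = 0.5
    mean_log_mu: float = 5.0  # log of per-gene abundance, natural log
    mean_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_utr_genes > self.n_genes:
            raise ValidationError("n_utr_genes exceeds n_genes")
        if self.n_de_utr_genes > self.n_utr_genes:
            raise ValidationError("n_de_utr_genes exceeds n_utr_genes")
        if self.n_de_other_genes > self.n_genes - self.n_utr_genes:
            raise ValidationError("n_de_other_genes exceeds unchanged genes")
        lo, hi = self.fold_range
        if not (1.0 < lo <= hi):
            raise ValidationError("fold_range must lie in (1, inf)")


@dataclass
class TruthTable:
    """Ground truth of a simulated benchmark.

    ``genes`` (per gene): utr_change, direction, fold_change, de_fold,
    n_extension (how many distal segments the long isoform adds),
    affected_bins. ``bins`` (per bin): type, segment role, isoform
    coverage, expected means per condition and the expected usage shift.
    ``isoforms`` holds per-gene isoform abundances per condition so the
    mixture can be recomputed independently.
    """

    genes: pd.DataFrame
    bins: pd.DataFrame
    isoforms: pd.DataFrame


def simulate_utr_counts(cfg: SimConfig) -> tuple[BinCountMatrix, TruthTable]:
    """Simulate a bins x samples count matrix with known UTR changes.

    Every gene carries a short and a long isoform; the long one includes
    1-3 distal 3' UTR segments beyond the short isoform's end (the
    next / second-next / third-next downstream poly(A) site). In
    UTR-change genes the two isoforms receive opposite fold changes
    (x f and /f, f ~ U(fold_range)) between conditions; whole-gene DE
    genes scale both isoforms equally, which shifts no usage. Bin means
    are isoform-abundance-weighted sums times a fixed per-bin coverage
    factor; counts are negative binomial with the configured dispersion.
    """
    rng = np.random.default_rng(cfg.seed)
    lo_b, hi_b = cfg.bins_per_gene

    utr_flags = np.zeros(cfg.n_genes, dtype=bool)
    utr_flags[: cfg.n_utr_genes] = True
    de_folds = np.ones(cfg.n_genes)
    de_idx = np.concatenate([
        np.arange(cfg.n_de_utr_genes),
        cfg.n_utr_genes + np.arange(cfg.n_de_other_genes),
    ])
    lo_f, hi_f = cfg.fold_range
    for i in de_idx:
        f = rng.uniform(lo_f, hi_f)
        de_folds[i] = f if rng.random() < 0.5 else 1.0 / f

    samples = [f"c{c}_r{r + 1}" for c in (1, 2) for r in range(cfg.replicates)]
    conditions = pd.Series(
        ["c1"] * cfg.replicates + ["c2"] * cfg.replicates, index=samples
    )

    gene_rows, bin_rows, iso_rows = [], [], []
    mu_rows = []  # per bin: (mu_c1, mu_c2)
    bin_ids = []
    pos = 1
    for gi in range(cfg.n_genes):
        gene = f"g{gi + 1:04d}"
        n_bins = int(rng.integers(lo_b, hi_b + 1))
        n_distal = min(3, n_bins - 1)
        n_core = n_bins - n_distal - 1  # CDS bins before the proximal UTR
        k_ext = int(rng.choice([1, 2, 3], p=np.asarray(cfg.extension_probs))
                    ) if n_distal == 3 else int(rng.integers(1, n_distal + 1))

        A = float(np.exp(rng.normal(cfg.mean_log_mu, cfg.mean_log_sigma)))
        theta = float(rng.uniform(0.3, 0.7))  # short-isoform share
        a_short, a_long = theta * A, (1 - theta) * A

        is_utr = bool(utr_flags[gi])
        if is_utr:
            f = float(rng.uniform(lo_f, hi_f))
            lengthen = bool(rng.random() < 0.5)
        else:
            f, lengthen = 1.0, False
        d = de_folds[gi]
        # condition-2 abundances: opposite usage folds, common DE fold
        if is_utr:
            if lengthen:
                a_short2, a_long2 = a_short / f, a_long * f
            else:
                a_short2, a_long2 = a_short * f, a_long / f
        else:
            a_short2, a_long2 = a_short, a_long
        a_short2 *= d
        a_long2 *= d

        # widths span orders of magnitude: CDS bins are short, APA-derived
        # UTR bins can reach kilobases
        widths = np.maximum(
            30, np.exp(rng.normal(np.log(300), 1.0, size=n_bins))
        ).astype(np.int64)
        rel = rng.uniform(0.5, 1.5, size=n_bins) * widths / widths.mean()
        affected = []
        for bi in range(n_bins):
            bid = f"{gene}:{bi + 1}"
            if bi < n_core:
                role, btype = "cds", "CDS"
            elif bi == n_core:
                role, btype = "proximal_utr", "3UTR"
            else:
                role, btype = f"distal_{bi - n_core}", "3UTR"
            distal_rank = bi - n_core  # 0 for proximal
            in_short = distal_rank <= 0
            in_long = distal_rank <= k_ext
            cov_short = 1.0 if in_short else 0.0
            cov_long = 1.0 if in_long else 0.0
            mu1 = rel[bi] * (cov_short * a_short + cov_long * a_long)
            mu2 = rel[bi] * (cov_short * a_short2 + cov_long * a_long2)
            if is_utr and in_long and not in_short:
                affected.append(bid)
            bin_ids.append(bid)
            start = pos
            end = pos + int(widths[bi]) - 1
            pos = end + 1
            bin_rows.append(
                (bid, "chrSim", start, end, "+", gene, btype, role,
                 int(widths[bi]), cov_short, cov_long, mu1, mu2,
                 (mu2 / mu1) if mu1 > 0 else np.nan)
            )
            mu_rows.append((mu1, mu2))
        pos += 1000  # intergenic gap
        gene_rows.append(
            (gene, is_utr,
             ("lengthen" if lengthen else "shorten") if is_utr else "none",
             f if is_utr else np.nan, d, k_ext, ",".join(affected))
        )
        iso_rows.append((gene, a_short, a_long, a_short2, a_long2))

    genes_df = pd.DataFrame(
        gene_rows,
        columns=["gene", "utr_change", "direction", "fold_change",
                 "de_fold", "n_extension", "affected_bins"],
    ).set_index("gene")
    bins_df = pd.DataFrame(
        bin_rows,
        columns=["bin_id", "chrom", "start", "end", "strand", "gene",
                 "type", "role", "width", "cov_short", "cov_long",
                 "mu_c1", "mu_c2", "expected_ratio"],
    ).set_index("bin_id")
    iso_df = pd.DataFrame(
        iso_rows,
        columns=["gene", "a_short_c1", "a_long_c1", "a_short_c2", "a_long_c2"],
    ).set_index("gene")

    mu = np.array(mu_rows)  # (n_bins_total, 2)
    n_rep = cfg.replicates
    mu_mat = np.column_stack([mu[:, 0]] * n_rep + [mu[:, 1]] * n_rep)
    phi = cfg.nb_dispersion * np.exp(
        rng.normal(0.0, cfg.nb_dispersion_spread, size=mu.shape[0])
    )
    r = (1.0 / phi)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = r / (r + mu_mat)
    counts = np.where(
        mu_mat > 0, rng.negative_binomial(r, np.where(mu_mat > 0, p, 1.0)), 0
    ).astype(np.int64)
    bins_df["dispersion"] = phi

    counts_df = pd.DataFrame(counts, index=pd.Index(bin_ids, name="bin_id"),
                             columns=samples)
    bin_info = bins_df[["chrom", "start", "end", "strand", "gene", "type",
                        "width"]].copy()
    bcm = BinCountMatrix(
        counts=counts_df,
        bin_info=bin_info,
        lib_sizes=counts_df.sum(axis=0),
        conditions=conditions,
    )
    truth = TruthTable(genes=genes_df, bins=bins_df, isoforms=iso_df)
    return bcm, truth
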