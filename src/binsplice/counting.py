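"""Bin-level read counting.

Every usable alignment is assigned once to every bin it overlaps by at
least one base, so a read spanning a bin junction increments both bins
and column sums may exceed the number of reads. Overlap is evaluated on
aligned blocks (CIGAR M/=/X), so intron-spanning reads do not count bins
inside their skipped region. Paired-end templates are counted once per
bin that either mate overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .bins import BinSet
from .errors import StageError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class BinCountMatrix:
    """Bins x samples integer counts with per-sample library metadata.

    ``bin_info`` carries the bin annotation (coordinates, gene, type,
    width) aligned row-for-row with ``counts``; ``lib_sizes`` is the
    number of usable alignments (templates) per sample, which can differ
    from the column sums because of multi-overlap assignment and off-bin
    reads.
    """

    counts: pd.DataFrame  # index bin_id, columns sample ids
    bin_info: pd.DataFrame  # index bin_id
    lib_sizes: pd.Series
    norm_factors: pd.Series = None
    conditions: pd.Series = None

    def __post_init__(self):
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        if not self.counts.index.equals(self.bin_info.index):
            raise ValidationError("counts and bin_info rows do not match")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.norm_factors

    def subset_bins(self, keep) -> "BinCountMatrix":
        return BinCountMatrix(
            counts=self.counts.loc[keep],
            bin_info=self.bin_info.loc[keep],
            lib_sizes=self.lib_sizes,
            norm_factors=self.norm_factors.copy(),
            conditions=self.conditions,
        )

    def write(self, counts_path: str | Path, libs_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="bin_id")
        meta = pd.DataFrame(
            {
                "lib_size": self.lib_sizes,
                "norm_factor": self.norm_factors,
                "condition": (
                    self.conditions
                    if self.conditions is not None
                    else pd.Series("NA", index=self.counts.columns)
                ),
            }
        )
        meta.to_csv(libs_path, sep="\t", index_label="sample")


def _bin_trees(bins: BinSet):
    trees: dict[str, IntervalTree] = {}
    ids = bins.bin_ids()
    strands = []
    for i, b in enumerate(bins):
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start - 1, b.end, i)
        strands.append(b.strand)
    return trees, ids, strands


def _template_strand(read: pysam.AlignedSegment) -> str:
    """Orientation of the template (fragment): mate-2 flags are flipped."""
    rev = read.is_reverse
    if read.is_paired and read.is_read2:
        rev = not rev
    return "-" if rev else "+"


def count_reads(
    bins: BinSet,
    sam_paths: dict[str, str | Path],
    stranded: str = "none",
    conditions: pd.Series | dict | None = None,
    min_mapq: int = 0,
    drop_duplicates: bool = False,
) -> BinCountMatrix:
    """Count alignments from SAM/BAM files into a BinCountMatrix.

    Parameters
    ----------
    bins
        The prepared BinSet.
    sam_paths
        Mapping sample id -> SAM/BAM path.
    stranded
        ``none`` (ignore strand), ``forward`` (template strand must match
        the bin strand) or ``reverse`` (must be opposite).
    """
    if stranded not in ("none", "forward", "reverse"):
        raise ValidationError(f"unknown stranded mode {stranded!r}")
    trees, bin_ids, strands = _bin_trees(bins)
    n_bins = len(bin_ids)
    mats = {}
    lib_sizes = {}
    for sample, path in sam_paths.items():
        vec = np.zeros(n_bins, dtype=np.int64)
        usable = 0
        any_chrom_match = False
        pair_hits: dict[str, set[int]] = {}
        pair_seen: set[str] = set()
        with pysam.AlignmentFile(str(path)) as af:
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                if drop_duplicates and read.is_duplicate:
                    continue
                chrom = read.reference_name
                if chrom in trees:
                    any_chrom_match = True
                if read.is_paired:
                    if read.query_name not in pair_seen:
                        pair_seen.add(read.query_name)
                        usable += 1
                else:
                    usable += 1
                tree = trees.get(chrom)
                if tree is None:
                    continue
                hits: set[int] = set()
                for bs, be in read.get_blocks():
                    for iv in tree.overlap(bs, be):
                        hits.add(iv.data)
                if stranded != "none":
                    ts = _template_strand(read)
                    want = ts if stranded == "forward" else ("-" if ts == "+" else "+")
                    hits = {i for i in hits if strands[i] == want}
                if read.is_paired:
                    pair_hits.setdefault(read.query_name, set()).update(hits)
                else:
                    for i in hits:
                        vec[i] += 1
        for hit_set in pair_hits.values():
            for i in hit_set:
                vec[i] += 1
        if usable > 0 and not any_chrom_match:
            raise StageError(
                f"no alignment in {path} maps to an annotated chromosome; "
                "check chromosome naming (a rename map may be needed)"
            )
        mats[sample] = vec
        lib_sizes[sample] = usable

    counts = pd.DataFrame(mats, index=pd.Index(bin_ids, name="bin_id"))
    bin_info = bins.to_dataframe().set_index("bin_id")
    cond = pd.Series(conditions) if conditions is not None else None
    return BinCountMatrix(
        counts=counts,
        bin_info=bin_info,
        lib_sizes=pd.Series(lib_sizes, dtype=np.int64),
        conditions=cond,
    )


def read_count_matrix(
    counts_path: str | Path,
    bins: BinSet | None = None,
    bin_info: pd.DataFrame | None = None,
    libs_path: str | Path | None = None,
    conditions: pd.Series | dict | None = None,
) -> BinCountMatrix:
    """Load a precomputed bins x samples counts TSV.

    The first column must hold bin ids. When a BinSet (or bin_info table)
    is given, every row must match one of its bins; otherwise a minimal
    bin_info is derived from the ids. Library sizes default to column sums
    unless a library TSV (sample, lib_size, norm_factor, condition) is
    provided.
    """
    df = pd.read_csv(counts_path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    df.index.name = "bin_id"
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValidationError("non-numeric counts in matrix")
    if not np.allclose(vals, np.round(vals)):
        raise ValidationError("non-integer counts in matrix")
    if (vals < 0).any():
        raise ValidationError("negative counts in matrix")
    df = df.astype(np.int64)

    if bins is not None:
        bin_info = bins.to_dataframe().set_index("bin_id")
    if bin_info is not None:
        missing = df.index.difference(bin_info.index)
        if len(missing):
            raise ValidationError(
                f"counts contain bins absent from the bin set: "
                f"{list(missing[:5])}"
            )
        bin_info = bin_info.loc[df.index]
    else:
        genes = [bid.rsplit(":", 1)[0] for bid in df.index]
        bin_info = pd.DataFrame({"gene": genes}, index=df.index)

    lib_sizes = df.sum(axis=0)
    norm = None
    if libs_path is not None:
        meta = pd.read_csv(libs_path, sep="\t", index_col=0)
        missing = [s for s in df.columns if s not in meta.index]
        if missing:
            raise ValidationError(
                f"library table is missing samples: {missing}"
            )
        meta = meta.loc[df.columns]
        lib_sizes = meta["lib_size"]
        if "norm_factor" in meta:
            norm = meta["norm_factor"]
        if conditions is None and "condition" in meta:
            conditions = meta["condition"]
    if conditions is not None:
        conditions = pd.Series(conditions)
        missing = [s for s in df.columns if s not in conditions.index]
        if missing:
            raise ValidationError(f"no condition label for samples: {missing}")
        conditions = conditions.loc[df.columns]
    return BinCountMatrix(
        counts=df,
        bin_info=bin_info,
        lib_sizes=pd.Series(lib_sizes),
        norm_factors=norm,
        conditions=conditions,
    )
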