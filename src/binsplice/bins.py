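"""Disjoint counting bins from a gene annotation.

The exon annotation is fragmented into the widest genomic ranges over
which the set of overlapping exon features is constant, each fragment
carrying the transcripts whose exons cover it. Bins are then labeled
CDS / UTR / 3UTR / non-coding, and poly(A) sites can be used to further
segment existing UTR bins and to extend genes with new 3' UTR bins up to
each site.

Coordinates are 1-based inclusive throughout (GTF convention); BED input
and output are converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .annotation import AnnotationModel
from .errors import ValidationError

log = logging.getLogger(__name__)

BIN_TYPES = ("CDS", "UTR", "3UTR", "non-coding")


@dataclass(frozen=True)
class GenomicBin:
    """A disjoint annotation fragment assigned to one gene."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    gene: str
    transcripts: frozenset[str]
    type: str = "CDS"
    gene_ambiguous: bool = False
    apa_derived: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(
                f"empty bin {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class ApaSiteSet:
    """Single-base poly(A) sites (1-based position, stranded)."""

    sites: list[tuple[str, int, str]]  # (chrom, pos, strand)

    def __post_init__(self):
        for chrom, pos, strand in self.sites:
            if pos <= 0:
                raise ValidationError(f"APA site position must be >= 1: {pos}")
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"APA site {chrom}:{pos} has invalid strand {strand!r}"
                )

    @classmethod
    def from_bed(cls, path: str | Path) -> "ApaSiteSet":
        """Read BED3/BED6 poly(A) sites (0-based half-open converted here).

        Multi-base BED intervals are reduced to their strand-aware 3' base,
        matching the single-base cleavage-site semantics.
        """
        sites = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValidationError(f"BED line with <3 fields: {line!r}")
                chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
                strand = fields[5] if len(fields) >= 6 else "+"
                pos = end if strand == "+" else start0 + 1
                sites.append((chrom, pos, strand))
        return cls(sites=sites)


@dataclass
class BinSet:
    """Ordered collection of bins plus the parameters that built it."""

    bins: list[GenomicBin]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sort()

    def sort(self) -> None:
        self.bins.sort(key=lambda b: (b.chrom, b.start, b.end, b.gene))

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def bin_ids(self) -> list[str]:
        """Stable per-gene ids gene:index, in coordinate order within gene."""
        counters: dict[str, int] = {}
        ids = []
        for b in self.bins:
            counters[b.gene] = counters.get(b.gene, 0) + 1
            ids.append(f"{b.gene}:{counters[b.gene]}")
        return ids

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_id": self.bin_ids(),
                "chrom": [b.chrom for b in self.bins],
                "start": [b.start for b in self.bins],
                "end": [b.end for b in self.bins],
                "strand": [b.strand for b in self.bins],
                "gene": [b.gene for b in self.bins],
                "transcripts": [",".join(sorted(b.transcripts)) for b in self.bins],
                "type": [b.type for b in self.bins],
                "gene_ambiguous": [b.gene_ambiguous for b in self.bins],
                "apa_derived": [b.apa_derived for b in self.bins],
                "width": [b.width for b in self.bins],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        """Portable serialization; re-read with :meth:`read_tsv`."""
        with open(path, "w") as fh:
            fh.write("# binsplice bins v1; coordinates 1-based inclusive\n")
            for key, val in sorted(self.params.items()):
                fh.write(f"# param {key}={val}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BinSet":
        params: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            for line in iter(fh.readline, ""):
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                if line.startswith("# param "):
                    key, _, val = line[len("# param "):].strip().partition("=")
                    params[key] = val
                pos = fh.tell()
            df = pd.read_csv(fh, sep="\t")
        bins = [
            GenomicBin(
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                gene=str(r.gene),
                transcripts=frozenset(
                    str(r.transcripts).split(",") if pd.notna(r.transcripts) else []
                ),
                type=r.type,
                gene_ambiguous=bool(r.gene_ambiguous),
                apa_derived=bool(r.apa_derived),
            )
            for r in df.itertuples()
        ]
        return cls(bins=bins, params=params)

    def write_bed(self, path: str | Path) -> None:
        """BED-like TSV (0-based half-open starts, as BED requires)."""
        with open(path, "w") as fh:
            fh.write(
                "# binsplice bins (BED-like, 0-based half-open): chrom, start, "
                "end, name=gene:binIndex, score=width, strand, type, "
                "geneAmbiguous, apaDerived\n"
            )
            for b, bid in zip(self.bins, self.bin_ids()):
                fh.write(
                    f"{b.chrom}\t{b.start - 1}\t{b.end}\t{bid}\t{b.width}\t"
                    f"{b.strand}\t{b.type}\t{int(b.gene_ambiguous)}\t"
                    f"{int(b.apa_derived)}\n"
                )


def _sweep(exons: list[tuple[int, int, str, str]],
           breakpoints: list[int] = ()):
    """Yield (start, end, active) elementary intervals of an exon set.

    ``exons`` are (start, end, gene_id, transcript_id); ``active`` is the
    set of (gene_id, transcript_id) exon features covering the interval.
    Intervals are split at every exon boundary and at every extra
    breakpoint, so each yielded range has a constant feature set.
    """
    events: dict[int, list[tuple[int, tuple]]] = {}
    for s, e, g, t in exons:
        events.setdefault(s, []).append((1, (g, t, s, e)))
        events.setdefault(e + 1, []).append((-1, (g, t, s, e)))
    for pos in breakpoints:
        events.setdefault(pos, [])
    active: dict[tuple, int] = {}
    prev = None
    for pos in sorted(events):
        if prev is not None and active:
            yield prev, pos - 1, {(g, t) for (g, t, _, _) in active}
        for delta, key in events[pos]:
            active[key] = active.get(key, 0) + delta
            if active[key] == 0:
                del active[key]
        prev = pos


def flatten_exons(ann: AnnotationModel, genewise: bool = False) -> BinSet:
    """Flatten exons into disjoint bins.

    With ``genewise=False`` (default) exons of all genes on a chromosome
    strand are flattened together; a fragment covered by exons of several
    genes is emitted once per gene with ``gene_ambiguous=True``, carrying
    only that gene's transcripts. With ``genewise=True`` each gene is
    flattened independently, so bins of different genes may overlap.
    """
    groups: dict[tuple, list[tuple[int, int, str, str]]] = {}
    breaks: dict[tuple, list[int]] = {}
    for tx in ann.transcripts.values():
        key = (
            (tx.chrom, tx.strand, tx.gene_id)
            if genewise
            else (tx.chrom, tx.strand)
        )
        for s, e in tx.exons:
            groups.setdefault(key, []).append((s, e, tx.gene_id, tx.id))
        # CDS edges split exons so coding and UTR parts become separate
        # bins even in single-isoform genes
        for s, e in tx.cds:
            breaks.setdefault(key, []).extend((s, e + 1))

    bins: list[GenomicBin] = []
    for key in sorted(groups):
        chrom, strand = key[0], key[1]
        for start, end, active in _sweep(groups[key], breaks.get(key, [])):
            by_gene: dict[str, set[str]] = {}
            for g, t in active:
                by_gene.setdefault(g, set()).add(t)
            ambiguous = len(by_gene) > 1
            for g, txs in by_gene.items():
                bins.append(
                    GenomicBin(
                        chrom=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        gene=g,
                        transcripts=frozenset(txs),
                        gene_ambiguous=ambiguous,
                    )
                )
    return BinSet(bins=bins, params={"genewise": genewise})


def _last_cds_boundary(tx) -> int | None:
    """Strand-aware 3'-most CDS edge of a transcript (None if no CDS)."""
    if not tx.cds:
        return None
    if tx.strand == "+":
        return max(e for _, e in tx.cds)
    return min(s for s, _ in tx.cds)


def label_bins(bins: BinSet, ann: AnnotationModel) -> BinSet:
    """Assign CDS / UTR / 3UTR / non-coding labels.

    A bin overlapping any CDS interval of its gene is CDS. A non-CDS bin
    with at least one protein-coding transcript among those covering it is
    UTR, refined to 3UTR when it lies strand-aware downstream of the last
    CDS of one of its coding transcripts. Bins covered by no protein-coding
    transcript are non-coding. UTR bins of transcripts that are coding by
    biotype only (no CDS records) keep the generic UTR label, since 5' and
    3' cannot be told apart without a CDS anchor.
    """
    cds_by_gene: dict[str, list[tuple[int, int]]] = {}
    for tx in ann.transcripts.values():
        cds_by_gene.setdefault(tx.gene_id, []).extend(tx.cds)

    labeled = []
    for b in bins:
        overlaps_cds = any(
            s <= b.end and e >= b.start for s, e in cds_by_gene.get(b.gene, [])
        )
        if overlaps_cds:
            btype = "CDS"
        else:
            coding_txs = [
                ann.transcripts[t] for t in b.transcripts
                if t in ann.transcripts and ann.transcripts[t].is_coding
            ]
            if not coding_txs:
                btype = "non-coding"
            else:
                btype = "UTR"
                for tx in coding_txs:
                    bd = _last_cds_boundary(tx)
                    if bd is None:
                        continue
                    downstream = (
                        b.start > bd if tx.strand == "+" else b.end < bd
                    )
                    if downstream:
                        btype = "3UTR"
                        break
        labeled.append(replace(b, type=btype))
    return BinSet(bins=labeled, params=dict(bins.params))


def apply_apa_sites(
    bins: BinSet,
    apa: ApaSiteSet,
    ann: AnnotationModel,
    max_utr_bin_size: int = 15_000,
) -> BinSet:
    """Segment and extend 3' UTR bins with poly(A) sites.

    For every site (matched by chromosome and strand) the nearest
    strand-aware upstream CDS or UTR bin boundary is located and a new
    3' UTR bin is created from that boundary (exclusive) to the site
    (inclusive), inheriting the boundary bin's gene and transcripts.
    The candidate is discarded when it would exceed ``max_utr_bin_size``,
    when a gene start is the closest upstream feature before any CDS/UTR
    (to avoid ambiguous assignment), or when it would overlap an existing
    bin of the same gene. A site inside an existing UTR/3UTR bin splits
    that bin at the site; sites inside CDS or non-coding bins are ignored.
    Sites are processed 5'→3' per strand so that successive downstream
    sites chain off previously created bins.
    """
    for b in bins:
        if b.strand not in ("+", "-"):
            raise ValidationError(
                "annotation is unstranded; upstream/downstream is undefined "
                "for APA processing"
            )
    known_chroms = {b.chrom for b in bins} | ann.chroms()
    work: dict[tuple[str, str], list[GenomicBin]] = {}
    for b in bins:
        work.setdefault((b.chrom, b.strand), []).append(b)
    gene_starts: dict[tuple[str, str], list[int]] = {}
    for g in ann.genes.values():
        gene_starts.setdefault((g.chrom, g.strand), []).append(g.tss)

    by_group: dict[tuple[str, str], list[int]] = {}
    for chrom, pos, strand in apa.sites:
        if chrom not in known_chroms:
            log.warning("APA site %s:%d not on an annotated chromosome; skipped",
                        chrom, pos)
            continue
        by_group.setdefault((chrom, strand), []).append(pos)

    for (chrom, strand), positions in sorted(by_group.items()):
        blist = work.setdefault((chrom, strand), [])
        positions.sort(reverse=(strand == "-"))
        for pos in positions:
            inside = [b for b in blist if b.start <= pos <= b.end]
            if inside:
                for b in inside:
                    if b.type not in ("UTR", "3UTR"):
                        continue  # only UTR context is segmented
                    three_prime_edge = b.end if strand == "+" else b.start
                    if pos == three_prime_edge:
                        continue  # site on an existing edge: no-op
                    blist.remove(b)
                    if strand == "+":
                        pieces = [(b.start, pos), (pos + 1, b.end)]
                    else:
                        pieces = [(pos, b.end), (b.start, pos - 1)]
                    for s, e in pieces:
                        blist.append(
                            replace(b, start=s, end=e, apa_derived=True)
                        )
                continue
            # extension: nearest strand-aware upstream CDS/UTR boundary
            if strand == "+":
                cands = [b for b in blist
                         if b.type != "non-coding" and b.end < pos]
                if not cands:
                    continue
                anchor = max(cands, key=lambda b: b.end)
                boundary = anchor.end
                width = pos - boundary
                guarded = any(
                    boundary < q <= pos
                    for q in gene_starts.get((chrom, strand), [])
                )
                new = (boundary + 1, pos)
            else:
                cands = [b for b in blist
                         if b.type != "non-coding" and b.start > pos]
                if not cands:
                    continue
                anchor = min(cands, key=lambda b: b.start)
                boundary = anchor.start
                width = boundary - pos
                guarded = any(
                    pos <= q < boundary
                    for q in gene_starts.get((chrom, strand), [])
                )
                new = (pos, boundary - 1)
            if guarded:
                log.info("APA site %s:%d: gene start upstream; ignored",
                         chrom, pos)
                continue
            if width > max_utr_bin_size:
                log.info("APA site %s:%d: candidate UTR of %d bp exceeds "
                         "max_utr_bin_size; ignored", chrom, pos, width)
                continue
            same_gene_overlap = any(
                b.gene == anchor.gene and b.start <= new[1] and b.end >= new[0]
                for b in blist
            )
            if same_gene_overlap:
                log.info("APA site %s:%d: candidate UTR overlaps an existing "
                         "bin of gene %s; ignored", chrom, pos, anchor.gene)
                continue
            blist.append(
                GenomicBin(
                    chrom=chrom,
                    start=new[0],
                    end=new[1],
                    strand=strand,
                    gene=anchor.gene,
                    transcripts=anchor.transcripts,
                    type="3UTR",
                    gene_ambiguous=anchor.gene_ambiguous,
                    apa_derived=True,
                )
            )

    out = [b for blist in work.values() for b in blist]
    params = dict(bins.params)
    params["max_utr_bin_size"] = max_utr_bin_size
    return BinSet(bins=out, params=params)


def build_bins(
    ann: AnnotationModel,
    apa: ApaSiteSet | None = None,
    max_utr_bin_size: int = 15_000,
    genewise: bool = False,
) -> BinSet:
    """Full bin preparation: flatten, label, and (optionally) apply APA sites."""
    bins = label_bins(flatten_exons(ann, genewise=genewise), ann)
    if apa is not None:
        bins = apply_apa_sites(bins, apa, ann, max_utr_bin_size=max_utr_bin_size)
    return bins
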