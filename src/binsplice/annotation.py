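"""Gene annotation input.

Reads GTF or GFF3 into a light in-memory gene/transcript/exon model with
1-based inclusive coordinates (the GTF convention, kept internally
throughout the package). Parsing of the two attribute dialects is
delegated to :mod:`gffutils`.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .errors import ValidationError

log = logging.getLogger(__name__)

Interval = tuple[int, int]  # 1-based inclusive (start, end)

_CODING_BIOTYPES = {"protein_coding"}


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    biotype: str | None = None
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    @property
    def is_coding(self) -> bool:
        """Protein-coding if it has CDS records or a protein_coding biotype.

        GTF dialects differ in which of the two they provide, so either
        marker suffices.
        """
        return bool(self.cds) or (self.biotype in _CODING_BIOTYPES)

    @property
    def span(self) -> Interval:
        start = min(s for s, _ in self.exons)
        end = max(e for _, e in self.exons)
        return start, end


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str | None = None
    transcript_ids: list[str] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Strand-aware gene start (5' end)."""
        return self.start if self.strand == "+" else self.end


@dataclass
class AnnotationModel:
    """Validated gene/transcript/exon/CDS hierarchy.

    Invariants: every exon and CDS interval belongs to exactly one
    transcript, every transcript to exactly one gene, and CDS intervals
    lie within their transcript's exons.
    """

    genes: dict[str, Gene]
    transcripts: dict[str, Transcript]

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [self.transcripts[t] for t in self.genes[gene_id].transcript_ids]

    def chroms(self) -> set[str]:
        return {g.chrom for g in self.genes.values()}

    def validate(self) -> None:
        for tx in self.transcripts.values():
            if tx.gene_id not in self.genes:
                raise ValidationError(
                    f"transcript {tx.id} references unknown gene {tx.gene_id}"
                )
            if not tx.exons:
                raise ValidationError(f"transcript {tx.id} has no exons")
            exs = sorted(tx.exons)
            for cs, ce in tx.cds:
                if not any(s <= cs and ce <= e for s, e in exs):
                    raise ValidationError(
                        f"CDS ({cs}-{ce}) of transcript {tx.id} is not "
                        "contained in its exons"
                    )
            gene = self.genes[tx.gene_id]
            s, e = tx.span
            if s < gene.start or e > gene.end:
                raise ValidationError(
                    f"exons of transcript {tx.id} ({s}-{e}) fall outside the "
                    f"span of gene {gene.id} ({gene.start}-{gene.end})"
                )


def _first_attr(feature, *names: str) -> str | None:
    for name in names:
        val = feature.attributes.get(name)
        if val:
            return val[0]
    return None


def _strip_prefix(value: str) -> str:
    # Ensembl GFF3 uses "gene:ENSG...", "transcript:ENST..." ID/Parent values
    return value.split(":", 1)[1] if ":" in value else value


def read_annotation(path: str | Path) -> AnnotationModel:
    """Read a GTF or GFF3 file (optionally gzipped) into an AnnotationModel.

    Transcripts lacking CDS records and a coding biotype are treated as
    non-coding. Raises :class:`ValidationError` for exons referencing
    unknown transcripts/genes (when the file declares them) or falling
    outside their gene's span, and for malformed attribute blocks.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"annotation file not found: {path}")
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises various parse errors
        raise ValidationError(f"failed to parse {path}: {exc}") from exc

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    declared_tx: set[str] = set()
    declared_genes: set[str] = set()

    for f in db.all_features():
        ftype = f.featuretype.lower()
        if ftype == "gene":
            gid = _first_attr(f, "gene_id", "ID")
            if gid is None:
                raise ValidationError(f"gene feature without gene_id at line: {f}")
            gid = _strip_prefix(gid)
            declared_genes.add(gid)
            genes[gid] = Gene(
                id=gid,
                chrom=f.seqid,
                strand=f.strand,
                start=f.start,
                end=f.end,
                biotype=_first_attr(f, "gene_biotype", "gene_type", "biotype"),
            )
        elif ftype in ("transcript", "mrna"):
            tid = _first_attr(f, "transcript_id", "ID")
            gid = _first_attr(f, "gene_id", "Parent")
            if tid is None or gid is None:
                raise ValidationError(
                    f"transcript feature missing transcript_id/gene_id: {f}"
                )
            tid, gid = _strip_prefix(tid), _strip_prefix(gid)
            declared_tx.add(tid)
            transcripts[tid] = Transcript(
                id=tid,
                gene_id=gid,
                chrom=f.seqid,
                strand=f.strand,
                biotype=_first_attr(
                    f, "transcript_biotype", "transcript_type", "biotype"
                ),
            )

    for ftype in ("exon", "CDS"):
        for f in db.features_of_type(ftype):
            tid = _first_attr(f, "transcript_id", "Parent")
            if tid is None:
                raise ValidationError(
                    f"{ftype} feature without transcript_id/Parent: {f}"
                )
            tid = _strip_prefix(tid)
            if tid not in transcripts:
                if declared_tx:
                    raise ValidationError(
                        f"{ftype} references unknown transcript {tid}"
                    )
                gid = _first_attr(f, "gene_id")
                if gid is None:
                    raise ValidationError(
                        f"{ftype} without transcript context: {f}"
                    )
                transcripts[tid] = Transcript(
                    id=tid,
                    gene_id=_strip_prefix(gid),
                    chrom=f.seqid,
                    strand=f.strand,
                )
            tx = transcripts[tid]
            interval = (f.start, f.end)
            if ftype == "exon":
                tx.exons.append(interval)
            else:
                tx.cds.append(interval)

    # genes not declared with an explicit feature: infer from transcripts
    for tx in transcripts.values():
        if tx.gene_id not in genes:
            if declared_genes:
                raise ValidationError(
                    f"transcript {tx.id} references unknown gene {tx.gene_id}"
                )
            if not tx.exons:
                raise ValidationError(f"transcript {tx.id} has no exons")
            genes[tx.gene_id] = Gene(
                id=tx.gene_id,
                chrom=tx.chrom,
                strand=tx.strand,
                start=tx.span[0],
                end=tx.span[1],
            )
        elif tx.gene_id not in declared_genes and tx.exons:
            # inferred gene records grow with their transcripts; declared
            # spans are authoritative and validated against
            g = genes[tx.gene_id]
            g.start = min(g.start, tx.span[0])
            g.end = max(g.end, tx.span[1])

    for tx in transcripts.values():
        tx.exons.sort()
        tx.cds.sort()
        genes[tx.gene_id].transcript_ids.append(tx.id)

    model = AnnotationModel(genes=genes, transcripts=transcripts)
    model.validate()
    return model
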