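"""GFF3 reading, writing and decoration for coding-gene annotations.

The in-memory model is a three-level hierarchy (gene -> transcript ->
CDS segment) bound to named contigs, with 1-based inclusive coordinates
exactly as GFF3 specifies.  "Exon" throughout this package means a CDS
segment: the annotations being curated are coding-only gene predictions,
and every per-gene statistic (mono/multi-exonic status, exon counts,
longest isoform) is defined over CDS segments.  ``exon`` features in
input files, if present, are ignored with a warning.

Decoration is kept separate from the annotation itself: product names
attach to mRNA lines, curation notes and horizontal-transfer tags attach
to the CDS lines of the affected genes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: GFF3 column-9 reserved characters that must be percent-encoded.
_ESCAPES = {
    "%": "%25",  # must be listed; str.translate applies all at once
    ";": "%3B",
    "=": "%3D",
    ",": "%2C",
    "&": "%26",
    "\t": "%09",
    "\n": "%0A",
}
_ESCAPE_TABLE = str.maketrans(_ESCAPES)


class Gff3Error(ValueError):
    """Raised for structurally invalid GFF3 input or decoration."""


@dataclass(frozen=True)
class CdsSegment:
    """One CDS feature line: a coding segment of a transcript."""

    start: int
    end: int
    strand: str
    phase: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise Gff3Error(f"CDS segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    id: str
    gene_id: str
    cds_segments: list[CdsSegment] = field(default_factory=list)

    @property
    def coding_length(self) -> int:
        return sum(seg.length for seg in self.cds_segments)

    @property
    def start(self) -> int:
        return min(seg.start for seg in self.cds_segments)

    @property
    def end(self) -> int:
        return max(seg.end for seg in self.cds_segments)


@dataclass
class Gene:
    id: str
    contig: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    """All gene models of one species, plus the contigs that carry them."""

    species: str
    genes: dict[str, Gene] = field(default_factory=dict)
    contigs: set[str] = field(default_factory=set)

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self.genes.values():
            yield from gene.transcripts

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def transcript_to_gene(self) -> dict[str, str]:
        return {tx.id: g.id for g in self.genes.values() for tx in g.transcripts}


@dataclass
class Decoration:
    """What to add to a GFF3 on top of the bare gene models.

    transcript_products
        product name per transcript, emitted as ``product=`` on mRNA lines.
    cds_notes
        free-text note per gene, emitted as ``Note=`` on every CDS line.
    hgt_tags
        genes whose CDS lines receive ``hgt_candidate=true``.
    """

    transcript_products: dict[str, str] = field(default_factory=dict)
    cds_notes: dict[str, str] = field(default_factory=dict)
    hgt_tags: set[str] = field(default_factory=set)

    def validate(self, annotation: GenomeAnnotation) -> None:
        tx_ids = {tx.id for tx in annotation.transcripts()}
        for tx_id in self.transcript_products:
            if tx_id not in tx_ids:
                raise Gff3Error(f"decoration references unknown transcript {tx_id!r}")
        for gene_id in list(self.cds_notes) + list(self.hgt_tags):
            if gene_id not in annotation.genes:
                raise Gff3Error(f"decoration references unknown gene {gene_id!r}")


def escape_attr(value: str) -> str:
    """Percent-encode the GFF3 column-9 reserved characters."""
    return value.translate(_ESCAPE_TABLE)


def parse_gff3(stream: Iterable[str] | TextIO, species: str = "") -> GenomeAnnotation:
    """Parse gene/mRNA/CDS features into a :class:`GenomeAnnotation`.

    Unknown feature types are skipped with a logged warning.  A CDS whose
    Parent cannot be resolved to an mRNA, or a feature with start > end,
    is a hard error naming the offending line.
    """
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    contigs: set[str] = set()
    # CDS lines may precede their mRNA in nonstandard files; buffer them.
    pending_cds: list[tuple[int, str, str, CdsSegment]] = []
    warned_types: set[str] = set()

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise Gff3Error(f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}")
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types on bad lines
            raise Gff3Error(f"line {lineno}: {exc}") from exc
        if feat.start is None or feat.end is None:
            raise Gff3Error(f"line {lineno}: missing coordinates")
        if feat.start > feat.end:
            raise Gff3Error(f"line {lineno}: start {feat.start} > end {feat.end}")
        ftype = feat.featuretype
        if ftype == "gene":
            gene_id = _required_attr(feat, "ID", lineno)
            if gene_id in genes:
                raise Gff3Error(f"line {lineno}: duplicate gene id {gene_id!r}")
            genes[gene_id] = Gene(
                id=gene_id, contig=feat.seqid, strand=feat.strand,
                start=feat.start, end=feat.end,
            )
            contigs.add(feat.seqid)
        elif ftype in ("mRNA", "transcript"):
            tx_id = _required_attr(feat, "ID", lineno)
            parent = _required_attr(feat, "Parent", lineno)
            if tx_id in transcripts:
                raise Gff3Error(f"line {lineno}: duplicate transcript id {tx_id!r}")
            transcripts[tx_id] = Transcript(id=tx_id, gene_id=parent)
        elif ftype == "CDS":
            parent = _required_attr(feat, "Parent", lineno)
            seg = CdsSegment(start=feat.start, end=feat.end,
                             strand=feat.strand, phase=feat.frame)
            pending_cds.append((lineno, parent, feat.seqid, seg))
        else:
            if ftype not in warned_types:
                logger.warning("ignoring feature type %r (first seen at line %d)", ftype, lineno)
                warned_types.add(ftype)

    for lineno, parent, seqid, seg in pending_cds:
        tx = transcripts.get(parent)
        if tx is None:
            raise Gff3Error(f"line {lineno}: CDS Parent {parent!r} does not resolve to an mRNA")
        tx.cds_segments.append(seg)
        contigs.add(seqid)

    for tx in transcripts.values():
        gene = genes.get(tx.gene_id)
        if gene is None:
            raise Gff3Error(f"mRNA {tx.id!r} has unknown Parent gene {tx.gene_id!r}")
        if not tx.cds_segments:
            raise Gff3Error(f"mRNA {tx.id!r} has no CDS segments")
        tx.cds_segments.sort(key=lambda s: s.start)
        gene.transcripts.append(tx)
    for gene in genes.values():
        if not gene.transcripts:
            raise Gff3Error(f"gene {gene.id!r} has no transcripts")
        gene.transcripts.sort(key=lambda t: t.id)
    return GenomeAnnotation(species=species, genes=genes, contigs=contigs)


def _required_attr(feat, key: str, lineno: int) -> str:
    values = feat.attributes.get(key, [])
    if not values:
        raise Gff3Error(f"line {lineno}: {feat.featuretype} feature lacks {key} attribute")
    return values[0]


def write_gff3(annotation: GenomeAnnotation, decoration: Decoration | None = None,
               source: str = "curanno") -> list[str]:
    """Render an annotation (plus optional decoration) as GFF3 lines.

    Feature order is deterministic: contigs lexicographically, genes by
    (start, end, id) within a contig, transcripts by id within a gene.
    Attributes are emitted in the fixed order ID, Parent, product, Note,
    hgt_candidate so output is byte-stable.
    """
    decoration = decoration or Decoration()
    decoration.validate(annotation)
    lines = ["##gff-version 3"]
    by_contig: dict[str, list[Gene]] = {}
    for gene in annotation.genes.values():
        by_contig.setdefault(gene.contig, []).append(gene)
    for contig in sorted(by_contig):
        for gene in sorted(by_contig[contig], key=lambda g: (g.start, g.end, g.id)):
            note = decoration.cds_notes.get(gene.id)
            tagged = gene.id in decoration.hgt_tags
            lines.append(_feature_line(contig, source, "gene", gene.start, gene.end,
                                       gene.strand, ".", [("ID", gene.id)]))
            for tx in sorted(gene.transcripts, key=lambda t: t.id):
                attrs = [("ID", tx.id), ("Parent", gene.id)]
                product = decoration.transcript_products.get(tx.id)
                if product is not None:
                    attrs.append(("product", product))
                lines.append(_feature_line(contig, source, "mRNA", tx.start, tx.end,
                                           gene.strand, ".", attrs))
                for seg in tx.cds_segments:
                    cds_attrs: list[tuple[str, str]] = [
                        ("ID", f"{tx.id}.cds"), ("Parent", tx.id)]
                    if note is not None:
                        cds_attrs.append(("Note", note))
                    if tagged:
                        cds_attrs.append(("hgt_candidate", "true"))
                    lines.append(_feature_line(contig, source, "CDS", seg.start, seg.end,
                                               seg.strand, seg.phase, cds_attrs))
    return lines


def _feature_line(seqid: str, source: str, ftype: str, start: int, end: int,
                  strand: str, phase: str, attrs: list[tuple[str, str]]) -> str:
    attr_str = ";".join(f"{k}={escape_attr(v)}" for k, v in attrs)
    return "\t".join([seqid, source, ftype, str(start), str(end), ".", strand, phase, attr_str])


def write_gff3_file(path, annotation: GenomeAnnotation,
                    decoration: Decoration | None = None) -> None:
    with open(path, "w") as fh:
        for line in write_gff3(annotation, decoration):
            fh.write(line + "\n")


def parse_gff3_file(path, species: str = "") -> GenomeAnnotation:
    with open(path) as fh:
        return parse_gff3(fh, species=species)


def parse_gff3_text(text: str, species: str = "") -> GenomeAnnotation:
    return parse_gff3(io.StringIO(text), species=species)


def longest_isoform(gene: Gene) -> Transcript:
    """The gene's representative transcript: greatest total coding length,
    ties broken by lexicographically smallest transcript id."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.id!r} has no transcripts")
    return min(gene.transcripts, key=lambda t: (-t.coding_length, t.id))


def exon_count(transcript: Transcript) -> int:
    """Number of CDS segments of the transcript."""
    return len(transcript.cds_segments)


def gene_order(annotation: GenomeAnnotation, contig: str) -> list[Gene]:
    """Genes on a contig in coordinate order (start, then end, then id).

    Strand is ignored: neighbourhood for the genomic-context filter is
    purely positional.
    """
    if contig not in annotation.contigs:
        raise KeyError(f"unknown contig {contig!r}")
    genes = [g for g in annotation.genes.values() if g.contig == contig]
    return sorted(genes, key=lambda g: (g.start, g.end, g.id))


def decoration_report(annotation: GenomeAnnotation, decoration: Decoration) -> list[str]:
    """TSV report of every decoration applied: gene_id, contig,
    decoration_kind, value."""
    tx2gene = annotation.transcript_to_gene()
    rows = [("gene_id", "contig", "decoration_kind", "value")]
    for tx_id in sorted(decoration.transcript_products):
        gene = annotation.genes[tx2gene[tx_id]]
        rows.append((gene.id, gene.contig, "product", decoration.transcript_products[tx_id]))
    for gene_id in sorted(decoration.cds_notes):
        gene = annotation.genes[gene_id]
        rows.append((gene.id, gene.contig, "contaminant_note", decoration.cds_notes[gene_id]))
    for gene_id in sorted(decoration.hgt_tags):
        gene = annotation.genes[gene_id]
        rows.append((gene.id, gene.contig, "hgt_tag", "true"))
    return ["\t".join(r) for r in rows]
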