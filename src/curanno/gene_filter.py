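"""Removal of likely false-positive single-exon gene models.

Automated gene predictors overcall single-exon genes.  A gene is
discarded only when it is single-exon (every isoform has exactly one CDS
segment) AND all three independent evidence channels are empty:

* no functional annotation on any isoform (no product name, no
  similarity hit, no gene-family assignment);
* no significant hit for its representative protein against the NR
  database (defaults: e-value <= 1e-5, coverage >= 50% on both sides,
  mirroring the HGT alignment gate);
* not a member of an orthogroup spanning more than one species.

Any single evidence channel rescues the gene; multi-exon genes are never
touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .evidence_io import AlignmentHit, FunctionalRecord, OrthogroupTable
from .gff_io import Gene, GenomeAnnotation, exon_count, longest_isoform
from .hgt import HgtConfig, hit_passes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    nr_max_evalue: float = 1e-5
    nr_min_query_cov: float = 0.5
    nr_min_subject_cov: float = 0.5

    def as_hit_gate(self) -> HgtConfig:
        return HgtConfig(min_query_cov=self.nr_min_query_cov,
                         min_subject_cov=self.nr_min_subject_cov,
                         max_evalue=self.nr_max_evalue)


@dataclass
class GeneEvidence:
    is_single_exon: bool
    has_functional: bool
    has_nr_hit: bool
    in_multispecies_og: bool

    @property
    def removed(self) -> bool:
        return (self.is_single_exon and not self.has_functional
                and not self.has_nr_hit and not self.in_multispecies_og)


@dataclass
class FilterReport:
    removed: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    per_gene_evidence: dict[str, GeneEvidence] = field(default_factory=dict)


def is_single_exon_gene(gene: Gene) -> bool:
    """True iff every isoform of the gene has exactly one CDS segment."""
    return all(exon_count(tx) == 1 for tx in gene.transcripts)


def multispecies_members(table: OrthogroupTable) -> set[str]:
    """Member ids of every orthogroup whose members come from >= 2 species."""
    out: set[str] = set()
    for og_id in table.groups:
        if table.n_species_in(og_id) >= 2:
            out.update(table.all_members(og_id))
    return out


def filter_single_exon(annotation: GenomeAnnotation,
                       records: list[FunctionalRecord],
                       nr_hits: list[AlignmentHit],
                       table: OrthogroupTable | None = None,
                       config: FilterConfig = FilterConfig()
                       ) -> tuple[GenomeAnnotation, FilterReport]:
    """Apply the three-evidence discard rule; returns the kept annotation
    and a complete per-gene report.

    NR hits are keyed by the longest-isoform transcript id of each gene.
    Orthogroup member ids may be either gene ids or longest-isoform
    transcript ids; ids unknown to the annotation are ignored with a
    warning.
    """
    by_tx: dict[str, FunctionalRecord] = {}
    for r in records:
        by_tx[r.transcript_id] = r

    gate = config.as_hit_gate()
    nr_by_query: dict[str, bool] = {}
    for hit in nr_hits:
        if hit_passes(hit, gate):
            nr_by_query[hit.query_id] = True

    tx2gene = annotation.transcript_to_gene()
    og_genes: set[str] = set()
    if table is not None:
        unknown = 0
        for member in multispecies_members(table):
            if member in annotation.genes:
                og_genes.add(member)
            elif member in tx2gene:
                og_genes.add(tx2gene[member])
            else:
                unknown += 1
        if unknown:
            # expected whenever the table spans several species
            logger.debug("%d orthogroup member ids not in this annotation; ignored",
                         unknown)

    report = FilterReport()
    kept_genes: dict[str, Gene] = {}
    for gene_id, gene in annotation.genes.items():
        rep = longest_isoform(gene)
        evidence = GeneEvidence(
            is_single_exon=is_single_exon_gene(gene),
            has_functional=any(
                tx.id in by_tx and by_tx[tx.id].has_any_evidence
                for tx in gene.transcripts),
            has_nr_hit=nr_by_query.get(rep.id, False),
            in_multispecies_og=gene_id in og_genes,
        )
        report.per_gene_evidence[gene_id] = evidence
        if evidence.removed:
            report.removed.append(gene_id)
        else:
            report.kept.append(gene_id)
            kept_genes[gene_id] = gene

    contigs = set(annotation.contigs)  # contigs are kept even if emptied
    filtered = GenomeAnnotation(species=annotation.species, genes=kept_genes,
                                contigs=contigs)
    return filtered, report


def filter_report_tsv(report: FilterReport) -> list[str]:
    """TSV lines: gene_id, is_single_exon, has_functional, has_nr_hit,
    in_multispecies_og, decision."""
    def b(x: bool) -> str:
        return "true" if x else "false"

    lines = ["\t".join(("gene_id", "is_single_exon", "has_functional",
                        "has_nr_hit", "in_multispecies_og", "decision"))]
    for gene_id in sorted(report.per_gene_evidence):
        e = report.per_gene_evidence[gene_id]
        lines.append("\t".join((gene_id, b(e.is_single_exon), b(e.has_functional),
                                b(e.has_nr_hit), b(e.in_multispecies_og),
                                "removed" if e.removed else "kept")))
    return lines
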