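"""Horizontal-gene-transfer candidate calling with genomic-context filtering.

Candidates are screened in two stages, using the longest isoform of each
gene as its representative protein:

1. *Alignment evidence.*  A gene is an initial candidate when its protein
   aligns to the microbial donor database (coverage at least 50% on both
   query and subject, e-value at most 1e-5, all inclusive boundaries)
   while failing to align to the plant donor database or to the recipient
   database.  The published rule is ambiguous between OR-of-absences and
   AND-of-absences; OR (``any_absent``) is the default and AND
   (``both_absent``) is available via :class:`HgtConfig`.

2. *Genomic context.*  A real transfer should be embedded in native
   sequence.  A candidate is kept only if it has an immediately preceding
   and an immediately following gene on the same contig (so genes at
   scaffold ends are always rejected), neither neighbour carries a
   contaminant-flagged transcript, and neither neighbour is itself an
   initial candidate (the neighbours must look native).  The first failed
   check, in that order, is recorded as the rejection reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .evidence_io import AlignmentHit
from .gff_io import Decoration, GenomeAnnotation, gene_order, longest_isoform

logger = logging.getLogger(__name__)

ANY_ABSENT = "any_absent"
BOTH_ABSENT = "both_absent"

REASONS = ("no_upstream_neighbor", "no_downstream_neighbor",
           "neighbor_contaminant", "neighbor_not_native")


@dataclass(frozen=True)
class HgtConfig:
    min_query_cov: float = 0.5
    min_subject_cov: float = 0.5
    max_evalue: float = 1e-5
    absence_rule: str = ANY_ABSENT

    def __post_init__(self) -> None:
        if not (0 < self.min_query_cov <= 1 and 0 < self.min_subject_cov <= 1):
            raise ValueError("coverage thresholds must lie in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if self.absence_rule not in (ANY_ABSENT, BOTH_ABSENT):
            raise ValueError(f"unknown absence rule {self.absence_rule!r}")


@dataclass(frozen=True)
class HgtVerdict:
    gene_id: str
    has_microbial: bool
    has_plant: bool
    has_recipient: bool
    initial_candidate: bool
    context_pass: bool | None = None  # None until the context filter ran
    rejection_reason: str | None = None
    final_candidate: bool = False


def hit_passes(hit: AlignmentHit, config: HgtConfig = HgtConfig()) -> bool:
    """Inclusive thresholds: coverage >= minimum on both sides, e-value <= cutoff."""
    if hit.qlen == 0 or hit.slen == 0:
        raise ValueError(f"hit {hit.query_id!r}: zero query or subject length")
    return (hit.query_cov >= config.min_query_cov
            and hit.subject_cov >= config.min_subject_cov
            and hit.evalue <= config.max_evalue)


def representative_queries(annotation: GenomeAnnotation) -> dict[str, str]:
    """Map longest-isoform transcript id -> gene id; the protein search
    used one representative protein per gene, keyed by that isoform."""
    return {longest_isoform(g).id: g.id for g in annotation.genes.values()}


def initial_candidates(gene_ids: list[str],
                       hits_by_db: dict[str, list[AlignmentHit]],
                       query_to_gene: dict[str, str],
                       config: HgtConfig = HgtConfig()) -> dict[str, HgtVerdict]:
    """Stage-1 verdicts (context fields unset) for every gene id.

    Hits whose query id maps to no known gene are ignored with a warning.
    """
    presence: dict[str, dict[str, bool]] = {
        g: {"microbial_donor": False, "plant_donor": False, "recipient": False}
        for g in gene_ids}
    for db_tag, hits in hits_by_db.items():
        if db_tag not in ("microbial_donor", "plant_donor", "recipient"):
            continue
        for hit in hits:
            gene_id = query_to_gene.get(hit.query_id)
            if gene_id is None:
                logger.warning("hit query %r maps to no known gene; ignored", hit.query_id)
                continue
            if gene_id not in presence:  # a gene outside the requested set
                continue
            if hit_passes(hit, config):
                presence[gene_id][db_tag] = True
    verdicts = {}
    for gene_id in gene_ids:
        p = presence[gene_id]
        microbial, plant, recipient = p["microbial_donor"], p["plant_donor"], p["recipient"]
        if config.absence_rule == ANY_ABSENT:
            initial = microbial and (not plant or not recipient)
        else:
            initial = microbial and not plant and not recipient
        verdicts[gene_id] = HgtVerdict(
            gene_id=gene_id, has_microbial=microbial, has_plant=plant,
            has_recipient=recipient, initial_candidate=initial)
    return verdicts


def context_filter(verdicts: dict[str, HgtVerdict], annotation: GenomeAnnotation,
                   transcript_flags: dict[str, bool],
                   config: HgtConfig = HgtConfig()) -> dict[str, HgtVerdict]:
    """Stage 2: complete the verdicts with the flanking-gene checks."""

    def gene_contaminated(gene) -> bool:
        return any(transcript_flags.get(tx.id, False) for tx in gene.transcripts)

    position: dict[str, tuple[str, int]] = {}
    ordered: dict[str, list] = {}
    for contig in annotation.contigs:
        genes = gene_order(annotation, contig)
        ordered[contig] = genes
        for i, gene in enumerate(genes):
            position[gene.id] = (contig, i)

    completed = {}
    for gene_id, verdict in verdicts.items():
        if not verdict.initial_candidate:
            completed[gene_id] = replace(verdict, context_pass=False, final_candidate=False)
            continue
        contig, idx = position[gene_id]
        genes = ordered[contig]
        reason = None
        if idx == 0:
            reason = "no_upstream_neighbor"
        elif idx == len(genes) - 1:
            reason = "no_downstream_neighbor"
        else:
            upstream, downstream = genes[idx - 1], genes[idx + 1]
            if gene_contaminated(upstream) or gene_contaminated(downstream):
                reason = "neighbor_contaminant"
            elif (verdicts[upstream.id].initial_candidate
                  or verdicts[downstream.id].initial_candidate):
                reason = "neighbor_not_native"
        ok = reason is None
        completed[gene_id] = replace(verdict, context_pass=ok,
                                     rejection_reason=reason, final_candidate=ok)
    return completed


def hgt_decoration(verdicts: dict[str, HgtVerdict]) -> Decoration:
    return Decoration(hgt_tags={v.gene_id for v in verdicts.values() if v.final_candidate})


def hgt_report(verdicts: dict[str, HgtVerdict], annotation: GenomeAnnotation) -> list[str]:
    """TSV lines: gene_id, contig, has_microbial, has_plant, has_recipient,
    initial_candidate, rejection_reason, final_candidate."""
    def b(x: bool) -> str:
        return "true" if x else "false"

    lines = ["\t".join(("gene_id", "contig", "has_microbial", "has_plant",
                        "has_recipient", "initial_candidate", "rejection_reason",
                        "final_candidate"))]
    for gene_id in sorted(verdicts):
        v = verdicts[gene_id]
        lines.append("\t".join((
            v.gene_id, annotation.genes[v.gene_id].contig, b(v.has_microbial),
            b(v.has_plant), b(v.has_recipient), b(v.initial_candidate),
            v.rejection_reason or "", b(v.final_candidate))))
    return lines
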