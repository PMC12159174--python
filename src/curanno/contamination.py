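"""Contaminant-transcript flagging and per-contig contamination calls.

A transcript counts as a contaminant when its best similarity hit is to
a microbial database, or when it has no similarity hit and its gene-family
assignments are exclusively microbial.  An upstream contaminant call, when
present on the record, is honoured verbatim.

A contig is classified as potentially contaminated when STRICTLY more
than a threshold fraction (default 75%) of its annotated transcripts are
flagged; a contig sitting exactly at the threshold is not flagged.  The
denominator is annotated transcripts assigned to the contig — not genes,
not proteins — and contigs carrying no annotated transcript are never
flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .evidence_io import FunctionalRecord
from .gff_io import Decoration, GenomeAnnotation

logger = logging.getLogger(__name__)

CONTAMINANT_NOTE = "potential contaminant contig"

MICROBIAL = "microbial"


@dataclass(frozen=True)
class ContaminationConfig:
    contig_threshold: float = 0.75  # strict inequality

    def __post_init__(self) -> None:
        if not 0 < self.contig_threshold < 1:
            raise ValueError("contig_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class ContigVerdict:
    contig: str
    n_transcripts: int
    n_contaminated: int
    proportion: float | None  # None when the contig has no transcripts
    flagged: bool


def flag_transcripts(records: list[FunctionalRecord]) -> dict[str, bool]:
    """Contaminant call per transcript id.

    Duplicate transcript ids in the evidence table are a hard error.
    """
    flags: dict[str, bool] = {}
    for record in records:
        if record.transcript_id in flags:
            raise ValueError(f"duplicate transcript id {record.transcript_id!r} in evidence")
        if record.contaminant_flag is not None:
            flags[record.transcript_id] = record.contaminant_flag
        else:
            microbial_similarity = (record.has_similarity_hit
                                    and record.similarity_db_tag == MICROBIAL)
            microbial_family_only = (not record.has_similarity_hit
                                     and record.family_tags == frozenset({MICROBIAL}))
            flags[record.transcript_id] = microbial_similarity or microbial_family_only
    return flags


def classify_contigs(annotation: GenomeAnnotation, flags: dict[str, bool],
                     config: ContaminationConfig = ContaminationConfig()) -> list[ContigVerdict]:
    """One verdict per contig of the annotation, in sorted contig order.

    Transcripts absent from ``flags`` default to uncontaminated with a
    warning: absence of evidence must not condemn an assembly.
    """
    n_tx: dict[str, int] = {c: 0 for c in annotation.contigs}
    n_bad: dict[str, int] = {c: 0 for c in annotation.contigs}
    missing = 0
    for gene in annotation.genes.values():
        for tx in gene.transcripts:
            n_tx[gene.contig] += 1
            if tx.id not in flags:
                missing += 1
            elif flags[tx.id]:
                n_bad[gene.contig] += 1
    if missing:
        logger.warning("%d transcripts missing from evidence; treated as uncontaminated",
                       missing)
    verdicts = []
    for contig in sorted(annotation.contigs):
        total, bad = n_tx[contig], n_bad[contig]
        if total == 0:
            verdicts.append(ContigVerdict(contig, 0, 0, None, False))
        else:
            prop = bad / total
            verdicts.append(ContigVerdict(contig, total, bad, prop,
                                          prop > config.contig_threshold))
    return verdicts


def contamination_decoration(verdicts: list[ContigVerdict],
                             annotation: GenomeAnnotation) -> Decoration:
    """A Note on every CDS of every gene residing on a flagged contig."""
    flagged = {v.contig for v in verdicts if v.flagged}
    notes = {g.id: CONTAMINANT_NOTE for g in annotation.genes.values()
             if g.contig in flagged}
    return Decoration(cds_notes=notes)


def contig_report(verdicts: list[ContigVerdict]) -> list[str]:
    """TSV lines: contig, n_transcripts, n_contaminated, proportion, flagged."""
    lines = ["\t".join(("contig", "n_transcripts", "n_contaminated",
                        "proportion", "flagged"))]
    for v in verdicts:
        prop = "" if v.proportion is None else f"{v.proportion:.4f}"
        lines.append("\t".join((v.contig, str(v.n_transcripts), str(v.n_contaminated),
                                prop, "true" if v.flagged else "false")))
    return lines
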