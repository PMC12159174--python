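import pytest

from curanno.evidence_io import AlignmentHit
from curanno.gff_io import CdsSegment, Gene, GenomeAnnotation, Transcript
from curanno.synthetic_data import SimParams, generate

SMALL_PARAMS = SimParams(seed=7, n_contigs=8, genes_per_contig=20.0,
                         n_hgt_true=2, n_hgt_decoy_end=1, n_hgt_decoy_neighbor=1,
                         n_junk_single_exon=15)


@pytest.fixture(scope="session")
def small_bundle():
    """A seeded 3-species bundle (~1000 genes) shared across tests."""
    return generate(SMALL_PARAMS)


def mk_tx(tx_id, gene_id, spans, strand="+"):
    return Transcript(id=tx_id, gene_id=gene_id,
                      cds_segments=[CdsSegment(s, e, strand) for s, e in spans])


def mk_gene(gene_id, contig, transcripts, strand="+"):
    start = min(s.start for t in transcripts for s in t.cds_segments)
    end = max(s.end for t in transcripts for s in t.cds_segments)
    return Gene(id=gene_id, contig=contig, strand=strand, start=start, end=end,
                transcripts=transcripts)


def mk_annotation(genes, species="test", extra_contigs=()):
    contigs = {g.contig for g in genes} | set(extra_contigs)
    return GenomeAnnotation(species=species, genes={g.id: g for g in genes},
                            contigs=contigs)


def mk_hit(query="q1", subject="s1", db_tag="microbial_donor", qstart=1, qend=100,
           qlen=100, sstart=1, send=100, slen=100, evalue=1e-30, pident=80.0,
           bitscore=200.0):
    return AlignmentHit(query_id=query, subject_id=subject, db_tag=db_tag,
                        pident=pident, aln_length=qend - qstart + 1, mismatches=0,
                        gap_opens=0, qstart=qstart, qend=qend, sstart=sstart,
                        send=send, evalue=evalue, bitscore=bitscore,
                        qlen=qlen, slen=slen)
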