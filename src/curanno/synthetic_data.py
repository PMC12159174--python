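"""Synthetic multi-species annotation sets with planted, machine-readable truth.

The generator emulates the statistical shape of automated coding-gene
annotations for a clade of microalgae: a few hundred to a few thousand
gene models per species spread over many contigs, a high mono-exonic
fraction, geometric-tailed exon counts for multi-exonic genes, and
occasional alternative isoforms.  On top of that background it plants
the exact situations the curation rules exist to detect:

* *contaminated contigs* — a chosen fraction of contigs where nearly all
  transcripts carry microbial similarity evidence (well above the 75%
  flagging threshold), while clean contigs stay well below it;
* *horizontally transferred genes* — mid-scaffold genes whose
  representative protein aligns only to the microbial donor database,
  flanked by clean native neighbours, plus two kinds of decoys that the
  genomic-context filter must reject: candidates sitting at a scaffold
  end, and candidates with a contaminant-flagged neighbour;
* *junk single-exon genes* — evidence-free single-exon models (no
  product, no significant NR hit, no orthogroup membership) that the
  three-evidence filter should remove; every non-junk gene is guaranteed
  at least one evidence channel.

E-values of planted passing hits are drawn log-uniformly in
[1e-50, 1e-6] and failing hits in [1e-4, 1], keeping both sides clear of
the 1e-5 decision boundary; boundary behaviour is tested separately with
hand-built hits.  Output is deterministic given the seed, and every
infeasible parameter combination (for example more planted transfers
than available mid-scaffold slots) raises before anything is emitted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evidence_io import (AlignmentHit, FunctionalRecord, OrthogroupTable,
                          read_functional_file, read_hits_file,
                          read_orthogroups_file, write_functional, write_hits,
                          write_orthogroups)
from .gff_io import (CdsSegment, Gene, GenomeAnnotation, Transcript,
                     longest_isoform, parse_gff3_file, write_gff3_file)

HIT_FILES = {"microbial_donor": "hits.microbial.tsv",
             "plant_donor": "hits.plant.tsv",
             "recipient": "hits.recipient.tsv",
             "nr": "hits.nr.tsv"}


@dataclass(frozen=True)
class SimParams:
    """Knobs of the generator; defaults describe one realistic small study.

    ``genes_per_contig`` is the mean of a Poisson draw (floored at 3 so
    every contig has interior gene positions).  ``exon_count_geom_p``
    parameterizes the geometric tail of multi-exon counts, truncated at
    ``max_exons``.  The planted counts are per species.
    """

    seed: int = 0
    n_species: int = 3
    n_contigs: int = 20
    genes_per_contig: float = 50.0
    mono_fraction: float = 0.6
    exon_count_geom_p: float = 0.45
    max_exons: int = 30
    multi_isoform_prob: float = 0.15
    frac_contaminated_contigs: float = 0.10
    contig_contamination_level: float = 0.95
    background_contamination_rate: float = 0.05
    n_hgt_true: int = 6
    n_hgt_decoy_end: int = 3
    n_hgt_decoy_neighbor: int = 3
    n_junk_single_exon: int = 60
    og_assigned_fraction: float = 0.92
    og_multispecies_fraction: float = 0.90

    def __post_init__(self) -> None:
        for name in ("mono_fraction", "frac_contaminated_contigs",
                     "contig_contamination_level", "background_contamination_rate",
                     "og_assigned_fraction", "og_multispecies_fraction"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in ("n_species", "n_contigs", "n_hgt_true", "n_hgt_decoy_end",
                     "n_hgt_decoy_neighbor", "n_junk_single_exon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_species < 1 or self.n_contigs < 1:
            raise ValueError("need at least one species and one contig")


@dataclass
class SyntheticTruth:
    contaminated_contigs: set[str] = field(default_factory=set)
    contaminant_transcripts: set[str] = field(default_factory=set)
    hgt_true: set[str] = field(default_factory=set)
    hgt_decoys: dict[str, str] = field(default_factory=dict)  # gene -> expected reason
    junk_genes: set[str] = field(default_factory=set)
    mono_genes: set[str] = field(default_factory=set)
    multi_genes: set[str] = field(default_factory=set)
    og_assignment: dict[str, str | None] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.junk_genes <= self.mono_genes:
            raise ValueError("junk genes must be mono-exonic")
        planted_hgt = self.hgt_true | set(self.hgt_decoys)
        if planted_hgt & self.junk_genes:
            raise ValueError("HGT plants must be disjoint from junk genes")


@dataclass
class FixtureBundle:
    params: SimParams
    annotations: dict[str, GenomeAnnotation]
    records: list[FunctionalRecord]
    hits_by_db: dict[str, list[AlignmentHit]]
    nr_hits: list[AlignmentHit]
    og_table: OrthogroupTable
    truth: SyntheticTruth


class InfeasibleParams(ValueError):
    """Requested planted structure cannot fit into the generated layout."""


def _phases(segments: list[CdsSegment], strand: str) -> list[CdsSegment]:
    ordered = segments if strand == "+" else list(reversed(segments))
    out, cum = [], 0
    for seg in ordered:
        phase = (3 - cum % 3) % 3
        out.append(CdsSegment(seg.start, seg.end, seg.strand, str(phase)))
        cum += seg.length
    return out if strand == "+" else list(reversed(out))


def _loguniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(10 ** rng.uniform(math.log10(low), math.log10(high)))


def _make_hit(rng: np.random.Generator, query_id: str, subject_id: str,
              db_tag: str, qlen: int, passing: bool) -> AlignmentHit:
    """A hit engineered to clear (or miss) the coverage+e-value gate."""
    if passing:
        qcov, scov = rng.uniform(0.6, 1.0), rng.uniform(0.6, 1.0)
        evalue = _loguniform(rng, 1e-50, 1e-6)
    elif rng.random() < 0.5:  # fail on coverage
        qcov, scov = rng.uniform(0.1, 0.45), rng.uniform(0.6, 1.0)
        evalue = _loguniform(rng, 1e-50, 1e-6)
    else:  # fail on e-value
        qcov, scov = rng.uniform(0.6, 1.0), rng.uniform(0.6, 1.0)
        evalue = _loguniform(rng, 1e-4, 1.0)
    slen = max(20, int(qlen * rng.uniform(0.8, 1.2)))
    qspan = min(qlen, max(1, int(round(qcov * qlen))))
    sspan = min(slen, max(1, int(round(scov * slen))))
    qstart = int(rng.integers(1, qlen - qspan + 2))
    sstart = int(rng.integers(1, slen - sspan + 2))
    aln = max(qspan, sspan)
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id, db_tag=db_tag,
        pident=round(float(rng.uniform(35, 95)), 1), aln_length=aln,
        mismatches=int(rng.integers(0, aln // 3 + 1)), gap_opens=int(rng.integers(0, 5)),
        qstart=qstart, qend=qstart + qspan - 1,
        sstart=sstart, send=sstart + sspan - 1,
        evalue=evalue, bitscore=round(float(rng.uniform(50, 900)), 1),
        qlen=qlen, slen=slen)


def generate(params: SimParams) -> FixtureBundle:
    """Build a full fixture bundle: annotations, evidence, orthogroups, truth."""
    rng = np.random.default_rng(params.seed)
    truth = SyntheticTruth()
    annotations: dict[str, GenomeAnnotation] = {}
    records: list[FunctionalRecord] = []
    hits_by_db: dict[str, list[AlignmentHit]] = {
        "microbial_donor": [], "plant_donor": [], "recipient": []}
    nr_hits: list[AlignmentHit] = []
    rep_of: dict[str, str] = {}        # gene id -> representative transcript id
    protlen: dict[str, int] = {}       # representative tx id -> protein length
    assignable: dict[str, list[str]] = {}  # species -> non-junk gene ids

    species_names = [f"sp{i + 1:02d}" for i in range(params.n_species)]
    for sp in species_names:
        annotation, sp_assignable = _generate_species(sp, params, rng, truth,
                                                      records, hits_by_db, nr_hits,
                                                      rep_of, protlen)
        annotations[sp] = annotation
        assignable[sp] = sp_assignable

    og_table = _build_orthogroups(params, rng, species_names, assignable, truth)
    truth.validate()
    return FixtureBundle(params=params, annotations=annotations, records=records,
                         hits_by_db=hits_by_db, nr_hits=nr_hits,
                         og_table=og_table, truth=truth)


def _generate_species(sp: str, params: SimParams, rng: np.random.Generator,
                      truth: SyntheticTruth, records: list[FunctionalRecord],
                      hits_by_db: dict[str, list[AlignmentHit]],
                      nr_hits: list[AlignmentHit],
                      rep_of: dict[str, str], protlen: dict[str, int]
                      ) -> tuple[GenomeAnnotation, list[str]]:
    contig_ids = [f"{sp}_ctg{i + 1:03d}" for i in range(params.n_contigs)]
    genes_on: dict[str, list[Gene]] = {}
    gene_counter = 0
    genes: dict[str, Gene] = {}

    for contig in contig_ids:
        n_genes = max(3, int(rng.poisson(params.genes_per_contig)))
        cursor = int(rng.integers(100, 2000))
        contig_genes = []
        for _ in range(n_genes):
            gene_counter += 1
            gene_id = f"{sp}_g{gene_counter:06d}"
            strand = "+" if rng.random() < 0.5 else "-"
            mono = rng.random() < params.mono_fraction
            if mono:
                n_exons = 1
            else:
                n_exons = min(params.max_exons,
                              1 + int(rng.geometric(params.exon_count_geom_p)))
                n_exons = max(2, n_exons)
            segments = []
            pos = cursor
            for _ in range(n_exons):
                length = int(rng.integers(30, 400)) * 3
                segments.append(CdsSegment(pos, pos + length - 1, strand))
                pos += length + int(rng.integers(50, 600))
            segments = _phases(segments, strand)
            tx1 = Transcript(id=f"{gene_id}.t1", gene_id=gene_id,
                             cds_segments=segments)
            transcripts = [tx1]
            if rng.random() < params.multi_isoform_prob:
                # second isoform: same structure, shortened terminal exon,
                # so a mono gene stays mono and a multi gene stays multi
                last = segments[-1]
                trim = 3 * int(rng.integers(1, max(2, last.length // 6)))
                if last.length - trim >= 3:
                    alt = segments[:-1] + [CdsSegment(last.start, last.end - trim,
                                                      strand)]
                    alt = _phases(alt, strand)
                    transcripts.append(Transcript(id=f"{gene_id}.t2",
                                                  gene_id=gene_id,
                                                  cds_segments=alt))
            gene = Gene(id=gene_id, contig=contig, strand=strand,
                        start=min(s.start for s in segments),
                        end=max(s.end for s in segments),
                        transcripts=transcripts)
            contig_genes.append(gene)
            genes[gene_id] = gene
            (truth.mono_genes if mono else truth.multi_genes).add(gene_id)
            cursor = pos + int(rng.integers(200, 2000))
        genes_on[contig] = contig_genes

    annotation = GenomeAnnotation(species=sp, genes=genes, contigs=set(contig_ids))
    for gene in genes.values():
        rep = longest_isoform(gene)
        rep_of[gene.id] = rep.id
        protlen[rep.id] = rep.coding_length // 3

    # --- contamination plants ------------------------------------------------
    n_contam = int(round(params.frac_contaminated_contigs * params.n_contigs))
    contam_contigs = sorted(rng.choice(contig_ids, size=n_contam, replace=False).tolist())
    clean_contigs = [c for c in contig_ids if c not in contam_contigs]
    truth.contaminated_contigs.update(contam_contigs)

    contaminant_tx: set[str] = set()
    for contig in contam_contigs:
        tx_ids = [tx.id for g in genes_on[contig] for tx in g.transcripts]
        n_bad = max(int(math.ceil(params.contig_contamination_level * len(tx_ids))),
                    int(math.floor(0.75 * len(tx_ids))) + 1)
        n_bad = min(n_bad, len(tx_ids))
        bad = rng.choice(tx_ids, size=n_bad, replace=False).tolist()
        contaminant_tx.update(bad)

    # --- HGT plants: one planted gene per clean contig -----------------------
    n_plants = params.n_hgt_true + params.n_hgt_decoy_end + params.n_hgt_decoy_neighbor
    usable = [c for c in clean_contigs if len(genes_on[c]) >= 3]
    if n_plants > len(usable):
        raise InfeasibleParams(
            f"{sp}: {n_plants} HGT plants requested but only {len(usable)} "
            f"clean contigs with >=3 genes available")
    plant_contigs = [usable[i] for i in
                     rng.choice(len(usable), size=n_plants, replace=False)]
    hgt_plants: set[str] = set()
    contaminated_neighbor_genes: set[str] = set()
    idx = 0
    for kind, count in (("true", params.n_hgt_true),
                        ("end", params.n_hgt_decoy_end),
                        ("neighbor", params.n_hgt_decoy_neighbor)):
        for k in range(count):
            contig = plant_contigs[idx]
            idx += 1
            ordered = sorted(genes_on[contig], key=lambda g: (g.start, g.end, g.id))
            if kind == "end":
                at_start = k % 2 == 0
                gene = ordered[0] if at_start else ordered[-1]
                truth.hgt_decoys[gene.id] = ("no_upstream_neighbor" if at_start
                                             else "no_downstream_neighbor")
            else:
                mid = int(rng.integers(1, len(ordered) - 1))
                gene = ordered[mid]
                if kind == "true":
                    truth.hgt_true.add(gene.id)
                else:
                    neighbor = ordered[mid + 1] if k % 2 == 0 else ordered[mid - 1]
                    contaminated_neighbor_genes.add(neighbor.id)
                    truth.hgt_decoys[gene.id] = "neighbor_contaminant"
            hgt_plants.add(gene.id)

    for gene_id in contaminated_neighbor_genes:
        contaminant_tx.update(tx.id for tx in genes[gene_id].transcripts)

    # background contamination only on contigs without plants, capped at 30%
    plant_contig_set = set(plant_contigs)
    for contig in clean_contigs:
        if contig in plant_contig_set:
            continue
        tx_ids = [tx.id for g in genes_on[contig] for tx in g.transcripts]
        cap = int(math.floor(0.3 * len(tx_ids)))
        n_bad = min(cap, int(rng.binomial(len(tx_ids),
                                          params.background_contamination_rate)))
        if n_bad:
            contaminant_tx.update(rng.choice(tx_ids, size=n_bad, replace=False).tolist())
    truth.contaminant_transcripts.update(contaminant_tx)

    # --- junk single-exon genes ---------------------------------------------
    protected = set(hgt_plants) | contaminated_neighbor_genes
    gene_of_tx = {tx.id: g.id for g in genes.values() for tx in g.transcripts}
    contaminated_genes = {gene_of_tx[t] for t in contaminant_tx}
    junk_pool = sorted(
        g.id for g in genes.values()
        if g.id in truth.mono_genes and len(g.transcripts) == 1
        and g.id not in protected and g.id not in contaminated_genes)
    if params.n_junk_single_exon > len(junk_pool):
        raise InfeasibleParams(
            f"{sp}: {params.n_junk_single_exon} junk genes requested but only "
            f"{len(junk_pool)} eligible single-exon genes available")
    junk = set(rng.choice(junk_pool, size=params.n_junk_single_exon,
                          replace=False).tolist())
    truth.junk_genes.update(junk)

    # --- functional records and NR evidence ----------------------------------
    # every non-junk gene is guaranteed at least one evidence channel
    # (product / similarity / family / significant NR hit)
    products = ("hypothetical protein", "kinase", "transporter", "heat shock protein",
                "light-harvesting protein", "silicon transporter", "histone")
    nr_channel: dict[str, bool] = {}
    for gene in genes.values():
        if gene.id in junk:
            nr_channel[gene.id] = False
            for tx in gene.transcripts:
                records.append(FunctionalRecord(transcript_id=tx.id))
            continue
        has_nr = gene.id in hgt_plants or rng.random() < 0.6
        gene_has_functional = False
        gene_records = []
        for tx in gene.transcripts:
            if tx.id in contaminant_tx:
                gene_records.append(FunctionalRecord(
                    transcript_id=tx.id,
                    product=str(rng.choice(products)),
                    has_similarity_hit=True, similarity_db_tag="microbial",
                    family_tags=frozenset({"microbial"})))
                gene_has_functional = True
                continue
            has_product = rng.random() < 0.7
            has_sim = rng.random() < 0.6
            fam_draw = rng.random()
            if fam_draw < 0.5:
                fams: frozenset[str] = frozenset({"non_microbial"})
            elif fam_draw < 0.6:
                fams = frozenset({"microbial", "non_microbial"})
            else:
                fams = frozenset()
            gene_records.append(FunctionalRecord(
                transcript_id=tx.id,
                product=str(rng.choice(products)) if has_product else None,
                has_similarity_hit=has_sim,
                similarity_db_tag="non_microbial" if has_sim else None,
                family_tags=fams))
            gene_has_functional |= has_product or has_sim or bool(fams)
        if not gene_has_functional and not has_nr:
            first = gene_records[0]
            gene_records[0] = FunctionalRecord(
                transcript_id=first.transcript_id,
                product=str(rng.choice(products)),
                has_similarity_hit=first.has_similarity_hit,
                similarity_db_tag=first.similarity_db_tag,
                family_tags=first.family_tags)
        records.extend(gene_records)
        nr_channel[gene.id] = has_nr

    # --- alignment hit tables --------------------------------------------------
    for gene in genes.values():
        rep = rep_of[gene.id]
        qlen = protlen[rep]
        if gene.id in hgt_plants:
            hits_by_db["microbial_donor"].append(
                _make_hit(rng, rep, f"mic|{rep}", "microbial_donor", qlen, True))
            if rng.random() < 0.4:  # failing recipient hit: still absent
                hits_by_db["recipient"].append(
                    _make_hit(rng, rep, f"rec|{rep}", "recipient", qlen, False))
        else:
            draw = rng.random()
            if draw < 0.15:  # conserved gene also present in donor databases
                hits_by_db["microbial_donor"].append(
                    _make_hit(rng, rep, f"mic|{rep}", "microbial_donor", qlen, True))
                hits_by_db["plant_donor"].append(
                    _make_hit(rng, rep, f"pla|{rep}", "plant_donor", qlen, True))
                hits_by_db["recipient"].append(
                    _make_hit(rng, rep, f"rec|{rep}", "recipient", qlen, True))
            elif draw < 0.8:  # ordinary native gene
                hits_by_db["recipient"].append(
                    _make_hit(rng, rep, f"rec|{rep}", "recipient", qlen, True))
            # else: no homology evidence in these databases

    # --- NR hits: evidence channel for non-junk genes -------------------------
    sp_assignable = []
    for gene in genes.values():
        rep = rep_of[gene.id]
        qlen = protlen[rep]
        if gene.id in junk:
            if rng.random() < 0.3:  # a non-significant NR hit must not rescue
                nr_hits.append(_make_hit(rng, rep, f"nr|{rep}", "nr", qlen, False))
        else:
            sp_assignable.append(gene.id)
            if nr_channel[gene.id]:
                nr_hits.append(_make_hit(rng, rep, f"nr|{rep}", "nr", qlen, True))
    return annotation, sp_assignable


def _build_orthogroups(params: SimParams, rng: np.random.Generator,
                       species_names: list[str],
                       assignable: dict[str, list[str]],
                       truth: SyntheticTruth) -> OrthogroupTable:
    """Group a fraction of non-junk genes into orthogroups; a set fraction
    of assigned genes land in groups spanning >= 2 species."""
    table = OrthogroupTable(species=list(species_names))
    multi_pool: dict[str, list[str]] = {}
    single_pool: dict[str, list[str]] = {}
    for sp in species_names:
        pool = list(assignable[sp])
        rng.shuffle(pool)
        n_assigned = int(round(params.og_assigned_fraction * len(pool)))
        assigned, unassigned = pool[:n_assigned], pool[n_assigned:]
        n_multi = int(round(params.og_multispecies_fraction * len(assigned)))
        multi_pool[sp] = assigned[:n_multi]
        single_pool[sp] = assigned[n_multi:]
        for g in unassigned:
            truth.og_assignment[g] = None

    og_counter = 0

    def next_id() -> str:
        nonlocal og_counter
        og_id = f"OG{og_counter:07d}"
        og_counter += 1
        return og_id

    # multi-species groups: draw members from >= 2 species while possible
    multi_group_ids: list[str] = []
    while True:
        nonempty = [sp for sp in species_names if multi_pool[sp]]
        if len(nonempty) < 2:
            break
        k = int(rng.integers(2, len(nonempty) + 1))
        chosen = [nonempty[i] for i in rng.choice(len(nonempty), size=k, replace=False)]
        og_id = next_id()
        row: dict[str, list[str]] = {sp: [] for sp in species_names}
        for sp in chosen:
            take = min(len(multi_pool[sp]), int(rng.integers(1, 6)))
            members, multi_pool[sp] = multi_pool[sp][:take], multi_pool[sp][take:]
            row[sp] = members
            for g in members:
                truth.og_assignment[g] = og_id
        table.groups[og_id] = row
        multi_group_ids.append(og_id)

    # leftovers of a single species join existing multi-species groups
    # (or fall back to the paralog pool when no such group exists)
    for sp in species_names:
        for g in multi_pool[sp]:
            if multi_group_ids:
                og_id = multi_group_ids[int(rng.integers(0, len(multi_group_ids)))]
                table.groups[og_id][sp].append(g)
                truth.og_assignment[g] = og_id
            else:
                single_pool[sp].append(g)
        multi_pool[sp] = []

    # single-species (paralog-only) groups of size >= 2; leftovers unassigned
    for sp in species_names:
        pool = single_pool[sp]
        i = 0
        while len(pool) - i >= 2:
            take = min(len(pool) - i, int(rng.integers(2, 5)))
            og_id = next_id()
            members = pool[i:i + take]
            row = {s: [] for s in species_names}
            row[sp] = members
            table.groups[og_id] = row
            for g in members:
                truth.og_assignment[g] = og_id
            i += take
        for g in pool[i:]:
            truth.og_assignment[g] = None
    return table


# ---------------------------------------------------------------------------
# fixture directory I/O

def write_fixture(bundle: FixtureBundle, directory) -> list[Path]:
    """Write the bundle as plain-text files; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for sp in sorted(bundle.annotations):
        path = directory / f"{sp}.gff3"
        write_gff3_file(path, bundle.annotations[sp])
        written.append(path)
    for db_tag, filename in HIT_FILES.items():
        hits = bundle.nr_hits if db_tag == "nr" else bundle.hits_by_db.get(db_tag, [])
        path = directory / filename
        path.write_text("".join(line + "\n" for line in write_hits(hits)))
        written.append(path)
    path = directory / "functional.tsv"
    path.write_text("".join(line + "\n" for line in write_functional(bundle.records)))
    written.append(path)
    path = directory / "Orthogroups.tsv"
    path.write_text("".join(line + "\n" for line in write_orthogroups(bundle.og_table)))
    written.append(path)
    truth = bundle.truth
    path = directory / "truth.json"
    path.write_text(json.dumps({
        "contaminated_contigs": sorted(truth.contaminated_contigs),
        "contaminant_transcripts": sorted(truth.contaminant_transcripts),
        "hgt_true": sorted(truth.hgt_true),
        "hgt_decoys": dict(sorted(truth.hgt_decoys.items())),
        "junk_genes": sorted(truth.junk_genes),
        "mono_genes": sorted(truth.mono_genes),
        "multi_genes": sorted(truth.multi_genes),
        "og_assignment": {g: og for g, og in sorted(truth.og_assignment.items())},
    }, indent=1) + "\n")
    written.append(path)
    return written


def read_truth(path) -> SyntheticTruth:
    data = json.loads(Path(path).read_text())
    return SyntheticTruth(
        contaminated_contigs=set(data["contaminated_contigs"]),
        contaminant_transcripts=set(data["contaminant_transcripts"]),
        hgt_true=set(data["hgt_true"]),
        hgt_decoys=dict(data["hgt_decoys"]),
        junk_genes=set(data["junk_genes"]),
        mono_genes=set(data["mono_genes"]),
        multi_genes=set(data["multi_genes"]),
        og_assignment=dict(data["og_assignment"]),
    )


def read_fixture(directory, params: SimParams | None = None) -> FixtureBundle:
    """Re-read a fixture directory written by :func:`write_fixture`."""
    directory = Path(directory)
    annotations = {}
    for path in sorted(directory.glob("*.gff3")):
        sp = path.stem
        annotations[sp] = parse_gff3_file(path, species=sp)
    hits_by_db = {db: read_hits_file(directory / fn, db)
                  for db, fn in HIT_FILES.items() if db != "nr"}
    nr_hits = read_hits_file(directory / HIT_FILES["nr"], "nr")
    records = read_functional_file(directory / "functional.tsv")
    og_table = read_orthogroups_file(directory / "Orthogroups.tsv")
    truth = read_truth(directory / "truth.json")
    return FixtureBundle(params=params or SimParams(), annotations=annotations,
                         records=records, hits_by_db=hits_by_db, nr_hits=nr_hits,
                         og_table=og_table, truth=truth)
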