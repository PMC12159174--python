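"""Descriptive statistics, orthogroup summaries, and QC/selection rules.

Per-annotation statistics follow the conventions of annotation summary
tables: a gene is mono-exonic when all of its isoforms have a single CDS
segment; the mono:mult ratio is the count of mono-exonic genes over the
count of multi-exonic genes; the median exon count of multi-exonic genes
is taken over the longest isoform of each such gene; the maximum exon
count is taken over all transcripts.

Orthogroup summaries include per-species assignment rates, counts of
species-specific groups, mean/median group size, the number of groups
covering every species, and the G50/O50 statistics: sorting groups by
descending size, O50 is the number of largest groups needed to hold at
least half of a reference gene total, and G50 is the size of the last
group consumed.  Two reference totals are reported: genes assigned to
any orthogroup, and all input genes.

QC decisions implement the completeness-discrepancy rule for excluding
annotations: an assembly is dropped when its genome-level completeness
is very low, or when the genome-level score exceeds the protein-level
score by more than a tolerated gap (a large gap means the annotation
failed to recover genes demonstrably present in the assembly).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .evidence_io import BuscoSummary, OrthogroupTable
from .gene_filter import is_single_exon_gene
from .gff_io import GenomeAnnotation, exon_count, longest_isoform

KEEP = "keep"
EXCLUDE_LOW_GENOME = "exclude_low_genome"
EXCLUDE_DISCREPANCY = "exclude_discrepancy"


@dataclass(frozen=True)
class AnnotationStats:
    n_genes: int
    n_tx: int
    n_mono: int
    n_mult: int
    mono_mult_ratio: float | None  # None when there are no multi-exon genes
    median_mult_exons: float | None
    max_mult_exons: int


@dataclass(frozen=True)
class OrthoStats:
    per_species_assigned_pct: dict[str, float]
    per_species_single_species_pct: dict[str, float]
    n_groups: int
    n_species_specific_groups: int
    n_genes_in_species_specific: int
    mean_size: float
    median_size: float
    g50_assigned: int
    o50_assigned: int
    g50_all: int
    o50_all: int
    n_all_species_groups: int


@dataclass(frozen=True)
class QcConfig:
    min_genome_complete_pct: float = 60.0
    max_discrepancy_pct: float = 10.0  # percentage points, genome minus protein

    def __post_init__(self) -> None:
        if self.min_genome_complete_pct < 0 or self.max_discrepancy_pct < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass(frozen=True)
class AssemblyMeta:
    accession: str
    species: str
    representative: bool
    n50: int
    n_annotated_proteins: int


def annotation_stats(annotation: GenomeAnnotation) -> AnnotationStats:
    if not annotation.genes:
        raise ValueError("annotation has no genes")
    n_mono = 0
    mult_rep_exons: list[int] = []
    max_mult = 0
    n_tx = 0
    for gene in annotation.genes.values():
        n_tx += len(gene.transcripts)
        max_mult = max(max_mult, max(exon_count(tx) for tx in gene.transcripts))
        if is_single_exon_gene(gene):
            n_mono += 1
        else:
            mult_rep_exons.append(exon_count(longest_isoform(gene)))
    n_mult = len(mult_rep_exons)
    return AnnotationStats(
        n_genes=annotation.n_genes,
        n_tx=n_tx,
        n_mono=n_mono,
        n_mult=n_mult,
        mono_mult_ratio=(n_mono / n_mult) if n_mult else None,
        median_mult_exons=statistics.median(mult_rep_exons) if mult_rep_exons else None,
        max_mult_exons=max_mult,
    )


def _g50_o50(sizes_desc: list[int], reference_total: int) -> tuple[int, int]:
    """(G50, O50): accumulate descending sizes until >= half the reference."""
    if reference_total <= 0 or not sizes_desc:
        return 0, 0
    half = reference_total / 2
    cumulative = 0
    for i, size in enumerate(sizes_desc, start=1):
        cumulative += size
        if cumulative >= half:
            return size, i
    return sizes_desc[-1], len(sizes_desc)  # <50% coverage: all groups consumed


def ortho_stats(table: OrthogroupTable,
                total_genes_per_species: dict[str, int]) -> OrthoStats:
    for sp in table.species:
        if sp not in total_genes_per_species:
            raise ValueError(f"species {sp!r} missing from gene totals")

    assigned: dict[str, int] = {sp: 0 for sp in table.species}
    in_specific: dict[str, int] = {sp: 0 for sp in table.species}
    sizes: list[tuple[int, str]] = []
    n_specific = 0
    n_genes_specific = 0
    n_all_species = 0
    for og_id, row in table.groups.items():
        size = sum(len(m) for m in row.values())
        sizes.append((size, og_id))
        n_sp = sum(1 for sp in table.species if row.get(sp))
        if n_sp == len(table.species):
            n_all_species += 1
        for sp in table.species:
            assigned[sp] += len(row.get(sp, []))
        if n_sp == 1:
            n_specific += 1
            n_genes_specific += size
            (only_sp,) = [sp for sp in table.species if row.get(sp)]
            in_specific[only_sp] += size

    # descending size, ties broken by group id for determinism
    sizes.sort(key=lambda t: (-t[0], t[1]))
    sizes_desc = [s for s, _ in sizes]
    total_assigned = sum(sizes_desc)
    total_all = sum(total_genes_per_species[sp] for sp in table.species)
    g50_assigned, o50_assigned = _g50_o50(sizes_desc, total_assigned)
    g50_all, o50_all = _g50_o50(sizes_desc, total_all)

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    return OrthoStats(
        per_species_assigned_pct={
            sp: pct(assigned[sp], total_genes_per_species[sp]) for sp in table.species},
        per_species_single_species_pct={
            sp: pct(in_specific[sp], total_genes_per_species[sp]) for sp in table.species},
        n_groups=len(table.groups),
        n_species_specific_groups=n_specific,
        n_genes_in_species_specific=n_genes_specific,
        mean_size=(total_assigned / len(sizes_desc)) if sizes_desc else 0.0,
        median_size=statistics.median(sizes_desc) if sizes_desc else 0.0,
        g50_assigned=g50_assigned,
        o50_assigned=o50_assigned,
        g50_all=g50_all,
        o50_all=o50_all,
        n_all_species_groups=n_all_species,
    )


def busco_exclusion(genome: BuscoSummary, protein: BuscoSummary,
                    config: QcConfig = QcConfig()) -> str:
    """QC decision for one assembly from its genome- and protein-level
    completeness summaries."""
    if genome.complete_pct < config.min_genome_complete_pct:
        return EXCLUDE_LOW_GENOME
    if genome.complete_pct - protein.complete_pct > config.max_discrepancy_pct:
        return EXCLUDE_DISCREPANCY
    return KEEP


def select_assembly(candidates: list[AssemblyMeta]) -> tuple[AssemblyMeta, bool]:
    """Pick one assembly per species: the representative one if any,
    else the largest N50 (ties by accession).  The second element says
    whether the chosen assembly qualifies for annotation (at most 1000
    already-annotated proteins, i.e. effectively unannotated)."""
    if not candidates:
        raise ValueError("no candidate assemblies")
    species = {c.species for c in candidates}
    if len(species) != 1:
        raise ValueError(f"candidates span multiple species: {sorted(species)}")
    representatives = [c for c in candidates if c.representative]
    if representatives:
        chosen = min(representatives, key=lambda c: c.accession)
    else:
        chosen = min(candidates, key=lambda c: (-c.n50, c.accession))
    return chosen, chosen.n_annotated_proteins <= 1000


def filter_rnaseq_libraries(rates: dict[str, float],
                            min_rate: float = 0.20) -> list[str]:
    """Library ids whose alignment rate is not below the minimum
    (a rate exactly at the minimum is kept)."""
    for lib, rate in rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"library {lib!r}: rate {rate} outside [0, 1]")
    return sorted(lib for lib, rate in rates.items() if rate >= min_rate)


def stats_report_row(species: str, stats: AnnotationStats) -> str:
    ratio = "" if stats.mono_mult_ratio is None else f"{stats.mono_mult_ratio:.2f}"
    med = "" if stats.median_mult_exons is None else f"{stats.median_mult_exons:g}"
    return "\t".join((species, str(stats.n_genes), str(stats.n_tx), ratio,
                      med, str(stats.max_mult_exons)))


STATS_HEADER = "\t".join(("species", "n_genes", "n_tx", "mono_mult_ratio",
                          "median_mult_exons", "max_mult_exons"))
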