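"""End-to-end curation run over a fixture bundle.

Stage order is fixed and mirrors how the individual analyses depend on
one another: transcript contaminant flags are computed first, contigs
are classified from them, the HGT context filter consumes the same
transcript flags, the single-exon filter runs afterwards, and statistics
are computed both before and after filtering.  Each stage emits a TSV
report; a JSON manifest records the configuration, input digests, and
package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .annot_stats import (STATS_HEADER, AnnotationStats, annotation_stats,
                          ortho_stats, stats_report_row)
from .contamination import (ContaminationConfig, classify_contigs,
                            contamination_decoration, contig_report,
                            flag_transcripts)
from .gene_filter import FilterConfig, filter_report_tsv, filter_single_exon
from .gff_io import Decoration, decoration_report, write_gff3_file
from .hgt import (HgtConfig, context_filter, hgt_decoration, hgt_report,
                  initial_candidates, representative_queries)
from .synthetic_data import FixtureBundle, read_fixture


@dataclass
class RunConfig:
    contamination: ContaminationConfig = field(default_factory=ContaminationConfig)
    hgt: HgtConfig = field(default_factory=HgtConfig)
    gene_filter: FilterConfig = field(default_factory=FilterConfig)
    apply_filter: bool = True


@dataclass
class SpeciesResult:
    species: str
    contig_verdicts: list
    hgt_verdicts: dict
    filter_report: object
    stats_before: AnnotationStats
    stats_after: AnnotationStats
    filtered_annotation: object
    decoration: Decoration


@dataclass
class RunResult:
    per_species: dict[str, SpeciesResult]
    ortho: object
    artifacts: list[Path]


def curate_species(species: str, bundle: FixtureBundle, flags: dict[str, bool],
                   config: RunConfig,
                   query_to_gene: dict[str, str] | None = None) -> SpeciesResult:
    annotation = bundle.annotations[species]
    verdicts = classify_contigs(annotation, flags, config.contamination)

    if query_to_gene is None:
        query_to_gene = {}
        for other in bundle.annotations.values():
            query_to_gene.update(representative_queries(other))
    initial = initial_candidates(sorted(annotation.genes), bundle.hits_by_db,
                                 query_to_gene, config.hgt)
    completed = context_filter(initial, annotation, flags, config.hgt)

    if config.apply_filter:
        filtered, report = filter_single_exon(
            annotation, bundle.records, bundle.nr_hits, bundle.og_table,
            config.gene_filter)
    else:
        from .gene_filter import FilterReport
        filtered, report = annotation, FilterReport(kept=sorted(annotation.genes))

    stats_before = annotation_stats(annotation)
    stats_after = annotation_stats(filtered) if filtered.genes else stats_before

    # decoration applies to the filtered (surviving) gene set
    kept_tx = {tx.id for tx in filtered.transcripts()}
    decoration = Decoration()
    for record in bundle.records:
        if record.transcript_id in kept_tx and record.product:
            decoration.transcript_products[record.transcript_id] = record.product
    contam_deco = contamination_decoration(verdicts, annotation)
    decoration.cds_notes = {g: n for g, n in contam_deco.cds_notes.items()
                            if g in filtered.genes}
    hgt_deco = hgt_decoration(completed)
    decoration.hgt_tags = {g for g in hgt_deco.hgt_tags if g in filtered.genes}

    return SpeciesResult(species=species, contig_verdicts=verdicts,
                         hgt_verdicts=completed, filter_report=report,
                         stats_before=stats_before, stats_after=stats_after,
                         filtered_annotation=filtered, decoration=decoration)


def run_curation(bundle: FixtureBundle, outdir, config: RunConfig | None = None,
                 input_paths: list[Path] | None = None) -> RunResult:
    """Run every curation stage on the bundle and write all artifacts."""
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    flags = flag_transcripts(bundle.records)
    query_to_gene: dict[str, str] = {}
    for annotation in bundle.annotations.values():
        query_to_gene.update(representative_queries(annotation))
    per_species: dict[str, SpeciesResult] = {}
    stats_before_lines = [STATS_HEADER]
    stats_after_lines = [STATS_HEADER]
    for species in sorted(bundle.annotations):
        result = curate_species(species, bundle, flags, config, query_to_gene)
        per_species[species] = result
        annotation = bundle.annotations[species]

        _write(outdir / f"{species}.contigs.tsv", contig_report(result.contig_verdicts),
               artifacts)
        _write(outdir / f"{species}.hgt.tsv",
               hgt_report(result.hgt_verdicts, annotation), artifacts)
        _write(outdir / f"{species}.filter.tsv",
               filter_report_tsv(result.filter_report), artifacts)
        _write(outdir / f"{species}.decorations.tsv",
               decoration_report(result.filtered_annotation, result.decoration),
               artifacts)
        path = outdir / f"{species}.decorated.gff3"
        write_gff3_file(path, result.filtered_annotation, result.decoration)
        artifacts.append(path)
        stats_before_lines.append(stats_report_row(species, result.stats_before))
        stats_after_lines.append(stats_report_row(species, result.stats_after))

    _write(outdir / "stats_before.tsv", stats_before_lines, artifacts)
    _write(outdir / "stats_after.tsv", stats_after_lines, artifacts)

    totals = {sp: bundle.annotations[sp].n_genes for sp in bundle.annotations}
    for sp in bundle.og_table.species:
        totals.setdefault(sp, 0)
    ortho = ortho_stats(bundle.og_table, totals)
    path = outdir / "ortho_stats.json"
    path.write_text(json.dumps(asdict(ortho), indent=1) + "\n")
    artifacts.append(path)

    manifest = {
        "tool": "curanno",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": {
            "contig_threshold": config.contamination.contig_threshold,
            "min_query_cov": config.hgt.min_query_cov,
            "min_subject_cov": config.hgt.min_subject_cov,
            "max_evalue": config.hgt.max_evalue,
            "absence_rule": config.hgt.absence_rule,
            "nr_max_evalue": config.gene_filter.nr_max_evalue,
            "nr_min_query_cov": config.gene_filter.nr_min_query_cov,
            "nr_min_subject_cov": config.gene_filter.nr_min_subject_cov,
            "apply_filter": config.apply_filter,
        },
        "input_digests": {p.name: _sha256(p) for p in (input_paths or [])},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1) + "\n")
    artifacts.append(path)
    return RunResult(per_species=per_species, ortho=ortho, artifacts=artifacts)


def run_curation_dir(fixture_dir, outdir, config: RunConfig | None = None) -> RunResult:
    fixture_dir = Path(fixture_dir)
    bundle = read_fixture(fixture_dir)
    inputs = sorted(p for p in fixture_dir.iterdir() if p.is_file())
    return run_curation(bundle, outdir, config, input_paths=inputs)


def _write(path: Path, lines: list[str], artifacts: list[Path]) -> None:
    path.write_text("".join(line + "\n" for line in lines))
    artifacts.append(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
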