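# Methods

## Scope and model

`curanno` curates coding-gene annotations after automated prediction.
Its in-memory model is a gene → transcript → CDS-segment hierarchy with
1-based inclusive coordinates, exactly as in GFF3.  "Exon" always means
a CDS segment: the annotations in scope are coding-only predictions, and
every statistic (mono/multi-exonic status, exon counts, isoform length)
is defined over CDS segments; `exon` features in input files are
ignored.  A gene's representative protein is its *longest isoform*, the
transcript with the greatest summed CDS length (ties broken by smallest
transcript id so the choice is order-independent); genomic span is never
used for length, because all downstream comparisons are protein-level.

## Decision rules and their parameters

**Transcript contaminant flag.**  A transcript is contaminated iff its
similarity hit is microbial, or it has no similarity hit and its
gene-family assignments are exclusively microbial ({microbial} and
nothing else).  An explicit upstream contaminant call on the record,
when present, is honoured verbatim — the derivation is a fallback, not
an override.  "High confidence" of the upstream similarity search is
deliberately not re-quantified here; it is the upstream tool's notion.

**Contig classification** (`contig_threshold`, default 0.75, strict).
A contig is flagged iff the contaminated fraction of its annotated
transcripts is strictly greater than the threshold; a contig at exactly
the threshold is not flagged.  The denominator is annotated transcripts
on the contig — not genes or proteins.  Transcripts missing from the
evidence default to clean with a warning (absence of evidence must not
condemn an assembly), and contigs without annotated transcripts are
reported but never flagged.

**HGT alignment gate** (`min_query_cov`/`min_subject_cov` 0.5,
`max_evalue` 1e-5, all inclusive).  Coverage is span/length computed per
hit from (qstart, qend, qlen) and (sstart, send, slen); multiple HSPs
are never merged — each hit is evaluated alone, the simplest faithful
reading of a tabular search output.  Subject coordinates are normalized
to sstart ≤ send at parse time.  The 14-column input dialect (outfmt 6 +
qlen + slen) is required, not approximated: both lengths enter the rule.

**Initial HGT candidates** (`absence_rule`, default `any_absent`).  A
gene is an initial candidate iff it has a passing microbial-donor hit
and is absent from the plant donor *or* the recipient database.  The
source wording is ambiguous between OR and AND of the two absences; OR
is the default and `both_absent` is a config switch, with both behaviours
pinned by an 8-row presence truth table in the tests.

**Genomic-context filter.**  Checks run in a fixed order and the first
failure is recorded: upstream neighbour exists, downstream neighbour
exists, neither neighbour carries a contaminant-flagged transcript,
neither neighbour is itself an initial candidate ("native" neighbours).
Neighbourhood is purely positional (sorted by start, then end, then id;
strand ignored).  Contaminant status of a neighbour is evaluated at the
transcript level of that neighbour, not at contig level — a stricter
and more local reading; contig-level screening is already done by the
contig rule.

**Single-exon filter** (`nr_max_evalue` 1e-5, `nr_min_*_cov` 0.5).  A
gene is removed iff all isoforms are single-exon AND all three evidence
channels are empty: functional annotation (any product, similarity hit,
or family assignment on any isoform), significant NR hit for the
representative protein, and membership in an orthogroup spanning ≥ 2
species.  The NR significance thresholds are not prescribed anywhere;
they deliberately mirror the HGT gate and are configurable.  A gene
with one single-exon and one multi-exon isoform counts as multi-exon —
the only reading consistent with mono/multi partitioning of genes.
Orthogroup member ids may be gene ids or representative-transcript ids;
both are mapped to genes, unknown ids are ignored.

**Statistics.**  Mono:mult ratio = mono-exonic genes / multi-exonic
genes.  The median exon count of multi-exon genes uses the longest
isoform of each such gene (protein-level convention); the maximum exon
count is taken over all transcripts (the broader reading, documented
because summary tables in the field are ambiguous between the two).
Medians of even-sized multisets are the mean of the central pair.

**G50/O50.**  Group sizes are sorted descending, ties broken by group id
for determinism, and accumulated until the cumulative count reaches at
least half of the reference total (inclusive).  O50 is the number of
groups consumed, G50 the size of the last one.  Two references are
reported: total genes assigned to orthogroups, and total input genes.
If the reference is never reached all groups are consumed; an empty
table yields (0, 0).

**QC decisions** (`min_genome_complete_pct` 60, `max_discrepancy_pct`
10).  Exclude when genome-level completeness is below the floor;
otherwise exclude when genome-level minus protein-level completeness
exceeds the discrepancy allowance; otherwise keep.  Only decision
examples exist to calibrate against (95 vs 72 excluded, 15 excluded,
56 excluded, near-equal scores kept), so both thresholds are
configurable; the defaults reproduce all recorded decisions with wide
margins on both sides.

**Selection rules.**  One assembly per species: the representative one
if any (ties by accession), else largest N50 (ties by accession).  An
assembly with ≤ 1000 already-annotated proteins qualifies for fresh
annotation (the cutoff admits organelle-only annotations).  RNA-seq
libraries with alignment rate ≥ 0.20 are kept, the boundary inclusive.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical shape of automated coding
annotations for a diatom-like clade — per the defaults, 3 species × 20
contigs × Poisson(50) genes (~3000 genes), mono fraction 0.6 (mono:mult
≈ 1.5, mid-range for such clades), truncated-geometric multi-exon
counts (p = 0.45, max 30; median 2–3), 15% of genes with a second
isoform — and plants: 10% contaminated contigs at 95% contaminant
transcripts (clean contigs ≤ 30% with a 5% background rate), and per
species 6 true mid-scaffold transfers, 3 scaffold-end decoys, 3
contaminant-neighbour decoys, and 60 evidence-free single-exon junk
genes.  92% of non-junk genes are assigned to orthogroups, 90% of those
to multi-species groups.  Planted passing hits draw e-values
log-uniformly from [1e-50, 1e-6] and failing hits from [1e-4, 1], so the
planted truth never sits on the 1e-5 boundary; boundary behaviour is
tested with hand-built hits instead.  At most one transfer is planted
per contig so context-filter neighbourhoods never interact, and every
non-junk gene is guaranteed at least one evidence channel directly
(product/similarity/family or NR), independent of the orthogroup draw.

The generator does *not* simulate nucleotide sequence, codon content,
read data, coverage/GC signatures of contamination, partially
contaminated genes, fragmented gene models, or annotation errors beyond
the planted junk-gene model.  Perfect precision/recall on this fixture
therefore demonstrates that the decision rules are implemented exactly
as specified on inputs where the truth is knowable — not that real
contaminated assemblies separate this cleanly, since real evidence is
noisy in ways the generator's clear margins deliberately avoid.

## Numerical and I/O choices

All boundary comparisons are explicit (strict > for the contig rule;
inclusive ≥/≤ for coverage, e-value, alignment rate, and protein
count), pinned by dedicated boundary tests.  GFF3 output is byte-stable:
contigs lexicographic, genes by (start, end, id), transcripts by id,
attributes in fixed order (ID, Parent, product, Note, hgt_candidate),
reserved characters percent-encoded.  Product names attach to mRNA
lines, curation notes and transfer tags to CDS lines.  Parsing uses
gffutils' line-level parser for columns/attributes and assembles the
hierarchy itself so that structural errors (unresolvable CDS parent,
start > end, wrong column count) fail hard with line numbers.  Fixture
generation uses a single NumPy generator seeded once; identical seeds
give byte-identical fixture files.

## Problem sizes

Randomized-oracle tests use 1000 instances per operation with small
per-instance sizes (≤ 12 genes or ≤ 10 transcripts per contig), and the
planted-recovery run uses the default ~3000-gene fixture; these sizes
give per-operation coverage of every branch while the full suite stays
in the low seconds.

## Known limitations

* The EnTAP-style evidence table is reduced to one boolean-and-tags
  record per transcript; the tool's native multi-column output is not
  parsed verbatim.
* HSPs are not merged for coverage, so a protein covered 2 × 30% by two
  split hits does not pass the gate.
* Orthogroup statistics trust the input table; groups are not re-inferred
  after filtering, and a gene id present in two groups is rejected
  rather than reconciled.
* Zero-transcript contigs are reported but carry no signal; the contig
  rule is silent on unannotated sequence.
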