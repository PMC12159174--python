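# curanno

Post-annotation curation for automated gene predictions in microbial
eukaryote genomes (diatoms and similar algae with abundant bacterial
co-culture contamination and a documented history of horizontal gene
transfer).

Automated annotation pipelines such as BRAKER produce raw gene sets that
need downstream curation before release: assembled contigs may derive
from co-cultured bacteria rather than the target organism, genuinely
transferred genes must be separated from contamination artifacts, and
single-exon gene models are systematically overpredicted.  `curanno`
implements the corresponding decision rules as a tested library with a
CLI, and ships a synthetic-data generator that plants each situation
with machine-readable ground truth so every rule is validated end to end
without any external downloads.

## The rules

**Contig contamination.**  Each transcript *t* receives a contaminant
flag *c(t)* from its functional evidence: *c(t)* = 1 if the transcript's
similarity hit is to a microbial reference database, or if it has no
similarity hit and its gene-family assignments are exclusively
microbial.  For a contig with annotated transcripts T, the contig is
classified as potentially contaminated iff

&nbsp;&nbsp;&nbsp;&nbsp; (1/|T|) Σ<sub>t∈T</sub> c(t) **>** 0.75,

a strict inequality — exactly 75% is not flagged.  Every CDS of every
gene on a flagged contig receives a `Note=` in the output GFF3.

**HGT candidates.**  Using the longest isoform per gene as its
representative protein, a hit passes the alignment gate iff query
coverage ≥ 0.5, subject coverage ≥ 0.5, and E ≤ 10⁻⁵ (all inclusive).
A gene is an *initial* candidate iff it has a passing hit in the
microbial donor database while lacking one in the plant donor database
or in the recipient (related-lineage) database.  The genomic-context
filter then rejects candidates at a scaffold end, candidates with a
contaminant-flagged flanking gene, and candidates whose neighbour is
itself a candidate; survivors are tagged `hgt_candidate=true` on their
CDS lines.

**Single-exon filter.**  A gene is removed iff it is single-exon in
every isoform **and** has no functional annotation (product, similarity
hit, or gene-family assignment) **and** has no significant NR hit
(same thresholds as the HGT gate) **and** is not a member of an
orthogroup spanning ≥ 2 species.  Any one evidence channel rescues it.

**Statistics and QC.**  Per-annotation gene counts, mono:mult ratio,
median/max exon counts; orthogroup assignment rates, species-specific
group counts, and G50/O50 (the orthogroup size, and number of largest
orthogroups, at which half of a reference gene total is covered);
BUSCO-based keep/exclude decisions (low genome completeness, or
genome-vs-protein completeness discrepancy); assembly selection
(representative flag, else largest N50; ≤ 1000 annotated proteins
qualifies for annotation) and RNA-seq library filtering (alignment rate
≥ 20% kept).

## Worked example

Generate a small three-species fixture with planted truth, then curate it:

```sh
curanno simulate --seed 4 --outdir demo_fx --n-contigs 8 --genes-per-contig 15 \
    --n-hgt-true 2 --n-hgt-decoy-end 1 --n-hgt-decoy-neighbor 1 --n-junk 10
curanno run --fixture-dir demo_fx --outdir demo_out
head -4 demo_out/stats_before.tsv demo_out/stats_after.tsv
```

```
==> demo_out/stats_before.tsv <==
species	n_genes	n_tx	mono_mult_ratio	median_mult_exons	max_mult_exons
sp01	133	148	1.42	3	7
sp02	117	141	1.44	3	9
sp03	119	128	1.38	3	9

==> demo_out/stats_after.tsv <==
species	n_genes	n_tx	mono_mult_ratio	median_mult_exons	max_mult_exons
sp01	123	138	1.24	3	7
sp02	107	131	1.23	3	9
sp03	109	118	1.18	3	9
```

Ten evidence-free single-exon genes were removed per species (133 → 123
for sp01), so the mono:mult ratio drops from 1.42 to 1.24 while the
multi-exon gene count is untouched.  The per-contig report shows the one
planted contaminated contig of sp01 (24 of 25 transcripts flagged, 96% >
75%):

```
$ grep true demo_out/sp01.contigs.tsv
sp01_ctg001	25	24	0.9600	true
```

and the HGT report retains exactly the two mid-scaffold planted
transfers (microbial hit present, plant/recipient absent, clean
neighbours):

```
$ awk '$NF=="true"' demo_out/sp01.hgt.tsv
sp01_g000041	sp01_ctg003	true	false	false	true		true
sp01_g000083	sp01_ctg005	true	false	false	true		true
```

The same operations are available as library functions
(`curanno.classify_contigs`, `curanno.initial_candidates`,
`curanno.filter_single_exon`, `curanno.annotation_stats`, ...) on plain
dataclasses parsed from GFF3, tabular hit files (BLAST/DIAMOND outfmt 6
plus `qlen`/`slen`), functional-annotation TSVs and `Orthogroups.tsv`.

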