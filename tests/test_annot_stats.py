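"""Descriptive statistics, orthogroup summaries, QC and selection rules."""

import random
import statistics

import pytest

from curanno.annot_stats import (EXCLUDE_DISCREPANCY, EXCLUDE_LOW_GENOME, KEEP,
                                 AssemblyMeta, QcConfig, annotation_stats,
                                 busco_exclusion, filter_rnaseq_libraries,
                                 ortho_stats, select_assembly)
from curanno.evidence_io import BuscoSummary, OrthogroupTable
from curanno.gff_io import exon_count, longest_isoform

from conftest import mk_annotation, mk_gene, mk_tx


def _mono(gid, contig="c1", start=1):
    return mk_gene(gid, contig, [mk_tx(f"{gid}.t1", gid, [(start, start + 299)])])


def _multi(gid, n_exons, contig="c1", start=1):
    spans = [(start + 400 * i, start + 400 * i + 299) for i in range(n_exons)]
    return mk_gene(gid, contig, [mk_tx(f"{gid}.t1", gid, spans)])


def test_ratio_three_mono_two_multi():
    genes = [_mono(f"m{i}", start=1 + 1000 * i) for i in range(3)]
    genes += [_multi(f"x{i}", 3, start=50_000 + 5000 * i) for i in range(2)]
    stats = annotation_stats(mk_annotation(genes))
    assert stats.n_mono == 3 and stats.n_mult == 2
    assert stats.mono_mult_ratio == 1.5 and stats.n_genes == 5


def test_single_multi_exon_gene_median_and_max():
    stats = annotation_stats(mk_annotation([_multi("g", 7)]))
    assert stats.median_mult_exons == 7 and stats.max_mult_exons == 7
    assert stats.mono_mult_ratio == 0.0


def test_empty_annotation_is_hard_error():
    with pytest.raises(ValueError):
        annotation_stats(mk_annotation([]))


def test_annotation_stats_matches_brute_force_recount(small_bundle):
    """All five fields against an independent recount from raw CDS records."""
    for ann in small_bundle.annotations.values():
        stats = annotation_stats(ann)
        mono = [g for g in ann.genes.values()
                if all(exon_count(t) == 1 for t in g.transcripts)]
        mult = [g for g in ann.genes.values() if g not in mono]
        assert stats.n_genes == len(ann.genes)
        assert stats.n_tx == sum(len(g.transcripts) for g in ann.genes.values())
        assert stats.n_mono == len(mono) and stats.n_mult == len(mult)
        assert stats.mono_mult_ratio == len(mono) / len(mult)
        assert stats.median_mult_exons == statistics.median(
            [len(longest_isoform(g).cds_segments) for g in mult])
        assert stats.max_mult_exons == max(
            len(t.cds_segments) for g in ann.genes.values() for t in g.transcripts)


# --- orthogroup statistics -------------------------------------------------

def _og_brute_force(table, totals):
    """Independent recount used as the oracle for ortho_stats."""
    sizes = sorted(((sum(len(m) for m in row.values()), og)
                    for og, row in table.groups.items()), key=lambda t: (-t[0], t[1]))
    assigned_total = sum(s for s, _ in sizes)
    all_total = sum(totals[sp] for sp in table.species)

    def g50o50(ref):
        cum = 0
        for i, (s, _) in enumerate(sizes, 1):
            cum += s
            if ref > 0 and cum >= ref / 2:
                return s, i
        return (sizes[-1][0], len(sizes)) if sizes and ref > 0 else (0, 0)

    return {"g50_assigned": g50o50(assigned_total)[0],
            "o50_assigned": g50o50(assigned_total)[1],
            "g50_all": g50o50(all_total)[0],
            "o50_all": g50o50(all_total)[1],
            "n_specific": sum(1 for _, og in sizes
                              if sum(1 for m in table.groups[og].values() if m) == 1),
            "n_all": sum(1 for _, og in sizes
                         if all(table.groups[og].get(sp) for sp in table.species))}


def test_g50_o50_worked_example():
    table = OrthogroupTable(species=["A"], groups={
        f"OG{i}": {"A": [f"a{i}_{j}" for j in range(n)]}
        for i, n in enumerate([10, 5, 3, 2])})
    stats = ortho_stats(table, {"A": 20})
    # 20 assigned genes: the first group alone reaches 10 >= 10
    assert stats.o50_assigned == 1 and stats.g50_assigned == 10
    assert stats.mean_size == 5.0 and stats.median_size == 4.0


def test_one_group_holding_everything():
    table = OrthogroupTable(species=["A", "B"], groups={
        "OG0": {"A": ["a1", "a2"], "B": ["b1"]}})
    stats = ortho_stats(table, {"A": 2, "B": 1})
    assert stats.per_species_assigned_pct == {"A": 100.0, "B": 100.0}
    assert stats.o50_assigned == 1 and stats.n_all_species_groups == 1
    assert stats.n_species_specific_groups == 0


def test_missing_species_total_is_hard_error():
    table = OrthogroupTable(species=["A"], groups={"OG0": {"A": ["a1"]}})
    with pytest.raises(ValueError, match="missing"):
        ortho_stats(table, {})


def test_ortho_stats_matches_brute_force_on_random_tables():
    rng = random.Random(3)
    for trial in range(50):
        n_species = rng.randint(1, 4)
        species = [f"sp{k}" for k in range(n_species)]
        groups, counter = {}, 0
        for g in range(rng.randint(1, 30)):
            row = {}
            for sp in species:
                members = [f"{sp}_g{counter + j}" for j in range(rng.randint(0, 5))]
                counter += len(members)
                row[sp] = members
            if any(row.values()):
                groups[f"OG{g:04d}"] = row
        table = OrthogroupTable(species=species, groups=groups)
        assigned = {sp: sum(len(groups[og][sp]) for og in groups) for sp in species}
        totals = {sp: assigned[sp] + rng.randint(0, 10) for sp in species}
        stats = ortho_stats(table, totals)
        oracle = _og_brute_force(table, totals)
        assert stats.g50_assigned == oracle["g50_assigned"]
        assert stats.o50_assigned == oracle["o50_assigned"]
        assert stats.g50_all == oracle["g50_all"]
        assert stats.o50_all == oracle["o50_all"]
        assert stats.n_species_specific_groups == oracle["n_specific"]
        assert stats.n_all_species_groups == oracle["n_all"]
        for sp in species:
            assert stats.per_species_assigned_pct[sp] == pytest.approx(
                100 * assigned[sp] / totals[sp] if totals[sp] else 0.0)


def test_o50_minimality_property(small_bundle):
    totals = {sp: small_bundle.annotations[sp].n_genes
              for sp in small_bundle.og_table.species}
    stats = ortho_stats(small_bundle.og_table, totals)
    sizes = sorted((small_bundle.og_table.group_size(og)
                    for og in small_bundle.og_table.groups), reverse=True)
    assigned = sum(sizes)
    assert sum(sizes[:stats.o50_assigned]) >= assigned / 2
    assert sum(sizes[:stats.o50_assigned - 1]) < assigned / 2


# --- QC and selection ------------------------------------------------------

def _busco(c, s=None, d=0.0):
    s = c if s is None else s
    return BuscoSummary(c, s, d, 0.0, round(100 - c, 1))


@pytest.mark.parametrize("genome, protein, expected", [
    (95.0, 72.0, EXCLUDE_DISCREPANCY),
    (15.0, 15.0, EXCLUDE_LOW_GENOME),
    (56.0, 56.0, EXCLUDE_LOW_GENOME),
    (98.0, 97.0, KEEP),
])
def test_busco_exclusion_decisions(genome, protein, expected):
    assert busco_exclusion(_busco(genome), _busco(protein), QcConfig()) == expected


def test_representative_assembly_beats_larger_n50():
    a = AssemblyMeta("GCA_1", "sp", representative=False, n50=500_000,
                     n_annotated_proteins=0)
    b = AssemblyMeta("GCA_2", "sp", representative=True, n50=100_000,
                     n_annotated_proteins=0)
    for order in ([a, b], [b, a]):
        chosen, _ = select_assembly(order)
        assert chosen is b


def test_largest_n50_without_representative_and_protein_boundary():
    a = AssemblyMeta("GCA_1", "sp", False, 200_000, 1000)
    b = AssemblyMeta("GCA_2", "sp", False, 900_000, 1001)
    chosen, candidate = select_assembly([a, b])
    assert chosen is b and candidate is False  # 1001 proteins: already annotated
    chosen, candidate = select_assembly([a])
    assert candidate is True  # exactly 1000 still qualifies


def test_select_assembly_empty_is_hard_error():
    with pytest.raises(ValueError):
        select_assembly([])


def test_rnaseq_rate_boundary():
    kept = filter_rnaseq_libraries({"keep": 0.20, "drop": 0.19, "good": 0.95})
    assert kept == ["good", "keep"]
    assert filter_rnaseq_libraries({}) == []
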