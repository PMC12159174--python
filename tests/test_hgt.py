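"""HGT candidate calling: alignment gate, absence rules, context filter."""

import itertools

import pytest

from curanno.evidence_io import EvidenceError
from curanno.hgt import (HgtConfig, context_filter, hgt_decoration, hit_passes,
                         initial_candidates, representative_queries)

from conftest import mk_annotation, mk_gene, mk_hit, mk_tx


# --- alignment gate --------------------------------------------------------

def test_query_coverage_exactly_half_passes():
    hit = mk_hit(qstart=1, qend=50, qlen=100, sstart=1, send=60, slen=100,
                 evalue=1e-10)
    assert hit_passes(hit)


def test_evalue_exactly_at_cutoff_passes_and_just_above_fails():
    assert hit_passes(mk_hit(evalue=1e-5))
    assert not hit_passes(mk_hit(evalue=1e-4))


def test_full_length_self_hit_passes():
    assert hit_passes(mk_hit(evalue=0.0))


def test_subject_coverage_below_half_fails():
    assert not hit_passes(mk_hit(sstart=1, send=49, slen=100))


def test_hit_invariants_rejected_at_construction():
    with pytest.raises(EvidenceError):
        mk_hit(qstart=10, qend=5)
    with pytest.raises(EvidenceError):
        mk_hit(qend=200, qlen=100)
    with pytest.raises(EvidenceError):
        mk_hit(evalue=-1.0)


# --- initial candidates ----------------------------------------------------

def _presence_verdict(microbial, plant, recipient, rule):
    hits_by_db = {"microbial_donor": [], "plant_donor": [], "recipient": []}
    if microbial:
        hits_by_db["microbial_donor"].append(mk_hit(query="g1.t1", db_tag="microbial_donor"))
    if plant:
        hits_by_db["plant_donor"].append(mk_hit(query="g1.t1", db_tag="plant_donor"))
    if recipient:
        hits_by_db["recipient"].append(mk_hit(query="g1.t1", db_tag="recipient"))
    verdicts = initial_candidates(["g1"], hits_by_db, {"g1.t1": "g1"},
                                  HgtConfig(absence_rule=rule))
    return verdicts["g1"]


@pytest.mark.parametrize("rule", ["any_absent", "both_absent"])
@pytest.mark.parametrize("microbial,plant,recipient",
                         list(itertools.product([False, True], repeat=3)))
def test_initial_candidate_truth_table(microbial, plant, recipient, rule):
    """All 8 presence combinations against the hand-enumerated rule."""
    if rule == "any_absent":
        expected = microbial and (not plant or not recipient)
    else:
        expected = microbial and not plant and not recipient
    verdict = _presence_verdict(microbial, plant, recipient, rule)
    assert verdict.initial_candidate is expected
    assert (verdict.has_microbial, verdict.has_plant, verdict.has_recipient) == \
        (microbial, plant, recipient)


def test_failing_hits_do_not_count_as_presence():
    hits = {"microbial_donor": [mk_hit(query="g1.t1", db_tag="microbial_donor",
                                       evalue=1e-3)]}
    verdict = initial_candidates(["g1"], hits, {"g1.t1": "g1"})["g1"]
    assert not verdict.has_microbial and not verdict.initial_candidate


def test_unknown_query_hits_are_ignored_with_warning(caplog):
    hits = {"microbial_donor": [mk_hit(query="ghost.t1", db_tag="microbial_donor")]}
    with caplog.at_level("WARNING"):
        verdicts = initial_candidates(["g1"], hits, {"g1.t1": "g1"})
    assert not verdicts["g1"].initial_candidate
    assert any("ghost" in r.message for r in caplog.records)


def test_tightening_thresholds_never_adds_candidates():
    queries = [f"g{i}.t1" for i in range(30)]
    hits = {"microbial_donor": [
        mk_hit(query=q, db_tag="microbial_donor", qstart=1, qend=40 + 2 * i,
               evalue=10.0 ** -(i + 1)) for i, q in enumerate(queries)]}
    q2g = {q: q[:-3] for q in queries}
    genes = list(q2g.values())
    loose = {g for g, v in initial_candidates(
        genes, hits, q2g, HgtConfig(min_query_cov=0.4, max_evalue=1e-3)).items()
        if v.initial_candidate}
    tight = {g for g, v in initial_candidates(
        genes, hits, q2g, HgtConfig(min_query_cov=0.6, max_evalue=1e-8)).items()
        if v.initial_candidate}
    assert tight <= loose


# --- context filter --------------------------------------------------------

def _chain(n, contig="c1"):
    genes = []
    for i in range(n):
        gid = f"g{i}"
        start = 1000 * (i + 1)
        genes.append(mk_gene(gid, contig, [mk_tx(f"{gid}.t1", gid,
                                                 [(start, start + 299)])]))
    return genes


def _run_context(candidate_ids, n=5, contaminated_tx=()):
    genes = _chain(n)
    ann = mk_annotation(genes)
    hits = {"microbial_donor": [mk_hit(query=f"{g}.t1", db_tag="microbial_donor")
                                for g in candidate_ids]}
    verdicts = initial_candidates([g.id for g in genes], hits,
                                  representative_queries(ann))
    flags = {tx.id: tx.id in contaminated_tx for tx in ann.transcripts()}
    return context_filter(verdicts, ann, flags)


def test_candidate_at_scaffold_start_rejected_as_no_upstream():
    done = _run_context(["g0"])
    assert not done["g0"].final_candidate
    assert done["g0"].rejection_reason == "no_upstream_neighbor"


def test_candidate_at_scaffold_end_rejected_as_no_downstream():
    done = _run_context(["g4"])
    assert done["g4"].rejection_reason == "no_downstream_neighbor"


def test_mid_scaffold_candidate_with_clean_neighbors_is_final():
    done = _run_context(["g2"])
    assert done["g2"].final_candidate and done["g2"].rejection_reason is None


def test_contaminant_neighbor_rejects_candidate():
    done = _run_context(["g2"], contaminated_tx={"g3.t1"})
    assert done["g2"].rejection_reason == "neighbor_contaminant"
    done = _run_context(["g2"], contaminated_tx={"g1.t1"})
    assert done["g2"].rejection_reason == "neighbor_contaminant"


def test_candidate_neighbor_rejects_candidate_as_not_native():
    done = _run_context(["g2", "g3"])
    assert done["g2"].rejection_reason == "neighbor_not_native"
    assert done["g3"].rejection_reason == "neighbor_not_native"


def test_final_subset_of_initial_and_decoration_matches(small_bundle):
    from curanno.contamination import flag_transcripts
    flags = flag_transcripts(small_bundle.records)
    q2g = {}
    for ann in small_bundle.annotations.values():
        q2g.update(representative_queries(ann))
    for ann in small_bundle.annotations.values():
        verdicts = initial_candidates(sorted(ann.genes), small_bundle.hits_by_db, q2g)
        done = context_filter(verdicts, ann, flags)
        final = {g for g, v in done.items() if v.final_candidate}
        initial = {g for g, v in done.items() if v.initial_candidate}
        assert final <= initial
        # genes at scaffold ends are never final
        from curanno.gff_io import gene_order
        for contig in ann.contigs:
            ordered = gene_order(ann, contig)
            if ordered:
                assert ordered[0].id not in final and ordered[-1].id not in final
        assert hgt_decoration(done).hgt_tags == final


def test_planted_hgt_recovery_with_expected_reasons(small_bundle):
    from curanno.contamination import flag_transcripts
    flags = flag_transcripts(small_bundle.records)
    q2g = {}
    for ann in small_bundle.annotations.values():
        q2g.update(representative_queries(ann))
    final, reasons = set(), {}
    for ann in small_bundle.annotations.values():
        done = context_filter(
            initial_candidates(sorted(ann.genes), small_bundle.hits_by_db, q2g),
            ann, flags)
        final |= {g for g, v in done.items() if v.final_candidate}
        reasons.update({g: v.rejection_reason for g, v in done.items()
                        if g in small_bundle.truth.hgt_decoys})
    assert final == small_bundle.truth.hgt_true
    assert reasons == small_bundle.truth.hgt_decoys
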