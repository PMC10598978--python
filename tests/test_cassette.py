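"""Cassette rules: positives filter boundaries, best-hit-per-locus, the
+/-500 bp architecture rule, window extraction and synteny comparison."""

import pytest

from cassette_scan.cassette import (
    CassetteCall,
    ReferenceCluster,
    best_hit_per_locus,
    call_cassette,
    compare_clusters,
    extract_window,
    filter_hits,
    read_reference_cluster,
    write_reference_cluster,
)
from cassette_scan.search import search_translated
from cassette_scan.seqio import Contig, reverse_complement
from cassette_scan.simulate import reference_cluster

from conftest import make_hit

REF = reference_cluster()  # mr10E..H at gaps 40/20/30, all '+'


def hits_at_reference(genome="g1", contig="c1", shift=0, **overrides):
    """One hit per reference gene at the reference coordinates (+shift)."""
    hits = []
    for gene, strand, start, end in REF.loci:
        kw = dict(query_id=f"{gene}_ref", query_family=gene, genome_id=genome,
                  contig_id=contig, subject_start=start + shift,
                  subject_end=end + shift, strand=strand,
                  alignment_length=(end - start) // 3)
        kw.update(overrides.get(gene, {}))
        hits.append(make_hit(**kw))
    return hits


class TestFilter:
    @pytest.mark.parametrize(
        "identity,coverage,ev,kept",
        [
            (40.0, 90.0, 1e-30, False),  # exactly 40% identity: strictly more-than
            (80.0, 70.0, 1e-30, False),  # exactly 70% coverage: strictly more-than
            (40.01, 70.01, 1e-6, True),  # just above both, threshold E inclusive
            (99.0, 99.0, 1e-30, True),
            (99.0, 99.0, 2e-6, False),  # E-value above threshold
        ],
    )
    def test_boundaries(self, identity, coverage, ev, kept):
        hit = make_hit(percent_identity=identity, query_coverage=coverage, evalue=ev)
        assert bool(filter_hits([hit])) is kept


class TestBestHitPerLocus:
    def test_highest_identity_wins_on_overlap(self):
        a = make_hit(query_id="qa", subject_start=0, subject_end=300, percent_identity=80)
        b = make_hit(query_id="qb", subject_start=200, subject_end=500, percent_identity=75)
        assert best_hit_per_locus([a, b]) == [a]

    def test_non_overlapping_both_kept(self):
        a = make_hit(query_id="qa", subject_start=0, subject_end=300)
        b = make_hit(query_id="qb", subject_start=300, subject_end=600)
        assert len(best_hit_per_locus([a, b])) == 2

    def test_transitive_overlap_forms_one_locus(self):
        a = make_hit(query_id="qa", subject_start=0, subject_end=300, percent_identity=70)
        b = make_hit(query_id="qb", subject_start=250, subject_end=600, percent_identity=71)
        c = make_hit(query_id="qc", subject_start=550, subject_end=900, percent_identity=72)
        assert best_hit_per_locus([a, b, c]) == [c]

    def test_full_tie_breaks_to_smallest_query_id(self):
        a = make_hit(query_id="qb", subject_start=0, subject_end=300)
        b = make_hit(query_id="qa", subject_start=100, subject_end=400)
        assert best_hit_per_locus([a, b]) == [b]


class TestCallCassette:
    def test_reference_spacing_is_complete(self):
        call = call_cassette(hits_at_reference(), REF, "g1")
        assert call.status == "complete"
        assert call.orientation == "forward"

    def test_gap_beyond_tolerance_is_partial(self):
        # widen the F->G gap by 501 bp: shift G and H right together
        over = {g: {"subject_start": s + 501, "subject_end": e + 501}
                for g, _, s, e in REF.loci[2:]}
        hits = hits_at_reference(**over)
        assert call_cassette(hits, REF, "g1").status == "partial"

    def test_gap_at_tolerance_is_complete(self):
        over = {g: {"subject_start": s + 500, "subject_end": e + 500}
                for g, _, s, e in REF.loci[2:]}
        assert call_cassette(hits_at_reference(**over), REF, "g1").status == "complete"

    def test_single_component_is_partial(self):
        g, strand, s, e = REF.loci[2]
        hit = make_hit(query_family=g, subject_start=s, subject_end=e, strand=strand)
        call = call_cassette([hit], REF, "g1")
        assert call.status == "partial" and call.n_components == 1

    def test_no_hits_is_absent(self):
        assert call_cassette([], REF, "g1").status == "absent"

    def test_full_reversal_is_complete(self):
        total = 5000
        hits = []
        for gene, strand, start, end in REF.loci:
            hits.append(make_hit(query_family=gene, subject_start=total - end,
                                 subject_end=total - start, strand="-",
                                 alignment_length=(end - start) // 3))
        call = call_cassette(hits, REF, "g1")
        assert call.status == "complete" and call.orientation == "reverse"

    def test_internal_single_gene_inversion_never_complete(self):
        over = {"mr10F": {"strand": "-"}}
        assert call_cassette(hits_at_reference(**over), REF, "g1").status == "partial"

    def test_shuffled_gene_order_not_complete(self):
        # swap E and F positions
        (e, _, es, ee), (f, _, fs, fe) = REF.loci[0], REF.loci[1]
        over = {e: {"subject_start": fs, "subject_end": fs + (ee - es)},
                f: {"subject_start": es, "subject_end": es + (fe - fs)}}
        assert call_cassette(hits_at_reference(**over), REF, "g1").status == "partial"

    def test_split_across_contigs_reports_majority_contig(self):
        hits = hits_at_reference()
        hits[3] = make_hit(query_family="mr10H", contig_id="c2",
                           subject_start=100, subject_end=700)
        call = call_cassette(hits, REF, "g1")
        assert call.status == "partial"
        assert call.contig_id == "c1" and call.n_components == 3

    def test_tolerance_monotonicity(self):
        """Relaxing tolerance never demotes; tightening never promotes."""
        over = {g: {"subject_start": s + 300, "subject_end": e + 300}
                for g, _, s, e in REF.loci[1:]}
        hits = hits_at_reference(**over)
        statuses = {}
        for tol in (100, 300, 600):
            ref = ReferenceCluster(REF.cluster_id, REF.loci, tolerance_bp=tol)
            statuses[tol] = call_cassette(hits, ref, "g1").status
        assert statuses == {100: "partial", 300: "complete", 600: "complete"}

    def test_reverse_complement_invariance_end_to_end(self, noiseless_dataset):
        """Reverse-complementing a whole contig leaves the call unchanged."""
        data = noiseless_dataset
        t = next(t for t in data.truth if t.status == "complete")
        contig = next(c for c in data.contigs if c.genome_id == t.genome_id)
        flipped = Contig(contig.contig_id, contig.genome_id,
                         reverse_complement(contig.sequence))
        for subject in (contig, flipped):
            hits = search_translated(data.queries, [subject])
            call = call_cassette(filter_hits(hits), data.reference, t.genome_id)
            assert call.status == "complete"


class TestReferenceIO:
    def test_round_trip(self, tmp_path):
        write_reference_cluster(REF, tmp_path / "ref.tsv")
        back = read_reference_cluster(tmp_path / "ref.tsv")
        assert back.loci == REF.loci and back.cluster_id == REF.cluster_id

    def test_overlapping_loci_rejected(self):
        with pytest.raises(ValueError):
            ReferenceCluster("x", (("a", "+", 0, 100), ("b", "+", 50, 150)))


class TestWindow:
    def _call(self, span_lo, span_hi, contig_len):
        hit = make_hit(subject_start=span_lo, subject_end=span_hi)
        return CassetteCall("g1", "c1", "partial", {"mr10E": hit}, "n/a")

    def test_centred_window_with_flanks(self):
        contig = Contig("c1", "g1", "A" * 50_000)
        call = self._call(23_000, 27_000, 50_000)
        window, coords = extract_window(contig, call, window_bp=10_000)
        assert len(window) == 10_000
        assert coords["mr10E"] == (3_000, 7_000, "+")

    def test_truncated_at_contig_start(self):
        contig = Contig("c1", "g1", "A" * 50_000)
        call = self._call(200, 2_900, 50_000)
        window, _ = extract_window(contig, call, window_bp=10_000)
        assert window.contig_id.endswith(":0-6550")
        assert len(window) < 10_000

    def test_absent_call_errors(self):
        contig = Contig("c1", "g1", "A" * 1000)
        call = CassetteCall("g1", None, "absent", {}, "n/a")
        with pytest.raises(ValueError):
            extract_window(contig, call)


class TestCompareClusters:
    def test_window_vs_itself_all_identity_100(self, noiseless_dataset):
        data = noiseless_dataset
        t = next(t for t in data.truth if t.status == "complete")
        contig = next(c for c in data.contigs if c.genome_id == t.genome_id)
        hits = search_translated(data.queries, [contig])
        call = call_cassette(filter_hits(hits), data.reference, t.genome_id)
        window = extract_window(contig, call)
        table = compare_clusters(window, window)
        assert set(table["family"]) == set(REF.gene_order)
        assert (table["percent_identity"] == 100.0).all()

    def test_disjoint_family_sets_all_unmatched(self):
        wa = (Contig("a", "g", "ATG" * 200), {"mr10E": (0, 30, "+")})
        wb = (Contig("b", "g", "ATG" * 200), {"mr10F": (0, 30, "+")})
        table = compare_clusters(wa, wb)
        assert (table["status"] == "unmatched").all()
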