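"""Chiastic junction calling and plant-specific screening."""

import numpy as np
import pytest

from backsplice.detect import (BackspliceCandidate, DetectionConfig,
                               SIGNAL_PRIORITY, adjust_backsplice_site,
                               aggregate_and_filter, annotation_boundary_snap,
                               check_splice_signal, chiastic_candidate,
                               classify_circ_type, paired_end_consistent)
from backsplice.io import (AlignmentSegment, GeneModel, GenomeSequence,
                           SplitReadAlignment, Transcript, revcomp)


def seg(read_start, read_end, chrom, ref_start, ref_end, strand="+",
        mismatches=0, score=None):
    if score is None:
        score = float(read_end - read_start + 1)
    return AlignmentSegment(read_start, read_end, chrom, ref_start, ref_end,
                            strand, mismatches, score)


def split_read(segments, rid="r1", mate=0, length=100):
    return SplitReadAlignment(rid, mate, list(segments), length)


def cand(chrom="c1", start=200, end=1049, strand="+", reads=("r1", "r2")):
    return BackspliceCandidate(chrom=chrom, start=start, end=end,
                               strand=strand, read_ids=list(reads))


class TestChiasticCandidate:
    def test_plus_strand_chiastic(self):
        sr = split_read([seg(1, 50, "c1", 1000, 1049),
                         seg(51, 100, "c1", 200, 249)])
        c = chiastic_candidate(sr)
        assert (c.chrom, c.start, c.end, c.strand) == ("c1", 200, 1049, "+")
        assert c.read_ids == ["r1"]

    def test_colinear_split_is_linear_junction(self):
        sr = split_read([seg(1, 50, "c1", 200, 249),
                         seg(51, 100, "c1", 1000, 1049)])
        assert chiastic_candidate(sr) is None

    def test_cross_chromosome_excluded(self):
        sr = split_read([seg(1, 50, "c1", 1000, 1049),
                         seg(51, 100, "c2", 200, 249)])
        assert chiastic_candidate(sr) is None

    def test_opposite_strand_segments_excluded(self):
        sr = split_read([seg(1, 50, "c1", 1000, 1049, "+"),
                         seg(51, 100, "c1", 200, 249, "-")])
        assert chiastic_candidate(sr) is None

    def test_minus_strand_mirror(self):
        # earlier-in-read part upstream => chiastic on the - strand
        sr = split_read([seg(1, 50, "c1", 200, 249, "-"),
                         seg(51, 100, "c1", 1000, 1049, "-")])
        c = chiastic_candidate(sr)
        assert (c.start, c.end, c.strand) == (200, 1049, "-")

    def test_segment_thresholds_respected(self):
        bad = split_read([seg(1, 50, "c1", 1000, 1049, mismatches=3),
                          seg(51, 100, "c1", 200, 249)])
        assert chiastic_candidate(bad) is None
        low_score = split_read([seg(1, 50, "c1", 1000, 1049, score=30.0),
                                seg(51, 100, "c1", 200, 249)])
        assert chiastic_candidate(low_score) is None

    def test_strand_symmetry(self):
        """Reverse complementing the genome (mirroring coordinates) and
        flipping segment strands yields the mirrored candidate."""
        L = 2000
        sr_plus = split_read([seg(1, 50, "c1", 1000, 1049, "+"),
                              seg(51, 100, "c1", 200, 249, "+")])
        c_plus = chiastic_candidate(sr_plus)
        mirror = lambda s, e: (L - e + 1, L - s + 1)
        sr_minus = split_read([
            seg(1, 50, "c1", *mirror(1000, 1049), "-"),
            seg(51, 100, "c1", *mirror(200, 249), "-")])
        c_minus = chiastic_candidate(sr_minus)
        assert (c_minus.start, c_minus.end) == mirror(c_plus.start, c_plus.end)
        assert c_minus.strand == "-"


class TestSpliceSignal:
    def _genome_with_signal(self, donor, acceptor, start=11, end=20):
        # acceptor dinucleotide ends at start-1; donor starts at end+1
        seq = "T" * (start - 3) + acceptor + "C" * (end - start + 1) \
            + donor + "T" * 6
        return GenomeSequence({"c1": seq})

    @pytest.mark.parametrize("donor,acceptor,expected", [
        ("GT", "AG", "GT-AG"), ("GC", "AG", "GC-AG"),
        ("AT", "AC", "AT-AC"), ("TT", "CC", "none"),
    ])
    def test_plus_strand_classes(self, donor, acceptor, expected):
        g = self._genome_with_signal(donor, acceptor)
        c = cand(start=11, end=20)
        assert check_splice_signal(g, c) == expected

    @pytest.mark.parametrize("donor,acceptor", [
        ("GT", "AG"), ("GC", "AG"), ("AT", "AC")])
    def test_minus_strand_equals_mirrored_plus(self, donor, acceptor):
        g = self._genome_with_signal(donor, acceptor)
        plus_class = check_splice_signal(g, cand(start=11, end=20))
        L = g.length("c1")
        g_rc = GenomeSequence({"c1": revcomp(g["c1"])})
        c_minus = cand(start=L - 20 + 1, end=L - 11 + 1, strand="-")
        assert check_splice_signal(g_rc, c_minus) == plus_class

    def test_chromosome_edge_gives_none(self):
        g = GenomeSequence({"c1": "ACGTACGTAC"})
        assert check_splice_signal(g, cand(start=1, end=8)) == "none"
        assert check_splice_signal(g, cand(start=3, end=10)) == "none"


class TestSiteAdjustment:
    def _fixture(self):
        """GT-AG present only at donor offset +2 for circle 21-40: poly-C
        background cannot form any other donor/acceptor dinucleotide."""
        s = list("C" * 80)
        s[18:20] = "AG"      # acceptor side for start=21 (pos 19-20)
        s[42:44] = "GT"      # donor side for end+2=42 (pos 43-44)
        g = GenomeSequence({"c1": "".join(s)})
        c = cand(start=21, end=40)
        assert check_splice_signal(g, c) == "none"
        return g, c

    def test_shift_found_and_matches_exhaustive_scan(self):
        g, c = self._fixture()
        adj = adjust_backsplice_site(g, c)
        assert (adj.signal, adj.acceptor_offset, adj.donor_offset) == \
            ("GT-AG", 0, 2)
        assert (adj.start, adj.end) == (21, 42)
        # independent oracle: scan all 121 offset pairs, apply stated order
        hits = []
        for da in range(-5, 6):
            for dd in range(-5, 6):
                sig = check_splice_signal(g, c, da, dd)
                if sig != "none":
                    hits.append((abs(da) + abs(dd),
                                 SIGNAL_PRIORITY.index(sig), abs(dd), da, dd,
                                 sig))
        best = min(hits)
        assert (best[3], best[4], best[5]) == \
            (adj.acceptor_offset, adj.donor_offset, adj.signal)

    def test_signal_at_origin_keeps_coordinates(self):
        g = GenomeSequence(
            {"c1": "T" * 8 + "AG" + "C" * 10 + "GT" + "T" * 6})
        c = cand(start=11, end=20)
        adj = adjust_backsplice_site(g, c)
        assert (adj.start, adj.end) == (11, 20)
        assert adj.signal == "GT-AG"

    def test_no_signal_anywhere_unchanged(self):
        g = GenomeSequence({"c1": "C" * 80})
        c = cand(start=21, end=40)
        adj = adjust_backsplice_site(g, c)
        assert (adj.start, adj.end, adj.signal) == (21, 40, "none")


class TestPairedEndConsistency:
    def test_mate_inside_circle(self):
        c = cand(start=200, end=1049)
        assert paired_end_consistent(c, [seg(1, 100, "c1", 500, 599)])

    def test_mate_far_downstream(self):
        c = cand(start=200, end=1049)
        assert not paired_end_consistent(c, [seg(1, 100, "c1", 11000, 11099)])

    def test_single_end_vacuous(self):
        assert paired_end_consistent(cand(), None)
        assert paired_end_consistent(cand(), [])


class TestAggregateFilter:
    def test_span_above_max_removed(self):
        c = cand(start=1000, end=151_000, reads=("r1", "r2", "r3"))
        assert aggregate_and_filter([c]) == []

    def test_long_span_kept_and_flagged(self):
        c = cand(start=1000, end=25_999, reads=("r1", "r2", "r3"))
        (out,) = aggregate_and_filter([c])
        assert out.span == 25_000
        assert "long" in out.flags

    def test_min_reads_enforced(self):
        c = cand(reads=("r1",))
        assert aggregate_and_filter([c]) == []

    def test_reads_pooled_by_key(self):
        a = cand(reads=("r1",))
        b = cand(reads=("r2",))
        (out,) = aggregate_and_filter([a, b])
        assert out.read_ids == ["r1", "r2"]

    def test_paired_consistency_requires_one_supporting_read(self):
        c = cand(reads=("r1", "r2"))
        assert aggregate_and_filter([c], consistent_reads=set()) == []
        assert len(aggregate_and_filter([c], consistent_reads={"r2"})) == 1

    def test_monotone_in_min_reads(self):
        rng = np.random.default_rng(0)
        cands = [cand(start=int(s), end=int(s) + 500,
                      reads=tuple(f"r{i}" for i in range(rng.integers(1, 6))))
                 for s in rng.integers(100, 5000, size=30)]
        prev = None
        for k in range(1, 7):
            cfg = DetectionConfig(min_junction_reads=k)
            keys = {c.key for c in aggregate_and_filter(cands, cfg)}
            if prev is not None:
                assert keys <= prev
            prev = keys

    def test_outputs_satisfy_span_invariants(self):
        rng = np.random.default_rng(1)
        cands = [cand(start=int(s), end=int(s + d),
                      reads=("r1", "r2"))
                 for s, d in zip(rng.integers(100, 10_000, 50),
                                 rng.integers(50, 150_000, 50))]
        for c in aggregate_and_filter(cands):
            assert c.start < c.end
            assert c.span <= DetectionConfig().max_length


class TestCircType:
    def test_exonic_intronic_intergenic(self, toy_gene):
        ann = [toy_gene]
        assert classify_circ_type(cand(start=301, end=700), ann) == "exonic"
        assert classify_circ_type(cand(start=103, end=698), ann) == "exonic"  # +-5
        assert classify_circ_type(cand(start=210, end=290), ann) == "intronic"
        assert classify_circ_type(cand(start=1500, end=1900), ann) == \
            "intergenic"

    def test_no_annotation_flags(self):
        c = cand()
        assert classify_circ_type(c, None) == "intergenic"
        assert "no-annotation" in c.flags


class TestAnnotationSnap:
    def test_snaps_to_matching_exon_boundaries(self, toy_gene):
        c = cand(start=303, end=698, strand="+")
        snapped = annotation_boundary_snap(c, [toy_gene])
        assert (snapped.start, snapped.end) == (301, 700)
        assert "annotation-snapped" in snapped.flags

    def test_no_match_returns_none(self, toy_gene):
        assert annotation_boundary_snap(cand(start=1500, end=1800),
                                        [toy_gene]) is None
        minus = cand(start=301, end=700, strand="-")
        assert annotation_boundary_snap(minus, [toy_gene]) is None
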