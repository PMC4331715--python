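"""Clustering, segment derivation, and segment-vector mapping."""

import pytest

from conftest import aln, make_locus
from ispasm.segmentation import (
    SegmentVectorRead,
    cluster_alignments,
    derive_segments,
    load_segment_vectors,
    to_segment_vector,
    vectorize_cluster,
    write_segment_vectors,
)
from ispasm.simulate import SimConfig, simulate_dataset


class TestClustering:
    def test_distant_reads_split_into_two_loci(self):
        a = aln(0, 75, read_id="a")
        b = aln(10_000, 75, read_id="b")
        assert len(cluster_alignments([[a, b]], max_gap=500)) == 2

    def test_singleton(self):
        a = aln(100, 75)
        clusters = cluster_alignments([[a]])
        assert clusters == [[a]]

    def test_tiling_reads_form_one_locus(self):
        reads = [aln(i * 50, 75, read_id=f"r{i}") for i in range(100)]
        clusters = cluster_alignments([reads], max_gap=200)
        assert len(clusters) == 1
        # brute-force check: union of footprints has no gap >= 200
        spans = sorted((a.start, a.end) for a in reads)
        merged_end = spans[0][1]
        for s, e in spans[1:]:
            assert s - merged_end < 200
            merged_end = max(merged_end, e)

    def test_junction_read_bridges_its_intron(self):
        # footprint includes the N gap, so a spliced read holds a
        # two-exon gene together even with an uncovered 400 bp intron
        j = aln(0, 75, 400, 75, read_id="j")
        clusters = cluster_alignments([[j]], max_gap=200)
        assert len(clusters) == 1

    def test_unsorted_input_is_an_error(self):
        a = aln(1000, 75, read_id="a")
        b = aln(0, 75, read_id="b")
        with pytest.raises(ValueError, match="sorted"):
            cluster_alignments([[a, b]])

    def test_empty_input(self):
        assert cluster_alignments([[], []]) == []

    def test_sample_order_invariance(self):
        s0 = [aln(0, 75, sample=0), aln(300, 75, sample=0, read_id="q")]
        s1 = [aln(150, 75, sample=1)]
        c1 = cluster_alignments([s0, s1])
        c2 = cluster_alignments([s1, s0])
        assert [[(a.start, a.end) for a in c] for c in c1] == [
            [(a.start, a.end) for a in c] for c in c2
        ]


class TestDeriveSegments:
    def test_junction_partitions_covered_exon(self):
        # junction at (100, 200) inside covered [0, 300): the intron is
        # also covered (retention-style), giving three segments
        cover = [aln(i, 75, read_id=f"c{i}") for i in range(0, 226, 25)]
        junc = aln(50, 50, 100, 75, read_id="j")
        segs = derive_segments(cover + [junc])
        bounds = [(s.start, s.end) for s in segs]
        assert bounds == [(0, 100), (100, 200), (200, 300)]

    def test_uncovered_intron_is_not_a_segment(self):
        left = aln(0, 100, read_id="l")
        right = aln(200, 100, read_id="r")
        junc = aln(60, 40, 100, 40, read_id="j")
        segs = derive_segments([left, right, junc])
        assert [(s.start, s.end) for s in segs] == [(0, 100), (200, 300)]

    def test_single_covered_interval_single_segment(self):
        segs = derive_segments([aln(10, 75), aln(50, 75, read_id="b")])
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (10, 125)

    def test_alternative_exons_yield_three_plus_segments(self):
        # isoform A: exon1 -> exon2a; isoform B: exon1 -> exon2b
        a1 = aln(0, 100, read_id="a1")
        a2 = aln(60, 40, 100, 80, read_id="a2")   # junction 100 -> 200
        b2 = aln(60, 40, 250, 80, read_id="b2")   # junction 100 -> 350
        cov2a = aln(200, 80, read_id="c2a")
        cov2b = aln(350, 80, read_id="c2b")
        segs = derive_segments([a1, a2, b2, cov2a, cov2b])
        assert len(segs) >= 3
        starts = [s.start for s in segs]
        assert starts == sorted(starts)

    def test_zero_coverage_is_an_error(self):
        with pytest.raises(ValueError):
            derive_segments([])

    def test_annotation_boundaries_are_unioned(self):
        cover = [aln(i, 75, read_id=f"c{i}") for i in range(0, 226, 25)]
        segs = derive_segments(cover, annotation_exons=[(0, 150), (150, 300)])
        assert [(s.start, s.end) for s in segs] == [(0, 150), (150, 300)]


class TestSegmentVectors:
    def setup_method(self):
        self.locus = make_locus([(0, 100), (100, 200), (300, 400)])

    def test_contained_read(self):
        assert to_segment_vector(aln(120, 50), self.locus.segments) == (2,)

    def test_junction_read_skips_segment(self):
        locus = make_locus([(0, 100), (150, 250), (300, 400)])
        v = to_segment_vector(aln(60, 40, 200, 40), locus.segments)
        assert v == (1, 3)

    def test_boundary_crossing_read(self):
        v = to_segment_vector(aln(80, 40), self.locus.segments)
        assert v == (1, 2)

    def test_mismatched_junction_is_unassignable(self):
        # splice coordinates 2 bp off every segment edge
        v = to_segment_vector(aln(60, 38, 202, 40), self.locus.segments)
        assert v is None

    def test_unassignable_reads_are_counted_not_fatal(self):
        good = aln(10, 50, read_id="g")
        bad = aln(60, 38, 202, 40, read_id="b")
        reads, dropped = vectorize_cluster([good, bad], self.locus.segments)
        assert dropped == 1
        assert [r.vector for r in reads] == [(1,)]


def test_simulated_reads_round_trip_cleanly(tmp_path):
    """With zero noise every simulated alignment maps onto segments."""
    cfg = SimConfig(n_samples=2, reads_per_sample=300, error_rate=0.0, seed=5)
    sim = simulate_dataset([1, 2], cfg)
    clusters = cluster_alignments(sim.alignments)
    assert len(clusters) == 2
    total = dropped = 0
    for cl in clusters:
        segs = derive_segments(cl)
        reads, d = vectorize_cluster(cl, segs)
        total += len(reads)
        dropped += d
        for r in reads:
            assert all(a < b for a, b in zip(r.vector, r.vector[1:]))
    assert dropped == 0
    assert total == sum(len(s) for s in sim.alignments)


def test_tsv_dialect_round_trip(tmp_path):
    reads = [
        SegmentVectorRead(0, "a", 1, (1, 2)),
        SegmentVectorRead(0, "a", 2, (4,)),
        SegmentVectorRead(1, "b", 0, (2, 3, 5)),
    ]
    path = tmp_path / "reads.tsv"
    write_segment_vectors(str(path), reads)
    assert load_segment_vectors(str(path)) == reads
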