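"""Read clustering and expressed-segment derivation.

A gene locus is a cluster of spliced alignments separated from its
neighbours by a run of bases not touched by any alignment footprint.
Within a locus, the reference sequence is partitioned into *expressed
segments*: maximal covered intervals uninterrupted by any splice
boundary (junction donor/acceptor observed in any sample, or annotated
exon edge).  Each alignment is then reduced to its *segment vector*,
the strictly increasing list of segment indices it covers, which is the
only representation downstream stages ever see.

Coordinates are 0-based half-open throughout; GTF I/O converts to the
1-based closed convention at the boundary of the package.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "Segment",
    "GeneLocus",
    "Alignment",
    "SegmentVectorRead",
    "read_sam",
    "cluster_alignments",
    "derive_segments",
    "to_segment_vector",
    "vectorize_cluster",
    "write_segment_vectors",
    "load_segment_vectors",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a reference sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Segment:
    """An expressed segment: index is 1-based and follows genomic order."""

    index: int
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class GeneLocus:
    """One read cluster: ordered disjoint segments plus bookkeeping.

    ``n_samples`` is F, the number of RNA-seq samples contributing
    reads, and ``read_length`` is L, used for effective-length
    corrections in the density formulas.
    """

    id: str
    chrom: str
    segments: list[Segment]
    n_samples: int
    read_length: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("a locus needs at least one sample")
        if self.read_length < 1:
            raise ValueError("read length must be positive")
        if not self.segments:
            raise ValueError("a locus needs at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end > b.start:
                raise ValueError("segments must be disjoint and sorted")

    @property
    def M(self) -> int:
        return len(self.segments)

    @property
    def seg_lengths(self) -> list[int]:
        return [s.length for s in self.segments]

    @property
    def start(self) -> int:
        return self.segments[0].start

    @property
    def end(self) -> int:
        return self.segments[-1].end


@dataclass(frozen=True)
class Alignment:
    """A spliced alignment reduced to its reference blocks.

    ``blocks`` are the M-runs of the alignment, i.e. maximal reference
    intervals not interrupted by an N (intron) operation.  ``mate`` is
    1 or 2 for the two ends of a paired fragment and 0 for single-end
    reads.
    """

    sample: int
    read_id: str
    mate: int
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("alignment without blocks")
        for (s, e) in self.blocks:
            if s >= e:
                raise ValueError("degenerate alignment block")
        for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
            if e1 > s2:
                raise ValueError("alignment blocks out of order")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def junctions(self) -> list[tuple[int, int]]:
        """(donor, acceptor) pairs; donor is the end of the upstream block."""
        return [
            (e1, s2)
            for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])
        ]


@dataclass(frozen=True)
class SegmentVectorRead:
    """An alignment expressed as the ordered segment indices it touches."""

    sample: int
    read_id: str
    mate: int
    vector: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.vector:
            raise ValueError("empty segment vector")
        if any(a >= b for a, b in zip(self.vector, self.vector[1:])):
            raise ValueError("segment vector must be strictly increasing")


# --- SAM/BAM input ---------------------------------------------------------

# CIGAR operations that consume the reference within a block (M, D, =, X);
# N (3) closes the current block and opens a new one after the intron.
_REF_IN_BLOCK = {0, 2, 7, 8}
_REF_SKIP = 3


def read_sam(path: str, sample: int) -> list[Alignment]:
    """Load primary mapped alignments from a SAM/BAM file.

    Deletions stay inside a block; only N operations split blocks, so
    block edges correspond to splice junctions.
    """
    import pysam

    out: list[Alignment] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            blocks: list[tuple[int, int]] = []
            pos = rec.reference_start
            cur = pos
            for op, ln in rec.cigartuples or ():
                if op in _REF_IN_BLOCK:
                    pos += ln
                elif op == _REF_SKIP:
                    if pos > cur:
                        blocks.append((cur, pos))
                    pos += ln
                    cur = pos
            if pos > cur:
                blocks.append((cur, pos))
            if not blocks:
                continue
            mate = 0
            if rec.is_paired:
                mate = 1 if rec.is_read1 else 2
            strand = "."
            if rec.has_tag("XS"):
                strand = rec.get_tag("XS")
            out.append(
                Alignment(
                    sample=sample,
                    read_id=rec.query_name,
                    mate=mate,
                    chrom=rec.reference_name,
                    blocks=tuple(blocks),
                    strand=strand,
                )
            )
    return out


# --- locus clustering ------------------------------------------------------

def cluster_alignments(
    per_sample: Sequence[Sequence[Alignment]],
    max_gap: int = 200,
) -> list[list[Alignment]]:
    """Cluster alignments (pooled over samples) into gene loci.

    Two alignments belong to the same locus when the gap between their
    footprints (leftmost to rightmost reference position, introns
    included) is smaller than ``max_gap``.  Junction reads therefore
    bridge the introns they span, keeping a multi-exon gene in one
    locus even when its introns carry no coverage.

    Input lists must be coordinate-sorted per sample; unsorted input is
    an explicit error rather than a silent mis-clustering.
    """
    for k, alns in enumerate(per_sample):
        prev: Optional[Alignment] = None
        for a in alns:
            if prev is not None and a.chrom == prev.chrom and a.start < prev.start:
                raise ValueError(
                    f"sample {k} alignments are not coordinate-sorted "
                    f"(read {a.read_id!r})"
                )
            if prev is None or a.chrom == prev.chrom:
                prev = a
            else:
                prev = a
    pooled = sorted(
        (a for alns in per_sample for a in alns),
        key=lambda a: (a.chrom, a.start, a.end, a.sample, a.read_id, a.mate),
    )
    clusters: list[list[Alignment]] = []
    cur: list[Alignment] = []
    cur_chrom = None
    cur_end = -1
    for a in pooled:
        if cur and a.chrom == cur_chrom and a.start - cur_end < max_gap:
            cur.append(a)
            cur_end = max(cur_end, a.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [a]
            cur_chrom = a.chrom
            cur_end = a.end
    if cur:
        clusters.append(cur)
    return clusters


# --- segment derivation ----------------------------------------------------

def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def derive_segments(
    alignments: Sequence[Alignment],
    annotation_exons: Optional[Sequence[tuple[int, int]]] = None,
    annotation_only: bool = False,
) -> list[Segment]:
    """Partition the covered reference into expressed segments.

    The boundary set is the union of every junction donor/acceptor
    position observed in the alignments and every annotated exon edge
    (``annotation_only`` restricts it to annotation).  Segments are the
    covered intervals between consecutive boundaries; uncovered
    stretches never become segments.  A junction whose coordinates
    match no existing boundary simply creates a new one — this is how
    shifted noisy junctions enter the graph, where the weighting scheme
    is expected to absorb them.
    """
    if not alignments:
        raise ValueError("cannot derive segments for a locus with no coverage")
    chrom = alignments[0].chrom
    cover = _merge_intervals(
        (s, e) for a in alignments for (s, e) in a.blocks
    )
    boundaries: set[int] = set()
    if not annotation_only:
        for a in alignments:
            for donor, acceptor in a.junctions():
                boundaries.add(donor)
                boundaries.add(acceptor)
    if annotation_exons:
        for s, e in annotation_exons:
            boundaries.add(s)
            boundaries.add(e)
    cuts = sorted(boundaries)
    segs: list[Segment] = []
    idx = 1
    for cs, ce in cover:
        lo = bisect.bisect_right(cuts, cs)
        hi = bisect.bisect_left(cuts, ce)
        edges = [cs] + cuts[lo:hi] + [ce]
        for a, b in zip(edges, edges[1:]):
            segs.append(Segment(idx, GenomicInterval(chrom, a, b)))
            idx += 1
    return segs


def to_segment_vector(
    aln: Alignment,
    segments: Sequence[Segment],
) -> Optional[tuple[int, ...]]:
    """Map an alignment onto the locus segments, or None if unassignable.

    Every internal block edge (a splice site) must coincide exactly
    with a segment boundary, and the segments under one block must be
    genomically contiguous.  Alignments violating either condition are
    unassignable; the caller counts them instead of crashing, since
    with annotation-restricted boundaries this is exactly where noisy
    junction reads fall out.
    """
    starts = [s.start for s in segments]
    ends = [s.end for s in segments]
    vector: list[int] = []
    nblocks = len(aln.blocks)
    for bi, (bs, be) in enumerate(aln.blocks):
        first = bisect.bisect_right(ends, bs)
        hit: list[int] = []
        j = first
        while j < len(segments) and segments[j].start < be:
            hit.append(j)
            j += 1
        if not hit:
            return None
        # block must not hang over the covered union
        if bs < segments[hit[0]].start or be > segments[hit[-1]].end:
            return None
        # segments under one block must be contiguous in the genome
        for a, b in zip(hit, hit[1:]):
            if segments[a].end != segments[b].start:
                return None
        # splice edges must match segment boundaries exactly
        if bi > 0 and bs != segments[hit[0]].start:
            return None
        if bi < nblocks - 1 and be != segments[hit[-1]].end:
            return None
        vector.extend(segments[h].index for h in hit)
    if any(a >= b for a, b in zip(vector, vector[1:])):
        return None
    return tuple(vector)


def vectorize_cluster(
    alignments: Sequence[Alignment],
    segments: Sequence[Segment],
) -> tuple[list[SegmentVectorRead], int]:
    """Convert a cluster's alignments to segment vectors.

    Returns the vectors plus the number of unassignable alignments
    dropped (feeding the run's noise statistics).
    """
    reads: list[SegmentVectorRead] = []
    dropped = 0
    for a in alignments:
        v = to_segment_vector(a, segments)
        if v is None:
            dropped += 1
        else:
            reads.append(SegmentVectorRead(a.sample, a.read_id, a.mate, v))
    return reads, dropped


# --- plain-text read dialect ----------------------------------------------

def write_segment_vectors(path: str, reads: Iterable[SegmentVectorRead]) -> None:
    """Write reads in the TSV dialect: sample, read id, mate, b_1,...,b_k."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"{r.sample}\t{r.read_id}\t{r.mate}\t"
                + ",".join(str(b) for b in r.vector)
                + "\n"
            )


def load_segment_vectors(path: str) -> list[SegmentVectorRead]:
    out: list[SegmentVectorRead] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields")
            sample, read_id, mate, vec = parts
            out.append(
                SegmentVectorRead(
                    int(sample),
                    read_id,
                    int(mate),
                    tuple(int(x) for x in vec.split(",")),
                )
            )
    return out
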