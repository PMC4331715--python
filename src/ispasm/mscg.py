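"""Multiple Sample Connectivity Graph (MSCG) construction and weighting.

The MSCG of a locus with M segments is a DAG over vertices
``{s=0, 1..M, t=M+1}``.  An internal edge (i, j), i < j, exists when at
least one read from any of the F samples joins segments i and j
consecutively — this covers both splice junctions and reads crossing
the shared boundary of two genomically adjacent segments.  Every
vertex also carries edges from s and to t, with the ones that would
allow an isoform to start or end in the middle of observed splicing
"inactivated" by a large finite sentinel weight.

Weights (natural log):

* vertex i:   ``w[i,i] = -log(d_i + 1)`` where
  ``d_i = sum_k C_i^k / (l_i - L + 1)`` is the average read density
  of the segment across samples (sub-read-length segments use the
  overlap window instead, see ``_effective_length``) — a reward
  (<= 0), so denser segments attract the shortest path;
* edge (i,j): ``w[i,j] = -log( (d_ij / sum_h d_ih) * (d_ij / sum_h d_hj) )``
  with ``d_ij = sum_k C_ij^k / (L - 1)``, i.e. the negative log of the
  probability that this junction, among the competing junctions at
  both of its endpoints, belongs to an isoform — a cost (>= 0) that is
  large precisely for the rare junctions produced by mis-mapped reads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .segmentation import GeneLocus, SegmentVectorRead

__all__ = [
    "BIG",
    "MSCG",
    "segment_density",
    "junction_weight",
    "terminal_weights",
    "build_mscg",
    "graph_to_jsonl",
]

#: Finite stand-in for the "infinite" weight on inactivated s/t edges.
#: Large enough never to be chosen while keeping the LP bounded; a
#: solver path using such an edge is a diagnostic failure.
BIG = 1e9


@dataclass
class MSCG:
    """Weighted connectivity graph for one locus.

    ``counts`` is the (M, F) per-segment per-sample read tally C_i^k;
    ``edge_counts`` maps internal edges to their per-sample junction
    tallies C_ij^k.  Vertex indexing is 1-based to match segment
    indices; s is 0 and t is M + 1.
    """

    M: int
    F: int
    seg_lengths: np.ndarray
    read_length: int
    counts: np.ndarray
    edge_counts: dict[tuple[int, int], np.ndarray]
    d: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_vertex: np.ndarray = field(default=None)  # type: ignore[assignment]
    edge_density: dict[tuple[int, int], float] = field(default_factory=dict)
    w_edge: dict[tuple[int, int], float] = field(default_factory=dict)
    w_source: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_sink: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def source(self) -> int:
        return 0

    @property
    def sink(self) -> int:
        return self.M + 1

    def internal_edges(self) -> list[tuple[int, int]]:
        return sorted(self.w_edge)

    def out_internal(self, i: int) -> list[int]:
        return sorted(j for (a, j) in self.w_edge if a == i)

    def in_internal(self, j: int) -> list[int]:
        return sorted(i for (i, b) in self.w_edge if b == j)

    def vertex_weight(self, i: int) -> float:
        return float(self.w_vertex[i - 1])

    def edge_weight(self, i: int, j: int) -> float:
        if i == 0:
            return float(self.w_source[j - 1])
        if j == self.M + 1:
            return float(self.w_sink[i - 1])
        return self.w_edge[(i, j)]


def segment_density(
    counts: Sequence[float] | np.ndarray,
    length: int,
    read_length: int,
) -> tuple[float, float]:
    """Average read density of a segment and its vertex weight."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative read counts")
    eff = _effective_length(length, read_length)
    d = float(c.sum() / eff)
    return d, -math.log(d + 1.0)


def _effective_length(length: int, read_length: int) -> float:
    """Window size normalizing a segment's read tally into a density.

    For segments at least one read long this is the number of start
    positions of a contained read, l - L + 1.  Shorter segments are
    only ever *touched* by reads, so their tally is normalized by the
    window of starts of an overlapping read, l + L - 1; without this
    a few stray reads on a 1 bp sliver (the debris of a shifted
    junction) would register an enormous density.
    """
    if length >= read_length:
        return float(length - read_length + 1)
    return float(length + read_length - 1)


def junction_weight(d_ij: float, row_sum: float, col_sum: float) -> float:
    """Edge cost from its density and the competing densities.

    ``row_sum`` sums d_ih over all internal out-edges of i and
    ``col_sum`` sums d_hj over all internal in-edges of j (both include
    d_ij itself); the s/t edges are excluded from the competition.
    """
    if d_ij <= 0:
        raise ValueError("junction weight undefined for zero density")
    p = (d_ij / row_sum) * (d_ij / col_sum)
    return -math.log(p)


def terminal_weights(graph: MSCG) -> MSCG:
    """Activate/inactivate the s and t edges in place.

    (s, i) is usable only when no internal edge reaches i — an isoform
    may not start downstream of observed splicing into its first
    segment; symmetrically for (i, t).
    """
    has_in = np.zeros(graph.M, dtype=bool)
    has_out = np.zeros(graph.M, dtype=bool)
    for (i, j) in graph.w_edge:
        has_out[i - 1] = True
        has_in[j - 1] = True
    graph.w_source = np.where(has_in, BIG, 0.0)
    graph.w_sink = np.where(has_out, BIG, 0.0)
    return graph


def build_mscg(
    locus: GeneLocus,
    reads: Iterable[SegmentVectorRead],
    depth_normalize: bool = False,
    filter_junctions: bool = False,
) -> MSCG:
    """Tally counts from all samples' segment vectors and weight the graph.

    An edge is created for every consecutive pair in any read's vector;
    candidate edges between genomically adjacent covered segments are
    kept only when some read actually crosses the shared boundary
    (zero-density edges are removed before weighting).
    ``filter_junctions`` additionally collapses near-identical spliced
    junctions onto their densest version (see
    ``_filter_shifted_junctions``); the assembly pipeline enables it,
    since shifted-alignment junction echoes are the entry points of
    spurious paths.  With ``depth_normalize`` per-sample counts are
    rescaled to the mean sample depth before the density formulas,
    relaxing the equal-depth assumption for real data.
    """
    M, F, L = locus.M, locus.n_samples, locus.read_length
    counts = np.zeros((M, F), dtype=float)
    edge_counts: dict[tuple[int, int], np.ndarray] = {}
    for r in reads:
        if r.sample < 0 or r.sample >= F:
            raise ValueError(f"sample index {r.sample} out of range")
        for i in r.vector:
            counts[i - 1, r.sample] += 1
        for i, j in zip(r.vector, r.vector[1:]):
            edge_counts.setdefault((i, j), np.zeros(F))[r.sample] += 1

    if depth_normalize:
        depth = counts.sum(axis=0)
        mean = depth[depth > 0].mean() if (depth > 0).any() else 1.0
        scale = np.where(depth > 0, mean / np.maximum(depth, 1e-300), 1.0)
        counts = counts * scale
        edge_counts = {e: c * scale for e, c in edge_counts.items()}

    graph = MSCG(
        M=M,
        F=F,
        seg_lengths=np.asarray(locus.seg_lengths, dtype=float),
        read_length=L,
        counts=counts,
        edge_counts=edge_counts,
    )

    d = np.empty(M)
    w = np.empty(M)
    for i in range(M):
        d[i], w[i] = segment_density(counts[i], locus.seg_lengths[i], L)
    graph.d = d
    graph.w_vertex = w

    denom = max(L - 1, 1)
    density = {
        e: float(c.sum() / denom)
        for e, c in edge_counts.items()
        if c.sum() > 0
    }
    if filter_junctions and density:
        density = _filter_shifted_junctions(density, locus)
    graph.edge_density = density

    row = np.zeros(M + 2)
    col = np.zeros(M + 2)
    for (i, j), dij in density.items():
        row[i] += dij
        col[j] += dij
    graph.w_edge = {
        (i, j): junction_weight(dij, row[i], col[j])
        for (i, j), dij in density.items()
    }
    return terminal_weights(graph)


#: Two spliced junctions whose donors and acceptors each differ by at
#: most this many bases are treated as competing versions of the same
#: splice event (alignment slippage shifts sites by a few bases).
JUNCTION_MERGE_TOL = 5


def _filter_shifted_junctions(
    density: dict[tuple[int, int], float],
    locus: GeneLocus,
) -> dict[tuple[int, int], float]:
    """Keep only the consensus junction within each positional cluster.

    Gap junctions (segments not sharing a genomic boundary) whose
    donors and acceptors both lie within JUNCTION_MERGE_TOL bases are
    competing versions of the same splice event — alignment slippage
    moves a splice site by a few bases, never to a different exon.
    Within such a cluster only the densest junction survives
    (winner-take-all); a genuinely alternative junction lands in a
    different cluster and is never at risk, whatever its depth.  The
    cost is that sub-tolerance alternative donors/acceptors (NAGNAG
    style) collapse onto their major form.
    """
    segs = locus.segments
    gaps = []
    for (i, j), dij in density.items():
        donor = segs[i - 1].end
        acceptor = segs[j - 1].start
        if donor != acceptor:
            gaps.append(((i, j), donor, acceptor, dij))
    drop = set()
    for (e, d1, a1, v1) in gaps:
        for (e2, d2, a2, v2) in gaps:
            if e2 == e:
                continue
            if (
                abs(d1 - d2) <= JUNCTION_MERGE_TOL
                and abs(a1 - a2) <= JUNCTION_MERGE_TOL
                and (v2 > v1 or (v2 == v1 and e2 < e))
            ):
                drop.add(e)
                break
    return {e: v for e, v in density.items() if e not in drop}


def graph_to_jsonl(graph: MSCG, locus_id: str = "") -> str:
    """JSON-lines dump: one record per vertex and edge (for --dump-graph)."""
    lines = []
    for i in range(1, graph.M + 1):
        lines.append(
            json.dumps(
                {
                    "locus": locus_id,
                    "type": "vertex",
                    "i": i,
                    "d": graph.d[i - 1],
                    "w": graph.w_vertex[i - 1],
                    "s_active": bool(graph.w_source[i - 1] == 0),
                    "t_active": bool(graph.w_sink[i - 1] == 0),
                }
            )
        )
    for (i, j) in graph.internal_edges():
        lines.append(
            json.dumps(
                {
                    "locus": locus_id,
                    "type": "edge",
                    "i": i,
                    "j": j,
                    "d": graph.edge_density[(i, j)],
                    "w": graph.w_edge[(i, j)],
                }
            )
        )
    return "\n".join(lines) + "\n"
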