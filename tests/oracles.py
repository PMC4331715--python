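"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — exhaustive enumeration and
literal re-implementations of definitions — and shares no code with
the implementation under test.
"""

from __future__ import annotations

import numpy as np

from ispasm.mscg import MSCG, build_mscg
from ispasm.pairing import ReadPattern
from ispasm.segmentation import (
    GeneLocus,
    GenomicInterval,
    Segment,
    SegmentVectorRead,
)


def enumerate_st_paths(graph: MSCG) -> list[tuple[int, ...]]:
    """All simple s→t paths (internal vertex tuples) by recursion."""
    starts = [
        i for i in range(1, graph.M + 1) if graph.w_source[i - 1] == 0
    ]
    ends = {
        i for i in range(1, graph.M + 1) if graph.w_sink[i - 1] == 0
    }
    out: dict[int, list[int]] = {i: [] for i in range(1, graph.M + 1)}
    for (i, j) in graph.w_edge:
        out[i].append(j)
    paths = []

    def walk(prefix):
        v = prefix[-1]
        if v in ends:
            paths.append(tuple(prefix))
        for nxt in sorted(out[v]):
            walk(prefix + [nxt])

    for s in starts:
        walk([s])
    return paths


def literal_mate_compatible(b: tuple[int, ...], path: tuple[int, ...]) -> bool:
    """The definitional test: a mate is compatible with an isoform iff
    the isoform contains all its segments and no other segment between
    the first and last."""
    pset = set(path)
    if not set(b) <= pset:
        return False
    inside = {i for i in pset if b[0] <= i <= b[-1]}
    return inside == set(b)


def literal_fragment_compatible(
    b: tuple[int, ...],
    b2: tuple[int, ...] | None,
    path: tuple[int, ...],
) -> bool:
    if not literal_mate_compatible(b, path):
        return False
    return b2 is None or literal_mate_compatible(b2, path)


def path_objective(
    graph: MSCG,
    path: tuple[int, ...],
    patterns: list[ReadPattern],
    w_vertex=None,
    w_edge=None,
) -> float:
    """Eq-style objective computed from first principles."""
    wv = graph.w_vertex if w_vertex is None else w_vertex
    we = graph.w_edge if w_edge is None else w_edge
    total = -float(graph.w_source[path[0] - 1])
    total -= float(graph.w_sink[path[-1] - 1])
    for i in path:
        total -= float(wv[i - 1])
    for e in zip(path, path[1:]):
        total -= float(we[e])
    pset = set(path)
    for p in patterns:
        if p.inclusion <= pset and not (p.exclusion & pset):
            total += p.alpha
    return total


def brute_force_optimum(
    graph: MSCG, patterns: list[ReadPattern]
) -> tuple[tuple[int, ...], float]:
    best = None
    best_path = None
    for path in enumerate_st_paths(graph):
        val = path_objective(graph, path, patterns)
        if best is None or val > best + 1e-12:
            best, best_path = val, path
    if best is None:
        raise RuntimeError("graph has no admissible s-t path")
    return best_path, best


def random_instance(rng: np.random.Generator, max_m: int = 8):
    """A random small locus, its graph, and random read patterns."""
    M = int(rng.integers(2, max_m + 1))
    L = 50
    pos = 0
    segs = []
    for i in range(M):
        ln = int(rng.integers(60, 200))
        segs.append(Segment(i + 1, GenomicInterval("c", pos, pos + ln)))
        pos += ln + int(rng.integers(0, 2)) * int(rng.integers(50, 100))
    locus = GeneLocus("rand", "c", segs, n_samples=2, read_length=L)
    reads = []
    for r in range(int(rng.integers(3, 25))):
        k = int(rng.integers(1, min(4, M) + 1))
        vec = tuple(sorted(rng.choice(M, size=k, replace=False) + 1))
        reads.append(
            SegmentVectorRead(int(rng.integers(2)), f"r{r}", 0, vec)
        )
    graph = build_mscg(locus, reads)
    n_pat = int(rng.integers(0, 8))
    patterns = []
    for _ in range(n_pat):
        k = int(rng.integers(1, min(3, M) + 1))
        inc = frozenset(int(x) + 1 for x in rng.choice(M, size=k, replace=False))
        rest = [i for i in range(1, M + 1) if i not in inc]
        exc = frozenset(
            int(x) for x in rng.choice(rest, size=min(len(rest), int(rng.integers(0, 3))), replace=False)
        )
        patterns.append(
            ReadPattern(inc, exc, float(rng.uniform(0.2, 4.0)),
                        multiplicity=1)
        )
    return locus, graph, patterns


def brute_force_matching(preds, truths, match_fn) -> int:
    """Maximum one-to-one matching size by exhaustive recursion."""
    edges = [
        [t for t in range(len(truths)) if match_fn(preds[p], truths[t])]
        for p in range(len(preds))
    ]

    def rec(p, used):
        if p == len(preds):
            return 0
        best = rec(p + 1, used)
        for t in edges[p]:
            if t not in used:
                best = max(best, 1 + rec(p + 1, used | {t}))
        return best

    return rec(0, frozenset())
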