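"""The iterative shortest-path loop and the whole-dataset pipeline.

One LP/ILP solve extracts a single best isoform; genes usually
express several.  After each extraction the graph is made less
attractive along the used path ("weight decay"): vertex rewards are
shrunk by ``gamma`` and every used internal edge is penalized by
``delta``, while all read patterns the emitted isoform explains are
removed from R'.  Further isoforms must therefore justify themselves
through still-unexplained read patterns or still-unused segments.
The loop stops when the best remaining path has no net reward
(objective below ``theta_stop``), when it re-discovers an already
emitted path, or after ``max_iter`` rounds.

Single-exon predictions are only emitted above a read-density floor:
stray coverage islands (typically intronic noise) are isolated
vertices with small but positive rewards, and without the floor they
would surface as spurious single-exon transcripts once the real
isoforms are exhausted.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .gtf import TranscriptRecord
from .jsmetric import (
    background_distribution,
    classify_and_inject,
    sample_densities,
    uncertain_pairs,
)
from .mscg import MSCG, build_mscg
from .pairing import ReadPattern, filter_informative, group_fragments, is_compatible
from .segmentation import (
    Alignment,
    GeneLocus,
    cluster_alignments,
    derive_segments,
    vectorize_cluster,
)
from .solver import PathsExhausted, build_program, solve_path

__all__ = ["AssemblyConfig", "IsoformCall", "assemble_locus", "assemble_all", "calls_to_records"]

logger = logging.getLogger("ispasm")


@dataclass
class AssemblyConfig:
    """Tunable parameters of the assembler; see docs/methods.md.

    ``alpha_real`` is the per-read compatibility reward (smaller for
    organisms with simple splicing), ``alpha_pseudo`` the reward of an
    injected co-expression constraint.  ``gamma`` multiplies the
    vertex rewards of an emitted path (0 removes consumed evidence
    entirely) and ``delta`` additively penalizes used edges.  Both
    default to the most forgetful setting: isoforms found later must
    be justified by still-unexplained read patterns, and shared
    junctions are never penalized — penalizing them steers later
    iterations onto rare spurious junction edges that run parallel to
    a heavily used true junction.
    """

    alpha_real: float = 1.0
    alpha_pseudo: float = 2.0
    fdr: float = 5.0
    n_perm: int = 1000
    gamma: float = 0.0
    delta: float = 0.0
    theta_stop: float = 0.0
    max_iter: int = 20
    max_gap: int = 200
    witness_span: float = 350.0
    filter_shifted_junctions: bool = True
    min_single_exon_density: float = 2.0
    min_exon_uniformity: float = 0.1
    depth_normalize: bool = False
    annotation_only: bool = False
    solver_time_limit: float = 60.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str) -> "AssemblyConfig":
        """Read a plain key=value (or 'key: value') config file."""
        cfg = cls()
        fields = {f: type(getattr(cfg, f)) for f in cfg.to_dict()}
        with open(path) as fh:
            for ln, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                sep = "=" if "=" in line else ":"
                if sep not in line:
                    raise ValueError(f"{path}:{ln}: expected key=value")
                key, val = (x.strip() for x in line.split(sep, 1))
                if key not in fields:
                    raise ValueError(f"{path}:{ln}: unknown option {key!r}")
                typ = fields[key]
                if typ is bool:
                    setattr(cfg, key, val.lower() in {"1", "true", "yes"})
                else:
                    setattr(cfg, key, typ(val))
        return cfg


@dataclass(frozen=True)
class IsoformCall:
    """One predicted isoform: consecutive path segments merged to exons."""

    locus_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    iteration: int
    objective: float
    support: int
    path: tuple[int, ...]


def _merge_path_to_exons(
    locus: GeneLocus, path: Sequence[int]
) -> tuple[tuple[int, int], ...]:
    exons: list[list[int]] = []
    for i in path:
        seg = locus.segments[i - 1]
        if exons and exons[-1][1] == seg.start:
            exons[-1][1] = seg.end
        else:
            exons.append([seg.start, seg.end])
    return tuple((s, e) for s, e in exons)


def _pooled_density(graph: MSCG, path: Sequence[int]) -> float:
    from .mscg import _effective_length

    total = sum(float(graph.counts[i - 1].sum()) for i in path)
    length = int(sum(graph.seg_lengths[i - 1] for i in path))
    return total / _effective_length(length, graph.read_length)


def _fragment_witnesses(
    fragments: Sequence[tuple[tuple[int, ...], Optional[tuple[int, ...]]]],
) -> set[frozenset[tuple[int, int]]]:
    """Transition pairs jointly observed inside a single fragment.

    A fragment's crossing set holds every consecutive segment pair of
    each mate's vector; two transitions appearing in one crossing set
    were produced by one molecule, which is the only direct evidence
    that two splicing choices co-occur on an isoform.
    """
    witnessed: set[frozenset[tuple[int, int]]] = set()
    for b, b2 in fragments:
        crossings = set(zip(b, b[1:]))
        if b2 is not None:
            crossings.update(zip(b2, b2[1:]))
        if len(crossings) >= 2:
            cl = sorted(crossings)
            for x in range(len(cl)):
                for y in range(x + 1, len(cl)):
                    witnessed.add(frozenset((cl[x], cl[y])))
    return witnessed


def _unwitnessed_novel_pairs(
    path: Sequence[int],
    emitted_transitions: set[tuple[int, int]],
    witnessed: set[frozenset[tuple[int, int]]],
    locus: GeneLocus,
    graph: MSCG,
    witness_span: float,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Novel transition pairs of a candidate that no molecule supports.

    Transitions absent from every previously emitted isoform are the
    candidate's novelty; maximal consecutive runs of them are its
    novel *blocks*.  Two failure modes are policed, each the signature
    of a chimeric path stitching together splicing choices that were
    never observed on one molecule:

    * novel transitions in *different* blocks — the candidate deviates
      from emitted structure in separate places and reconnects through
      it in between.  Each cross-block pair must be witnessed by a
      single fragment whose mates cross both, at any distance: where
      no molecule links the deviations, the emitted isoforms already
      explain each one separately;
    * *consecutive spliced junctions* along the candidate (contiguity
      steps between them do not insulate) where at least one junction
      is novel and the two lie within plausible fragment reach
      (``witness_span``) — near enough that a molecule carrying both
      splice choices would have been sequenced across them.  A true
      secondary isoform shares these junction pairs with its chimeric
      lookalike, so the same witness decides both consistently; pairs
      beyond fragment reach are unknowable from short reads and pass.

    Contiguity transitions are never required to be witnessed — they
    arise from coverage structure, not splicing choices, and
    read-through artifacts are handled by the exon-uniformity check.
    """
    transitions = list(zip(path, path[1:]))
    segs = locus.segments
    novel = [t not in emitted_transitions for t in transitions]

    bad = []
    # cross-block rule: novel transitions separated by emitted ones
    blocks: list[list[int]] = []
    prev_novel = -2
    for idx, is_novel in enumerate(novel):
        if is_novel:
            if idx == prev_novel + 1:
                blocks[-1].append(idx)
            else:
                blocks.append([idx])
            prev_novel = idx
    for x in range(len(blocks)):
        for y in range(x + 1, len(blocks)):
            for i1 in blocks[x]:
                for i2 in blocks[y]:
                    t1, t2 = transitions[i1], transitions[i2]
                    if frozenset((t1, t2)) not in witnessed:
                        bad.append((t1, t2))

    # adjacent-splice rule: consecutive spliced junctions along the
    # candidate (contiguity steps between them do not insulate)
    pos = {}
    cum = 0.0
    for t in transitions:
        cum += float(graph.seg_lengths[t[0] - 1])
        pos[t] = cum
    gap_idx = [
        idx
        for idx, t in enumerate(transitions)
        if segs[t[1] - 1].start != segs[t[0] - 1].end
    ]
    for i1, i2 in zip(gap_idx, gap_idx[1:]):
        t1, t2 = transitions[i1], transitions[i2]
        if not (novel[i1] or novel[i2]):
            continue
        if pos[t2] - pos[t1] + 2 > witness_span:
            continue
        if frozenset((t1, t2)) not in witnessed:
            bad.append((t1, t2))
    return bad


def _exon_density_uniform(
    exons: Sequence[tuple[int, int]],
    path: Sequence[int],
    graph: MSCG,
    locus: GeneLocus,
    min_frac: float,
) -> bool:
    """Check that each predicted exon carries uniform read density.

    The segments merged into one exon of a real isoform are covered by
    the same molecules, so their densities agree up to sampling noise
    and edge effects.  A predicted exon mixing a genuine exon with
    adjacent stray intronic coverage (read-through and nested
    intron-blob calls) shows an internal density cliff of one to two
    orders of magnitude instead; ``min_frac`` is the lowest tolerated
    min/max density ratio within one exon.  Genuine intron retention
    expressed at a sizeable fraction of its flanks still passes.
    """
    segs = locus.segments
    for (s, e) in exons:
        ds = [
            float(graph.d[i - 1])
            for i in path
            if segs[i - 1].start >= s and segs[i - 1].end <= e
        ]
        if len(ds) >= 2 and min(ds) < min_frac * max(ds):
            return False
    return True


def assemble_locus(
    locus: GeneLocus,
    graph: MSCG,
    patterns: Sequence[ReadPattern],
    config: AssemblyConfig,
    fragments: Sequence[tuple[tuple[int, ...], Optional[tuple[int, ...]]]] = (),
) -> tuple[list[IsoformCall], dict]:
    """Run the iterative extraction loop on one locus.

    ``fragments`` (the raw mate vectors) feed the molecule-level
    co-occurrence check; candidates from the second iteration on that
    combine unwitnessed novel splicing choices are not emitted —
    instead the offending edge pair is banned and the solve repeats.
    Candidates whose predicted exons mix coverage levels spanning an
    internal density cliff are likewise banned (exact-path cut).
    """
    w_vertex = graph.w_vertex.copy()
    w_edge = dict(graph.w_edge)
    remaining = list(patterns)
    delta = config.delta
    witnessed = _fragment_witnesses(fragments)
    banned: list[tuple[tuple[int, int], tuple[int, int]]] = []
    banned_paths: list[tuple[int, ...]] = []
    calls: list[IsoformCall] = []
    emitted: set[tuple[int, ...]] = set()
    emitted_transitions: set[tuple[int, int]] = set()
    n_ilp = 0
    n_vetoed = 0
    stop_reason = "max_iter"
    for iteration in range(1, config.max_iter + 1):
        problem = build_program(
            graph, remaining, w_vertex=w_vertex, w_edge=w_edge,
            banned_pairs=banned, banned_paths=banned_paths,
        )
        try:
            sol = solve_path(
                problem, mode="auto", time_limit=config.solver_time_limit
            )
        except PathsExhausted:
            stop_reason = "exhausted"
            break
        if sol.solver_used == "ILP":
            n_ilp += 1
        if sol.objective < config.theta_stop:
            stop_reason = "objective"
            break
        if sol.path in emitted:
            stop_reason = "duplicate"
            break
        if calls:
            bad = _unwitnessed_novel_pairs(
                sol.path, emitted_transitions, witnessed, locus, graph,
                config.witness_span,
            )
            if bad:
                banned.extend(bad)
                n_vetoed += 1
                continue
        exons = _merge_path_to_exons(locus, sol.path)
        if not _exon_density_uniform(
            exons, sol.path, graph, locus, config.min_exon_uniformity
        ):
            banned_paths.append(sol.path)
            n_vetoed += 1
            continue
        if len(exons) == 1:
            if _pooled_density(graph, sol.path) < config.min_single_exon_density:
                stop_reason = "single_exon_floor"
                break
        support = sum(
            p.multiplicity
            for p in remaining
            if not p.pseudo and is_compatible(p, sol.path)
        )
        calls.append(
            IsoformCall(
                locus_id=locus.id,
                chrom=locus.chrom,
                strand=locus.strand,
                exons=exons,
                iteration=iteration,
                objective=sol.objective,
                support=support,
                path=sol.path,
            )
        )
        emitted.add(sol.path)
        emitted_transitions.update(zip(sol.path, sol.path[1:]))
        # weight decay: shrink consumed vertex rewards, penalize used edges
        for i in sol.path:
            w_vertex[i - 1] *= config.gamma
        for e in zip(sol.path, sol.path[1:]):
            if e in w_edge:
                w_edge[e] += delta
        remaining = [p for p in remaining if not is_compatible(p, sol.path)]
    stats = {
        "locus": locus.id,
        "segments": locus.M,
        "calls": len(calls),
        "ilp_solves": n_ilp,
        "vetoed_paths": n_vetoed,
        "stop": stop_reason,
    }
    return calls, stats


def infer_read_length(per_sample: Sequence[Sequence[Alignment]]) -> int:
    lengths = [a.aligned_length for alns in per_sample for a in alns]
    if not lengths:
        raise ValueError("no alignments")
    return int(round(statistics.median(lengths)))


def assemble_all(
    per_sample: Sequence[Sequence[Alignment]],
    config: Optional[AssemblyConfig] = None,
    annotation: Optional[Sequence[TranscriptRecord]] = None,
    read_length: Optional[int] = None,
    dump_graph: Optional[list] = None,
) -> tuple[list[IsoformCall], dict]:
    """Full pipeline: cluster → segment → graph → JS injection → ISP loop.

    ``per_sample`` holds coordinate-sorted alignments, one list per
    sample.  Returns the calls in deterministic genomic order plus a
    summary of per-stage counters.  ``dump_graph``, when given a list,
    collects the weighted graph of every locus for diagnostics.
    """
    if config is None:
        config = AssemblyConfig()
    F = len(per_sample)
    if F < 1:
        raise ValueError("need at least one sample")
    summary = {
        "samples": F,
        "alignments": sum(len(s) for s in per_sample),
        "loci": 0,
        "calls": 0,
        "ilp_solves": 0,
        "vetoed_paths": 0,
        "dropped_alignments": 0,
        "noisy_fragments_dropped": 0,
        "discarded_lone_mates": 0,
        "pseudo_reads": 0,
    }
    calls: list[IsoformCall] = []
    if summary["alignments"] == 0:
        return calls, summary
    L = read_length if read_length is not None else infer_read_length(per_sample)
    clusters = cluster_alignments(per_sample, max_gap=config.max_gap)
    summary["loci"] = len(clusters)
    for idx, cluster in enumerate(clusters):
        chrom = cluster[0].chrom
        lo = min(a.start for a in cluster)
        hi = max(a.end for a in cluster)
        ann_exons = None
        if annotation is not None:
            ann_exons = [
                (s, e)
                for rec in annotation
                if rec.chrom == chrom and rec.start < hi and rec.end > lo
                for (s, e) in rec.exons
            ]
        segments = derive_segments(
            cluster,
            annotation_exons=ann_exons,
            annotation_only=config.annotation_only,
        )
        locus = GeneLocus(
            id=f"LOC{idx + 1:06d}",
            chrom=chrom,
            segments=segments,
            n_samples=F,
            read_length=L,
        )
        svreads, dropped = vectorize_cluster(cluster, segments)
        summary["dropped_alignments"] += dropped
        graph = build_mscg(
            locus,
            svreads,
            depth_normalize=config.depth_normalize,
            filter_junctions=config.filter_shifted_junctions,
        )
        if dump_graph is not None:
            dump_graph.append((locus.id, graph))
        fragments, lone = group_fragments(svreads)
        summary["discarded_lone_mates"] += lone
        # a fragment whose alignment crosses a filtered junction is a
        # shifted-alignment artifact; keep it out of the reward pool
        kept_fragments = []
        for b, b2 in fragments:
            pairs = list(zip(b, b[1:]))
            if b2 is not None:
                pairs += list(zip(b2, b2[1:]))
            if all(p in graph.w_edge for p in pairs):
                kept_fragments.append((b, b2))
            else:
                summary["noisy_fragments_dropped"] += 1
        fragments = kept_fragments
        pseudo: list[ReadPattern] = []
        if F >= 2 and locus.M >= 2:
            pairs = uncertain_pairs(graph)
            if pairs:
                rng = np.random.default_rng([config.seed, idx])
                bg = background_distribution(
                    sample_densities(graph), n_perm=config.n_perm, rng=rng
                )
                pseudo, _ = classify_and_inject(
                    pairs,
                    graph,
                    bg,
                    beta=config.fdr,
                    alpha_pseudo=config.alpha_pseudo,
                )
        summary["pseudo_reads"] += len(pseudo)
        patterns = filter_informative(
            fragments, alpha=config.alpha_real, M=locus.M, pseudo=pseudo
        )
        locus_calls, stats = assemble_locus(
            locus, graph, patterns, config, fragments=fragments
        )
        summary["ilp_solves"] += stats["ilp_solves"]
        summary["vetoed_paths"] += stats["vetoed_paths"]
        calls.extend(locus_calls)
        logger.info("%s", json.dumps(stats, sort_keys=True))
    calls.sort(key=lambda c: (c.chrom, c.exons[0][0], c.exons[-1][1], c.iteration))
    summary["calls"] = len(calls)
    return calls, summary


def calls_to_records(calls: Iterable[IsoformCall]) -> list[TranscriptRecord]:
    """Convert calls to GTF-ready transcript records."""
    out = []
    counters: dict[str, int] = {}
    for c in calls:
        n = counters.get(c.locus_id, 0) + 1
        counters[c.locus_id] = n
        out.append(
            TranscriptRecord(
                transcript_id=f"{c.locus_id}.{n}",
                gene_id=c.locus_id,
                chrom=c.chrom,
                strand=c.strand,
                exons=c.exons,
                attributes={
                    "iteration": c.iteration,
                    "objective": f"{c.objective:.4f}",
                    "support": c.support,
                },
            )
        )
    return out
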