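"""Jensen-Shannon co-expression test for ambiguous segment pairs.

Alternative ("uncertain") segments — those some edge of the graph can
skip — may combine into several isoform sets that the edge structure
alone cannot distinguish.  Across F samples, two uncertain segments
that always rise and fall together are probably on the same isoform;
two with anti-correlated expression probably belong to different
isoforms.  The statistic is the JS metric, the square root of the
Jensen-Shannon divergence between the two segments' across-sample
expression distributions.  With base-2 entropies it lives in [0, 1]
and is a true metric.

The observed JS value for a pair is compared against an empirical
background built by permuting every segment's per-sample densities
across the sample labels; at FDR beta%, values in the lowest beta% of
the background mean co-expression and values in the highest beta%
mean exclusivity.  Each verdict is converted into pseudo paired-end
reads that reward (but never force) paths consistent with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .mscg import MSCG
from .pairing import ReadPattern

__all__ = [
    "PairClassification",
    "js_metric",
    "expression_profiles",
    "uncertain_pairs",
    "background_distribution",
    "classify_and_inject",
]

#: At most this many uncertain pairs are scored per locus (top pairs by
#: min segment density), bounding the permutation cost on odd loci.
MAX_UNCERTAIN_PAIRS = 50


@dataclass(frozen=True)
class PairClassification:
    pair: tuple[int, int]
    js: float
    verdict: str  # "coexpressed" | "exclusive" | "neutral"
    quantile: float


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def js_metric(p: Sequence[float], q: Sequence[float]) -> float:
    """Square root of the Jensen-Shannon divergence, base-2 logs."""
    pa = np.asarray(p, dtype=float)
    qa = np.asarray(q, dtype=float)
    if pa.shape != qa.shape:
        raise ValueError("profiles must have equal length")
    jsd = _entropy2((pa + qa) / 2.0) - (_entropy2(pa) + _entropy2(qa)) / 2.0
    return math.sqrt(max(jsd, 0.0))


def sample_densities(graph: MSCG) -> np.ndarray:
    """Per-sample read densities d_i^k, shape (M, F)."""
    from .mscg import _effective_length

    eff = np.array(
        [_effective_length(int(l), graph.read_length) for l in graph.seg_lengths]
    )
    return graph.counts / eff[:, None]


def expression_profiles(graph: MSCG) -> tuple[np.ndarray, np.ndarray]:
    """Normalize each segment's densities into an across-sample distribution.

    Segments with zero total density get a uniform profile and are
    flagged degenerate; their verdicts are forced neutral downstream.
    """
    dens = sample_densities(graph)
    total = dens.sum(axis=1)
    degenerate = total <= 0
    profiles = np.empty_like(dens)
    profiles[~degenerate] = dens[~degenerate] / total[~degenerate, None]
    profiles[degenerate] = 1.0 / graph.F
    return profiles, degenerate


def uncertain_pairs(graph: MSCG) -> list[tuple[int, int]]:
    """Pairs of alternative segments whose joint fate the edges leave open.

    A segment is *skippable* when some edge (a, b) jumps over it
    (a < i < b).  Two skippable segments form an uncertain pair unless
    one lies strictly inside the other's minimal flanking edge — in
    that case the edge set already ties their fates together.  Output
    is capped at MAX_UNCERTAIN_PAIRS by descending min segment density.
    """
    span: dict[int, tuple[int, int]] = {}
    for (a, b) in graph.w_edge:
        if b - a <= 1:
            continue
        for i in range(a + 1, b):
            cur = span.get(i)
            if cur is None or (b - a) < (cur[1] - cur[0]):
                span[i] = (a, b)
    skippable = sorted(span)
    pairs: list[tuple[int, int]] = []
    for ii, i in enumerate(skippable):
        for j in skippable[ii + 1:]:
            ai, bi = span[i]
            aj, bj = span[j]
            if ai < j < bi or aj < i < bj:
                continue
            pairs.append((i, j))
    if len(pairs) > MAX_UNCERTAIN_PAIRS:
        pairs.sort(
            key=lambda p: -min(graph.d[p[0] - 1], graph.d[p[1] - 1])
        )
        pairs = sorted(pairs[:MAX_UNCERTAIN_PAIRS])
    return pairs


def background_distribution(
    densities: np.ndarray,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Null JS values from label-permuted expression.

    Each permutation shuffles every segment's F density values across
    the sample labels independently, then scores one randomly chosen
    segment pair.  Deterministic under a seeded generator.
    """
    dens = np.asarray(densities, dtype=float)
    M, F = dens.shape
    if M < 2 or F < 2:
        raise ValueError("background needs >= 2 segments and >= 2 samples")
    if rng is None:
        rng = np.random.default_rng()
    out = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permuted(dens, axis=1)
        i = rng.integers(M)
        j = rng.integers(M - 1)
        if j >= i:
            j += 1
        pi, pj = perm[i], perm[j]
        si, sj = pi.sum(), pj.sum()
        pi = pi / si if si > 0 else np.full(F, 1.0 / F)
        pj = pj / sj if sj > 0 else np.full(F, 1.0 / F)
        out[t] = js_metric(pi, pj)
    return out


def classify_and_inject(
    pairs: Sequence[tuple[int, int]],
    graph: MSCG,
    background: np.ndarray,
    beta: float = 5.0,
    alpha_pseudo: float = 2.0,
) -> tuple[list[ReadPattern], list[PairClassification]]:
    """Classify uncertain pairs and emit the corresponding pseudo reads.

    Co-expressed (JS at or below the beta-th background percentile):
    one pseudo pair with IS = {i, j}.  Exclusively expressed (JS at or
    above the (100-beta)-th percentile): pseudo reads IS = {i}, ES =
    {j} injected in both directions so either exclusive isoform earns
    the reward.  ``beta = 0`` disables injection entirely, as does
    F = 1 (no across-sample signal) or a degenerate profile.
    """
    classifications: list[PairClassification] = []
    pseudo: list[ReadPattern] = []
    if beta <= 0 or len(background) == 0 or graph.F < 2:
        return pseudo, [
            PairClassification((i, j), float("nan"), "neutral", float("nan"))
            for (i, j) in pairs
        ]
    profiles, degenerate = expression_profiles(graph)
    lo = float(np.percentile(background, beta))
    hi = float(np.percentile(background, 100.0 - beta))
    n_bg = len(background)
    for (i, j) in pairs:
        js = js_metric(profiles[i - 1], profiles[j - 1])
        quantile = float(np.count_nonzero(background <= js)) / n_bg
        if degenerate[i - 1] or degenerate[j - 1]:
            verdict = "neutral"
        elif js <= lo:
            verdict = "coexpressed"
            pseudo.append(
                ReadPattern(
                    frozenset({i, j}), frozenset(), alpha_pseudo, pseudo=True
                )
            )
        elif js >= hi:
            verdict = "exclusive"
            pseudo.append(
                ReadPattern(
                    frozenset({i}), frozenset({j}), alpha_pseudo, pseudo=True
                )
            )
            pseudo.append(
                ReadPattern(
                    frozenset({j}), frozenset({i}), alpha_pseudo, pseudo=True
                )
            )
        else:
            verdict = "neutral"
        classifications.append(PairClassification((i, j), js, verdict, quantile))
    return pseudo, classifications
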