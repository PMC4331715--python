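"""Paired-end inclusion/exclusion sets and read-path compatibility.

A fragment p = (b, b') with segment vectors b and b' implies that a
compatible isoform must contain every segment either mate touches
(the inclusion set IS_p) and must skip every segment that lies
strictly inside a mate's span without being touched (the exclusion
set ES_p).  A path P, identified with its internal vertex set, is
compatible with p iff ``IS_p ⊆ P`` and ``ES_p ∩ P = ∅`` — equivalent
to each mate's vector being a gapless run of P within its span.

Fragments touching a single segment carry no assembly information and
are dropped; identical (IS, ES) patterns are collapsed, scaling the
per-read reward by their multiplicity.  Pseudo reads injected by the
co-expression test are exempt from the |IS| >= 2 filter, since an
exclusivity constraint has |IS| = 1 by design.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .segmentation import SegmentVectorRead

__all__ = [
    "ReadPattern",
    "inclusion_exclusion",
    "group_fragments",
    "filter_informative",
    "is_compatible",
]


@dataclass(frozen=True)
class ReadPattern:
    """A collapsed (IS, ES) constraint with its objective reward.

    ``alpha`` already includes the multiplicity scaling, so the
    objective contribution of a satisfied pattern is simply alpha.
    """

    inclusion: frozenset[int]
    exclusion: frozenset[int]
    alpha: float
    multiplicity: int = 1
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.inclusion & self.exclusion:
            raise ValueError("inclusion and exclusion sets must be disjoint")
        if not self.inclusion:
            raise ValueError("a pattern needs at least one inclusion segment")
        if self.alpha < 0:
            raise ValueError("pattern reward must be non-negative")


def _validate_vector(b: Sequence[int], M: Optional[int]) -> None:
    if any(x >= y for x, y in zip(b, b[1:])):
        raise ValueError("segment vector must be strictly increasing")
    if b and (b[0] < 1 or (M is not None and b[-1] > M)):
        raise ValueError("segment index out of range")


def inclusion_exclusion(
    b: Sequence[int],
    b2: Optional[Sequence[int]] = None,
    M: Optional[int] = None,
) -> tuple[set[int], set[int]]:
    """IS and ES of a fragment (``b2=None`` for a single-end read).

    IS is the union of both vectors; ES collects every index strictly
    inside a mate's first..last span that the mate skips.  The gap
    between the two mates is deliberately unconstrained.
    """
    _validate_vector(b, M)
    mates = [tuple(b)]
    if b2 is not None:
        _validate_vector(b2, M)
        mates.append(tuple(b2))
    inc: set[int] = set()
    for m in mates:
        inc.update(m)
    exc: set[int] = set()
    for m in mates:
        if len(m) >= 2:
            exc.update(i for i in range(m[0] + 1, m[-1]) if i not in inc)
    exc -= inc
    return inc, exc


def group_fragments(
    reads: Iterable[SegmentVectorRead],
) -> tuple[list[tuple[tuple[int, ...], Optional[tuple[int, ...]]]], int]:
    """Pair mates by (sample, read id).

    Returns the fragments (vector, mate vector or None) and the number
    of lone mates discarded — a mate flagged as part of a pair whose
    partner landed outside the locus.
    """
    groups: dict[tuple[int, str], dict[int, tuple[int, ...]]] = defaultdict(dict)
    order: list[tuple[int, str]] = []
    for r in reads:
        key = (r.sample, r.read_id)
        if key not in groups:
            order.append(key)
        groups[key][r.mate] = r.vector
    fragments: list[tuple[tuple[int, ...], Optional[tuple[int, ...]]]] = []
    discarded = 0
    for key in order:
        mates = groups[key]
        if 0 in mates:
            fragments.append((mates[0], None))
        elif 1 in mates and 2 in mates:
            fragments.append((mates[1], mates[2]))
        else:
            discarded += 1
    return fragments, discarded


def filter_informative(
    fragments: Iterable[tuple[tuple[int, ...], Optional[tuple[int, ...]]]],
    alpha: float = 1.0,
    M: Optional[int] = None,
    pseudo: Iterable[ReadPattern] = (),
) -> list[ReadPattern]:
    """Build the informative pattern set R'.

    Real fragments with |IS| = 1 are excluded; identical patterns are
    collapsed with alpha scaled by multiplicity.  Pseudo patterns are
    appended unchanged.
    """
    tally: Counter[tuple[frozenset[int], frozenset[int]]] = Counter()
    for b, b2 in fragments:
        inc, exc = inclusion_exclusion(b, b2, M)
        if len(inc) < 2:
            continue
        tally[(frozenset(inc), frozenset(exc))] += 1
    patterns = [
        ReadPattern(inc, exc, alpha * n, multiplicity=n)
        for (inc, exc), n in sorted(
            tally.items(), key=lambda kv: (sorted(kv[0][0]), sorted(kv[0][1]))
        )
    ]
    patterns.extend(pseudo)
    return patterns


def is_compatible(pattern: ReadPattern, path: Iterable[int]) -> bool:
    """True iff the path contains all of IS and none of ES."""
    pset = set(path)
    return pattern.inclusion <= pset and not (pattern.exclusion & pset)
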