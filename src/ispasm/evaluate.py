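"""Transcript-level scoring of predictions against a reference set.

Two transcripts match when their exon chains are identical except for
the start of the first exon and the end of the last exon — assembly
cannot know the exact transcription start and polyadenylation sites,
but every splice boundary must be recovered exactly.  The rule is
vacuous for single-exon transcripts, which by default match on any
overlap.  With K one-to-one matched pairs among N reference and M
predicted transcripts, sensitivity is K/N and precision is K/M.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from .gtf import TranscriptRecord, read_transcripts

__all__ = ["MatchReport", "transcripts_match", "score_predictions"]

Chain = Union[TranscriptRecord, Sequence[tuple[int, int]]]


@dataclass
class MatchReport:
    n_matched: int
    n_truth: int
    n_pred: int
    matched_pairs: list[tuple[int, int]]   # (pred index, truth index)
    pred_matched: list[bool]
    truth_matched: list[bool]

    @property
    def sensitivity(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 0.0

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_pred if self.n_pred else 0.0

    def to_dict(self) -> dict:
        return {
            "matched": self.n_matched,
            "reference": self.n_truth,
            "predicted": self.n_pred,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
        }


def _as_record(x: Chain) -> TranscriptRecord:
    if isinstance(x, TranscriptRecord):
        return x
    return TranscriptRecord("anon", "anon", "?", ".", tuple(x))


def transcripts_match(
    a: Chain,
    b: Chain,
    single_exon_overlap: bool = True,
) -> bool:
    """Exon-chain identity up to the two free outer coordinates.

    Requires equal exon counts, identical internal boundaries, and —
    for multi-exon chains — identical first-exon end and last-exon
    start.  Chromosomes must agree; strands are compared only when
    both are set.
    """
    ra, rb = _as_record(a), _as_record(b)
    if not ra.exons or not rb.exons:
        raise ValueError("empty exon chain")
    if ra.chrom != rb.chrom and "?" not in (ra.chrom, rb.chrom):
        return False
    if ra.strand != rb.strand and "." not in (ra.strand, rb.strand):
        return False
    ea, eb = ra.exons, rb.exons
    if len(ea) != len(eb):
        return False
    if len(ea) == 1:
        if single_exon_overlap:
            return ea[0][0] < eb[0][1] and eb[0][0] < ea[0][1]
        return ea == eb
    if ea[0][1] != eb[0][1] or ea[-1][0] != eb[-1][0]:
        return False
    return ea[1:-1] == eb[1:-1]


def _overlap(a: TranscriptRecord, b: TranscriptRecord) -> int:
    return sum(
        max(0, min(e1, e2) - max(s1, s2))
        for s1, e1 in a.exons
        for s2, e2 in b.exons
    )


def score_predictions(
    pred: Union[str, Sequence[TranscriptRecord]],
    truth: Union[str, Sequence[TranscriptRecord]],
    single_exon_overlap: bool = True,
) -> MatchReport:
    """Greedy one-to-one matching in genomic order.

    Each predicted transcript credits at most one reference
    transcript (ties broken by longest exonic overlap), so duplicated
    predictions cannot inflate sensitivity.  Arguments may be GTF
    paths or records.
    """
    preds = read_transcripts(pred) if isinstance(pred, str) else list(pred)
    truths = read_transcripts(truth) if isinstance(truth, str) else list(truth)
    preds_sorted = sorted(
        range(len(preds)), key=lambda i: (preds[i].chrom, preds[i].start, preds[i].end)
    )
    truth_taken = [False] * len(truths)
    pred_matched = [False] * len(preds)
    pairs: list[tuple[int, int]] = []
    for pi in preds_sorted:
        best = None
        best_ov = -1
        for ti, t in enumerate(truths):
            if truth_taken[ti]:
                continue
            if transcripts_match(preds[pi], t, single_exon_overlap):
                ov = _overlap(preds[pi], t)
                if ov > best_ov:
                    best, best_ov = ti, ov
        if best is not None:
            truth_taken[best] = True
            pred_matched[pi] = True
            pairs.append((pi, best))
    return MatchReport(
        n_matched=len(pairs),
        n_truth=len(truths),
        n_pred=len(preds),
        matched_pairs=sorted(pairs),
        pred_matched=pred_matched,
        truth_matched=truth_taken,
    )
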