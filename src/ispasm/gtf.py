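"""Minimal transcript-level GTF interchange.

Internally everything is 0-based half-open; GTF records are written
and read with the 1-based closed convention.  Reading goes through
gffutils so attribute quoting and feature ordering quirks are handled
by an established parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["TranscriptRecord", "read_transcripts", "write_transcripts"]


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript as an ordered exon chain (0-based half-open)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    attributes: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript without exons")
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError("degenerate exon")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if e1 >= s2:
                raise ValueError("exons must be sorted and non-overlapping")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def read_transcripts(path: str) -> list[TranscriptRecord]:
    """Load transcripts (exon features grouped by transcript_id)."""
    import gffutils

    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - depends on input defects
        raise ValueError(f"malformed GTF {path!r}: {exc}") from exc
    groups: dict[str, dict] = {}
    order: list[str] = []
    for feat in db.all_features(featuretype="exon", order_by=("seqid", "start")):
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise ValueError(f"{path}: exon at line with no transcript_id")
        gid = feat.attributes.get("gene_id", [tid])[0]
        if tid not in groups:
            groups[tid] = {
                "gene": gid,
                "chrom": feat.seqid,
                "strand": feat.strand or ".",
                "exons": [],
            }
            order.append(tid)
        groups[tid]["exons"].append((feat.start - 1, feat.end))
    out = []
    for tid in order:
        g = groups[tid]
        out.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=g["gene"],
                chrom=g["chrom"],
                strand=g["strand"],
                exons=tuple(sorted(g["exons"])),
            )
        )
    return out


def _fmt_attrs(record: TranscriptRecord) -> str:
    parts = [
        f'gene_id "{record.gene_id}"',
        f'transcript_id "{record.transcript_id}"',
    ]
    for k, v in record.attributes.items():
        parts.append(f'{k} "{v}"')
    return "; ".join(parts) + ";"


def write_transcripts(
    path: str,
    records: Iterable[TranscriptRecord],
    source: str = "ispasm",
) -> None:
    """Write transcript + exon features, sorted by genomic position."""
    records = sorted(
        records, key=lambda r: (r.chrom, r.start, r.end, r.transcript_id)
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 2\n##source ispasm\n")
        for r in records:
            attrs = _fmt_attrs(r)
            fh.write(
                f"{r.chrom}\t{source}\ttranscript\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )
            for (s, e) in r.exons:
                fh.write(
                    f"{r.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                    f"{r.strand}\t.\t{attrs}\n"
                )
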