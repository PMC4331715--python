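"""Multi-sample RNA-seq read simulator with ground truth.

The generator plants gene loci with known isoform structures, draws
per-isoform expression independently per sample from a log-normal
model, places read (or fragment) starts uniformly along each
transcript, and emits perfect spliced alignments — mapping is taken
as exact for clean reads so the assembler is exercised in isolation
from any particular aligner.  Two noise mechanisms corrupt a chosen
fraction of reads:

* *noisy junction reads*: copies of real junction reads whose splice
  coordinates are shifted by 1-3 bases toward either side, mimicking
  mapper slippage around splice sites;
* *noisy intron reads*: contiguous reads placed uniformly inside the
  introns of a random transcript, mimicking intron retention and
  other intronic "dark matter" signal.

A selected fragment is replaced by its noisy counterpart, so the
noisy fraction of the output equals the configured error rate and
totals stay fixed.  All randomness flows through one seeded
generator, making every dataset bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .gtf import TranscriptRecord
from .segmentation import Alignment, GeneLocus, GenomicInterval, Segment, SegmentVectorRead

__all__ = [
    "SimConfig",
    "SimResult",
    "random_locus",
    "simulate_expression",
    "generate_reads",
    "add_noise",
    "simulate_dataset",
    "ambiguity_scenario",
    "write_sam",
]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    ``reads_per_sample`` counts fragments per locus per sample.
    ``error_rate`` is the fraction of fragments replaced by noise,
    split between the two mechanisms by ``junction_noise_frac``.
    Expression defaults (meanlog=1, sdlog=1) give the heavy-tailed
    spread typical of transcript abundances.
    """

    n_samples: int = 4
    read_length: int = 75
    paired: bool = True
    frag_mean: float = 250.0
    frag_sd: float = 25.0
    reads_per_sample: int = 800
    error_rate: float = 0.0
    junction_noise_frac: float = 0.5
    expr_meanlog: float = 1.0
    expr_sdlog: float = 1.0
    expression_mode: str = "independent"  # | "exclusive" | "coexpressed"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_samples < 1 or self.read_length < 1:
            raise ValueError("counts must be positive")


@dataclass
class SimResult:
    transcripts: list[TranscriptRecord]
    abundances: dict[str, float]            # transcript_id -> per-sample list
    alignments: list[list[Alignment]]       # per sample, coordinate-sorted
    n_noisy: int
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def fragments_total(self) -> int:
        ids = {(a.sample, a.read_id) for s in self.alignments for a in s}
        return len(ids)


def _tx_length(exons: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in exons)


def _tx_to_blocks(
    exons: Sequence[tuple[int, int]], tx_start: int, length: int
) -> tuple[tuple[int, int], ...]:
    """Map a transcript-coordinate interval onto genomic exon blocks."""
    blocks: list[tuple[int, int]] = []
    off = 0
    remaining = length
    pos = tx_start
    for (s, e) in exons:
        exlen = e - s
        if pos < off + exlen and remaining > 0:
            within = max(pos - off, 0)
            take = min(exlen - within, remaining)
            blocks.append((s + within, s + within + take))
            remaining -= take
            pos += take
        off += exlen
        if remaining <= 0:
            break
    if remaining > 0:
        raise ValueError("interval extends past transcript end")
    return tuple(blocks)


def random_locus(
    rng: np.random.Generator,
    n_isoforms: int,
    chrom: str = "chr1",
    offset: int = 0,
    gene_id: str = "gene",
) -> list[TranscriptRecord]:
    """Plant a locus: a full exon chain plus distinct exon-skip variants.

    Exons are 100-300 bp, introns 150-400 bp, so splice boundaries are
    well separated relative to the 1-3 bp junction-noise shifts.  All
    isoforms share the terminal exons; each additional isoform skips a
    different internal exon, which keeps every planted pair of
    isoforms distinguishable under the exon-chain matching rule.
    """
    if n_isoforms < 1:
        raise ValueError("need at least one isoform")
    n_exons = max(int(rng.integers(2, 6)), n_isoforms + 1) if n_isoforms == 1 else n_isoforms + 2
    exons: list[tuple[int, int]] = []
    pos = offset
    for _ in range(n_exons):
        ln = int(rng.integers(100, 301))
        exons.append((pos, pos + ln))
        pos += ln + int(rng.integers(150, 401))
    records = [
        TranscriptRecord(
            transcript_id=f"{gene_id}.1",
            gene_id=gene_id,
            chrom=chrom,
            strand=".",
            exons=tuple(exons),
        )
    ]
    internal = list(range(1, n_exons - 1))
    skips = rng.choice(internal, size=n_isoforms - 1, replace=False)
    for t, skip in enumerate(sorted(int(s) for s in skips), start=2):
        chain = tuple(ex for i, ex in enumerate(exons) if i != skip)
        records.append(
            TranscriptRecord(
                transcript_id=f"{gene_id}.{t}",
                gene_id=gene_id,
                chrom=chrom,
                strand=".",
                exons=chain,
            )
        )
    return records


def simulate_expression(
    n_isoforms: int,
    n_samples: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-isoform, per-sample abundances, shape (n_isoforms, F).

    ``independent`` draws every entry i.i.d. log-normal;
    ``exclusive`` expresses isoform i only in samples with
    k mod n_isoforms == i; ``coexpressed`` gives all isoforms of a
    sample the same abundance.  The latter two exist to reproduce
    across-sample co-expression and exclusivity patterns.
    """
    F = n_samples
    if cfg.expression_mode == "independent":
        return rng.lognormal(cfg.expr_meanlog, cfg.expr_sdlog, size=(n_isoforms, F))
    if cfg.expression_mode == "exclusive":
        ab = np.zeros((n_isoforms, F))
        for k in range(F):
            i = k % n_isoforms
            ab[i, k] = rng.lognormal(cfg.expr_meanlog, cfg.expr_sdlog)
        return ab
    if cfg.expression_mode == "coexpressed":
        per_sample = rng.lognormal(cfg.expr_meanlog, cfg.expr_sdlog, size=F)
        return np.tile(per_sample, (n_isoforms, 1))
    raise ValueError(f"unknown expression mode {cfg.expression_mode!r}")


def generate_reads(
    transcripts: Sequence[TranscriptRecord],
    abundances: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[list[list[Alignment]]]:
    """Simulate one locus: per-sample lists of fragments.

    A fragment is one single-end alignment or a mate pair.  Fragment
    counts per isoform are multinomial with probabilities equal to
    the abundance shares; starts are uniform along the transcript;
    paired fragments get a normal insert length clipped into
    [read_length, transcript length].  Transcripts shorter than a
    read are skipped.
    """
    L = cfg.read_length
    usable = [t for t in transcripts if _tx_length(t.exons) >= L]
    if len(usable) < len(transcripts):
        import warnings

        warnings.warn("transcripts shorter than the read length were skipped")
    if not usable:
        return [[] for _ in range(cfg.n_samples)]
    idx = [i for i, t in enumerate(transcripts) if t in usable]
    out: list[list[list[Alignment]]] = []
    for k in range(cfg.n_samples):
        share = abundances[idx, k].astype(float)
        frags: list[list[Alignment]] = []
        if share.sum() <= 0:
            out.append(frags)
            continue
        n_per_tx = rng.multinomial(cfg.reads_per_sample, share / share.sum())
        rid = 0
        for t_i, n in zip(idx, n_per_tx):
            tx = transcripts[t_i]
            tlen = _tx_length(tx.exons)
            for _ in range(int(n)):
                name = f"s{k}_f{rid}_{tx.transcript_id}"
                rid += 1
                if cfg.paired and tlen >= L:
                    frag = int(round(rng.normal(cfg.frag_mean, cfg.frag_sd)))
                    frag = min(max(frag, L), tlen)
                    start = int(rng.integers(0, tlen - frag + 1))
                    b1 = _tx_to_blocks(tx.exons, start, L)
                    mate2_len = min(L, frag)
                    b2 = _tx_to_blocks(tx.exons, start + frag - mate2_len, mate2_len)
                    frags.append(
                        [
                            Alignment(k, name, 1, tx.chrom, b1),
                            Alignment(k, name, 2, tx.chrom, b2),
                        ]
                    )
                else:
                    start = int(rng.integers(0, tlen - L + 1))
                    frags.append(
                        [Alignment(k, name, 0, tx.chrom, _tx_to_blocks(tx.exons, start, L))]
                    )
        out.append(frags)
    return out


def _shift_fragment(
    frag: Sequence[Alignment], rng: np.random.Generator, tag: str
) -> Optional[list[Alignment]]:
    """Copy a junction-containing fragment with every splice coordinate
    shifted by an independent offset in {±1, ±2, ±3}."""
    coords: set[int] = set()
    for a in frag:
        for donor, acceptor in a.junctions():
            coords.add(donor)
            coords.add(acceptor)
    if not coords:
        return None
    shift = {
        c: c + int(rng.choice([-3, -2, -1, 1, 2, 3])) for c in sorted(coords)
    }
    moved: list[Alignment] = []
    for a in frag:
        blocks = [list(b) for b in a.blocks]
        for bi in range(len(blocks)):
            if bi < len(blocks) - 1:
                blocks[bi][1] = shift.get(blocks[bi][1], blocks[bi][1])
            if bi > 0:
                blocks[bi][0] = shift.get(blocks[bi][0], blocks[bi][0])
        tb = tuple(tuple(b) for b in blocks)
        if any(s >= e for s, e in tb):
            return None
        if any(e1 > s2 for (_, e1), (s2, _) in zip(tb, tb[1:])):
            return None
        moved.append(Alignment(a.sample, f"{tag}{a.read_id}", a.mate, a.chrom, tb))
    return moved


def _intron_read(
    transcripts: Sequence[TranscriptRecord],
    sample: int,
    L: int,
    rng: np.random.Generator,
    tag: str,
) -> Optional[list[Alignment]]:
    spliced = [t for t in transcripts if len(t.exons) >= 2]
    for _ in range(50):
        if not spliced:
            return None
        tx = spliced[int(rng.integers(len(spliced)))]
        introns = [
            (e1, s2)
            for (_, e1), (s2, _) in zip(tx.exons, tx.exons[1:])
            if s2 - e1 >= L
        ]
        if not introns:
            continue
        positions = np.array([e - s - L + 1 for s, e in introns])
        choice = rng.choice(len(introns), p=positions / positions.sum())
        s, e = introns[int(choice)]
        start = int(rng.integers(s, e - L + 1))
        name = f"{tag}s{sample}_i{start}_{tx.transcript_id}"
        return [Alignment(sample, name, 0, tx.chrom, ((start, start + L),))]
    return None


def add_noise(
    per_sample_fragments: list[list[list[Alignment]]],
    transcripts: Sequence[TranscriptRecord],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[list[list[Alignment]]], int]:
    """Replace an ``error_rate`` fraction of fragments with noisy ones.

    Each fragment is independently selected with probability
    ``error_rate``; selected fragments become shifted-junction copies
    of a random junction fragment or fresh intronic reads, according
    to ``junction_noise_frac``.  Returns the noisy fragment count.
    """
    if cfg.error_rate <= 0:
        return per_sample_fragments, 0
    n_noisy = 0
    out: list[list[list[Alignment]]] = []
    for k, frags in enumerate(per_sample_fragments):
        junk = [f for f in frags if any(len(a.blocks) >= 2 for a in f)]
        new_frags: list[list[Alignment]] = []
        for fi, frag in enumerate(frags):
            if rng.random() >= cfg.error_rate:
                new_frags.append(frag)
                continue
            noisy: Optional[list[Alignment]] = None
            want_junction = rng.random() < cfg.junction_noise_frac
            if want_junction and junk:
                for _ in range(20):
                    cand = junk[int(rng.integers(len(junk)))]
                    noisy = _shift_fragment(cand, rng, f"nj_{k}_{fi}_")
                    if noisy is not None:
                        break
            if noisy is None:
                noisy = _intron_read(transcripts, k, cfg.read_length, rng, f"ni_{k}_{fi}_")
            if noisy is None:
                new_frags.append(frag)  # locus offers no noise source
                continue
            new_frags.append(noisy)
            n_noisy += 1
        out.append(new_frags)
    return out, n_noisy


def simulate_dataset(
    isoform_counts: Sequence[int],
    cfg: SimConfig,
    locus_spacing: int = 100_000,
) -> SimResult:
    """Simulate an ensemble of loci on one chromosome.

    ``isoform_counts[i]`` is the number of planted isoforms of locus
    i.  Loci are spaced far beyond any clustering gap, so each forms
    its own read cluster downstream.
    """
    rng = np.random.default_rng(cfg.seed)
    transcripts: list[TranscriptRecord] = []
    abundances: dict[str, list[float]] = {}
    per_sample: list[list[Alignment]] = [[] for _ in range(cfg.n_samples)]
    n_noisy = 0
    for li, k in enumerate(isoform_counts):
        txs = random_locus(rng, k, chrom="chr1", offset=li * locus_spacing,
                           gene_id=f"g{li + 1}")
        ab = simulate_expression(k, cfg.n_samples, cfg, rng)
        frags = generate_reads(txs, ab, cfg, rng)
        frags, noisy = add_noise(frags, txs, cfg, rng)
        n_noisy += noisy
        transcripts.extend(txs)
        for t_i, tx in enumerate(txs):
            abundances[tx.transcript_id] = [float(x) for x in ab[t_i]]
        for smp, fl in zip(per_sample, frags):
            for frag in fl:
                smp.extend(frag)
    for smp in per_sample:
        smp.sort(key=lambda a: (a.chrom, a.start, a.end, a.read_id, a.mate))
    return SimResult(
        transcripts=transcripts,
        abundances=abundances,
        alignments=per_sample,
        n_noisy=n_noisy,
        config=cfg,
    )


# --- constructed ambiguity scenario ---------------------------------------

def ambiguity_scenario(
    mode: str,
    reads_per_pattern: int = 30,
    read_length: int = 75,
) -> tuple[GeneLocus, list[SegmentVectorRead], list[tuple[tuple[int, int], ...]]]:
    """Two samples, one graph, opposite co-expression patterns.

    Five 200 bp segments; segments 2 and 4 are the alternative pair.
    ``mode='exclusive'``: sample 0 expresses (1,2,3,5) and sample 1
    expresses (1,3,4,5), so segments 2 and 4 never co-occur.
    ``mode='coexpressed'``: both samples express (1,2,3,4,5) and
    (1,3,5) equally, so segments 2 and 4 rise and fall together.
    Both modes induce the same connectivity graph; only the
    across-sample expression distinguishes them.  Returns the locus,
    the segment-vector reads, and the true exon chains.
    """
    seg_len, gap = 200, 200
    segments = [
        Segment(i + 1, GenomicInterval("chrA", i * (seg_len + gap),
                                       i * (seg_len + gap) + seg_len))
        for i in range(5)
    ]
    locus = GeneLocus("ambig", "chrA", segments, n_samples=2,
                      read_length=read_length)

    def span(idx: Sequence[int]) -> tuple[tuple[int, int], ...]:
        return tuple((segments[i - 1].start, segments[i - 1].end) for i in idx)

    if mode == "exclusive":
        per_sample_paths = {0: [(1, 2, 3, 5)], 1: [(1, 3, 4, 5)]}
        truths = [span((1, 2, 3, 5)), span((1, 3, 4, 5))]
    elif mode == "coexpressed":
        per_sample_paths = {0: [(1, 2, 3, 4, 5), (1, 3, 5)],
                            1: [(1, 2, 3, 4, 5), (1, 3, 5)]}
        truths = [span((1, 2, 3, 4, 5)), span((1, 3, 5))]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # paired fragments covering consecutive junction pairs, so that the
    # co-occurrence of every adjacent splicing choice is witnessed by
    # molecules — as it would be in any real paired-end library
    reads: list[SegmentVectorRead] = []
    rid = 0
    for sample, paths in per_sample_paths.items():
        for path in paths:
            pairs = list(zip(path, path[1:]))
            for x, (a, b) in enumerate(pairs):
                mate2 = pairs[x + 1] if x + 1 < len(pairs) else pairs[x - 1]
                for _ in range(reads_per_pattern):
                    name = f"r{rid}"
                    rid += 1
                    if len(pairs) == 1:
                        reads.append(SegmentVectorRead(sample, name, 0, (a, b)))
                    else:
                        reads.append(SegmentVectorRead(sample, name, 1, (a, b)))
                        reads.append(SegmentVectorRead(sample, name, 2, mate2))
    return locus, reads, truths


def write_sam(path: str, alignments: Sequence[Alignment],
              chrom_lengths: dict[str, int]) -> None:
    """Write simulated alignments as plain SAM (sequence-free)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in sorted(chrom_lengths.items())],
    }
    tid = {c: i for i, (c, _) in enumerate(sorted(chrom_lengths.items()))}
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for a in sorted(alignments, key=lambda x: (x.chrom, x.start)):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = a.read_id
            rec.reference_id = tid[a.chrom]
            rec.reference_start = a.start
            rec.mapping_quality = 60
            flag = 0
            if a.mate:
                flag |= 0x1 | (0x40 if a.mate == 1 else 0x80)
            rec.flag = flag
            cigar = []
            prev_end = None
            for (s, e) in a.blocks:
                if prev_end is not None:
                    cigar.append((3, s - prev_end))  # N
                cigar.append((0, e - s))             # M
                prev_end = e
            rec.cigartuples = cigar
            fh.write(rec)
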