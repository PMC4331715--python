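import numpy as np
import pytest

from ispasm.segmentation import (
    Alignment,
    GeneLocus,
    GenomicInterval,
    Segment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_locus(seg_bounds, n_samples=1, read_length=75, locus_id="L"):
    """Build a GeneLocus from (start, end) tuples."""
    segs = [
        Segment(i + 1, GenomicInterval("chr1", s, e))
        for i, (s, e) in enumerate(seg_bounds)
    ]
    return GeneLocus(locus_id, "chr1", segs, n_samples, read_length)


def aln(start, *block_lens_and_gaps, sample=0, read_id="r", mate=0,
        chrom="chr1"):
    """Alignment from alternating block length / gap length integers."""
    blocks = []
    pos = start
    for i, ln in enumerate(block_lens_and_gaps):
        if i % 2 == 0:
            blocks.append((pos, pos + ln))
        pos += ln
    return Alignment(sample, read_id, mate, chrom, tuple(blocks))
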