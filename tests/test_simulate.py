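"""Simulator: expression model, read placement, noise mechanisms."""

import numpy as np
import pytest

from ispasm.gtf import TranscriptRecord
from ispasm.simulate import (
    SimConfig,
    add_noise,
    generate_reads,
    random_locus,
    simulate_dataset,
    simulate_expression,
)


def _tx(exons, tid="t1"):
    return TranscriptRecord(tid, "g", "chr1", ".", tuple(exons))


class TestExpression:
    def test_seeded_reproducibility(self):
        cfg = SimConfig(seed=3)
        a = simulate_expression(3, 4, cfg, np.random.default_rng(3))
        b = simulate_expression(3, 4, cfg, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_zero_sd_gives_equal_abundances(self):
        cfg = SimConfig(expr_sdlog=0.0)
        ab = simulate_expression(2, 5, cfg, np.random.default_rng(0))
        assert np.allclose(ab, np.exp(cfg.expr_meanlog))

    def test_log_abundance_mean_matches_model(self):
        cfg = SimConfig(expr_meanlog=1.0, expr_sdlog=1.0)
        ab = simulate_expression(1, 1000, cfg, np.random.default_rng(1))
        se = cfg.expr_sdlog / np.sqrt(1000)
        assert abs(np.log(ab).mean() - 1.0) < 3 * se

    def test_exclusive_mode_partitions_samples(self):
        cfg = SimConfig(expression_mode="exclusive")
        ab = simulate_expression(2, 4, cfg, np.random.default_rng(0))
        assert np.all((ab > 0).sum(axis=0) == 1)

    def test_independent_samples_are_uncorrelated(self):
        cfg = SimConfig()
        rng = np.random.default_rng(2)
        draws = np.array([
            simulate_expression(2, 2, cfg, rng)[:, 0] for _ in range(500)
        ])
        r = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert abs(r) < 0.15


class TestGenerateReads:
    def test_single_exon_transcript_has_unspliced_reads(self):
        tx = _tx([(0, 500)])
        cfg = SimConfig(n_samples=1, paired=False, reads_per_sample=200)
        frags = generate_reads([tx], np.array([[1.0]]), cfg,
                               np.random.default_rng(0))
        for frag in frags[0]:
            assert len(frag) == 1 and len(frag[0].blocks) == 1

    def test_read_counts_proportional_to_abundance(self):
        txs = [_tx([(0, 1000)], "a"), _tx([(0, 1000)], "b")]
        ab = np.array([[2.0], [1.0]])
        cfg = SimConfig(n_samples=1, paired=False, reads_per_sample=9000)
        frags = generate_reads(txs, ab, cfg, np.random.default_rng(5))
        n_a = sum("_a" in f[0].read_id for f in frags[0])
        n, p = 9000, 2 / 3
        se = np.sqrt(n * p * (1 - p))
        assert abs(n_a - n * p) < 3 * se

    def test_junction_coverage_tracks_abundance(self):
        # doubling abundance roughly doubles junction-crossing reads
        exons = [(0, 300), (500, 800)]
        txs = [_tx(exons, "a"), _tx(exons, "b")]
        cfg = SimConfig(n_samples=1, paired=False, reads_per_sample=6000)
        frags = generate_reads(txs, np.array([[2.0], [1.0]]), cfg,
                               np.random.default_rng(8))
        cross = {"a": 0, "b": 0}
        for f in frags[0]:
            if len(f[0].blocks) == 2:
                cross["a" if "_a" in f[0].read_id else "b"] += 1
        ratio = cross["a"] / cross["b"]
        assert 1.6 < ratio < 2.5

    def test_short_transcript_skipped_with_warning(self):
        txs = [_tx([(0, 20)], "tiny"), _tx([(0, 500)], "ok")]
        cfg = SimConfig(n_samples=1, paired=False, reads_per_sample=50)
        with pytest.warns(UserWarning):
            frags = generate_reads(txs, np.array([[1.0], [1.0]]), cfg,
                                   np.random.default_rng(0))
        assert all("_ok" in f[0].read_id for f in frags[0])

    def test_paired_fragments_have_two_mates(self):
        tx = _tx([(0, 300), (500, 900)])
        cfg = SimConfig(n_samples=1, paired=True, reads_per_sample=100)
        frags = generate_reads([tx], np.array([[1.0]]), cfg,
                               np.random.default_rng(0))
        assert all(len(f) == 2 for f in frags[0])
        for m1, m2 in frags[0]:
            assert (m1.mate, m2.mate) == (1, 2)
            assert m1.read_id == m2.read_id


class TestNoise:
    def _clean(self, n=1000, seed=0):
        tx = _tx([(0, 300), (500, 800), (1000, 1300)])
        cfg = SimConfig(n_samples=1, paired=False, reads_per_sample=n,
                        error_rate=0.1, seed=seed)
        frags = generate_reads([tx], np.array([[1.0]]), cfg,
                               np.random.default_rng(seed))
        return tx, cfg, frags

    def test_zero_error_rate_is_identity(self):
        tx, cfg, frags = self._clean()
        cfg.error_rate = 0.0
        out, n_noisy = add_noise(frags, [tx], cfg, np.random.default_rng(1))
        assert n_noisy == 0 and out == frags

    def test_noisy_fraction_matches_rate(self):
        tx, cfg, frags = self._clean(n=20000)
        out, n_noisy = add_noise(frags, [tx], cfg, np.random.default_rng(1))
        n, p = 20000, 0.1
        se = np.sqrt(n * p * (1 - p))
        assert abs(n_noisy - n * p) < 3 * se
        assert sum(len(f) for f in out[0]) == sum(len(f) for f in frags[0])

    def test_shifted_junctions_miss_true_boundaries_by_1_to_3(self):
        tx, cfg, frags = self._clean(n=5000)
        out, _ = add_noise(frags, [tx], cfg, np.random.default_rng(2))
        true_bounds = {300, 500, 800, 1000}
        checked = 0
        for f in out[0]:
            for a in f:
                if not a.read_id.startswith("nj_"):
                    continue
                for donor, acceptor in a.junctions():
                    for c in (donor, acceptor):
                        dist = min(abs(c - b) for b in true_bounds)
                        assert 1 <= dist <= 3
                        checked += 1
        assert checked > 50

    def test_intron_reads_fall_inside_introns(self):
        tx, cfg, frags = self._clean(n=5000)
        out, _ = add_noise(frags, [tx], cfg, np.random.default_rng(3))
        introns = [(300, 500), (800, 1000)]
        n_intron = 0
        for f in out[0]:
            for a in f:
                if a.read_id.startswith("ni_"):
                    assert len(a.blocks) == 1
                    s, e = a.blocks[0]
                    assert any(s >= i0 and e <= i1 for i0, i1 in introns)
                    n_intron += 1
        assert n_intron > 50


class TestDataset:
    def test_bit_reproducible_under_seed(self):
        cfg = SimConfig(n_samples=2, reads_per_sample=100, error_rate=0.05,
                        seed=9)
        a = simulate_dataset([1, 2], cfg)
        b = simulate_dataset([1, 2], cfg)
        assert a.alignments == b.alignments
        assert a.abundances == b.abundances

    def test_planted_structures(self):
        rng = np.random.default_rng(4)
        txs = random_locus(rng, 4)
        assert len(txs) == 4
        full = txs[0].exons
        for t in txs[1:]:
            assert len(t.exons) == len(full) - 1
            assert set(t.exons) < set(full)
        # all isoforms pairwise distinguishable under exon-chain identity
        chains = {t.exons for t in txs}
        assert len(chains) == 4

    def test_loci_are_well_separated(self):
        cfg = SimConfig(n_samples=1, reads_per_sample=50, seed=0)
        sim = simulate_dataset([1, 1, 1], cfg)
        genes = sorted({t.gene_id for t in sim.transcripts})
        assert genes == ["g1", "g2", "g3"]
        spans = [
            (min(t.start for t in sim.transcripts if t.gene_id == g),
             max(t.end for t in sim.transcripts if t.gene_id == g))
            for g in genes
        ]
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            assert s2 - e1 > 10_000
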